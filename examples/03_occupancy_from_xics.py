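"""Phosphosite occupancy from a pair of extracted ion chromatograms.

Builds a synthetic XIC pair with a planted 20% occupancy (Gaussian peaks
plus 5% apex-relative noise), integrates both peaks, and reports the
relative stoichiometry: modified area / (modified + unmodified area).
"""

from ptmforge.synth import gen_xic_pair
from ptmforge.xic import integrate_peak, occupancy

t_mod, t_unmod, truth = gen_xic_pair(occupancy=0.20, total_area=1e6, seed=11)

p_mod = integrate_peak(t_mod)
p_unmod = integrate_peak(t_unmod)
res = occupancy(p_mod.area, p_unmod.area)

print(f"modified peak:   apex {p_mod.rt_apex:.2f} min, area {p_mod.area:12.0f}")
print(f"unmodified peak: apex {p_unmod.rt_apex:.2f} min, area {p_unmod.area:12.0f}")
print(f"occupancy: {res.occupancy:.3f}  (planted {truth['occupancy']})")
# The occupancy is a relative stoichiometry: no correction for different
# ionization efficiencies of the phospho and unmodified forms.
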