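"""Theoretical m/z of the four derivatized H3K36 methyl-peptidoforms.

Histones are propionylated before tryptic digestion so that K-rich
peptides cleave uniformly. Free and monomethyl lysines accept a propionyl
group; di- and tri-methyl lysines are blocked. The four methylation
states of the K36-containing tryptic peptide KSAPSTGGVKKPHR therefore
carry different modification sets, and each has a distinct m/z at z=3
that is used to extract its ion chromatogram.
"""

from ptmforge import chem

print(f"peptide: {chem.H3_K36_PEPTIDE} (K36 = peptide position "
      f"{chem.H3_K36_PEPTIDE_POSITION}), charge {chem.H3_K36_CHARGE}+\n")
for state in ("me0", "me1", "me2", "me3"):
    pf = chem.h3k36_peptidoform(state)
    n_prop = sum(m.name == "propionyl" for _, m in pf.mods)
    print(f"{state}: m/z = {chem.mz(pf):8.2f}   "
          f"({n_prop} propionyl, mass {chem.monoisotopic_mass(pf):.4f} Da)")

# Each printed m/z is the center of the 10 ppm extraction window used for
# quantification; me0/me1 carry 3 propionyl groups, me2/me3 only 2.
lo, hi = chem.ppm_window(chem.mz(chem.h3k36_peptidoform("me0")), 10)
print(f"\nme0 10-ppm XIC window: {lo:.4f} - {hi:.4f} Th")
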