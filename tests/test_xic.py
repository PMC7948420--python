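"""XIC peak integration, occupancy, isobaric disambiguation, methyl fractions."""

import math

import numpy as np
import pytest

from ptmforge.synth import gen_xic_pair
from ptmforge.xic import (
    ChromatogramTrace,
    disambiguate_isobaric,
    integrate_peak,
    methylation_distribution,
    occupancy,
)


def make_gaussian_trace(area=1000.0, center=10.0, sigma=0.1, rt_max=20.0, dt=0.005):
    rt = np.arange(0, rt_max, dt)
    amp = area / (sigma * math.sqrt(2 * math.pi))
    return ChromatogramTrace(rt, amp * np.exp(-0.5 * ((rt - center) / sigma) ** 2))


class TestIntegration:
    def test_rectangular_pulse_area(self):
        rt = np.arange(0, 10, 0.001)
        inten = np.where((rt >= 4) & (rt <= 5), 100.0, 0.0)
        peak = integrate_peak(ChromatogramTrace(rt, inten))
        assert peak.area == pytest.approx(100.0, rel=0.01)

    def test_gaussian_analytic_area(self):
        peak = integrate_peak(make_gaussian_trace(area=2500.0))
        assert peak.area == pytest.approx(2500.0, rel=0.01)
        assert peak.rt_start < peak.rt_apex < peak.rt_end

    def test_flat_zero_trace_flagged_empty(self):
        rt = np.linspace(0, 10, 100)
        peak = integrate_peak(ChromatogramTrace(rt, np.zeros_like(rt)))
        assert peak.area == 0.0 and peak.empty

    def test_explicit_window_overrides_detection(self):
        trace = make_gaussian_trace(area=1000.0, center=10.0)
        peak = integrate_peak(trace, rt_window=(9.0, 11.0))
        assert peak.area == pytest.approx(1000.0, rel=0.01)
        assert peak.rt_start >= 9.0 and peak.rt_end <= 11.0

    def test_invalid_trace_rejected(self):
        with pytest.raises(ValueError):
            ChromatogramTrace(np.array([1.0, 1.0, 2.0]), np.array([0.0, 1.0, 0.0]))
        with pytest.raises(ValueError):
            ChromatogramTrace(np.array([1.0, 2.0]), np.array([-1.0, 1.0]))


class TestOccupancy:
    def test_arithmetic(self):
        assert occupancy(1.0, 3.0).occupancy == pytest.approx(0.25)
        assert occupancy(0.0, 5.0).occupancy == 0.0

    def test_both_zero_undefined(self):
        res = occupancy(0.0, 0.0)
        assert not res.defined and math.isnan(res.occupancy)

    def test_scale_invariance(self):
        a = occupancy(2.0, 6.0).occupancy
        b = occupancy(2000.0, 6000.0).occupancy
        assert a == pytest.approx(b, abs=1e-12)

    def test_planted_occupancy_recovered(self):
        t_mod, t_unmod, truth = gen_xic_pair(0.20, seed=42)
        res = occupancy(integrate_peak(t_mod).area, integrate_peak(t_unmod).area)
        assert res.occupancy == pytest.approx(0.20, abs=0.02)

    def test_noise_free_recovery_tight(self):
        t_mod, t_unmod, _ = gen_xic_pair(0.25, noise_frac=0.0, seed=1)
        res = occupancy(integrate_peak(t_mod).area, integrate_peak(t_unmod).area)
        assert res.occupancy == pytest.approx(0.25, abs=0.01)


class TestDisambiguation:
    def test_identity_assignment(self):
        traces = [make_gaussian_trace(center=10.0), make_gaussian_trace(center=20.0)]
        out = disambiguate_isobaric(traces, [10.0, 20.0])
        assert [a.assigned for a in out] == [0, 1]
        assert not any(a.ambiguous for a in out)

    def test_symmetric_tie_flagged(self):
        out = disambiguate_isobaric([make_gaussian_trace(center=15.0)], [10.0, 20.0])
        assert out[0].assigned is None and out[0].ambiguous

    def test_three_planted_peaks_recovered(self):
        centers = [5.0, 10.0, 16.0]
        traces = [make_gaussian_trace(center=c) for c in centers]
        out = disambiguate_isobaric(traces, centers)
        assert [a.assigned for a in out] == [0, 1, 2]

    def test_duplicate_expectations_rejected(self):
        with pytest.raises(ValueError):
            disambiguate_isobaric([make_gaussian_trace()], [10.0, 10.0])


class TestMethylDistribution:
    def test_uniform(self):
        dist = methylation_distribution({"me0": 100, "me1": 100, "me2": 100, "me3": 100})
        assert dist.as_tuple() == pytest.approx((0.25, 0.25, 0.25, 0.25))

    def test_absent_state(self):
        dist = methylation_distribution({"me0": 100, "me1": 100, "me2": 200, "me3": 0})
        assert dist.as_tuple() == pytest.approx((0.25, 0.25, 0.5, 0.0))

    def test_fractions_sum_to_one(self):
        dist = methylation_distribution({"me0": 13.3, "me1": 7.1, "me2": 0.2, "me3": 99.0})
        assert sum(dist.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_flags_ablation(self):
        dist = methylation_distribution({s: 0.0 for s in ("me0", "me1", "me2", "me3")})
        assert dist.all_absent

    def test_label_permutation_permutes_fractions(self):
        areas = {"me0": 40.0, "me1": 15.0, "me2": 15.0, "me3": 30.0}
        dist = methylation_distribution(areas)
        swapped = methylation_distribution(
            {"me0": areas["me3"], "me1": areas["me2"], "me2": areas["me1"], "me3": areas["me0"]}
        )
        assert dist.fractions["me0"] == pytest.approx(swapped.fractions["me3"])
        assert dist.fractions["me1"] == pytest.approx(swapped.fractions["me2"])

    def test_planted_distribution_recovered(self):
        planted = (0.40, 0.15, 0.15, 0.30)
        total = 5e5
        areas = {}
        for state, frac in zip(("me0", "me1", "me2", "me3"), planted):
            rt = np.arange(0, 20, 0.005)
            amp = frac * total / (0.1 * math.sqrt(2 * math.pi))
            rng = np.random.default_rng(hash(state) % 2**31)
            inten = np.clip(
                amp * np.exp(-0.5 * ((rt - 10) / 0.1) ** 2)
                + rng.normal(0, 0.05 * amp, rt.size),
                0,
                None,
            )
            areas[state] = integrate_peak(ChromatogramTrace(rt, inten)).area
        dist = methylation_distribution(areas)
        assert dist.as_tuple() == pytest.approx(planted, abs=0.02)
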