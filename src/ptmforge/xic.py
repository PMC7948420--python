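"""Extracted-ion-chromatogram peak integration and relative stoichiometry.

Relative occupancy of a phosphosite is the area of the phosphopeptide XIC
peak divided by the total (phospho + unmodified) area; H3K36 methylation
stoichiometry is each methyl-state area over the four-state total. The
integrator is deliberately simple and fully deterministic: a decile-median
baseline, derivative-free bound detection from the apex, and trapezoidal
integration of the baseline-subtracted signal. Peak bounds can be forced
with an explicit retention-time window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChromatogramTrace",
    "PeakIntegration",
    "OccupancyResult",
    "MethylDistribution",
    "PeakAssignment",
    "integrate_peak",
    "occupancy",
    "disambiguate_isobaric",
    "methylation_distribution",
]

METHYL_STATES = ("me0", "me1", "me2", "me3")


@dataclass(frozen=True)
class ChromatogramTrace:
    """Retention time (minutes, strictly increasing) vs intensity."""

    rt: np.ndarray
    intensity: np.ndarray
    target_mz: float | None = None
    tol_ppm: float = 10.0

    def __post_init__(self) -> None:
        rt = np.asarray(self.rt, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "rt", rt)
        object.__setattr__(self, "intensity", inten)
        if rt.ndim != 1 or rt.shape != inten.shape or rt.size < 2:
            raise ValueError("rt and intensity must be equal-length 1-D, length >= 2")
        if not np.all(np.diff(rt) > 0):
            raise ValueError("rt must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class PeakIntegration:
    rt_start: float
    rt_apex: float
    rt_end: float
    area: float  # intensity * minutes
    baseline: float
    empty: bool = False  # set when the trace carries no signal


def _baseline(intensity: np.ndarray) -> float:
    """Median of the lowest decile of intensities (>= 1 point)."""
    k = max(1, intensity.size // 10)
    lowest = np.partition(intensity, k - 1)[:k]
    return float(np.median(lowest))


def integrate_peak(
    trace: ChromatogramTrace,
    rt_window: tuple[float, float] | None = None,
    bound_frac: float = 0.005,
) -> PeakIntegration:
    """Integrate the dominant peak of an XIC trace.

    Baseline is the median of the lowest decile of in-window intensities.
    If ``rt_window`` is not given, bounds are found by walking outward
    from the apex until the baseline-subtracted signal falls below
    ``bound_frac`` of the apex signal. Area is the trapezoidal integral
    of the baseline-subtracted signal, clipped at zero.
    """
    rt, inten = trace.rt, trace.intensity
    if rt_window is not None:
        lo, hi = rt_window
        sel = (rt >= lo) & (rt <= hi)
        if sel.sum() < 2:
            raise ValueError("rt_window selects fewer than 2 points")
        rt, inten = rt[sel], inten[sel]

    base = _baseline(inten)
    signal = inten - base
    apex_idx = int(np.argmax(signal))
    apex_sig = signal[apex_idx]
    if apex_sig <= 0:
        return PeakIntegration(rt[0], rt[0], rt[-1], 0.0, base, empty=True)

    if rt_window is not None:
        i0, i1 = 0, len(rt) - 1
    else:
        cut = bound_frac * apex_sig
        i0 = apex_idx
        while i0 > 0 and signal[i0 - 1] > cut:
            i0 -= 1
        i1 = apex_idx
        while i1 < len(rt) - 1 and signal[i1 + 1] > cut:
            i1 += 1
    area = float(np.trapezoid(np.clip(signal[i0 : i1 + 1], 0, None), rt[i0 : i1 + 1]))
    return PeakIntegration(
        rt_start=float(rt[i0]),
        rt_apex=float(rt[apex_idx]),
        rt_end=float(rt[i1]),
        area=max(area, 0.0),
        baseline=base,
    )


@dataclass(frozen=True)
class OccupancyResult:
    area_modified: float
    area_unmodified: float
    occupancy: float  # NaN when both areas are zero

    @property
    def defined(self) -> bool:
        return not math.isnan(self.occupancy)


def occupancy(area_mod: float, area_unmod: float) -> OccupancyResult:
    """Relative occupancy: modified / (modified + unmodified) peak area.

    Ionization-efficiency differences between the modified and unmodified
    forms are not corrected; the value is a relative stoichiometry.
    Both areas zero yields an undefined (NaN) occupancy, not an error.
    """
    if area_mod < 0 or area_unmod < 0:
        raise ValueError("areas must be non-negative")
    total = area_mod + area_unmod
    frac = area_mod / total if total > 0 else math.nan
    return OccupancyResult(area_mod, area_unmod, frac)


@dataclass(frozen=True)
class PeakAssignment:
    trace_index: int
    peak_rt: float
    assigned: int | None  # index into expected_rts, None if unassigned
    ambiguous: bool


def disambiguate_isobaric(
    traces: list[ChromatogramTrace],
    expected_rts: list[float],
    tol_min: float = 0.5,
) -> list[PeakAssignment]:
    """Assign each trace's apex peak to the nearest expected retention time.

    Isobaric peptidoforms share an m/z window and are told apart purely by
    retention time. A peak whose two nearest expectations are equidistant
    (within ``tol_min``) is flagged ambiguous and left unassigned.
    """
    if len(set(expected_rts)) != len(expected_rts):
        raise ValueError("expected retention times must be distinct")
    out = []
    for idx, trace in enumerate(traces):
        peak = integrate_peak(trace)
        if peak.empty:
            out.append(PeakAssignment(idx, peak.rt_apex, None, False))
            continue
        dists = sorted(
            (abs(peak.rt_apex - ert), j) for j, ert in enumerate(expected_rts)
        )
        if len(dists) > 1 and dists[1][0] - dists[0][0] <= tol_min:
            out.append(PeakAssignment(idx, peak.rt_apex, None, True))
        else:
            out.append(PeakAssignment(idx, peak.rt_apex, dists[0][1], False))
    return out


@dataclass(frozen=True)
class MethylDistribution:
    """Fractional distribution over ordered methylation states me0..me3."""

    areas: dict
    fractions: dict
    all_absent: bool = False  # knockout case: no state detected

    def as_tuple(self) -> tuple[float, float, float, float]:
        return tuple(self.fractions[s] for s in METHYL_STATES)


def methylation_distribution(areas: dict[str, float]) -> MethylDistribution:
    """Normalize me0..me3 peak areas to state fractions summing to 1.

    All-zero input (e.g. a methyltransferase-deletion strain) returns the
    distribution flagged ``all_absent`` with NaN fractions.
    """
    vals = {s: float(areas.get(s, 0.0)) for s in METHYL_STATES}
    if any(v < 0 for v in vals.values()):
        raise ValueError("areas must be non-negative")
    total = sum(vals.values())
    if total == 0:
        return MethylDistribution(vals, {s: math.nan for s in METHYL_STATES}, True)
    return MethylDistribution(vals, {s: v / total for s, v in vals.items()})
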