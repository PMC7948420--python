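"""Per-residue sequence coverage across a multi-protease / multi-fragmentation design.

Each (protease, fragmentation) pair is one experiment; depth counts how
many distinct experiments observed a peptide covering each residue, and
combined coverage is the fraction of residues observed at least once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CoverageProfile", "CoverageMappingError", "map_peptides"]


class CoverageMappingError(ValueError):
    """One or more peptides could not be located in the protein."""


@dataclass
class CoverageProfile:
    protein_id: str
    length: int
    depth: np.ndarray  # per-residue experiment count
    per_experiment_coverage: dict  # experiment -> fraction
    combined_coverage: float  # fraction of residues with depth >= 1

    @property
    def combined_coverage_pct(self) -> float:
        """Percent coverage rounded to 1 decimal (reporting convention)."""
        return round(100.0 * self.combined_coverage, 1)

    def depth_histogram(self) -> dict[int, int]:
        vals, counts = np.unique(self.depth, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def depth_track(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": np.arange(1, self.length + 1), "depth": self.depth}
        )


def map_peptides(
    protein: str,
    peptides: list[tuple[str, object]],
    protein_id: str = "protein",
) -> CoverageProfile:
    """Map (peptide, experiment) observations onto a protein.

    Peptides must match exactly as substrings; every occurrence of a
    peptide contributes coverage. Raises :class:`CoverageMappingError`
    listing all unlocatable peptides.
    """
    n = len(protein)
    missing = sorted({p for p, _ in peptides if protein.find(p) < 0})
    if missing:
        raise CoverageMappingError(f"peptides not found in protein: {missing}")

    masks: dict[object, np.ndarray] = {}
    for pep, exp in peptides:
        mask = masks.setdefault(exp, np.zeros(n, dtype=bool))
        start = protein.find(pep)
        while start >= 0:
            mask[start : start + len(pep)] = True
            start = protein.find(pep, start + 1)

    depth = np.zeros(n, dtype=int)
    per_exp = {}
    for exp, mask in masks.items():
        depth += mask
        per_exp[exp] = float(mask.mean())
    combined = float((depth > 0).mean()) if n else 0.0
    return CoverageProfile(protein_id, n, depth, per_exp, combined)
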