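"""PSM quality filtering and collation into non-redundant peptidoforms and sites.

A peptide-spectrum match (PSM) table is a pandas DataFrame with one row
per match. Required columns::

    protein_id   str
    peptide      str   plain residue sequence
    mods         str   "pos:name;pos:name" (1-based peptide positions), "" if none
    protease     str   trypsin | lysarginase | aspn | chymotrypsin
    fragmentation str  HCD | EThcD
    ion_score    float
    expect_p     float
    psm_fdr      float  fraction in [0, 1]
    loc_prob     str   "pos:percent;..." per modified site, "" if none
    retention_time, precursor_mz, charge  (pass-through metadata)

Quality filtering applies the standard high-stringency thresholds for
modified peptides: FDR < 0.01 (strict), ion score >= 30 (inclusive),
expectation value p < 0.05 (strict), and site localization probability
>= 95% (inclusive) for *every* localized site on the PSM. A PSM failing
any criterion contributes no sites at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "FilterThresholds",
    "SchemaError",
    "MappingError",
    "SiteAnnotation",
    "CollationSummary",
    "filter_psms",
    "collate_sites",
    "parse_mods_field",
    "parse_locprob_field",
]

REQUIRED_COLUMNS = (
    "protein_id",
    "peptide",
    "mods",
    "protease",
    "fragmentation",
    "ion_score",
    "expect_p",
    "psm_fdr",
    "loc_prob",
)


class SchemaError(ValueError):
    """A required PSM table column is missing."""


class MappingError(ValueError):
    """A peptide could not be located in its parent protein."""


@dataclass(frozen=True)
class FilterThresholds:
    """PSM admission thresholds; defaults are the standard stringent cutoffs."""

    fdr: float = 0.01
    score: float = 30.0
    expect: float = 0.05
    locprob: float = 95.0

    def __post_init__(self) -> None:
        if min(self.fdr, self.score, self.expect, self.locprob) < 0:
            raise ValueError("thresholds must be non-negative")


def _check_schema(records: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise SchemaError(f"PSM table missing required column: {col!r}")


def parse_mods_field(text: str) -> list[tuple[int, str]]:
    """Parse "pos:name;pos:name" into [(position, mod_name), ...]."""
    if not isinstance(text, str) or not text.strip():
        return []
    out = []
    for item in text.split(";"):
        pos, name = item.split(":")
        out.append((int(pos), name))
    return out


def parse_locprob_field(text: str) -> dict[int, float]:
    """Parse "pos:percent;..." into {position: percent}."""
    if not isinstance(text, str) or not text.strip():
        return {}
    out = {}
    for item in text.split(";"):
        pos, prob = item.split(":")
        out[int(pos)] = float(prob)
    return out


def _locprobs_pass(text: str, cutoff: float) -> bool:
    return all(p >= cutoff for p in parse_locprob_field(text).values())


def filter_psms(
    records: pd.DataFrame, thresholds: FilterThresholds = FilterThresholds()
) -> pd.DataFrame:
    """Return the subset of PSMs passing every quality criterion.

    Boundary semantics follow the printed inequalities: FDR and
    expectation value strict (<), ion score and localization inclusive (>=).
    """
    _check_schema(records)
    t = thresholds
    keep = (
        (records["psm_fdr"] < t.fdr)
        & (records["ion_score"] >= t.score)
        & (records["expect_p"] < t.expect)
        & records["loc_prob"].map(lambda s: _locprobs_pass(s, t.locprob))
    )
    return records.loc[keep].copy()


@dataclass
class SiteAnnotation:
    """One modified residue on a protein with aggregated evidence."""

    protein_id: str
    position: int  # 1-based protein coordinate
    residue: str
    ptm_type: str
    evidence: set = field(default_factory=set)  # {(protease, fragmentation)}
    novelty: str = "novel"  # "novel" | "known"
    occupancy: float | None = None

    @property
    def site_key(self) -> tuple[str, int, str]:
        return (self.protein_id, self.position, self.ptm_type)


@dataclass(frozen=True)
class CollationSummary:
    n_nonredundant_peptidoforms: int
    n_unique_sites: dict  # protein_id -> count

    @property
    def n_total_sites(self) -> int:
        return sum(self.n_unique_sites.values())


def _locate(peptide: str, protein: str) -> int:
    """0-based start of the (first) occurrence of peptide in protein."""
    idx = protein.find(peptide)
    if idx < 0:
        raise MappingError(f"peptide {peptide!r} not found in protein")
    return idx


def collate_sites(
    filtered: pd.DataFrame,
    proteins: dict[str, str],
    known_sites: pd.DataFrame | None = None,
) -> tuple[list[SiteAnnotation], CollationSummary]:
    """Collate filtered PSMs into unique modification sites.

    Peptidoforms are deduplicated on (protein, sequence, mods); sites on
    (protein, 1-based position, ptm type), aggregating the
    (protease, fragmentation) evidence of every supporting PSM.

    ``known_sites`` is an optional table with columns protein_id,
    position, ptm_type; matching sites are annotated ``novelty="known"``.
    """
    _check_schema(filtered)
    known: set[tuple[str, int, str]] = set()
    if known_sites is not None:
        known = {
            (r.protein_id, int(r.position), r.ptm_type)
            for r in known_sites.itertuples()
        }

    peptidoforms: set[tuple[str, str, str]] = set()
    sites: dict[tuple[str, int, str], SiteAnnotation] = {}
    for row in filtered.itertuples():
        mods = parse_mods_field(row.mods)
        if not mods:
            continue
        protein_seq = proteins.get(row.protein_id)
        if protein_seq is None:
            raise MappingError(f"unknown protein: {row.protein_id!r}")
        offset = _locate(row.peptide, protein_seq)
        peptidoforms.add((row.protein_id, row.peptide, row.mods))
        for pep_pos, mod_name in mods:
            prot_pos = offset + pep_pos  # 1-based protein coordinate
            key = (row.protein_id, prot_pos, mod_name)
            ann = sites.get(key)
            if ann is None:
                ann = SiteAnnotation(
                    protein_id=row.protein_id,
                    position=prot_pos,
                    residue=protein_seq[prot_pos - 1],
                    ptm_type=mod_name,
                    novelty="known" if key in known else "novel",
                )
                sites[key] = ann
            ann.evidence.add((row.protease, row.fragmentation))

    per_protein: dict[str, int] = {}
    for key in sites:
        per_protein[key[0]] = per_protein.get(key[0], 0) + 1
    ordered = sorted(sites.values(), key=lambda s: (s.protein_id, s.position, s.ptm_type))
    return ordered, CollationSummary(len(peptidoforms), per_protein)
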