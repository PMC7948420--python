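"""Assembly of a draft kinase/phosphatase -> histone-enzyme regulatory network.

Evidence lines of four types are screened by fixed admission rules and
merged into typed edges:

* motif predictions (NetworKIN-style): admitted when score > 2 (strict);
* quantitative perturbation data: admitted when p < 0.05 and the fold
  change has the class-appropriate sign (< -1.5 for a kinase deletion,
  > 1.5 for a phosphatase deletion), on the signed linear scale as given;
* physical kinase-substrate interactions: admitted as protein-level
  evidence;
* genetic interactions: never create an edge on their own — they only
  corroborate a connection already supported by another evidence type.

Kinases reaching two or more distinct substrate enzymes are flagged as
multi-substrate regulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "MOTIF_SCORE_MIN",
    "QUANT_P_MAX",
    "QUANT_FC_MAG",
    "EvidenceEdge",
    "RegulatoryNetwork",
    "admit_motif",
    "admit_quant",
    "admit_physical",
    "assemble",
]

MOTIF_SCORE_MIN = 2.0
QUANT_P_MAX = 0.05
QUANT_FC_MAG = 1.5


@dataclass
class EvidenceEdge:
    """One regulator -> substrate(-site) link with typed evidence lines."""

    regulator: str
    substrate: str
    site: int | None  # 1-based position or None for protein-level
    evidence: set = field(default_factory=set)
    corroborated_genetic: bool = False

    @property
    def key(self) -> tuple:
        return (self.regulator, self.substrate, self.site)


def _require(df: pd.DataFrame, cols: tuple[str, ...], table: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"{table} table missing required column: {c!r}")


def _site_of(row) -> int | None:
    site = getattr(row, "site", None)
    if site is None or (isinstance(site, float) and pd.isna(site)) or site == "":
        return None
    return int(site)


def admit_motif(records: pd.DataFrame) -> list[EvidenceEdge]:
    """Admit motif-prediction records with score strictly above 2."""
    _require(records, ("regulator", "substrate", "score"), "motif")
    if records["score"].isna().any():
        raise ValueError("motif table has records with missing score")
    out = []
    for row in records.itertuples():
        if row.score > MOTIF_SCORE_MIN:
            out.append(
                EvidenceEdge(row.regulator, row.substrate, _site_of(row), {"motif_prediction"})
            )
    return out


def admit_quant(records: pd.DataFrame) -> list[EvidenceEdge]:
    """Admit perturbation-quantification records by sign and significance.

    A kinase deletion must decrease the phosphopeptide (fold change
    < -1.5); a phosphatase deletion must increase it (> 1.5); both
    require p < 0.05.
    """
    _require(
        records,
        ("regulator", "substrate", "regulator_class", "fold_change", "p_value"),
        "quant",
    )
    out = []
    for row in records.itertuples():
        cls = row.regulator_class
        if cls not in ("kinase", "phosphatase"):
            raise ValueError(f"unknown regulator class: {cls!r}")
        if row.p_value >= QUANT_P_MAX:
            continue
        ok = (
            row.fold_change < -QUANT_FC_MAG
            if cls == "kinase"
            else row.fold_change > QUANT_FC_MAG
        )
        if ok:
            out.append(
                EvidenceEdge(row.regulator, row.substrate, _site_of(row), {"quant_perturbation"})
            )
    return out


def admit_physical(records: pd.DataFrame) -> list[EvidenceEdge]:
    """Admit physical kinase-substrate interaction records (no threshold)."""
    _require(records, ("regulator", "substrate"), "physical")
    return [
        EvidenceEdge(row.regulator, row.substrate, _site_of(row), {"physical_interaction"})
        for row in records.itertuples()
    ]


@dataclass
class RegulatoryNetwork:
    edges: list  # EvidenceEdge, merged
    multi_substrate_regulators: set

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "regulator": e.regulator,
                "substrate": e.substrate,
                "site": e.site,
                "evidence": ";".join(sorted(e.evidence)),
                "corroborated_genetic": e.corroborated_genetic,
                "multi_substrate_regulator": e.regulator in self.multi_substrate_regulators,
            }
            for e in self.edges
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "regulator", "substrate", "site", "evidence",
                "corroborated_genetic", "multi_substrate_regulator",
            ],
        )

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for e in self.edges:
            g.add_node(e.regulator, kind="regulator",
                       multi_substrate=e.regulator in self.multi_substrate_regulators)
            g.add_node(e.substrate, kind="enzyme")
            prev = g.get_edge_data(e.regulator, e.substrate)
            sites = set() if prev is None else set(prev["sites"])
            evid = set() if prev is None else set(prev["evidence"])
            if e.site is not None:
                sites.add(e.site)
            g.add_edge(
                e.regulator,
                e.substrate,
                sites=sorted(sites),
                evidence=sorted(evid | e.evidence),
                corroborated_genetic=(prev or {}).get("corroborated_genetic", False)
                or e.corroborated_genetic,
            )
        return g


def assemble(
    motif_edges: list[EvidenceEdge],
    quant_edges: list[EvidenceEdge],
    physical_edges: list[EvidenceEdge] | None = None,
    genetic_records: pd.DataFrame | None = None,
) -> RegulatoryNetwork:
    """Merge admitted evidence into a network.

    Edges merge on (regulator, substrate, site). Protein-level records
    (no site) additionally corroborate every site-level edge of the same
    regulator/substrate pair. Genetic interactions attach only where at
    least one non-genetic evidence line already supports the connection;
    genetic-only records are dropped.
    """
    merged: dict[tuple, EvidenceEdge] = {}
    for e in [*motif_edges, *quant_edges, *(physical_edges or [])]:
        cur = merged.get(e.key)
        if cur is None:
            merged[e.key] = EvidenceEdge(e.regulator, e.substrate, e.site, set(e.evidence))
        else:
            cur.evidence |= e.evidence

    # Protein-level evidence corroborates that pair's site-level edges.
    for e in list(merged.values()):
        if e.site is None:
            for other in merged.values():
                if (
                    other.site is not None
                    and other.regulator == e.regulator
                    and other.substrate == e.substrate
                ):
                    other.evidence |= e.evidence

    if genetic_records is not None:
        _require(genetic_records, ("regulator", "substrate"), "genetic")
        for row in genetic_records.itertuples():
            site = _site_of(row)
            for e in merged.values():
                pair = e.regulator == row.regulator and e.substrate == row.substrate
                if pair and (site is None or e.site == site):
                    e.evidence.add("genetic_interaction")
                    e.corroborated_genetic = True

    for e in merged.values():
        assert e.evidence - {"genetic_interaction"}, "genetic-only edge leaked"

    substrates_per_reg: dict[str, set] = {}
    for e in merged.values():
        substrates_per_reg.setdefault(e.regulator, set()).add(e.substrate)
    multi = {r for r, subs in substrates_per_reg.items() if len(subs) >= 2}

    ordered = sorted(
        merged.values(), key=lambda e: (e.regulator, e.substrate, e.site is None, e.site or 0)
    )
    return RegulatoryNetwork(ordered, multi)
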