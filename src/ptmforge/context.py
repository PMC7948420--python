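"""Sequence context for modification sites.

Covers four independent questions about a mapped site:

* does it sit in predicted intrinsic disorder (per-residue score track,
  threshold 0.5 with >= semantics)?
* does it fall inside an annotated domain (1-based inclusive intervals)?
* is the residue — and its phosphorylation — conserved in an ortholog,
  judged through a global alignment with free end gaps?
* what does it contribute to the local net charge of an N-terminal
  regulatory window once phosphorylation and point mutations are counted?

The aligner is a Gotoh-style affine-gap dynamic program in which terminal
gap runs are free (semi-global alignment); tie-breaking in the traceback
is deterministic (diagonal, then the gap consuming the query).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "DisorderTrack",
    "DomainInterval",
    "AlignmentResult",
    "AlphabetError",
    "InvalidMutationError",
    "disorder_context",
    "domain_context",
    "align_free_end_gaps",
    "conserved_phosphosites",
    "net_charge",
    "SET2_NTERM15",
    "SET2_PHOSPHOSITES",
]

NEG_INF = float("-inf")


class AlphabetError(ValueError):
    """A sequence symbol is absent from the substitution matrix."""


class InvalidMutationError(ValueError):
    """A phosphosite mutation was specified at a non-serine position."""


# ---------------------------------------------------------------------------
# Disorder and domain context


@dataclass(frozen=True)
class DisorderTrack:
    """Per-residue disorder propensity in [0, 1] for one protein."""

    protein_id: str
    scores: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 1:
            raise ValueError("scores must be 1-D")
        if np.any((scores < 0) | (scores > 1)):
            raise ValueError("disorder scores must lie in [0, 1]")

    def is_disordered(self, position: int) -> bool:
        if not 1 <= position <= self.scores.size:
            raise IndexError(f"position {position} outside track of length {self.scores.size}")
        return bool(self.scores[position - 1] >= self.threshold)


@dataclass(frozen=True)
class DomainInterval:
    protein_id: str
    name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    domain_class: str = "catalytic"  # catalytic | regulatory | interaction

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("require 1 <= start <= end")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def disorder_context(site_positions: list[int], track: DisorderTrack) -> dict:
    """Flag each site as ordered/disordered and tally the protein.

    Returns per-site flags plus the fraction of protein residues at or
    above the disorder threshold and counts of sites on either side.
    """
    flags = {pos: track.is_disordered(pos) for pos in site_positions}
    n_dis = sum(flags.values())
    return {
        "site_disordered": flags,
        "percent_disordered": float((track.scores >= track.threshold).mean()) * 100.0,
        "n_sites_disordered": n_dis,
        "n_sites_ordered": len(site_positions) - n_dis,
    }


def domain_context(
    site_positions: list[int], domains: list[DomainInterval]
) -> dict:
    """Flag sites inside any domain interval (endpoints inclusive)."""
    flags = {
        pos: any(d.contains(pos) for d in domains) for pos in site_positions
    }
    n_in = sum(flags.values())
    frac = n_in / len(site_positions) if site_positions else 0.0
    return {"site_in_domain": flags, "n_in_domain": n_in, "fraction_in_domain": frac}


# ---------------------------------------------------------------------------
# Free-end-gap pairwise alignment


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    a_to_b: dict  # 1-based position in A -> 1-based position in B, or None

    def __post_init__(self) -> None:
        if self.aligned_a.replace("-", "") == "" or len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("malformed alignment rows")


def _matrix_lookup(matrix, a: str, b: str) -> float:
    try:
        return float(matrix[a, b])
    except (KeyError, IndexError, ValueError):
        raise AlphabetError(f"symbol pair ({a!r}, {b!r}) not in substitution matrix") from None


def align_free_end_gaps(
    seq_a: str,
    seq_b: str,
    matrix=None,
    gap_open: float = 12.0,
    gap_extend: float = 3.0,
) -> AlignmentResult:
    """Optimal global alignment with unpenalized terminal gaps.

    Internal gap runs cost ``gap_open`` for the first gapped column and
    ``gap_extend`` for each further column; runs touching either end of
    the alignment are free, so a short query floats inside a longer
    subject at no cost. Default scoring is BLOSUM62 with 12/3 penalties.
    Ties in the traceback resolve to the diagonal move first, then the
    gap consuming sequence A.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if matrix is None:
        matrix = substitution_matrices.load("BLOSUM62")
    m, n = len(seq_a), len(seq_b)

    # Pre-check alphabet so errors do not depend on alignment path.
    for ch in set(seq_a) | set(seq_b):
        _matrix_lookup(matrix, ch, ch)

    # State matrices: M ends in a match column, X ends in (a_i, -) i.e. a
    # gap in B, Y ends in (-, b_j). A gap-in-B run sits at fixed j, so it
    # is terminal iff j == 0 or j == n (and symmetrically for Y).
    M = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    X = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    # Backpointers: which state the max came from (0=M, 1=X, 2=Y).
    Mp = [[-1] * (n + 1) for _ in range(m + 1)]
    Xp = [[-1] * (n + 1) for _ in range(m + 1)]
    Yp = [[-1] * (n + 1) for _ in range(m + 1)]

    M[0][0] = 0.0
    for i in range(0, m + 1):
        for j in range(0, n + 1):
            if i > 0:
                xopen = 0.0 if (j == 0 or j == n) else gap_open
                xext = 0.0 if (j == 0 or j == n) else gap_extend
                cand = (
                    M[i - 1][j] - xopen,
                    X[i - 1][j] - xext,
                    Y[i - 1][j] - xopen,
                )
                best = max(cand)
                X[i][j] = best
                Xp[i][j] = (0, 1, 2)[cand.index(best)]
            if j > 0:
                yopen = 0.0 if (i == 0 or i == m) else gap_open
                yext = 0.0 if (i == 0 or i == m) else gap_extend
                cand = (
                    M[i][j - 1] - yopen,
                    X[i][j - 1] - yopen,
                    Y[i][j - 1] - yext,
                )
                best = max(cand)
                Y[i][j] = best
                Yp[i][j] = (0, 1, 2)[cand.index(best)]
            if i > 0 and j > 0:
                s = _matrix_lookup(matrix, seq_a[i - 1], seq_b[j - 1])
                cand = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                best = max(cand)
                if best > NEG_INF:
                    M[i][j] = best + s
                    Mp[i][j] = (0, 1, 2)[cand.index(best)]

    finals = (M[m][n], X[m][n], Y[m][n])
    score = max(finals)
    state = finals.index(score)  # prefers M, then X (gap in B), then Y

    # Traceback.
    rows_a: list[str] = []
    rows_b: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        if state == 0:
            rows_a.append(seq_a[i - 1])
            rows_b.append(seq_b[j - 1])
            state = Mp[i][j]
            i, j = i - 1, j - 1
        elif state == 1:
            rows_a.append(seq_a[i - 1])
            rows_b.append("-")
            state = Xp[i][j]
            i -= 1
        else:
            rows_a.append("-")
            rows_b.append(seq_b[j - 1])
            state = Yp[i][j]
            j -= 1
    aligned_a = "".join(reversed(rows_a))
    aligned_b = "".join(reversed(rows_b))

    a_to_b: dict[int, int | None] = {}
    ai = bi = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-":
            ai += 1
        if cb != "-":
            bi += 1
        if ca != "-":
            a_to_b[ai] = bi if cb != "-" else None
    return AlignmentResult(aligned_a, aligned_b, float(score), a_to_b)


def conserved_phosphosites(
    site_positions: list[int],
    alignment: AlignmentResult,
    partner_seq: str,
    partner_phospho: set[int] | list[int] = (),
) -> dict[int, str]:
    """Classify each phosphosite of sequence A against its ortholog.

    ``phosphosite_conserved``: aligned partner residue is S/T/Y *and* a
    known phosphosite; ``residue_conserved``: partner residue is S/T/Y;
    ``not_conserved``: aligned to a non-phosphoacceptor; ``not_aligned``:
    aligned to a gap.
    """
    partner_phospho = set(partner_phospho)
    out = {}
    for pos in site_positions:
        partner_pos = alignment.a_to_b.get(pos)
        if partner_pos is None:
            out[pos] = "not_aligned"
        elif partner_seq[partner_pos - 1] in "STY":
            out[pos] = (
                "phosphosite_conserved"
                if partner_pos in partner_phospho
                else "residue_conserved"
            )
        else:
            out[pos] = "not_conserved"
    return out


# ---------------------------------------------------------------------------
# N-terminal net-charge model

#: Composition model of the Set2p N-terminal regulatory window (residues
#: 1-15): lysine at 3, phosphorylatable serines at 6/8/10, the EDEKE
#: acidic patch at 11-15, uncharged filler elsewhere. Only charged and
#: phosphorylatable positions affect the model, so the filler residues
#: are immaterial to every computed charge.
SET2_NTERM15 = "MAKAASASASEDEKE"
SET2_PHOSPHOSITES = (6, 8, 10)


def net_charge(
    window: str,
    phospho_positions: list[int] | tuple[int, ...] = (),
    mutations: dict[int, str] | None = None,
) -> int:
    """Net charge of an N-terminal window under simple counting rules.

    +1 for the free N-terminus; +1 per K/R; -1 per D/E; -2 per
    phosphorylated serine (two ionizable phosphate charges); a
    phosphonull S->A mutation contributes 0 and a phosphomimetic S->D
    contributes -1. Histidine and all other residues count 0. Mutations
    are only legal at serine positions; a mutated position cannot also be
    phosphorylated.
    """
    mutations = dict(mutations or {})
    for pos, new in mutations.items():
        if not 1 <= pos <= len(window):
            raise InvalidMutationError(f"mutation position {pos} outside window")
        if window[pos - 1] != "S":
            raise InvalidMutationError(
                f"mutation at position {pos} targets {window[pos - 1]!r}, not serine"
            )
        if new not in ("A", "D"):
            raise InvalidMutationError(f"unsupported substitution S->{new}")
    phospho = set(phospho_positions) - set(mutations)
    for pos in phospho:
        if window[pos - 1] != "S":
            raise InvalidMutationError(f"phosphosite at non-serine position {pos}")

    charge = 1  # free N-terminal amine
    for i, aa in enumerate(window, start=1):
        if i in mutations:
            aa = mutations[i]
            charge += -1 if aa == "D" else 0
            continue
        if i in phospho:
            charge += -2
        elif aa in "KR":
            charge += 1
        elif aa in "DE":
            charge += -1
    return charge
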