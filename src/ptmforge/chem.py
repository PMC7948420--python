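"""Monoisotopic mass and m/z arithmetic for modified peptides.

Implements the peptide chemistry underlying histone-PTM quantification:
peptidoform mass/m-z calculation, the propionylation rules used for
derivatized histone methyl-peptides (free and monomethyl lysines accept a
propionyl group; di- and tri-methyl lysines do not), and in-silico
digestion for the four proteases used in multi-protease coverage designs
(trypsin, LysargiNase, Asp-N, chymotrypsin).

Monoisotopic residue masses are taken from pyteomics; coordinates are
1-based inclusive throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pmass

__all__ = [
    "WATER_MASS",
    "PROTON_MASS",
    "AminoAcidMassTable",
    "Modification",
    "ModificationRegistry",
    "load_registry",
    "Peptidoform",
    "ProteaseRule",
    "PROTEASES",
    "DigestPeptide",
    "monoisotopic_mass",
    "mz",
    "propionylate",
    "digest",
    "ppm_window",
    "InvalidSequenceError",
    "InvalidChargeError",
    "InvalidStateError",
]

WATER_MASS: float = _pmass.calculate_mass(formula="H2O")  # 18.010565 Da
PROTON_MASS: float = 1.00727646677  # Da

_STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


class InvalidSequenceError(ValueError):
    """Sequence contains a residue code with no mass entry."""


class InvalidChargeError(ValueError):
    """Charge state must be a positive integer."""


class InvalidStateError(ValueError):
    """A modification state was requested on an incompatible residue."""


@dataclass(frozen=True)
class AminoAcidMassTable:
    """Monoisotopic residue masses plus the water and proton constants."""

    residue_masses: Mapping[str, float]
    water_mass: float = WATER_MASS
    proton_mass: float = PROTON_MASS

    def __post_init__(self) -> None:
        missing = [aa for aa in _STANDARD_RESIDUES if aa not in self.residue_masses]
        if missing:
            raise ValueError(f"mass table missing standard residues: {missing}")
        if any(m <= 0 for m in self.residue_masses.values()):
            raise ValueError("residue masses must be positive")

    def mass_of(self, residue: str) -> float:
        try:
            return self.residue_masses[residue]
        except KeyError:
            raise InvalidSequenceError(f"unknown residue code: {residue!r}") from None


DEFAULT_MASS_TABLE = AminoAcidMassTable(
    residue_masses={aa: _pmass.std_aa_mass[aa] for aa in _STANDARD_RESIDUES}
)


@dataclass(frozen=True)
class Modification:
    """A named mass shift with the residues/termini it may sit on.

    ``targets`` uses one-letter residue codes plus the pseudo-targets
    ``N-term`` and ``C-term``.
    """

    name: str
    delta_mass: float
    targets: frozenset[str]

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_mass):
            raise ValueError("delta_mass must be finite")

    def allows(self, target: str) -> bool:
        return target in self.targets


class ModificationRegistry(dict):
    """Name-indexed modification table; loaded from the packaged TSV."""

    def register(self, mod: Modification) -> None:
        self[mod.name] = mod

    def get_mod(self, name: str) -> Modification:
        try:
            return self[name]
        except KeyError:
            raise KeyError(f"unknown modification: {name!r}") from None


def load_registry() -> ModificationRegistry:
    """Load the packaged modification table (name, delta_mass, targets)."""
    reg = ModificationRegistry()
    text = resources.files("ptmforge.data").joinpath("modifications.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("name\t"):
            continue
        name, delta, targets = line.split("\t")
        reg.register(
            Modification(name, float(delta), frozenset(targets.split(",")))
        )
    return reg


REGISTRY = load_registry()


@dataclass(frozen=True)
class Peptidoform:
    """A peptide sequence with positioned modifications and a charge state.

    ``mods`` holds ``(position, Modification)`` pairs where position is a
    1-based residue index, or the strings ``"N-term"``/``"C-term"``.
    """

    sequence: str
    mods: tuple[tuple[int | str, Modification], ...] = ()
    charge: int = 1

    def __post_init__(self) -> None:
        for pos, mod in self.mods:
            if isinstance(pos, str):
                if pos not in ("N-term", "C-term"):
                    raise ValueError(f"bad terminus label: {pos!r}")
                target = pos
            else:
                if not 1 <= pos <= len(self.sequence):
                    raise ValueError(
                        f"mod position {pos} outside 1..{len(self.sequence)}"
                    )
                target = self.sequence[pos - 1]
            if not mod.allows(target):
                raise InvalidStateError(
                    f"{mod.name} not allowed on target {target!r} (position {pos})"
                )

    def with_charge(self, charge: int) -> "Peptidoform":
        return Peptidoform(self.sequence, self.mods, charge)


def monoisotopic_mass(
    pf: Peptidoform, table: AminoAcidMassTable = DEFAULT_MASS_TABLE
) -> float:
    """Neutral monoisotopic mass: residue masses + water + modification deltas."""
    total = table.water_mass
    for aa in pf.sequence:
        total += table.mass_of(aa)
    for _, mod in pf.mods:
        total += mod.delta_mass
    return total


def mz(pf: Peptidoform, table: AminoAcidMassTable = DEFAULT_MASS_TABLE) -> float:
    """Mass-to-charge ratio (M + z*proton)/z for the peptidoform's charge."""
    z = pf.charge
    if not isinstance(z, int) or z < 1:
        raise InvalidChargeError(f"charge must be a positive integer, got {z!r}")
    return (monoisotopic_mass(pf, table) + z * table.proton_mass) / z


def mz_reported(pf: Peptidoform, table: AminoAcidMassTable = DEFAULT_MASS_TABLE) -> float:
    """m/z rounded to 2 decimals (round-half-even), the reporting convention."""
    return round(mz(pf, table), 2)


_METHYL_MOD = {"me1": "methyl", "me2": "dimethyl", "me3": "trimethyl"}


def propionylate(
    sequence: str,
    k_methyl_states: Mapping[int, str] | None = None,
    nterm: bool = False,
    charge: int = 1,
    registry: ModificationRegistry = REGISTRY,
) -> Peptidoform:
    """Apply in-vitro propionylation chemistry to a (methylated) peptide.

    Free (me0) and monomethyl (me1) lysine side chains gain a propionyl
    group (me1 lysines carry methyl + propionyl); di- and tri-methylated
    lysines are blocked and carry only their methyl marks. Lysines not
    listed in ``k_methyl_states`` are treated as me0. Optionally the
    peptide N-terminus is propionylated too.
    """
    states = dict(k_methyl_states or {})
    for pos, state in states.items():
        if not 1 <= pos <= len(sequence) or sequence[pos - 1] != "K":
            raise InvalidStateError(
                f"methyl state {state!r} assigned to non-lysine position {pos}"
            )
        if state not in ("me0", "me1", "me2", "me3"):
            raise InvalidStateError(f"unknown methyl state {state!r}")

    prop = registry.get_mod("propionyl")
    mods: list[tuple[int | str, Modification]] = []
    if nterm:
        mods.append(("N-term", prop))
    for i, aa in enumerate(sequence, start=1):
        if aa != "K":
            continue
        state = states.get(i, "me0")
        if state in ("me0", "me1"):
            if state == "me1":
                mods.append((i, registry.get_mod("methyl")))
            mods.append((i, prop))
        else:
            mods.append((i, registry.get_mod(_METHYL_MOD[state])))
    return Peptidoform(sequence, tuple(mods), charge)


@dataclass(frozen=True)
class ProteaseRule:
    """Deterministic cleavage rule: residues, side, and exceptions."""

    name: str
    residues: frozenset[str]
    side: str  # "C" cleave C-terminal to residue, "N" cleave N-terminal
    not_before: frozenset[str] = frozenset()
    max_missed: int = 0

    def cleavage_points(self, protein: str) -> list[int]:
        """0-based indices i such that the bond between protein[i-1] and
        protein[i] is cleaved (i.e. a new peptide starts at i)."""
        points = []
        n = len(protein)
        for i in range(1, n):
            if self.side == "C":
                if protein[i - 1] in self.residues and protein[i] not in self.not_before:
                    points.append(i)
            else:
                if protein[i] in self.residues:
                    points.append(i)
        return points


def _make_proteases(aspn_de: bool = True) -> dict[str, ProteaseRule]:
    return {
        "trypsin": ProteaseRule("trypsin", frozenset("KR"), "C", frozenset("P")),
        "lysarginase": ProteaseRule("lysarginase", frozenset("KR"), "N"),
        "aspn": ProteaseRule("aspn", frozenset("DE" if aspn_de else "D"), "N"),
        "chymotrypsin": ProteaseRule(
            "chymotrypsin", frozenset("FYWLKR"), "C", frozenset("P")
        ),
    }


#: Default protease table. Asp-N is configured to cleave before D and E
#: (ambic-buffer behaviour); use ``_make_proteases(aspn_de=False)`` for
#: strict D-only cleavage.
PROTEASES: dict[str, ProteaseRule] = _make_proteases()


@dataclass(frozen=True)
class DigestPeptide:
    peptide: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    missed_cleavages: int


def digest(
    protein: str,
    rule: ProteaseRule | str,
    max_missed: int | None = None,
) -> list[DigestPeptide]:
    """In-silico digestion returning peptides with up to ``max_missed``
    internal missed cleavages, ordered by start then length."""
    if not protein:
        raise ValueError("protein sequence is empty")
    if isinstance(rule, str):
        try:
            rule = PROTEASES[rule]
        except KeyError:
            raise ValueError(f"unknown protease: {rule!r}") from None
    mm = rule.max_missed if max_missed is None else max_missed
    if mm < 0:
        raise ValueError("max_missed must be >= 0")

    bounds = [0, *rule.cleavage_points(protein), len(protein)]
    out: list[DigestPeptide] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + mm, len(bounds))):
            s, e = bounds[i], bounds[j]
            out.append(DigestPeptide(protein[s:e], s + 1, e, j - i - 1))
    return out


def ppm_window(center_mz: float, tol_ppm: float) -> tuple[float, float]:
    """Symmetric relative mass window: center*(1 ± tol/1e6)."""
    if center_mz <= 0 or tol_ppm <= 0:
        raise ValueError("center_mz and tol_ppm must be positive")
    return center_mz * (1 - tol_ppm / 1e6), center_mz * (1 + tol_ppm / 1e6)


# ---------------------------------------------------------------------------
# H3K36 methyl-peptidoform convenience constructors

#: Triply-charged tryptic H3 peptide spanning K36 (K27..R40 in histone
#: numbering; K36 is peptide position 10).
H3_K36_PEPTIDE = "KSAPSTGGVKKPHR"
H3_K36_PEPTIDE_POSITION = 10
H3_K36_CHARGE = 3


def h3k36_peptidoform(methyl_state: str, charge: int = H3_K36_CHARGE) -> Peptidoform:
    """The derivatized K36-containing peptidoform for one methyl state.

    me0/me1 are triply propionylated (K27, K36, K37); me2/me3 are doubly
    propionylated because the methylated side chain is blocked.
    """
    return propionylate(
        H3_K36_PEPTIDE,
        {H3_K36_PEPTIDE_POSITION: methyl_state},
        nterm=False,
        charge=charge,
    )
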