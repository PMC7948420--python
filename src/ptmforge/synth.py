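"""Seeded synthetic-data generators with recorded ground truth.

Every input the pipeline consumes can be generated here: proteins, PSM
tables straddling the quality thresholds, Gaussian XIC traces with known
areas, methylation-state counts drawn from a proportional-odds model, and
typed kinase-evidence tables with planted true edges. Each generator is a
pure function of (parameters, seed), and one global seed fans out to
per-generator child seeds through ``numpy.random.SeedSequence(seed,
spawn_key=(k,))``, so regenerating any single fixture is stable.

Default parameters mirror the measured study conditions: three biological
replicates per strain, a wild-type methylation distribution of roughly
40/15/15/30% across me0..me3, XIC noise at 5% of the peak apex, a 10 ppm
mass window, and planted occupancies spanning the observed sub-0.1%-to-26%
stoichiometry range.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem
from .xic import ChromatogramTrace

__all__ = [
    "child_rng",
    "gen_protein",
    "choose_phospho_sites",
    "gen_psm_table",
    "gen_xic_pair",
    "gen_methyl_counts",
    "gen_evidence_tables",
    "gen_disorder_track",
    "gen_domains",
    "make_fixture_dir",
    "DEFAULT_CUTPOINTS",
    "OBSERVED_OCCUPANCY_RANGE",
]

#: Cumulative logits reproducing the wild-type H3K36 state distribution
#: (~40% me0, ~15% me1, ~15% me2, ~30% me3).
DEFAULT_CUTPOINTS = (-0.405465, 0.200671, 0.847298)

#: Span of relative phosphosite occupancies observed in the study data.
OBSERVED_OCCUPANCY_RANGE = (0.001, 0.26)

_GENERATOR_KEYS = {
    "protein": 0,
    "psm": 1,
    "xic": 2,
    "methyl": 3,
    "evidence": 4,
    "disorder": 5,
    "domains": 6,
}


def child_rng(seed: int, generator: str) -> np.random.Generator:
    """Deterministic per-generator RNG derived from one global seed."""
    key = _GENERATOR_KEYS.get(generator)
    if key is None:
        raise ValueError(f"unknown generator name: {generator!r}")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def gen_protein(length: int, composition: dict[str, float] | None = None,
                seed: int = 0) -> str:
    """Random protein sequence; ``composition`` biases residue frequencies."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = child_rng(seed, "protein")
    probs = np.full(_AA.size, 1.0 / _AA.size)
    if composition:
        for aa, frac in composition.items():
            probs[np.where(_AA == aa)[0][0]] = frac
        probs /= probs.sum()
    return "".join(rng.choice(_AA, size=length, p=probs))


def choose_phospho_sites(protein: str, n: int, seed: int = 0) -> list[int]:
    """Pick n distinct S/T/Y positions (1-based) as plantable phosphosites."""
    rng = child_rng(seed, "psm")
    candidates = [i + 1 for i, aa in enumerate(protein) if aa in "STY"]
    if len(candidates) < n:
        raise ValueError(f"protein has only {len(candidates)} S/T/Y residues")
    return sorted(rng.choice(candidates, size=n, replace=False).tolist())


def _peptide_for_site(protein: str, position: int) -> chem.DigestPeptide:
    """Tryptic peptide (<=1 missed cleavage) containing the site; prefers
    informative lengths."""
    products = [
        p for p in chem.digest(protein, "trypsin", 1) if p.start <= position <= p.end
    ]
    products.sort(key=lambda p: (len(p.peptide) < 6, p.missed_cleavages, p.start))
    return products[0]


_PROTEASES = ("trypsin", "lysarginase", "aspn", "chymotrypsin")
_FRAGS = ("HCD", "EThcD")


def gen_psm_table(
    protein_id: str,
    protein: str,
    true_sites: list[tuple[int, str]],
    n_psms: int = 25,
    decoy_fraction: float = 0.4,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """PSM table in which planted sites pass the quality filters and decoy
    records each fail exactly one criterion.

    ``true_sites`` is a list of (1-based position, ptm_type). Decoy PSMs
    are placed on S/T positions outside the planted set so a correct
    filter + collation recovers exactly the planted sites.
    """
    rng = child_rng(seed, "psm")
    n_decoys = int(round(n_psms * decoy_fraction))
    n_true = n_psms - n_decoys
    if n_true < len(true_sites):
        raise ValueError("n_psms too small to support every planted site")

    site_assignment = list(range(len(true_sites)))
    site_assignment += rng.integers(0, len(true_sites), n_true - len(true_sites)).tolist()

    rows = []
    for k in site_assignment:
        pos, ptm = true_sites[k]
        pep = _peptide_for_site(protein, pos)
        pep_pos = pos - pep.start + 1
        pf = chem.Peptidoform(
            pep.peptide,
            ((pep_pos, chem.REGISTRY.get_mod(ptm)),),
            charge=int(rng.integers(2, 4)),
        )
        rows.append(
            {
                "protein_id": protein_id,
                "peptide": pep.peptide,
                "mods": f"{pep_pos}:{ptm}",
                "protease": rng.choice(_PROTEASES),
                "fragmentation": rng.choice(_FRAGS),
                "ion_score": float(rng.uniform(35, 90)),
                "expect_p": float(rng.uniform(1e-5, 0.04)),
                "psm_fdr": float(rng.uniform(0.0, 0.009)),
                "loc_prob": f"{pep_pos}:{rng.uniform(95.5, 100):.2f}",
                "retention_time": float(rng.uniform(10, 90)),
                "precursor_mz": round(chem.mz(pf), 4),
                "charge": pf.charge,
            }
        )

    true_positions = {p for p, _ in true_sites}
    decoy_candidates = [
        i + 1
        for i, aa in enumerate(protein)
        if aa in "ST" and i + 1 not in true_positions
    ]
    for _ in range(n_decoys):
        pos = int(rng.choice(decoy_candidates))
        pep = _peptide_for_site(protein, pos)
        pep_pos = pos - pep.start + 1
        failure = rng.choice(["score", "fdr", "expect", "locprob"])
        row = {
            "protein_id": protein_id,
            "peptide": pep.peptide,
            "mods": f"{pep_pos}:phospho",
            "protease": rng.choice(_PROTEASES),
            "fragmentation": rng.choice(_FRAGS),
            "ion_score": float(rng.uniform(35, 90)),
            "expect_p": float(rng.uniform(1e-5, 0.04)),
            "psm_fdr": float(rng.uniform(0.0, 0.009)),
            "loc_prob": f"{pep_pos}:{rng.uniform(95.5, 100):.2f}",
            "retention_time": float(rng.uniform(10, 90)),
            "precursor_mz": 0.0,
            "charge": int(rng.integers(2, 4)),
        }
        if failure == "score":
            row["ion_score"] = float(rng.uniform(5, 29.9))
        elif failure == "fdr":
            row["psm_fdr"] = float(rng.uniform(0.011, 0.2))
        elif failure == "expect":
            row["expect_p"] = float(rng.uniform(0.051, 0.5))
        else:
            row["loc_prob"] = f"{pep_pos}:{rng.uniform(40, 94.9):.2f}"
        rows.append(row)

    df = pd.DataFrame(rows)
    truth = {
        "protein_id": protein_id,
        "true_sites": [[p, t] for p, t in true_sites],
        "n_true_psms": n_true,
        "n_decoy_psms": n_decoys,
        "seed": seed,
    }
    return df, truth


def gen_xic_pair(
    occupancy: float,
    total_area: float = 1e6,
    rt_mod: float = 12.0,
    rt_unmod: float = 15.0,
    sigma_rt: float = 0.08,
    noise_frac: float = 0.05,
    rt_range: tuple[float, float] = (0.0, 30.0),
    dt: float = 0.01,
    seed: int = 0,
) -> tuple[ChromatogramTrace, ChromatogramTrace, dict]:
    """Paired modified/unmodified XIC traces with planted peak areas.

    Peaks are Gaussian in retention time with areas ``occupancy * total``
    and ``(1 - occupancy) * total``. Each trace carries iid Gaussian
    noise with standard deviation ``noise_frac`` of its own peak apex
    (scan-to-scan variation scales with the analyte signal); a trace with
    no analyte carries a residual background at 1% of the paired apex
    scale. Intensities are clipped at zero.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must be in [0, 1]")
    rng = child_rng(seed, "xic")
    rt = np.arange(rt_range[0], rt_range[1] + dt / 2, dt)

    def peak(area: float, center: float) -> np.ndarray:
        if area == 0:
            return np.zeros_like(rt)
        amp = area / (sigma_rt * np.sqrt(2 * np.pi))
        return amp * np.exp(-0.5 * ((rt - center) / sigma_rt) ** 2)

    area_mod = occupancy * total_area
    area_unmod = (1.0 - occupancy) * total_area
    sig_mod = peak(area_mod, rt_mod)
    sig_unmod = peak(area_unmod, rt_unmod)
    floor = 0.01 * max(sig_mod.max(), sig_unmod.max())
    sd_mod = noise_frac * (sig_mod.max() if sig_mod.max() > 0 else floor)
    sd_unmod = noise_frac * (sig_unmod.max() if sig_unmod.max() > 0 else floor)
    sig_mod = np.clip(sig_mod + rng.normal(0, sd_mod, rt.size), 0, None)
    sig_unmod = np.clip(sig_unmod + rng.normal(0, sd_unmod, rt.size), 0, None)
    truth = {
        "occupancy": occupancy,
        "area_modified": area_mod,
        "area_unmodified": area_unmod,
        "rt_mod": rt_mod,
        "rt_unmod": rt_unmod,
        "noise_sd_modified": sd_mod,
        "noise_sd_unmodified": sd_unmod,
        "seed": seed,
    }
    return (
        ChromatogramTrace(rt, sig_mod),
        ChromatogramTrace(rt, sig_unmod),
        truth,
    )


def _po_probs(cutpoints: np.ndarray, beta: float) -> np.ndarray:
    cum = 1.0 / (1.0 + np.exp(-(np.asarray(cutpoints) - beta)))
    return np.diff(np.concatenate([[0.0], cum, [1.0]]))


def gen_methyl_counts(
    strain_betas: dict[str, float],
    cutpoints: tuple[float, float, float] = DEFAULT_CUTPOINTS,
    n_replicates: int = 3,
    effective_n: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Replicate methylation-state counts from a proportional-odds model."""
    if not np.all(np.diff(cutpoints) > 0):
        raise ValueError("cutpoints must be strictly increasing")
    rng = child_rng(seed, "methyl")
    rows = []
    for strain, beta in strain_betas.items():
        probs = _po_probs(np.asarray(cutpoints, dtype=float), beta)
        for rep in range(n_replicates):
            counts = rng.multinomial(effective_n, probs)
            rows.append(
                {
                    "strain": strain,
                    "replicate": rep + 1,
                    "me0": int(counts[0]),
                    "me1": int(counts[1]),
                    "me2": int(counts[2]),
                    "me3": int(counts[3]),
                }
            )
    truth = {
        "strain_betas": dict(strain_betas),
        "cutpoints": list(cutpoints),
        "n_replicates": n_replicates,
        "effective_n": effective_n,
        "seed": seed,
    }
    return pd.DataFrame(rows), truth


def gen_evidence_tables(
    planted_edges: list[dict],
    n_noise_records: int = 10,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Evidence tables in which planted edges pass the admission rules and
    noise records each fail at least one rule.

    Each planted edge is a dict with keys ``regulator``, ``substrate``,
    optional ``site``, ``regulator_class`` ("kinase"/"phosphatase"),
    ``evidence_types`` (non-genetic subset of the four types) and an
    optional ``genetic`` flag requesting a corroborating genetic record.
    """
    rng = child_rng(seed, "evidence")
    motif, quant, physical, genetic = [], [], [], []
    for e in planted_edges:
        site = e.get("site")
        cls = e.get("regulator_class", "kinase")
        types = set(e.get("evidence_types", {"motif_prediction"}))
        if not types - {"genetic_interaction"}:
            raise ValueError("planted edge must carry non-genetic evidence")
        base = {"regulator": e["regulator"], "substrate": e["substrate"], "site": site}
        if "motif_prediction" in types:
            motif.append({**base, "score": float(rng.uniform(2.5, 6.0))})
        if "quant_perturbation" in types:
            fc = -float(rng.uniform(1.6, 4.0)) if cls == "kinase" else float(rng.uniform(1.6, 4.0))
            quant.append(
                {**base, "regulator_class": cls, "fold_change": fc,
                 "p_value": float(rng.uniform(1e-4, 0.04))}
            )
        if "physical_interaction" in types:
            physical.append(base)
        if e.get("genetic"):
            genetic.append({**base, "interaction": "synthetic_lethal"})

    planted_pairs = {(e["regulator"], e["substrate"]) for e in planted_edges}
    for k in range(n_noise_records):
        reg, sub = f"NOISEK{k}", f"NOISEE{k}"
        assert (reg, sub) not in planted_pairs
        kind = rng.choice(["motif_low", "quant_p", "quant_sign", "genetic_only"])
        base = {"regulator": reg, "substrate": sub, "site": None}
        if kind == "motif_low":
            motif.append({**base, "score": float(rng.uniform(0.0, 2.0))})
        elif kind == "quant_p":
            quant.append({**base, "regulator_class": "kinase",
                          "fold_change": -2.0, "p_value": float(rng.uniform(0.05, 0.9))})
        elif kind == "quant_sign":
            quant.append({**base, "regulator_class": "kinase",
                          "fold_change": float(rng.uniform(1.6, 3.0)),
                          "p_value": float(rng.uniform(1e-4, 0.04))})
        else:
            genetic.append({**base, "interaction": "suppression"})

    cols = ["regulator", "substrate", "site"]
    tables = {
        "motif": pd.DataFrame(motif, columns=cols + ["score"]),
        "quant": pd.DataFrame(quant, columns=cols + ["regulator_class", "fold_change", "p_value"]),
        "physical": pd.DataFrame(physical, columns=cols),
        "genetic": pd.DataFrame(genetic, columns=cols + ["interaction"]),
    }
    truth = {
        "planted_edges": [
            {
                "regulator": e["regulator"],
                "substrate": e["substrate"],
                "site": e.get("site"),
                "evidence_types": sorted(set(e.get("evidence_types", {"motif_prediction"}))),
                "genetic": bool(e.get("genetic")),
            }
            for e in planted_edges
        ],
        "n_noise_records": n_noise_records,
        "seed": seed,
    }
    return tables, truth


def gen_disorder_track(length: int, seed: int = 0, smooth: int = 15) -> np.ndarray:
    """Smooth per-residue disorder propensity in [0, 1]."""
    rng = child_rng(seed, "disorder")
    raw = rng.uniform(0, 1, length + 2 * smooth)
    kernel = np.ones(2 * smooth + 1) / (2 * smooth + 1)
    smoothed = np.convolve(raw, kernel, mode="valid")[:length]
    lo, hi = smoothed.min(), smoothed.max()
    return (smoothed - lo) / (hi - lo) if hi > lo else smoothed


def gen_domains(length: int, n_domains: int = 2, seed: int = 0) -> list[tuple[int, int]]:
    """Non-overlapping 1-based inclusive domain intervals."""
    rng = child_rng(seed, "domains")
    width = max(10, length // (n_domains * 3))
    starts = np.sort(rng.choice(length - width, size=n_domains, replace=False) + 1)
    out = []
    last_end = 0
    for s in starts:
        s = max(int(s), last_end + 1)
        e = min(s + width - 1, length)
        if s <= e:
            out.append((s, e))
            last_end = e
    return out


def make_fixture_dir(path: str | Path, seed: int = 0, n_sites: int = 10) -> dict:
    """Write a self-contained fixture directory plus ground_truth.json.

    Contents: protein FASTA, PSM TSV, a pair of XIC trace TSVs, a
    methylation-count TSV, the four evidence tables, a disorder track and
    a domain table.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    protein = gen_protein(400, {"K": 0.08, "R": 0.06, "S": 0.12, "T": 0.08}, seed=seed)
    with open(path / "protein.fasta", "w") as fh:
        fh.write(">ENZ1 synthetic histone-modifying enzyme\n")
        for i in range(0, len(protein), 60):
            fh.write(protein[i : i + 60] + "\n")

    sites = choose_phospho_sites(protein, n_sites, seed=seed)
    psms, psm_truth = gen_psm_table(
        "ENZ1", protein, [(p, "phospho") for p in sites], n_psms=4 * n_sites, seed=seed
    )
    psms.to_csv(path / "psms.tsv", sep="\t", index=False)

    occ = 0.20
    t_mod, t_unmod, xic_truth = gen_xic_pair(occ, seed=seed)
    for name, tr in (("xic_modified", t_mod), ("xic_unmodified", t_unmod)):
        pd.DataFrame({"rt": tr.rt, "intensity": tr.intensity}).to_csv(
            path / f"{name}.tsv", sep="\t", index=False
        )

    betas = {"WT": 0.0, "triple_null": 1.5, "triple_mimetic": 0.8}
    methyl, methyl_truth = gen_methyl_counts(betas, seed=seed)
    methyl.to_csv(path / "methyl_counts.tsv", sep="\t", index=False)

    planted = [
        {"regulator": "KIN1", "substrate": "ENZ1", "site": sites[0],
         "evidence_types": {"motif_prediction", "quant_perturbation"}, "genetic": True},
        {"regulator": "KIN1", "substrate": "ENZ2",
         "evidence_types": {"physical_interaction"}},
        {"regulator": "PPH1", "substrate": "ENZ1", "site": sites[1],
         "regulator_class": "phosphatase", "evidence_types": {"quant_perturbation"}},
    ]
    tables, net_truth = gen_evidence_tables(planted, n_noise_records=8, seed=seed)
    for name, df in tables.items():
        df.to_csv(path / f"evidence_{name}.tsv", sep="\t", index=False)

    disorder = gen_disorder_track(len(protein), seed=seed)
    pd.DataFrame(
        {"position": np.arange(1, len(protein) + 1), "score": np.round(disorder, 4)}
    ).to_csv(path / "disorder.tsv", sep="\t", index=False)
    domains = gen_domains(len(protein), seed=seed)
    pd.DataFrame(
        [{"protein_id": "ENZ1", "name": f"DOM{i+1}", "start": s, "end": e,
          "domain_class": "catalytic"} for i, (s, e) in enumerate(domains)]
    ).to_csv(path / "domains.tsv", sep="\t", index=False)

    truth = {
        "seed": seed,
        "protein_length": len(protein),
        "psm": psm_truth,
        "xic": xic_truth,
        "methyl": methyl_truth,
        "network": net_truth,
        "domains": domains,
    }
    with open(path / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
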