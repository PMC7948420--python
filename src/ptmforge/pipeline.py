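"""End-to-end orchestration: filter -> collate -> coverage -> quant ->
context -> stats -> network, from a single declarative configuration.

Every stage reads/writes plain TSV/JSON under the output directory, the
run report lists each output with a SHA-256 checksum, and a failing stage
halts its dependents with a stage-named diagnostic. Re-running the same
configuration on the same inputs is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import coverage as covmod
from . import network as netmod
from . import ordinal, psm, xic
from .context import DisorderTrack, DomainInterval, disorder_context, domain_context

__all__ = ["RunConfig", "StageError", "run_pipeline", "DEFAULT_THRESHOLDS"]

#: Every admission/quality threshold used anywhere in the pipeline, under
#: one documented key, defaulting to the standard printed value.
DEFAULT_THRESHOLDS = {
    "fdr": 0.01,
    "ion_score": 30.0,
    "expect": 0.05,
    "locprob": 95.0,
    "xic_ppm": 10.0,
    "disorder": 0.5,
    "networkin": 2.0,
    "quant_p": 0.05,
    "fc": 1.5,
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    thresholds: dict = field(default_factory=dict)
    seed: int = 0
    reference_strain: str = "WT"

    def __post_init__(self) -> None:
        unknown = set(self.thresholds) - set(DEFAULT_THRESHOLDS)
        if unknown:
            raise ValueError(f"unknown threshold key(s): {sorted(unknown)}")

    def threshold(self, key: str) -> float:
        if key not in DEFAULT_THRESHOLDS:
            raise KeyError(f"unknown threshold key: {key!r}")
        return float(self.thresholds.get(key, DEFAULT_THRESHOLDS[key]))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "stages": {}, "manifest": {}}
    outputs: list[Path] = []

    def record(stage: str, summary: dict, files: list[Path]) -> None:
        report["stages"][stage] = summary
        outputs.extend(files)

    def fail(stage: str, exc: Exception) -> None:
        report["stages"][stage] = {"error": f"{type(exc).__name__}: {exc}"}
        _finish(report, outputs, outdir)
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    # -- filter ------------------------------------------------------------
    try:
        psms = pd.read_csv(indir / "psms.tsv", sep="\t", keep_default_na=False,
                           na_values=[])
        for col in ("ion_score", "expect_p", "psm_fdr"):
            psms[col] = pd.to_numeric(psms[col])
        thresholds = psm.FilterThresholds(
            fdr=config.threshold("fdr"),
            score=config.threshold("ion_score"),
            expect=config.threshold("expect"),
            locprob=config.threshold("locprob"),
        )
        filtered = psm.filter_psms(psms, thresholds)
        fpath = outdir / "filtered_psms.tsv"
        filtered.to_csv(fpath, sep="\t", index=False)
        record("filter", {"n_input": len(psms), "n_passing": len(filtered)}, [fpath])
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - report any stage failure
        fail("filter", exc)

    # -- collate -----------------------------------------------------------
    try:
        proteins = _read_fasta(indir / "protein.fasta")
        known_path = indir / "known_sites.tsv"
        known = (
            pd.read_csv(known_path, sep="\t") if known_path.exists() else None
        )
        sites, summary = psm.collate_sites(filtered, proteins, known)
        spath = outdir / "sites.tsv"
        pd.DataFrame(
            [
                {
                    "protein_id": s.protein_id,
                    "position": s.position,
                    "residue": s.residue,
                    "ptm_type": s.ptm_type,
                    "novelty": s.novelty,
                    "evidence": ";".join(
                        f"{p}/{f}" for p, f in sorted(s.evidence)
                    ),
                }
                for s in sites
            ]
        ).to_csv(spath, sep="\t", index=False)
        record(
            "collate",
            {
                "n_nonredundant_peptidoforms": summary.n_nonredundant_peptidoforms,
                "n_unique_sites": summary.n_unique_sites,
            },
            [spath],
        )
    except StageError:
        raise
    except Exception as exc:
        fail("collate", exc)

    # -- coverage ----------------------------------------------------------
    try:
        cov_rows, files = [], []
        for pid, seq in proteins.items():
            peps = [
                (r.peptide, (r.protease, r.fragmentation))
                for r in filtered.itertuples()
                if r.protein_id == pid
            ]
            prof = covmod.map_peptides(seq, peps, protein_id=pid)
            cov_rows.append(
                {"protein_id": pid, "length": prof.length,
                 "combined_coverage_pct": prof.combined_coverage_pct}
            )
            dpath = outdir / f"depth_{pid}.tsv"
            prof.depth_track().to_csv(dpath, sep="\t", index=False)
            files.append(dpath)
        cpath = outdir / "coverage.tsv"
        pd.DataFrame(cov_rows).to_csv(cpath, sep="\t", index=False)
        record("coverage", {"proteins": cov_rows}, [cpath, *files])
    except StageError:
        raise
    except Exception as exc:
        fail("coverage", exc)

    # -- quant -------------------------------------------------------------
    try:
        quant_summary = {}
        qfiles = []
        mod_path = indir / "xic_modified.tsv"
        if mod_path.exists():
            t_mod = pd.read_csv(mod_path, sep="\t")
            t_unmod = pd.read_csv(indir / "xic_unmodified.tsv", sep="\t")
            a_mod = xic.integrate_peak(
                xic.ChromatogramTrace(t_mod["rt"].to_numpy(), t_mod["intensity"].to_numpy())
            )
            a_unmod = xic.integrate_peak(
                xic.ChromatogramTrace(t_unmod["rt"].to_numpy(), t_unmod["intensity"].to_numpy())
            )
            occ = xic.occupancy(a_mod.area, a_unmod.area)
            qpath = outdir / "occupancy.tsv"
            pd.DataFrame(
                [{"area_modified": occ.area_modified,
                  "area_unmodified": occ.area_unmodified,
                  "occupancy": occ.occupancy}]
            ).to_csv(qpath, sep="\t", index=False)
            qfiles.append(qpath)
            quant_summary["occupancy"] = occ.occupancy
        record("quant", quant_summary, qfiles)
    except StageError:
        raise
    except Exception as exc:
        fail("quant", exc)

    # -- context -----------------------------------------------------------
    try:
        ctx_summary = {}
        cfiles = []
        dis_path = indir / "disorder.tsv"
        if dis_path.exists() and sites:
            track_df = pd.read_csv(dis_path, sep="\t")
            pid = sites[0].protein_id
            track = DisorderTrack(pid, track_df["score"].to_numpy(),
                                  threshold=config.threshold("disorder"))
            positions = [s.position for s in sites if s.protein_id == pid]
            dis = disorder_context(positions, track)
            ctx_summary["percent_disordered"] = round(dis["percent_disordered"], 1)
            ctx_summary["n_sites_disordered"] = dis["n_sites_disordered"]
            ctx_summary["n_sites_ordered"] = dis["n_sites_ordered"]
            dom_path = indir / "domains.tsv"
            dom_flags = {}
            if dom_path.exists():
                dom_df = pd.read_csv(dom_path, sep="\t")
                domains = [
                    DomainInterval(r.protein_id, r.name, int(r.start), int(r.end),
                                   getattr(r, "domain_class", "catalytic"))
                    for r in dom_df.itertuples()
                ]
                dom = domain_context(positions, domains)
                ctx_summary["fraction_in_domain"] = dom["fraction_in_domain"]
                dom_flags = dom["site_in_domain"]
            xpath = outdir / "site_context.tsv"
            pd.DataFrame(
                [{"protein_id": pid, "position": p,
                  "disordered": dis["site_disordered"][p],
                  "in_domain": dom_flags.get(p, False)} for p in positions]
            ).to_csv(xpath, sep="\t", index=False)
            cfiles.append(xpath)
        record("context", ctx_summary, cfiles)
    except StageError:
        raise
    except Exception as exc:
        fail("context", exc)

    # -- stats -------------------------------------------------------------
    try:
        stats_summary = {}
        sfiles = []
        mpath = indir / "methyl_counts.tsv"
        if mpath.exists():
            counts = pd.read_csv(mpath, sep="\t")
            po = ordinal.fit_proportional_odds(
                counts, config.reference_strain, mode="counts"
            )
            ac = ordinal.fit_adjacent_category(
                counts, config.reference_strain, mode="counts"
            )
            stat, df_, p = ordinal.lr_test(po, ac)
            frame = po.summary_frame()
            tpath = outdir / "methyl_stats.tsv"
            frame.to_csv(tpath, sep="\t", index=False)
            sfiles.append(tpath)
            stats_summary = {
                "common_odds_ratios": {
                    r["strain"]: r["odds_ratio"] for _, r in frame.iterrows()
                },
                "p_values": {r["strain"]: r["p_value"] for _, r in frame.iterrows()},
                "proportional_odds_lr": {"statistic": stat, "df": df_, "p": p},
            }
        record("stats", stats_summary, sfiles)
    except StageError:
        raise
    except Exception as exc:
        fail("stats", exc)

    # -- network -----------------------------------------------------------
    try:
        net_summary = {}
        nfiles = []
        motif_path = indir / "evidence_motif.tsv"
        if motif_path.exists():
            def load(name):
                p = indir / f"evidence_{name}.tsv"
                return pd.read_csv(p, sep="\t") if p.exists() else None

            motif = netmod.admit_motif(load("motif"))
            quant = netmod.admit_quant(load("quant"))
            phys_df = load("physical")
            physical = netmod.admit_physical(phys_df) if phys_df is not None and len(phys_df) else []
            net = netmod.assemble(motif, quant, physical, load("genetic"))
            npath = outdir / "network_edges.tsv"
            net.edge_table().to_csv(npath, sep="\t", index=False)
            nfiles.append(npath)
            net_summary = {
                "n_edges": len(net.edges),
                "multi_substrate_regulators": sorted(net.multi_substrate_regulators),
            }
        record("network", net_summary, nfiles)
    except StageError:
        raise
    except Exception as exc:
        fail("network", exc)

    # -- planted-truth comparison, when available --------------------------
    truth_path = indir / "ground_truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        cmp: dict = {}
        planted_sites = {tuple(s) for s in truth["psm"]["true_sites"]}
        recovered = {
            (s.position, s.ptm_type) for s in sites
        }
        cmp["sites"] = {
            "planted": len(planted_sites),
            "recovered": len(recovered),
            "exact_match": recovered == planted_sites,
        }
        if "occupancy" in report["stages"]["quant"]:
            cmp["occupancy"] = {
                "planted": truth["xic"]["occupancy"],
                "recovered": report["stages"]["quant"]["occupancy"],
            }
        report["planted_vs_recovered"] = cmp

    return _finish(report, outputs, outdir)


def _finish(report: dict, outputs: list[Path], outdir: Path) -> dict:
    for path in outputs:
        report["manifest"][path.name] = _sha256(path)
    rpath = outdir / "run_report.json"
    rpath.write_text(json.dumps(report, indent=1, sort_keys=True, default=str))
    return report
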