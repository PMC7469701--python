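"""End-to-end orchestration: simulate -> profiles -> abundance test ->
off-target trend -> FACS, with TSV/JSON outputs under one run directory and a
machine-readable summary."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, abundance, facs, io, offtarget, profiles, simulate
from .config import RunConfig
from .types import CleavageModel, CountMatrix, FragmentSet, SampleDesign

log = logging.getLogger("csmkd")


@dataclass
class RunReport:
    outdir: Path
    summary: dict

    @property
    def summary_path(self) -> Path:
        return self.outdir / "summary.json"


def _stage_seed(cfg: RunConfig, k: int) -> int:
    # deterministic per-stage derivation from the root seed, kept < 2**31
    return (cfg.seed * 1_000_003 + k) % (2**31 - 1)


def build_inputs(cfg: RunConfig):
    """Stage 1: transcriptome, crRNA, design, fragments (with contamination),
    counts."""
    t = cfg.transcriptome
    model = simulate.make_transcriptome(
        n_genes=t["n_genes"],
        length_range=tuple(t["length_range"]),
        gc_target=t["gc_target"],
        target_length=t["target_length"],
        target_weight=t.get("target_weight"),
        seed=_stage_seed(cfg, 1),
    )
    crrna = simulate.make_crrna(model, cfg.crrna["protospacer_start"])
    if cfg.complementarity_spectrum:
        model = simulate.plant_complementarity_spectrum(
            model, crrna, cfg.complementarity_spectrum, seed=_stage_seed(cfg, 2)
        )
    design = simulate.make_design(
        n_batches=cfg.design["n_batches"],
        timepoints=cfg.design["timepoints"],
        conditions=cfg.design["conditions"],
    )
    model = simulate.apply_batch_effects(model, design, batch_factors=cfg.batch_factors)
    cleave = CleavageModel(**cfg.cleavage)
    frags = simulate.simulate_fragments(
        model,
        crrna,
        cleave,
        design,
        depth=cfg.depth,
        fraglen=tuple(cfg.fraglen),
        seed=_stage_seed(cfg, 3),
        dispersion=cfg.dispersion,
    )
    rates = {
        s.sample_id: float(cfg.contamination.get(s.timepoint, 0.0)) for s in design.samples
    }
    frags = simulate.spike_crrna_contamination(frags, crrna, rates, seed=_stage_seed(cfg, 4))
    counts = simulate.counts_from_fragments(frags)
    return model, crrna, cleave, design, frags, counts


def profile_stage(cfg: RunConfig, crrna, cleave, design: SampleDesign, frags: FragmentSet, outdir: Path) -> dict:
    """Stage 2: coverage/LFC/end profiles, diff-ends, peak call, stagger scan
    and crRNA persistence on the target transcript."""
    a = cfg.analysis
    tp = cfg.design["timepoints"][-1] if len(cfg.design["timepoints"]) else None
    inj_ids = design.subset(timepoint=tp, condition="injected").sample_ids
    mock_ids = design.subset(timepoint=tp, condition="mock").sample_ids
    tid = crrna.target_id

    cov_inj = [profiles.coverage_fraction(frags, tid, s) for s in inj_ids]
    cov_mock = [profiles.coverage_fraction(frags, tid, s) for s in mock_ids]
    lfc = profiles.lfc_coverage(cov_inj, cov_mock, epsilon=a["epsilon"])
    ends_inj = [profiles.end_distribution(frags, tid, s, a["which_ends"], normalized=True) for s in inj_ids]
    ends_mock = [profiles.end_distribution(frags, tid, s, a["which_ends"], normalized=True) for s in mock_ids]
    diff = profiles.diff_ends(ends_inj, ends_mock, ci_method=a["ci_method"])
    peak = profiles.call_cleavage_peak(diff, crrna, min_z=a["min_z"])
    anchor = peak.position if peak else crrna.protospacer_start
    stag = profiles.stagger_scan(diff, anchor, stagger=cleave.stagger, n_offsets=a["n_offsets"], min_z=a["min_z"])

    tps = list(cfg.design["timepoints"])
    frags_by_tp = {
        t: FragmentSet(
            frags.df[frags.df["sample_id"].isin(design.subset(timepoint=t).sample_ids)],
            frags.transcript_lengths,
        )
        for t in tps
    }
    persist = profiles.crrna_persistence(frags_by_tp, crrna) if len(tps) >= 2 else None

    L = frags.transcript_lengths[tid]
    prof_df = pd.DataFrame(
        {
            "position": np.arange(L),
            "coverage_injected": np.mean([c.values for c in cov_inj], axis=0),
            "coverage_mock": np.mean([c.values for c in cov_mock], axis=0),
            "lfc": lfc.values,
            "diff_ends": diff.mean_diff,
            "ci_low": diff.ci_low,
            "ci_high": diff.ci_high,
        }
    )
    prof_df.to_csv(outdir / "target_profiles.tsv", sep="\t", index=False, float_format="%.8g")

    if cfg.plots:
        _plot_profiles(prof_df, crrna, outdir / "target_profiles.png")

    return {
        "profiled_timepoint": tp,
        "peak": None
        if peak is None
        else {
            "position": peak.position,
            "score": peak.score,
            "z": peak.z,
            "within_protospacer": peak.within_protospacer,
        },
        "true_cut_positions": cleave.cut_positions(crrna.protospacer_start),
        "stagger_verdict": stag.verdict,
        "stagger_scores": dict(zip(map(str, stag.offsets), stag.scores)),
        "persistence": None
        if persist is None
        else {"values": persist.values, "ratio_first_to_last": persist.ratio, "defined": persist.defined},
    }


def _plot_profiles(prof_df: pd.DataFrame, crrna, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(4, 1, figsize=(8, 9), sharex=True)
    x = prof_df["position"]
    axes[0].plot(x, prof_df["coverage_injected"], color="crimson", label="injected")
    axes[0].plot(x, prof_df["coverage_mock"], color="steelblue", label="mock")
    axes[0].set_ylabel("coverage fraction")
    axes[0].legend(frameon=False)
    axes[1].plot(x, prof_df["lfc"], color="black")
    axes[1].axhline(0, lw=0.5, color="grey")
    axes[1].set_ylabel("LFC coverage")
    axes[2].plot(x, prof_df["diff_ends"], color="black")
    axes[2].fill_between(x, prof_df["ci_low"], prof_df["ci_high"], alpha=0.3)
    axes[2].set_ylabel("diff. ends")
    axes[3].axvspan(crrna.protospacer_start, crrna.protospacer_end, color="orange", alpha=0.4)
    axes[3].set_ylabel("protospacer")
    axes[3].set_xlabel("position (nt)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def test_stage(cfg: RunConfig, design: SampleDesign, counts: CountMatrix, outdir: Path, target_id: str) -> dict:
    """Stage 3: per-timepoint target LRT, volcano table and QC."""
    a = cfg.analysis
    results = {}
    volcano_tables = {}
    for tp in cfg.design["timepoints"]:
        sub = design.subset(timepoint=tp)
        cm = counts.align_to(sub)
        vt = abundance.volcano_table(cm, sub, method=a["test_method"], min_mean=a["min_mean"])
        volcano_tables[tp] = vt
        vt.to_csv(outdir / f"volcano_{tp}.tsv", sep="\t", index=False, float_format="%.6g")
        row = vt[vt["gene"] == target_id]
        results[tp] = {
            "target_lfc": None if row.empty else float(row["lfc"].iloc[0]),
            "target_p": None if row.empty else float(row["p"].iloc[0]),
            "target_padj": None if row.empty else float(row["padj"].iloc[0]),
        }
    pca = abundance.pca_samples(counts.align_to(design))
    corr = abundance.correlation_qc(counts.align_to(design))
    depth_ok = abundance.depth_qc(counts.align_to(design), floor=a["depth_floor"])
    off_diag = corr.to_numpy()[~np.eye(len(corr), dtype=bool)]
    qc = {
        "pca_variance_pct": [float(v) for v in pca.variance_pct[:5]],
        "correlation_min": float(off_diag.min()),
        "correlation_max": float(off_diag.max()),
        "depth_pass_fraction": float(depth_ok.mean()),
    }
    return {"per_timepoint": results, "qc": qc}


def offtarget_stage(cfg: RunConfig, model, crrna, design: SampleDesign, counts: CountMatrix, outdir: Path) -> dict:
    """Stage 4: complementarity index and grouped trend test (first timepoint)."""
    index = offtarget.complementarity_index(crrna.spacer, model)
    index.table.to_csv(outdir / "complementarity_index.tsv", sep="\t")
    tp = cfg.design["timepoints"][0]
    sub = design.subset(timepoint=tp)
    trend = offtarget.group_trend(
        counts.align_to(sub), sub, index, cfg.analysis["thresholds"], target_id=model.target_id
    )
    trend.drop(columns="genes").to_csv(outdir / "offtarget_trend.tsv", sep="\t", index=False, float_format="%.6g")
    ok = trend.dropna(subset=["lfc", "se"])
    flat = (
        float(((ok["lfc"].abs() - 1.96 * ok["se"]) <= 0).mean()) if len(ok) else float("nan")
    )
    return {
        "trend": [
            {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in row.items()}
            for row in trend.drop(columns="genes").to_dict("records")
        ],
        "fraction_groups_ci_contains_zero": flat,
        "tested_timepoint": tp,
    }


def facs_stage(cfg: RunConfig, outdir: Path) -> dict:
    """Stage 5: simulated FACS gating and fold change."""
    f = cfg.facs
    ctrl = simulate.simulate_facs_events(
        f["n"], high_frac=f["high_frac"], high_multiplier=f["high_multiplier"],
        knockdown_factor=1.0, seed=_stage_seed(cfg, 5), sample_id="control",
    )
    inj = simulate.simulate_facs_events(
        f["n"], high_frac=f["high_frac"], high_multiplier=f["high_multiplier"],
        knockdown_factor=f["knockdown_factor"], seed=_stage_seed(cfg, 6), sample_id="injected",
    )
    fold = cfg.analysis["gating_fold"]
    g_ctrl = facs.gate_high(ctrl, "control", fold=fold)
    g_inj = facs.gate_high(inj, "injected", fold=fold)
    fc = facs.fold_change(g_ctrl, g_inj)
    events = pd.concat([ctrl.df, inj.df], ignore_index=True)
    events.to_csv(outdir / "facs_events.csv", index=False, float_format="%.6g")
    return {
        "true_knockdown_factor": f["knockdown_factor"],
        "estimated_fold_change": None if not np.isfinite(fc.fold_change) else float(fc.fold_change),
        "ci": [float(fc.ci_low), None if not np.isfinite(fc.ci_high) else float(fc.ci_high)],
        "control_high": g_ctrl.n_high,
        "injected_high": g_inj.n_high,
    }


def run(cfg: RunConfig, outdir: str | Path) -> RunReport:
    """Execute all stages in order; identical config + seed gives identical
    outputs. On a stage failure the exception names the stage and partial
    outputs are kept next to a FAILED marker."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    summary: dict = {"version": __version__, "config_hash": cfg.content_hash(), "seed": cfg.seed}
    stage = "simulate"
    try:
        log.info("stage: simulate")
        model, crrna, cleave, design, frags, counts = build_inputs(cfg)
        io.write_fasta(model, outdir / "transcriptome.fasta")
        io.write_fragments(frags, outdir / "fragments.tsv")
        io.write_counts(counts, outdir / "counts.tsv")
        io.write_design(design, outdir / "design.tsv")
        summary["n_fragments"] = int(len(frags))
        summary["protospacer"] = [crrna.protospacer_start, crrna.protospacer_end]

        stage = "profile"
        log.info("stage: profile")
        summary["profile"] = profile_stage(cfg, crrna, cleave, design, frags, outdir)

        stage = "test"
        log.info("stage: test")
        summary["abundance"] = test_stage(cfg, design, counts, outdir, model.target_id)

        stage = "offtarget"
        log.info("stage: offtarget")
        summary["offtarget"] = offtarget_stage(cfg, model, crrna, design, counts, outdir)

        stage = "facs"
        log.info("stage: facs")
        summary["facs"] = facs_stage(cfg, outdir)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return RunReport(outdir, summary)
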