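"""End-to-end pipeline: simulate -> (preprocess) -> detect -> fractionate ->
CAF -> fit, each stage reading only prior-stage artifacts on disk."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import caf as caf_mod
from . import chronometry, detection, inference, io
from .synthetic import build_design, render_epochs, simulate_trials

logger = logging.getLogger(__name__)

TRIALS_CSV = "trials.csv"
DETECT_CSV = "detect.csv"


def stage_simulate(cfg: io.RunConfig, out: Path) -> None:
    design = build_design(cfg.n_participants, seed=cfg.seed)
    trials = simulate_trials(design, cfg.generative, seed=cfg.seed + 1)
    trials.to_csv(out / TRIALS_CSV, index=False)
    epoch_dir = out / "epochs"
    for pid, sub in trials.groupby("participant_id"):
        epochs = render_epochs(sub, cfg.generative, seed=cfg.seed + 1000 + int(pid))
        io.write_epochs(epochs, epoch_dir, stem=f"sub-{pid:03d}")
    logger.info("simulated %d trials for %d participants",
                len(trials), cfg.n_participants)


def stage_detect(cfg: io.RunConfig, out: Path) -> None:
    epoch_dir = out / "epochs"
    rows = []
    for npy in sorted(epoch_dir.glob("sub-*.npy")):
        epochs = io.read_epochs(epoch_dir, stem=npy.stem)
        for k, epoch in enumerate(epochs):
            det = detection.detect_epoch(epoch, cfg.detection)
            rows.append({
                "participant_id": epoch.meta.get("participant_id"),
                "block": epoch.meta.get("block"),
                "trial_index": epoch.meta.get("trial_index"),
                "press_time_ms": epoch.press_time_ms,
                "onset_ms": det.onset_ms,
                "n_windows": len(det.windows),
                "multi_window": det.multi_window,
                "valid": det.valid,
                "reject_reason": det.reject_reason,
                "partial_detected": det.partial,
                "partial_onset_ms": det.partial_onset_ms,
            })
            if cfg.review_dir and not det.valid:
                _export_review_plot(epoch, det, Path(cfg.review_dir), npy.stem, k)
    det_df = pd.DataFrame(rows)
    det_df.to_csv(out / DETECT_CSV, index=False)
    logger.info("detection: %.2f%% of epochs rejected, %.2f%% partial",
                100 * (1 - det_df["valid"].mean()),
                100 * det_df["partial_detected"].mean())


def _export_review_plot(epoch, det, review_dir: Path, stem: str, k: int) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    review_dir.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 4))
    t = epoch.times()
    for ax, ch in zip(axes, ("response", "non_response")):
        ax.plot(t, epoch.channel(ch), lw=0.4)
        ax.set_ylabel(ch)
    for w in det.windows:
        axes[0].axvspan(w.start_ms, w.end_ms, alpha=0.2, color="orange")
    if det.onset_ms is not None:
        axes[0].axvline(det.onset_ms, color="red", lw=0.8)
    axes[0].set_title(f"{stem} epoch {k}: {det.reject_reason}")
    axes[1].set_xlabel("time (ms)")
    fig.savefig(review_dir / f"{stem}_epoch{k:04d}.png", dpi=90)
    plt.close(fig)


def stage_fractionate(cfg: io.RunConfig, out: Path) -> None:
    trials = pd.read_csv(out / TRIALS_CSV)
    det = pd.read_csv(out / DETECT_CSV)
    keys = ["participant_id", "block", "trial_index"]
    merged = trials.merge(
        det.drop(columns=["press_time_ms"]), on=keys, how="left"
    )
    merged["press_time_ms"] = np.where(merged["timeout"], np.nan,
                                       merged["true_rt"])
    merged["valid"] = merged["valid"].fillna(False).astype(bool)
    merged["partial"] = merged["partial_detected"].fillna(False).astype(bool)
    chron = chronometry.fractionate_trials(merged)
    chron.to_csv(out / "chronometry.csv", index=False)
    for measure in ("pmt", "accuracy", "partial_error"):
        table = chronometry.analysis_filter(chron, measure)
        name = "chronometric" if measure == "pmt" else measure
        table.to_csv(out / f"{name}.csv", index=False)
    summaries = chronometry.exclude_participants(
        chronometry.participant_summaries(chron)
    )
    summaries.to_csv(out / "participants.csv", index=False)
    logger.info(
        "rates: rejected %.2f%%, partial errors %.2f%%, partial correct %.2f%%",
        100 * summaries["rejected_rate"].mean(),
        100 * summaries["partial_error_rate"].mean(),
        100 * summaries["partial_correct_rate"].mean(),
    )
    logger.info("fractionated %d trials; %d participants flagged for exclusion",
                len(chron), int(summaries["excluded"].sum()))


def stage_caf(cfg: io.RunConfig, out: Path) -> None:
    acc = pd.read_csv(out / "accuracy.csv")
    binned = caf_mod.bin_quantiles(acc)
    table = caf_mod.caf_summarize(binned)
    table.to_csv(out / "caf.csv", index=False)
    caf_mod.plot_caf(table, out / "caf.png")


def stage_fit(cfg: io.RunConfig, out: Path) -> None:
    chron = pd.read_csv(out / "chronometric.csv")
    data = chron.rename(columns={"participant_id": "participant",
                                 "stimulus_id": "item", "block": "bias"})
    data["participant"] = "s" + data["participant"].astype(str)
    for measure in cfg.fit_measures:
        spec = inference.ModelSpec(measure, family="gaussian")
        result = inference.fit(spec, data)
        result.fixed_effects.to_csv(out / f"fit_{measure}_coefficients.csv")
        result.random_effects.to_csv(out / f"fit_{measure}_random_effects.csv",
                                     index=False)
        inference.lexicality_contrasts(result).to_csv(
            out / f"fit_{measure}_contrasts.csv")
        logger.info("fit %s: converged=%s BIC=%.1f",
                    measure, result.converged, result.bic)


_STAGES = {
    "simulate": stage_simulate,
    "detect": stage_detect,
    "fractionate": stage_fractionate,
    "caf": stage_caf,
    "fit": stage_fit,
}


def run_pipeline(cfg: io.RunConfig) -> Path:
    """Run the configured stages in order; any failure propagates with a
    stage-tagged message.  Writes a resolved-config copy next to outputs."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), "INFO"))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_resolved_config(cfg, out / "resolved_config.yaml")
    for stage in cfg.stages:
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            _STAGES[stage](cfg, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
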