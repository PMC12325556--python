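"""RT fractionation, trial classification and exclusion rules.

A valid trial's RT (stimulus to button press) is split at the detected EMG
onset into the premotor time (PMT, stimulus to onset) and the motor time
(MT, onset to press); RT = PMT + MT holds exactly by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

PURE_CORRECT = "pure_correct"
PARTIAL_ERROR_CORRECT = "partial_error_correct"
PARTIAL_CORRECT_ERROR = "partial_correct_error"
PLAIN_ERROR = "plain_error"
TIMEOUT = "timeout"
REJECTED = "rejected"

TRIAL_CLASSES = (
    PURE_CORRECT, PARTIAL_ERROR_CORRECT, PARTIAL_CORRECT_ERROR,
    PLAIN_ERROR, TIMEOUT, REJECTED,
)

CHRONOMETRIC_MEASURES = ("rt", "pmt", "mt")


@dataclass(frozen=True)
class TrialChronometry:
    rt: float
    pmt: float
    mt: float
    onset: float
    rejected: bool = False

    def __post_init__(self) -> None:
        if not self.rejected and not (0 < self.pmt < self.rt and self.mt > 0):
            raise ValueError("fractionation violates 0 < pmt < rt, mt > 0")


def fractionate(onset_ms: float, press_time_ms: float) -> TrialChronometry:
    """Split one RT at the EMG onset; degenerate detections (onset at or
    after the press, or before the stimulus) are rejected."""
    if onset_ms is None or press_time_ms is None:
        raise ValueError("fractionate requires both an onset and a press time")
    if onset_ms >= press_time_ms or onset_ms <= 0:
        return TrialChronometry(press_time_ms, np.nan, np.nan, onset_ms, rejected=True)
    return TrialChronometry(
        rt=press_time_ms, pmt=onset_ms, mt=press_time_ms - onset_ms, onset=onset_ms
    )


def classify_trial(correct: bool, partial: bool, timeout: bool,
                   valid_detection: bool = True) -> str:
    """Map accuracy, covert-activation and timeout flags to the trial class.

    Timeouts take precedence; chronometrically unusable (invalid-detection)
    responded trials are 'rejected' but keep their accuracy information for
    the accuracy analyses (see :func:`analysis_filter`).
    """
    if timeout:
        return TIMEOUT
    if not valid_detection:
        return REJECTED
    if correct:
        return PARTIAL_ERROR_CORRECT if partial else PURE_CORRECT
    return PARTIAL_CORRECT_ERROR if partial else PLAIN_ERROR


def fractionate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Vectorized fractionation + classification over a merged trial table.

    Expects columns: press_time_ms, onset_ms, correct, partial, timeout,
    valid (detection validity).  Adds rt/pmt/mt (NaN where unusable) and
    trial_class.
    """
    out = trials.copy()
    onset = out["onset_ms"].to_numpy(dtype=float)
    press = out["press_time_ms"].to_numpy(dtype=float)
    responded = ~out["timeout"].to_numpy(dtype=bool) & np.isfinite(press)
    degenerate = responded & (np.isnan(onset) | (onset >= press) | (onset <= 0))
    usable = (
        responded & out["valid"].to_numpy(dtype=bool) & ~degenerate
    )
    out["rt"] = np.where(responded, press, np.nan)
    out["pmt"] = np.where(usable, onset, np.nan)
    out["mt"] = np.where(usable, press - onset, np.nan)
    out["trial_class"] = [
        classify_trial(c, p, t, v)
        for c, p, t, v in zip(
            out["correct"], out["partial"], out["timeout"],
            out["valid"].to_numpy(dtype=bool) & ~degenerate,
        )
    ]
    return out


def analysis_filter(trials: pd.DataFrame, measure: str,
                    rt_range: tuple[float, float] | None = None) -> pd.DataFrame:
    """Select the analysis set for one measure.

    - chronometric (rt/pmt/mt): pure-correct, valid, experimental trials;
    - accuracy: all responded experimental trials (timeouts removed);
    - partial_error: correct responded experimental trials.

    ``rt_range`` is an optional chronometric trimming hook (low, high in ms);
    no trimming is applied by default.
    """
    exp = ~trials["is_filler"].astype(bool)
    responded = trials["trial_class"] != TIMEOUT
    if measure in CHRONOMETRIC_MEASURES:
        keep = exp & (trials["trial_class"] == PURE_CORRECT) & trials[measure].notna()
        if rt_range is not None:
            keep &= trials["rt"].between(*rt_range)
    elif measure == "accuracy":
        keep = exp & responded
    elif measure == "partial_error":
        keep = exp & responded & trials["correct"].astype(bool)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    return trials[keep].copy()


def participant_summaries(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant accuracy, rejected-epoch rate and partial-error rate
    (experimental trials only)."""
    exp = trials[~trials["is_filler"].astype(bool)]
    responded = exp[exp["trial_class"] != TIMEOUT]
    grp = responded.groupby("participant_id")
    out = pd.DataFrame({
        "accuracy": grp["correct"].mean(),
        "rejected_rate": grp.apply(
            lambda g: (g["trial_class"] == REJECTED).mean(), include_groups=False
        ),
        "partial_error_rate": grp.apply(
            lambda g: g.loc[g["correct"].astype(bool), "partial"].mean(),
            include_groups=False,
        ),
        # covert correct-hand activation on error trials; reported only
        "partial_correct_rate": grp.apply(
            lambda g: float(g.loc[~g["correct"].astype(bool), "partial"].mean())
            if (~g["correct"].astype(bool)).any() else 0.0,
            include_groups=False,
        ),
    }).reset_index()
    return out


def exclude_participants(
    summaries: pd.DataFrame,
    accuracy_sd_criterion: float = 2.5,
    max_rejected_rate: float = 0.25,
) -> pd.DataFrame:
    """Flag participants with accuracy below mean − 2.5 SD of the sample, or
    with more than 25% rejected epochs.

    The mean and SD are computed on the full candidate sample in a single
    pass (no iterative re-exclusion).  With fewer than 3 participants the
    accuracy rule is skipped with a warning.
    """
    out = summaries.copy()
    out["excluded"] = False
    out["exclusion_reason"] = ""
    high_rej = out["rejected_rate"] > max_rejected_rate
    out.loc[high_rej, "excluded"] = True
    out.loc[high_rej, "exclusion_reason"] = "rejected_rate"
    if len(out) < 3:
        warnings.warn("fewer than 3 participants: accuracy exclusion skipped")
        return out
    mean = out["accuracy"].mean()
    sd = out["accuracy"].std(ddof=1)
    low_acc = out["accuracy"] < mean - accuracy_sd_criterion * sd
    out.loc[low_acc, "excluded"] = True
    out.loc[low_acc & high_rej, "exclusion_reason"] = "accuracy+rejected_rate"
    out.loc[low_acc & ~high_rej, "exclusion_reason"] = "accuracy"
    return out
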