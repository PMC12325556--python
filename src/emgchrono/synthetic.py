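"""Synthetic biased lexical-decision experiment with raw-EMG rendering.

Three layers, each usable on its own:

1. :func:`build_design` — trial tables for the three-block design (neutral
   50/50, word-bias 75/25, pseudoword-bias 25/75; 240 experimental trials
   analyzed per block, fillers making up the bias in biased blocks).
2. :func:`simulate_trials` — trial-level premotor time (PMT), motor time
   (MT), accuracy and partial-error outcomes from a crossed random-effects
   generative model whose fixed-effect defaults are the published estimates;
   RT = PMT + MT exactly.
3. :func:`render_epoch` / :func:`render_recording` — 1000 Hz two-channel EMG
   epochs (or a continuous recording plus event table) whose burst onsets
   and offsets realize the simulated PMT and RT.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import (
    BIAS_LEVELS,
    GenerativeParams,
    WaveformParams,
)
from .preprocessing import EmgEpoch, Recording

N_EXPERIMENTAL_PER_CATEGORY = 120
N_FILLERS = 240
_SETS = (1, 2, 3)

DESIGN_COLUMNS = [
    "participant_id", "block", "block_position", "trial_index", "stimulus_id",
    "lexicality", "is_filler", "mapping_half", "response_hand",
]


def _experimental_items(set_index: int) -> tuple[list[str], list[str]]:
    words = [f"w{set_index}_{i:03d}" for i in range(1, N_EXPERIMENTAL_PER_CATEGORY + 1)]
    pseudo = [f"p{set_index}_{i:03d}" for i in range(1, N_EXPERIMENTAL_PER_CATEGORY + 1)]
    return words, pseudo


def _filler_items(lexicality: str) -> list[str]:
    prefix = "fw" if lexicality == "word" else "fp"
    return [f"{prefix}_{i:03d}" for i in range(1, N_FILLERS + 1)]


def build_design(n_participants: int, seed: int = 0) -> pd.DataFrame:
    """Generate per-participant trial tables for the three-block design.

    Counterbalancing proxies: the block order after the initial neutral block
    alternates with participant parity; the stimulus-set -> block assignment
    rotates with participant index; the initial stimulus-response mapping
    alternates every second participant.  The mapping reverses exactly once,
    halfway through each block.  Deterministic given ``seed``.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for p in range(n_participants):
        pid = p + 1
        biased = ["word_bias", "pseudoword_bias"]
        if p % 2 == 1:
            biased = biased[::-1]
        blocks = ["neutral"] + biased
        first_mapping = (p // 2) % 2  # 0: word->right; 1: word->left
        for b, block in enumerate(blocks):
            set_idx = _SETS[(p + b) % 3]
            words, pseudo = _experimental_items(set_idx)
            items = [(s, "word", False) for s in words]
            items += [(s, "pseudoword", False) for s in pseudo]
            if block == "word_bias":
                items += [(s, "word", True) for s in _filler_items("word")]
            elif block == "pseudoword_bias":
                items += [(s, "pseudoword", True) for s in _filler_items("pseudoword")]
            # split each stratum evenly across the two mapping halves
            halves: dict[int, list] = {1: [], 2: []}
            for stratum in ("word", "pseudoword"):
                for filler in (False, True):
                    sub = [it for it in items if it[1] == stratum and it[2] == filler]
                    if not sub:
                        continue
                    order = rng.permutation(len(sub))
                    mid = len(sub) // 2
                    halves[1] += [sub[i] for i in order[:mid]]
                    halves[2] += [sub[i] for i in order[mid:]]
            trial = 0
            for half in (1, 2):
                mapping = first_mapping if half == 1 else 1 - first_mapping
                order = rng.permutation(len(halves[half]))
                for i in order:
                    stim, lex, filler = halves[half][i]
                    if mapping == 0:
                        hand = "right" if lex == "word" else "left"
                    else:
                        hand = "left" if lex == "word" else "right"
                    trial += 1
                    rows.append({
                        "participant_id": pid,
                        "block": block,
                        "block_position": b + 1,
                        "trial_index": trial,
                        "stimulus_id": stim,
                        "lexicality": lex,
                        "is_filler": filler,
                        "mapping_half": half,
                        "response_hand": hand,
                    })
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def _linear_predictor(fixed, bias: np.ndarray, lex: np.ndarray) -> np.ndarray:
    unknown = set(np.unique(bias)) - set(BIAS_LEVELS)
    if unknown:
        raise ValueError(f"unknown bias level(s) {sorted(unknown)}")
    unknown = set(np.unique(lex)) - {"word", "pseudoword"}
    if unknown:
        raise ValueError(f"unknown lexicality level(s) {sorted(unknown)}")
    pw = (lex == "pseudoword").astype(float)
    pb = (bias == "pseudoword_bias").astype(float)
    wb = (bias == "word_bias").astype(float)
    return (
        fixed.intercept
        + fixed.bias_pseudoword * pb
        + fixed.bias_word * wb
        + fixed.lexicality_pseudoword * pw
        + fixed.bias_pseudoword_x_lexicality * pb * pw
        + fixed.bias_word_x_lexicality * wb * pw
    )


def _random_intercepts(levels: np.ndarray, sd: float, rng) -> dict:
    return dict(zip(levels, rng.normal(0.0, sd, size=len(levels))))


def simulate_trials(
    design: pd.DataFrame,
    params: GenerativeParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw trial-level outcomes for every design row.

    PMT and MT are gaussian with crossed participant/item random intercepts
    and (optionally correlated) residuals, floored at physiologically minimal
    values; RT = PMT + MT exactly.  Accuracy and partial (non-response-hand)
    activation are Bernoulli on the logit scale.  On error trials the partial
    flag represents a covert *correct* activation, drawn at the constant
    ``partial_correct_rate``.  Trials with RT beyond the response deadline
    are flagged ``timeout``.
    """
    params = params or GenerativeParams()
    rng = np.random.default_rng(seed)
    out = design.copy().reset_index(drop=True)
    n = len(out)
    bias = out["block"].to_numpy()
    lex = out["lexicality"].to_numpy()
    participants = np.sort(out["participant_id"].unique())
    items = np.sort(out["stimulus_id"].unique())

    effects = {}
    for m in ("pmt", "mt", "accuracy", "partial_error"):
        mp = params.measure(m)
        u = _random_intercepts(participants, mp.participant_sd, rng)
        w = _random_intercepts(items, mp.item_sd, rng)
        lp = _linear_predictor(mp.fixed, bias, lex)
        lp += out["participant_id"].map(u).to_numpy()
        lp += out["stimulus_id"].map(w).to_numpy()
        effects[m] = lp

    rho = params.pmt_mt_correlation
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    pmt = effects["pmt"] + params.pmt.residual_sd * z1
    mt = effects["mt"] + params.mt.residual_sd * z2
    pmt = np.maximum(pmt, params.pmt_floor_ms)
    mt = np.maximum(mt, params.mt_floor_ms)

    def expit(x):
        return 1.0 / (1.0 + np.exp(-x))

    correct = rng.random(n) < expit(effects["accuracy"])
    p_partial = np.where(
        correct, expit(effects["partial_error"]), params.partial_correct_rate
    )
    partial = rng.random(n) < p_partial

    out["true_pmt"] = pmt
    out["true_mt"] = mt
    out["true_rt"] = pmt + mt
    out["correct"] = correct
    out["partial"] = partial
    out["timeout"] = out["true_rt"] > params.timeout_ms
    return out


def _burst(n: int, amplitude: float, rise: int, rng) -> np.ndarray:
    """Noise-carrier burst under a trapezoidal envelope.

    The envelope steps to 0.5 at the onset sample and ramps linearly to 1
    over ``rise`` samples (symmetric decay at the end); the carrier is a
    random sign times U(0.5, 1.5), so the onset sample is bounded away from
    zero and noise-free onset detection is sample-exact.
    """
    env = np.ones(n)
    r = min(rise, n)
    if r > 0:
        ramp = 0.5 + 0.5 * np.arange(1, r + 1) / r
        env[:r] = np.minimum(env[:r], ramp)
        env[-r:] = np.minimum(env[-r:], ramp[::-1])
    sign = rng.choice((-1.0, 1.0), size=n)
    mag = rng.uniform(0.5, 1.5, size=n)
    return amplitude * env * sign * mag


def render_epoch(trial, params: GenerativeParams | None = None, rng=None) -> EmgEpoch:
    """Render one trial's two-channel EMG epoch from its simulated outcomes.

    Row 0 holds the channel of the hand that actually pressed (the trial's
    assigned hand on correct trials, the opposite one on errors); it carries
    the response burst from true_pmt to true_rt.  Row 1 carries a smaller
    burst iff the trial has covert (partial) activation.  Ground truth is
    stored in ``meta``.
    """
    params = params or GenerativeParams()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if isinstance(trial, pd.DataFrame):
        if len(trial) != 1:
            raise ValueError("render_epoch expects a single trial")
        trial = trial.iloc[0]
    if bool(trial["timeout"]):
        raise ValueError("cannot render an epoch for a timeout trial")

    wf = params.waveform
    fs = wf.sampling_rate
    n = wf.n_samples
    t = wf.epoch_start_ms + np.arange(n) * 1000.0 / fs
    samples = rng.normal(0.0, wf.baseline_noise_sd, size=(2, n))
    if wf.line_noise_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi, size=2)
        for ch in range(2):
            samples[ch] += wf.line_noise_amplitude * np.sin(
                2 * np.pi * wf.line_noise_freq * t / 1000.0 + phase[ch]
            )

    rise = max(1, int(round(wf.rise_ms * fs / 1000.0)))

    def idx(ms: float) -> int:
        return int(round((ms - wf.epoch_start_ms) * fs / 1000.0))

    pmt, rt = float(trial["true_pmt"]), float(trial["true_rt"])
    i0, i1 = idx(pmt), idx(rt)
    truncated = False
    if i1 > n:
        i1, truncated = n, True
    samples[0, i0:i1] += _burst(i1 - i0, wf.burst_amplitude, rise, rng)

    partial_onset_ms = None
    if bool(trial["partial"]):
        onset = rng.uniform(0.4, 0.7) * pmt
        j0 = idx(onset)
        j1 = min(j0 + int(round(wf.partial_burst_duration_ms * fs / 1000.0)), n)
        samples[1, j0:j1] += _burst(j1 - j0, wf.partial_burst_amplitude, rise, rng)
        partial_onset_ms = wf.epoch_start_ms + j0 * 1000.0 / fs

    hand = trial["response_hand"]
    pressed = hand if bool(trial["correct"]) else ("left" if hand == "right" else "right")
    meta = {
        k: trial[k]
        for k in ("participant_id", "block", "trial_index", "stimulus_id",
                  "lexicality", "is_filler", "response_hand", "correct",
                  "partial", "timeout")
        if k in trial
    }
    meta.update(
        true_pmt=pmt, true_mt=float(trial["true_mt"]), true_rt=rt,
        true_onset_ms=wf.epoch_start_ms + i0 * 1000.0 / fs,
        partial_onset_ms=partial_onset_ms, pressed_hand=pressed,
        truncated=truncated,
    )
    return EmgEpoch(samples, fs, t0_ms=wf.epoch_start_ms,
                    press_time_ms=rt, meta=meta)


def _trial_seeds(seed: int, n: int) -> list:
    return np.random.SeedSequence(seed).spawn(n)


def render_epochs(trials: pd.DataFrame, params: GenerativeParams | None = None,
                  seed: int = 0) -> list[EmgEpoch]:
    """Render every non-timeout trial; per-trial child seeds make each epoch
    reproducible independently of the others."""
    params = params or GenerativeParams()
    seeds = _trial_seeds(seed, len(trials))
    out = []
    for s, (_, row) in zip(seeds, trials.iterrows()):
        if bool(row["timeout"]):
            continue
        out.append(render_epoch(row, params, np.random.default_rng(s)))
    return out


def render_recording(
    trials: pd.DataFrame,
    params: GenerativeParams | None = None,
    seed: int = 0,
    gap_ms: float = 400.0,
) -> Recording:
    """Stitch one participant's trials into a continuous two-channel recording.

    Epochs are rendered with the same per-trial child seeds as
    :func:`render_epochs` and embedded at non-overlapping offsets, so
    re-epoching the recording reproduces the directly rendered epochs
    bit-identically.  Channels are named by hand ('left', 'right').  Events:
    one ``stimulus`` row per trial and one ``press_left``/``press_right`` row
    per responded trial.
    """
    params = params or GenerativeParams()
    wf = params.waveform
    fs = wf.sampling_rate
    span = wf.epoch_end_ms - wf.epoch_start_ms
    stride_ms = span + gap_ms
    trials = trials.reset_index(drop=True)
    n_trials = len(trials)
    total = int(round((stride_ms * n_trials + -wf.epoch_start_ms + gap_ms)
                      * fs / 1000.0)) + 1
    seeds = _trial_seeds(seed, n_trials)
    bg = np.random.default_rng(np.random.SeedSequence((seed, 0x5EED)))
    data = bg.normal(0.0, wf.baseline_noise_sd, size=(2, total))
    names = ("left", "right")
    events = []
    for k, (_, row) in enumerate(trials.iterrows()):
        stim_ms = -wf.epoch_start_ms + gap_ms + k * stride_ms
        events.append({"onset_ms": stim_ms, "type": "stimulus",
                       "trial_index": int(row["trial_index"])})
        if bool(row["timeout"]):
            continue
        epoch = render_epoch(row, params, np.random.default_rng(seeds[k]))
        i0 = int(round((stim_ms + wf.epoch_start_ms) * fs / 1000.0))
        rows = {epoch.meta["pressed_hand"]: 0}
        rows["left" if epoch.meta["pressed_hand"] == "right" else "right"] = 1
        for ch, name in enumerate(names):
            data[ch, i0:i0 + epoch.n_samples] = epoch.samples[rows[name]]
        events.append({
            "onset_ms": stim_ms + float(row["true_rt"]),
            "type": f"press_{epoch.meta['pressed_hand']}",
            "trial_index": int(row["trial_index"]),
        })
    ev = pd.DataFrame(events, columns=["onset_ms", "type", "trial_index"])
    return Recording(data, fs, names, ev)
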