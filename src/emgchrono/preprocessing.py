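"""Filtering, epoching and baseline statistics for two-channel surface EMG.

Conventions: all times are in ms relative to stimulus onset; sample index 0
corresponds to the epoch start (−500 ms by default); intervals are closed at
the start and open at the end.  Epoch row 0 is the response channel (the hand
that pressed), row 1 the non-response channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

logger = logging.getLogger(__name__)

RESPONSE = "response"
NON_RESPONSE = "non_response"
_CHANNEL_ROW = {RESPONSE: 0, NON_RESPONSE: 1}

EPOCH_START_MS = -500.0
EPOCH_END_MS = 2100.0


def channel_row(channel: str) -> int:
    try:
        return _CHANNEL_ROW[channel]
    except KeyError:
        raise ValueError(f"unknown channel {channel!r}") from None


@dataclass
class EmgEpoch:
    """Per-trial two-channel EMG on a fixed time base around stimulus onset."""

    samples: np.ndarray  # (2, T): row 0 response channel, row 1 non-response
    sampling_rate: float
    t0_ms: float = EPOCH_START_MS
    press_time_ms: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != 2:
            raise ValueError("samples must have shape (2, T)")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def times(self) -> np.ndarray:
        step = 1000.0 / self.sampling_rate
        return self.t0_ms + step * np.arange(self.n_samples)

    def index_of(self, t_ms: float) -> int:
        """Sample index nearest to a time in ms."""
        return int(round((t_ms - self.t0_ms) * self.sampling_rate / 1000.0))

    def time_of(self, index: int) -> float:
        return self.t0_ms + index * 1000.0 / self.sampling_rate

    def channel(self, channel: str) -> np.ndarray:
        return self.samples[channel_row(channel)]


@dataclass
class Recording:
    """Continuous multi-channel recording with an event table.

    ``events`` columns: onset_ms, type (stimulus | press_left | press_right),
    trial_index.
    """

    data: np.ndarray  # (n_channels, T)
    sampling_rate: float
    channel_names: tuple[str, ...]
    events: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names must match number of rows")

    @property
    def duration_ms(self) -> float:
        return self.data.shape[1] * 1000.0 / self.sampling_rate


@dataclass(frozen=True)
class BaselineStats:
    """Mean and SD of the rectified signal over the pre-stimulus window."""

    mean_abs: float
    sd_abs: float


def highpass(signal, fs: float, cutoff: float = 10.0, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth high-pass (forward-backward, order doubles)."""
    signal = np.asarray(signal, dtype=float)
    if fs <= 2 * cutoff:
        raise ValueError(f"sampling rate {fs} Hz too low for {cutoff} Hz high-pass")
    sos = scipy.signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    padlen = min(signal.shape[-1] - 1, int(fs))  # >= 1 s of reflection padding
    return scipy.signal.sosfiltfilt(sos, signal, padlen=padlen)


def notch(signal, fs: float, line_freq: float = 50.0, q: float = 35.0) -> np.ndarray:
    """Zero-phase second-order IIR notch (Q = 35, bandwidth ~ 1.4 Hz)."""
    signal = np.asarray(signal, dtype=float)
    if fs <= 2 * line_freq:
        raise ValueError(f"sampling rate {fs} Hz too low for {line_freq} Hz notch")
    b, a = scipy.signal.iirnotch(line_freq, q, fs=fs)
    padlen = min(signal.shape[-1] - 1, int(fs))
    return scipy.signal.filtfilt(b, a, signal, padlen=padlen)


def filter_emg(signal, fs: float, hp_cutoff: float = 10.0,
               line_freq: float = 50.0) -> np.ndarray:
    """Standard preprocessing chain: high-pass then line-noise notch."""
    return notch(highpass(signal, fs, cutoff=hp_cutoff), fs, line_freq=line_freq)


_HANDS = ("left", "right")


def epoch_recording(
    recording: Recording,
    trials: pd.DataFrame | None = None,
    window_ms: tuple[float, float] = (EPOCH_START_MS, EPOCH_END_MS),
    timeout_ms: float = 1500.0,
) -> list[EmgEpoch]:
    """Cut fixed epochs around every stimulus event (pure slicing).

    The response channel is the hand of the first press event in
    (0, timeout_ms] after the stimulus; for trials without a press it falls
    back to the trial's ``response_hand`` from ``trials`` (indexed by
    trial_index).  Stimuli without the required signal margin are skipped
    with a log entry.
    """
    t0, t1 = window_ms
    ev = recording.events
    required = {"onset_ms", "type", "trial_index"}
    if not required.issubset(ev.columns):
        raise ValueError(f"events table must have columns {sorted(required)}")
    fs = recording.sampling_rate
    name_to_row = {n: i for i, n in enumerate(recording.channel_names)}
    for hand in _HANDS:
        if hand not in name_to_row:
            raise ValueError(f"recording must have a {hand!r} channel")
    trial_meta = None
    if trials is not None:
        trial_meta = trials.set_index("trial_index", drop=False)

    presses = ev[ev["type"].str.startswith("press")]
    epochs: list[EmgEpoch] = []
    for _, stim in ev[ev["type"] == "stimulus"].iterrows():
        onset = float(stim["onset_ms"])
        i0 = int(round((onset + t0) * fs / 1000.0))
        n = int(round((t1 - t0) * fs / 1000.0)) + 1
        if i0 < 0 or i0 + n > recording.data.shape[1]:
            logger.warning(
                "skipping stimulus at %.0f ms (trial %s): insufficient signal margin",
                onset, stim["trial_index"],
            )
            continue
        rel = presses["onset_ms"] - onset
        hit = presses[(rel > 0) & (rel <= timeout_ms)]
        press_time = None
        pressed_hand = None
        if len(hit):
            first = hit.iloc[np.argmin(hit["onset_ms"].to_numpy())]
            press_time = float(first["onset_ms"]) - onset
            pressed_hand = first["type"].removeprefix("press_")
        meta = {"trial_index": stim["trial_index"]}
        if trial_meta is not None and stim["trial_index"] in trial_meta.index:
            meta.update(trial_meta.loc[stim["trial_index"]].to_dict())
        if pressed_hand is None:
            pressed_hand = meta.get("response_hand", "right")
        other = "left" if pressed_hand == "right" else "right"
        sl = recording.data[:, i0:i0 + n]
        samples = np.vstack([sl[name_to_row[pressed_hand]], sl[name_to_row[other]]])
        meta["pressed_hand"] = pressed_hand
        epochs.append(
            EmgEpoch(samples.copy(), fs, t0_ms=t0, press_time_ms=press_time, meta=meta)
        )
    return epochs


def baseline_stats(epoch: EmgEpoch, channel: str = RESPONSE) -> BaselineStats:
    """Rectified mean/SD over the pre-stimulus baseline ([t0, 0) ms)."""
    if epoch.t0_ms >= 0:
        raise ValueError("epoch does not cover a pre-stimulus baseline")
    stop = epoch.index_of(0.0)
    rect = np.abs(epoch.channel(channel)[:stop])
    return BaselineStats(float(rect.mean()), float(rect.std(ddof=1)))
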