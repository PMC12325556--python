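"""Parameter containers for the generative model and burst detection.

The generative defaults encode the published fixed-effect estimates for a
three-block biased visual lexical-decision experiment: chronometric measures
(premotor time PMT, motor time MT, in ms) and binary outcomes (response
accuracy and partial errors, on the log-odds scale).  All effects are
expressed in treatment coding with *neutral* as the bias reference and
*word* as the lexicality reference, so a linear predictor for a cell is::

    intercept + bias_pseudoword*[bias==pseudoword_bias]
              + bias_word*[bias==word_bias]
              + lexicality_pseudoword*[lex==pseudoword]
              + interaction terms

RT is never parameterized directly: it is the sum PMT + MT by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

BIAS_LEVELS = ("neutral", "word_bias", "pseudoword_bias")
LEXICALITY_LEVELS = ("word", "pseudoword")

CHRONOMETRIC_MEASURES = ("pmt", "mt")
BINARY_MEASURES = ("accuracy", "partial_error")


@dataclass(frozen=True)
class FixedEffects:
    """Treatment-coded fixed effects (reference: neutral bias, word)."""

    intercept: float
    bias_pseudoword: float
    bias_word: float
    lexicality_pseudoword: float
    bias_pseudoword_x_lexicality: float
    bias_word_x_lexicality: float

    def linear_predictor(self, bias: str, lexicality: str) -> float:
        if bias not in BIAS_LEVELS:
            raise ValueError(f"unknown bias level {bias!r}")
        if lexicality not in LEXICALITY_LEVELS:
            raise ValueError(f"unknown lexicality level {lexicality!r}")
        lp = self.intercept
        pw = lexicality == "pseudoword"
        if bias == "pseudoword_bias":
            lp += self.bias_pseudoword
            if pw:
                lp += self.bias_pseudoword_x_lexicality
        elif bias == "word_bias":
            lp += self.bias_word
            if pw:
                lp += self.bias_word_x_lexicality
        if pw:
            lp += self.lexicality_pseudoword
        return lp

    def lexicality_contrast(self, bias: str) -> float:
        """True word − pseudoword effect within one bias level."""
        return self.linear_predictor(bias, "word") - self.linear_predictor(
            bias, "pseudoword"
        )


# Published fixed-effect estimates used as generative truth (defaults).
PMT_FIXED = FixedEffects(518.14, 6.37, -50.19, 80.21, -95.35, 74.11)
MT_FIXED = FixedEffects(134.40, -4.72, -0.81, 3.51, 0.50, 1.02)
ACCURACY_FIXED = FixedEffects(3.95, -1.24, 0.49, -0.04, 1.94, -1.45)
PARTIAL_ERROR_FIXED = FixedEffects(-3.32, 0.68, -0.69, 0.15, -1.74, 1.27)


@dataclass(frozen=True)
class MeasureParams:
    """Generative parameters for one trial-level measure.

    ``participant_sd`` and ``item_sd`` are crossed random-intercept SDs;
    ``residual_sd`` applies to gaussian (chronometric) measures only and must
    be 0 for log-odds measures.
    """

    fixed: FixedEffects
    participant_sd: float
    item_sd: float
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("participant_sd", "item_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class WaveformParams:
    """Raw-EMG rendering parameters.

    The response burst is a noise carrier under a trapezoidal envelope that
    steps to half amplitude at the onset sample, ramps to full amplitude over
    ``rise_ms``, and decays over the final ``rise_ms`` before the button
    press.  The half-amplitude onset step keeps the first burst sample above
    the epoch-average rectified level, which makes noise-free onset detection
    sample-exact.  ``burst_amplitude`` is the plateau RMS in multiples of the
    carrier's unit RMS, so burst_amplitude / baseline_noise_sd is the
    burst-to-noise RMS ratio.
    """

    sampling_rate: float = 1000.0
    epoch_start_ms: float = -500.0
    epoch_end_ms: float = 2100.0
    baseline_noise_sd: float = 1.0
    burst_amplitude: float = 5.0
    partial_burst_amplitude: float = 2.5
    partial_burst_duration_ms: float = 100.0
    rise_ms: float = 5.0
    line_noise_amplitude: float = 0.0
    line_noise_freq: float = 50.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.baseline_noise_sd < 0:
            raise ValueError("baseline_noise_sd must be >= 0")
        if self.burst_amplitude <= self.baseline_noise_sd:
            raise ValueError("burst_amplitude must exceed baseline_noise_sd")

    @property
    def n_samples(self) -> int:
        span = self.epoch_end_ms - self.epoch_start_ms
        return int(round(span * self.sampling_rate / 1000.0)) + 1


@dataclass(frozen=True)
class GenerativeParams:
    """Complete simulation truth for the synthetic experiment.

    Chronometric random/residual SDs (ms) are documented placeholders — the
    published random-effect variances live in supplementary material — chosen
    at magnitudes typical of lexical-decision PMT/MT data; fixed-effect
    recovery in this balanced design is unbiased regardless of their values.
    """

    pmt: MeasureParams = field(
        default_factory=lambda: MeasureParams(PMT_FIXED, 80.0, 30.0, 100.0)
    )
    mt: MeasureParams = field(
        default_factory=lambda: MeasureParams(MT_FIXED, 15.0, 5.0, 25.0)
    )
    accuracy: MeasureParams = field(
        default_factory=lambda: MeasureParams(ACCURACY_FIXED, 0.8, 0.3)
    )
    partial_error: MeasureParams = field(
        default_factory=lambda: MeasureParams(PARTIAL_ERROR_FIXED, 0.8, 0.3)
    )
    pmt_mt_correlation: float = 0.0  # within-trial residual correlation
    partial_correct_rate: float = 0.003  # covert correct-hand bursts on errors
    pmt_floor_ms: float = 50.0
    mt_floor_ms: float = 25.0
    timeout_ms: float = 1500.0
    waveform: WaveformParams = field(default_factory=WaveformParams)

    def __post_init__(self) -> None:
        if self.timeout_ms <= 0:
            raise ValueError("timeout_ms must be > 0")
        if not -1.0 <= self.pmt_mt_correlation <= 1.0:
            raise ValueError("pmt_mt_correlation must be in [-1, 1]")
        for m in BINARY_MEASURES:
            if getattr(self, m).residual_sd != 0.0:
                raise ValueError(f"{m} is a log-odds measure; residual_sd must be 0")

    def measure(self, name: str) -> MeasureParams:
        if name not in CHRONOMETRIC_MEASURES + BINARY_MEASURES:
            raise ValueError(f"unknown measure {name!r}")
        return getattr(self, name)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DetectionConfig:
    """Burst-window and onset-detection rules.

    threshold_sd: multiples of the baseline rectified-signal SD above the
        baseline rectified mean defining supra-threshold activity.
    merge_gap_ms: windows separated by a gap strictly shorter than this are
        aggregated into one.
    min_duration_ms: windows strictly shorter than this are discarded.
    """

    threshold_sd: float = 3.5
    merge_gap_ms: float = 25.0
    min_duration_ms: float = 50.0
    onset_search_start_ms: float = 0.0
    partial_search_back_ms: float = 100.0

    def __post_init__(self) -> None:
        for name in ("threshold_sd", "merge_gap_ms", "min_duration_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _fixed_from_mapping(d: Mapping) -> FixedEffects:
    return FixedEffects(**d)


def generative_params_from_dict(d: Mapping) -> GenerativeParams:
    """Build GenerativeParams from a (YAML-loaded) nested mapping.

    Unknown keys raise, so config typos fail loudly.
    """
    kwargs: dict = {}
    d = dict(d)
    for m in CHRONOMETRIC_MEASURES + BINARY_MEASURES:
        if m in d:
            sub = dict(d.pop(m))
            fixed = sub.pop("fixed", None)
            base = getattr(GenerativeParams(), m)
            mp_kwargs = {
                "fixed": _fixed_from_mapping(fixed) if fixed else base.fixed,
                "participant_sd": sub.pop("participant_sd", base.participant_sd),
                "item_sd": sub.pop("item_sd", base.item_sd),
                "residual_sd": sub.pop("residual_sd", base.residual_sd),
            }
            if sub:
                raise ValueError(f"unknown keys in {m!r} params: {sorted(sub)}")
            kwargs[m] = MeasureParams(**mp_kwargs)
    if "waveform" in d:
        kwargs["waveform"] = WaveformParams(**d.pop("waveform"))
    allowed = {
        "pmt_mt_correlation",
        "partial_correct_rate",
        "pmt_floor_ms",
        "mt_floor_ms",
        "timeout_ms",
    }
    for k in list(d):
        if k in allowed:
            kwargs[k] = d.pop(k)
    if d:
        raise ValueError(f"unknown generative-parameter keys: {sorted(d)}")
    return GenerativeParams(**kwargs)
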