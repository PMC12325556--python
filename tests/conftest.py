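import numpy as np
import pandas as pd
import pytest

from emgchrono import EmgEpoch, build_design, simulate_trials


@pytest.fixture(scope="session")
def design_one():
    return build_design(1, seed=7)


@pytest.fixture(scope="session")
def trials_one(design_one):
    return simulate_trials(design_one, seed=8)


def make_epoch(
    signal_response=None,
    signal_non_response=None,
    fs=1000.0,
    t0_ms=-500.0,
    n=2601,
    press_time_ms=None,
    **meta,
):
    """Hand-built epoch: channels default to silence."""
    resp = np.zeros(n) if signal_response is None else np.asarray(signal_response, float)
    nonresp = (
        np.zeros(len(resp))
        if signal_non_response is None
        else np.asarray(signal_non_response, float)
    )
    return EmgEpoch(
        np.vstack([resp, nonresp]), fs, t0_ms=t0_ms,
        press_time_ms=press_time_ms, meta=meta,
    )


def step_epoch(onset_ms, press_ms, amplitude=1.0, n=2601, t0_ms=-500.0, fs=1000.0):
    """Noise-free step burst: constant amplitude from onset to press."""
    x = np.zeros(n)
    i0 = int(round((onset_ms - t0_ms) * fs / 1000.0))
    i1 = int(round((press_ms - t0_ms) * fs / 1000.0))
    x[i0:i1] = amplitude
    return make_epoch(x, press_time_ms=press_ms)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
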