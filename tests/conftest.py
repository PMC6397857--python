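import dataclasses

import numpy as np
import pytest

from vo2kinetics import SessionMeta, simulate_transition
from vo2kinetics.breath_io import BreathSeries
from vo2kinetics.preprocess import clean_transition
from vo2kinetics.synthetic_data import DEFAULT_NOISE, DEFAULT_TRUTH, NoiseParams


@pytest.fixture(scope="session")
def sw_meta() -> SessionMeta:
    return SessionMeta("S01", "CON", "square_wave", transition_onset=180.0, work_load=211.0)


@pytest.fixture(scope="session")
def noiseless_noise() -> NoiseParams:
    return dataclasses.replace(DEFAULT_NOISE, vo2_sd=0.0, hr_sd=0.0, artifact_rate=0.0)


@pytest.fixture(scope="session")
def noiseless_transition(sw_meta, noiseless_noise):
    """Noise-free square-wave recording at the default (group-mean) truth."""
    return simulate_transition(DEFAULT_TRUTH, noiseless_noise, sw_meta)


@pytest.fixture(scope="session")
def noiseless_bundle(noiseless_transition):
    """Cleaned/interpolated/binned channels of the noiseless recording."""
    return clean_transition([noiseless_transition])


def make_series(t, vo2, meta=None, vco2=None, hr=None):
    """Minimal valid BreathSeries around a VO2 trace (test helper)."""
    t = np.asarray(t, dtype=float)
    vo2 = np.asarray(vo2, dtype=float)
    if meta is None:
        meta = SessionMeta("T", "CON", "square_wave", transition_onset=0.0)
    return BreathSeries(
        meta=meta,
        t=t,
        vo2=vo2,
        vco2=0.9 * vo2 if vco2 is None else np.asarray(vco2, float),
        hr=None if hr is None else np.asarray(hr, float),
    )
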