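import numpy as np
import pytest

from smfe import screening as scr
from smfe import synthetic as syn
from smfe.curves import ScreeningParams

#: gamma work-distribution parameters used throughout as the reference
#: experimental condition (shape, rate in 1/kBT)
GAMMA_SHAPE = 4.42
GAMMA_RATE = 0.023


@pytest.fixture(scope="session")
def default_params():
    return ScreeningParams()


@pytest.fixture(scope="session")
def mixed_dataset():
    """100 curves of known composition: 40 single-event, 30 flat, 20 double, 10 drift."""
    return syn.gen_dataset(
        {"single_event": 40, "flat": 30, "double_rupture": 20, "drift_only": 10},
        shape=GAMMA_SHAPE, rate=GAMMA_RATE, seed=42,
    )


@pytest.fixture(scope="session")
def mixed_screened(mixed_dataset, default_params):
    curves, _ = mixed_dataset
    return scr.screen_dataset(curves, default_params)


@pytest.fixture(scope="session")
def single_event_dataset():
    """200 single-event curves with works drawn from the reference gamma law."""
    return syn.gen_dataset({"single_event": 200}, shape=GAMMA_SHAPE,
                           rate=GAMMA_RATE, seed=7)


@pytest.fixture(scope="session")
def screened_single_events(single_event_dataset, default_params):
    curves, annotations = single_event_dataset
    events, qc = scr.screen_dataset(curves, default_params)
    return events, qc, annotations


@pytest.fixture(scope="session")
def gamma_sample_large():
    return syn.gen_work_sample(100_000, GAMMA_SHAPE, GAMMA_RATE, seed=123)
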