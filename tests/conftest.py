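import warnings

import numpy as np
import pandas as pd
import pytest

import crisismort as cm
from crisismort.pipeline import DEFAULT_CANDIDATES, build_model_frame

warnings.filterwarnings("ignore", category=UserWarning, module="crisismort")


@pytest.fixture(scope="session")
def world():
    """A default synthetic world shared by read-only tests."""
    return cm.generate_world(cm.WorldConfig(seed=101))


@pytest.fixture(scope="session")
def null_world():
    """World with all coefficients zero: every true rate equals baseline."""
    cfg = cm.WorldConfig(seed=202, true_coefficients={}, true_coefficients_u5={})
    return cm.generate_world(cfg)


@pytest.fixture(scope="session")
def surveys(world):
    return cm.generate_surveys(world, 30, seed=303)


@pytest.fixture(scope="session")
def model_frame(world, surveys):
    return build_model_frame(surveys, world.panel_true, DEFAULT_CANDIDATES)


@pytest.fixture()
def tiny_panel():
    """Hand-built 2-district, 38-month panel with reference years + excess window."""
    districts = ["A", "B"]
    months = pd.period_range("2014-01", "2017-02", freq="M")
    idx = pd.MultiIndex.from_product([districts, months], names=["district", "month"])
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        {
            "sam_rate": rng.uniform(50, 250, len(idx)),
            "measles_rate": rng.choice([0.0, 5.0], len(idx)),
            "malaria_rate": rng.uniform(0, 80, len(idx)),
            "conflict_rate": rng.uniform(0, 1, len(idx)),
        },
        index=idx,
    )
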