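import numpy as np
import pytest

import hifdyn as h
from hifdyn.io import TimeSeriesData


@pytest.fixture(scope="session")
def full_model():
    return h.build_default_model(12, 18)


@pytest.fixture(scope="session")
def cyto_model():
    return h.build_cytoplasmic_model()


@pytest.fixture(scope="session")
def table2():
    return h.timeseries_table()


@pytest.fixture(scope="session")
def training_data(table2):
    return TimeSeriesData.from_frame(table2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_state(model, rng, scale=5.0):
    """Random non-negative state for a model (oracle-test helper)."""
    return h.SpeciesState(
        {name: float(v) for name, v in zip(model.species, scale * rng.random(len(model.species)))}
    )


def random_params(model, rng):
    params = model.default_parameters()
    return h.ParameterSet(
        {name: float(value * rng.lognormal(0, 1)) for name, value in params.items()}
    )


# --- session-scoped fitted model (shared by fitting + acceptance tests) ----

@pytest.fixture(scope="session")
def fitted_final(training_data):
    """Two-step fit of the final model to the training table.

    Expensive; shared across the fitting ordering checks and the
    pattern-level acceptance criterion.
    """
    cyto, full = h.two_step_fit(
        training_data,
        h.FitConfig(restarts=3, seed=0, max_nfev=400),
        h.FitConfig(restarts=5, seed=1, max_nfev=800, jitter_sd=2.0),
    )
    return cyto, full
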