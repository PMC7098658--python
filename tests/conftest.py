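import numpy as np
import pytest

from essclock.synthetic import (
    FixtureSpec,
    aggregate_mm_timeseries,
    build_ess_two_gene,
    build_mm_two_gene,
    generate_datasets,
)


@pytest.fixture(scope="session")
def ess_fixture():
    """The frozen extended S-System two-gene circuit and its ground truth."""
    return build_ess_two_gene()


@pytest.fixture(scope="session")
def mm_fixture():
    return build_mm_two_gene()


@pytest.fixture(scope="session")
def ess_datasets(ess_fixture):
    model, _ = ess_fixture
    return generate_datasets(model, FixtureSpec())


@pytest.fixture(scope="session")
def mm_datasets(mm_fixture):
    return generate_datasets(mm_fixture, FixtureSpec(circuit="mm_two_gene"))


@pytest.fixture(scope="session")
def mm_datasets_aggregated(mm_datasets):
    return {k: aggregate_mm_timeseries(v) for k, v in mm_datasets.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
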