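import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

from phytoscreen.synthetic import (
    GenesetSpec,
    LibrarySpec,
    PredictionSpec,
    generate_genesets,
    generate_library,
    generate_predictions,
)
from phytoscreen.targets import aggregate_and_filter


@pytest.fixture(scope="session")
def default_library():
    """Default planted benchmark: 5 knowns, 10 analogs, 10 decoys, seed 1."""
    return generate_library(LibrarySpec())


@pytest.fixture(scope="session")
def default_predictions(default_library):
    return generate_predictions(default_library.library, PredictionSpec())


@pytest.fixture(scope="session")
def default_target_set(default_predictions):
    return aggregate_and_filter(default_predictions.predictions)


@pytest.fixture(scope="session")
def default_genesets(default_target_set):
    return generate_genesets(default_target_set, GenesetSpec())
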