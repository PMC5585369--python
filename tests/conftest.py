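import dataclasses

import pytest

from mirlsa.encoding import Configuration
from mirlsa.synthetic import PlantedSpec, generate


@pytest.fixture(scope="session")
def default_fixture():
    """The standard planted-structure dataset (seed 42) and its ground truth."""
    return generate(PlantedSpec())


@pytest.fixture(scope="session")
def clean_fixture():
    """Noise-free variant (p_out = 0): cross-group links exist only if planted."""
    return generate(dataclasses.replace(PlantedSpec(), p_out=0.0))


@pytest.fixture(scope="session")
def tuned_config():
    """The published best configuration: targets (NBI-weighted), family and
    neighbour sources on top of the mandatory disease block, in-matrix
    inference, cutoffs 0.05/0.25/0.65, dim 400 and query expansion."""
    return Configuration(
        use_targets=True,
        use_family=True,
        use_neighbors=True,
        nbi_on_targets=True,
        infer_in_matrix=True,
        cutoffs=(0.05, 0.25, 0.65),
        dim=400,
        expand_query=True,
    )
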