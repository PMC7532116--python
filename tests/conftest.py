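import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# degenerate-denominator / dying-cluster warnings are expected in the
# unconstrained weak-SNR runs and would swamp the output
logging.getLogger("palmer").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def block_matrix():
    """Perfectly separable 6x4 block matrix: genes 1-3 load on GO 1-2,
    genes 4-6 on GO 3-4."""
    from palmer import BinaryAssociationMatrix

    values = np.array(
        [
            [1, 1, 0, 0],
            [1, 1, 0, 0],
            [1, 1, 0, 0],
            [0, 0, 1, 1],
            [0, 0, 1, 1],
            [0, 0, 1, 1],
        ]
    )
    return BinaryAssociationMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(1, 7)],
        go_ids=[f"t{j}" for j in range(1, 5)],
    )


@pytest.fixture
def block_constraints():
    from palmer import ConstraintSet

    return ConstraintSet(assignments={"g1": 1, "g4": 2}, n_clusters=2)
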