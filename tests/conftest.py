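import numpy as np
import pytest

import dpccn


@pytest.fixture
def rng():
    return np.random.default_rng(20210503)


@pytest.fixture
def small_matrix():
    """A deterministic 8x3 expression matrix for container/IO tests."""
    rng = np.random.default_rng(5)
    return dpccn.ExpressionMatrix(
        values=rng.standard_normal((8, 3)),
        gene_names=["gA", "gB", "gC"],
        sample_ids=[f"s{i}" for i in range(8)],
    )


@pytest.fixture(scope="session")
def backbone_200x20():
    """Independent standard-normal backbone, shared across tests."""
    return dpccn.generate_backbone(dpccn.BackboneSpec(n=200, p=20, seed=42))
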