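import numpy as np
import pandas as pd
import pytest

from stepsig.synthetic import SyntheticConfig, generate_counts


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    return SyntheticConfig(
        n_genes=60,
        n_signature_genes=8,
        samples_per_group=6,
        signature_fold=4.0,
        seed=7,
    )


@pytest.fixture
def small_cohort(small_config):
    return generate_counts(small_config)


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples log-expression with one clean two-level gene."""
    return pd.DataFrame(
        {
            "s1": [1.0, 2.0, 5.0],
            "s2": [1.2, 2.0, 5.5],
            "s3": [4.8, 2.0, 6.0],
            "s4": [5.1, 2.0, 6.5],
        },
        index=["gA", "gB", "gC"],
    )
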