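import numpy as np
import pytest

import skewconstraint as sc


@pytest.fixture
def two_condition_df():
    """One realization of the two-condition constrained-performance data."""
    return sc.generate_two_condition_dataset(n_per_condition=2000, seed=42)


@pytest.fixture
def table1_spec():
    """Mean and shape depend on resource; one shared scale."""
    return sc.ModelSpec(
        response="performance",
        mu_formula="~resource",
        sigma_formula="~1",
        alpha_formula="~resource",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
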