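import numpy as np
import pytest

from depsim import (
    CountsMatrix,
    FixtureSpec,
    estimate_size_factors,
    fit_marginals,
    forward_transform,
    make_fixture,
)
from depsim.marginals import NormalizedMatrix


@pytest.fixture(scope="session")
def small_reference():
    """A 120-gene, 12-sample NB reference with two planted spikes."""
    cm, truth = make_fixture(FixtureSpec(p=120, n=12, seed=20250901))
    return cm, truth


@pytest.fixture(scope="session")
def small_model_parts(small_reference):
    """Size factors, negbin marginals and latent Z for the small reference."""
    cm, _ = small_reference
    s = estimate_size_factors(cm)
    marg = fit_marginals(cm, "negbin", s)
    Z = forward_transform(cm, marg, s)
    return cm, s, marg, Z


def random_centered_Z(p, n, seed):
    rng = np.random.default_rng(seed)
    M = rng.standard_normal((p, n))
    M -= M.mean(axis=1, keepdims=True)
    return NormalizedMatrix(Z=M)


def counts_from_array(values, counts_mode=True):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    return CountsMatrix(
        values=values,
        gene_ids=np.array([f"g{i}" for i in range(p)], dtype=object),
        sample_ids=np.array([f"s{j}" for j in range(n)], dtype=object),
        counts_mode=counts_mode,
    )
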