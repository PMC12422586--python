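"""Fitting a reference model and simulating datasets from it.

``fit_reference_model`` runs the full pipeline (size factors, marginal
fit, normalizing transform, covariance factor fit) and bundles the
result; ``simulate`` draws latent scores ``z = D v + U W u`` in O(pk)
per sample and maps them through the marginal quantile functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._version import __version__ as _pkg_version
from .marginals import (
    CountsMatrix,
    MarginalModel,
    NormalizedMatrix,
    estimate_size_factors,
    fit_marginals,
    forward_transform,
    inverse_transform,
)
from .covariance import (
    CovarianceFactors,
    SGDConfig,
    fit_corpcor,
    fit_independent,
    fit_pca,
    fit_spiked_wishart,
)

__all__ = [
    "ReferenceModel",
    "SimulatedDataset",
    "fit_reference_model",
    "generate_normal_scores",
    "simulate",
    "simulate_batch",
]

METHODS = ("independent", "pca", "wishart", "corpcor")


@dataclass
class ReferenceModel:
    """A fitted simulator: marginals + covariance factors + size factors."""

    marginals: MarginalModel
    factors: CovarianceFactors
    size_factors: np.ndarray | None
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return len(self.gene_ids)

    def replace_marginals(self, marginals: MarginalModel) -> "ReferenceModel":
        """Copy with new marginals; the covariance factors are shared
        (not copied), preserving the fitted dependence structure."""
        return ReferenceModel(
            marginals=marginals,
            factors=self.factors,
            size_factors=None
            if self.size_factors is None
            else self.size_factors.copy(),
            gene_ids=self.gene_ids.copy(),
            sample_ids=self.sample_ids.copy(),
            metadata=dict(self.metadata),
        )


@dataclass
class SimulatedDataset:
    """Simulated p x m matrix plus the provenance needed to reproduce it."""

    values: np.ndarray
    gene_ids: np.ndarray
    size_factors: np.ndarray | None
    seed: int
    method: str

    @property
    def m(self) -> int:
        return self.values.shape[1]


def fit_reference_model(
    counts: CountsMatrix,
    family: str = "negbin",
    method: str = "wishart",
    k: int | None = None,
    *,
    seed: int = 0,
    size_factors: np.ndarray | None = None,
    sgd_config: SGDConfig | None = None,
) -> ReferenceModel:
    """Fit marginals, transform, and fit the covariance factors.

    ``k`` defaults to n-2 for the PCA method and n-1 for the spiked
    Wishart.  The default method is the spiked Wishart, the recommended
    starting point.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    n = counts.n
    s = size_factors
    if s is None and family in ("poisson", "negbin") and counts.counts_mode:
        s = estimate_size_factors(counts)
    marg = fit_marginals(counts, family, s)
    Z = forward_transform(counts, marg, s)
    meta = {"family": family, "method": method, "seed": seed, "version": _pkg_version}
    if method == "independent":
        factors = fit_independent(Z)
    elif method == "pca":
        kk = n - 2 if k is None else k
        factors = fit_pca(Z, kk)
    elif method == "wishart":
        kk = n - 1 if k is None else k
        factors, fit = fit_spiked_wishart(Z, kk, seed=seed, sgd_config=sgd_config)
        meta["sgd_final_loss"] = float(fit.loss_trace[-1])
        meta["fitted_c"] = fit.c
    else:
        factors = fit_corpcor(Z)
    return ReferenceModel(
        marginals=marg,
        factors=factors,
        size_factors=s,
        gene_ids=counts.gene_ids.copy(),
        sample_ids=counts.sample_ids.copy(),
        metadata=meta,
    )


def generate_normal_scores(
    factors: CovarianceFactors,
    m: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """m latent columns ~ N(0, D^2 + U W^2 U^T), each O(pk).

    z = D*v + U (W*u) with u ~ N(0, I_k), v ~ N(0, I_p); no p x p
    object is ever formed.  Deterministic given the seed.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.standard_normal((factors.k, m))
    v = rng.standard_normal((factors.p, m))
    z = factors.D[:, None] * v
    if factors.k:
        z += factors.U @ (factors.W[:, None] * u)
    return z


def simulate(
    model: ReferenceModel,
    m: int,
    seed: int,
    *,
    size_factor_mode: str = "resample",
) -> SimulatedDataset:
    """Simulate m samples from a fitted model.

    Two independent child streams are derived from ``seed`` (stream 0:
    latent scores, stream 1: size-factor resampling), so the same seed
    always reproduces the same dataset bit for bit.  Size factors for
    the simulated samples are resampled with replacement from the
    reference ones (``"resample"``) or all fixed to 1 (``"unit"``).
    """
    ss = np.random.SeedSequence(seed)
    score_seed, sf_seed = ss.spawn(2)
    z = generate_normal_scores(model.factors, m, np.random.default_rng(score_seed))
    s_sim = None
    if model.marginals.family in ("poisson", "negbin"):
        if size_factor_mode == "resample" and model.size_factors is not None:
            rng = np.random.default_rng(sf_seed)
            s_sim = rng.choice(model.size_factors, size=m, replace=True)
        elif size_factor_mode in ("unit", "resample"):
            s_sim = np.ones(m)
        else:
            raise ValueError("size_factor_mode must be 'resample' or 'unit'")
    X = inverse_transform(z, model.marginals, s_sim)
    return SimulatedDataset(
        values=X,
        gene_ids=model.gene_ids.copy(),
        size_factors=s_sim,
        seed=seed,
        method=model.factors.method,
    )


def simulate_batch(
    model: ReferenceModel,
    m: int,
    n_datasets: int,
    root_seed: int,
    *,
    size_factor_mode: str = "resample",
) -> list[SimulatedDataset]:
    """n_datasets independent replicate simulations from one root seed.

    Dataset b uses the derived seed ``SeedSequence([root_seed, b])``, so
    each replicate is reproducible on its own, independent of order.
    """
    out = []
    for b in range(n_datasets):
        child = int(
            np.random.SeedSequence([root_seed, b]).generate_state(1, np.uint32)[0]
        )
        out.append(
            simulate(model, m, child, size_factor_mode=size_factor_mode)
        )
    return out
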