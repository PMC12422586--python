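"""Synthetic reference datasets with known (planted) latent dependence.

``make_fixture`` generates a negative-binomial counts matrix through
the same Gaussian-copula mechanism the package fits: latent scores with
a planted rank-r spiked correlation matrix are pushed through NB
quantile functions with log-normal base means, log-normal dispersions
and per-sample size factors.  Because the planted truth (spike
directions, strengths, per-gene parameters) is returned alongside the
counts, every fitting method can be tested for parameter recovery
without downloading any real accession.  Defaults emulate a small bulk
RNA-seq study: a dozen samples, thousands of genes, a few strong
expression programs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .marginals import CountsMatrix

__all__ = ["FixtureSpec", "make_fixture"]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic NB reference with planted correlation.

    ``spike_strengths`` are the latent low-rank variances before
    standardization: the planted latent covariance is
    I + sum_j w_j^2 u_j u_j^T, rescaled per gene to unit diagonal
    (a correlation matrix).  Base means are log-normal (natural-log
    parameters ``mean_log_mu``/``mean_log_sigma``); dispersions are
    log-normal around ``dispersion_median``; size factors are
    log-normal with sd ``size_factor_spread``, renormalized to
    geometric mean 1.
    """

    p: int = 2000
    n: int = 12
    r: int = 2
    spike_strengths: tuple = (5.0, 3.0)
    mean_log_mu: float = np.log(200.0)
    mean_log_sigma: float = 1.5
    dispersion_median: float = 0.1
    dispersion_log_sigma: float = 0.5
    size_factor_spread: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.p > self.n > self.r >= 0):
            raise ValueError("need p > n > r >= 0")
        if len(self.spike_strengths) != self.r:
            raise ValueError("one spike strength per latent dimension")
        if any(w <= 0 for w in self.spike_strengths) and self.r:
            raise ValueError("spike strengths must be positive")
        if (
            self.mean_log_sigma < 0
            or self.dispersion_median <= 0
            or self.dispersion_log_sigma < 0
            or self.size_factor_spread < 0
        ):
            raise ValueError("all scales must be positive")


def make_fixture(spec: FixtureSpec) -> tuple[CountsMatrix, dict]:
    """Generate the synthetic reference and return its planted truth.

    The truth dict holds ``U`` (p x r effective spike directions on the
    standardized latent scale, orthonormal), ``Q_raw`` (the directions
    before per-gene standardization), ``w`` (spike strengths),
    ``latent`` (the p x n latent correlation-scale scores actually
    used), ``q`` (base means), ``alpha`` (dispersions) and
    ``size_factors``.
    """
    rng = np.random.default_rng(spec.seed)
    p, n, r = spec.p, spec.n, spec.r

    if r:
        Q, _ = np.linalg.qr(rng.standard_normal((p, r)))
        w = np.asarray(spec.spike_strengths, dtype=float)
        raw = Q @ (w[:, None] * rng.standard_normal((r, n)))
        raw += rng.standard_normal((p, n))
        scale = np.sqrt(1.0 + (Q**2) @ w**2)
        latent = raw / scale[:, None]
        # effective spike directions on the standardized (correlation)
        # scale: per-gene rescaling deforms the raw orthonormal Q
        U_eff, _ = np.linalg.qr(Q / scale[:, None])
    else:
        Q = np.empty((p, 0))
        w = np.empty(0)
        latent = rng.standard_normal((p, n))
        U_eff = Q

    q = rng.lognormal(mean=spec.mean_log_mu, sigma=spec.mean_log_sigma, size=p)
    alpha = rng.lognormal(
        mean=np.log(spec.dispersion_median), sigma=spec.dispersion_log_sigma, size=p
    )
    s = rng.lognormal(mean=0.0, sigma=spec.size_factor_spread, size=n)
    s = s / np.exp(np.mean(np.log(s)))

    u = stats.norm.cdf(latent)
    mu = np.outer(q, s)
    rr = 1.0 / alpha
    pr = rr[:, None] / (rr[:, None] + mu)
    counts = stats.nbinom.ppf(np.clip(u, 1e-12, 1 - 1e-12), rr[:, None], pr)

    cm = CountsMatrix(
        values=counts,
        gene_ids=np.array([f"gene_{i}" for i in range(p)], dtype=object),
        sample_ids=np.array([f"sample_{j}" for j in range(n)], dtype=object),
    )
    truth = {
        "U": U_eff,
        "Q_raw": Q,
        "w": w,
        "latent": latent,
        "q": q,
        "alpha": alpha,
        "size_factors": s,
    }
    return cm, truth
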