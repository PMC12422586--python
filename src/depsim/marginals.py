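"""Per-gene marginal distributions and the normalizing (copula) transforms.

A reference matrix ``X`` (p genes x n samples) is reduced to latent
normal scores ``Z`` by applying each gene's fitted CDF followed by the
standard-normal quantile function, ``Z_ij = Phi^-1(F_i(X_ij))``.
Discrete families use the deterministic mid-probability transform
``u = F(x-1) + P(x)/2`` so that ``u`` is uniform in expectation.
Simulation reverses the path: latent scores are pushed through ``Phi``
and then through each gene's quantile function ``F_i^-1``.

Supported families: ``normal``, ``poisson``, ``negbin`` (negative
binomial with sample-specific size factors; variance = mu + alpha*mu^2)
and ``empirical`` (arbitrary ordered discrete values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "CountsMatrix",
    "MarginalModel",
    "NormalizedMatrix",
    "estimate_size_factors",
    "fit_marginals",
    "forward_transform",
    "inverse_transform",
]

FAMILIES = ("normal", "poisson", "negbin", "empirical")

#: clipping bound applied to u before the normal quantile, keeps Z finite
CLIP_EPS = 1e-12

#: smallest admissible negative-binomial dispersion
MIN_DISPERSION = 1e-8


@dataclass
class CountsMatrix:
    """A p x n reference matrix of genes by samples.

    ``counts_mode=True`` enforces nonnegative integer entries (RNA-seq
    read counts); otherwise entries are arbitrary reals (e.g.,
    metabolite abundances).
    """

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    counts_mode: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        p, n = self.values.shape
        if p < 1 or n < 2:
            raise ValueError(f"need p >= 1 genes and n >= 2 samples, got {p} x {n}")
        if len(self.gene_ids) != p or len(self.sample_ids) != n:
            raise ValueError("gene/sample id lengths do not match the matrix")
        if len(set(self.gene_ids)) != p:
            raise ValueError("duplicate gene ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing or non-finite values in the matrix")
        if self.counts_mode:
            if np.any(self.values < 0):
                i, j = np.argwhere(self.values < 0)[0]
                raise ValueError(
                    f"negative count at gene {self.gene_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}"
                )
            if not np.all(self.values == np.round(self.values)):
                i, j = np.argwhere(self.values != np.round(self.values))[0]
                raise ValueError(
                    f"non-integer count at gene {self.gene_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}"
                )

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass
class MarginalModel:
    """Fitted per-gene univariate distributions.

    Parameter arrays are per gene: ``mu``/``sigma`` (normal), ``rate``
    (poisson), ``q``/``alpha`` (negbin base mean on the size-factor
    normalized scale and dispersion), or the packed empirical support
    (``emp_values``, ``emp_probs`` concatenated with ``emp_offsets``).
    ``degenerate`` flags constant genes, which are simulated as that
    constant and excluded from dependence fitting.
    """

    family: str
    gene_ids: np.ndarray
    params: dict = field(default_factory=dict)
    degenerate: np.ndarray | None = None

    @property
    def p(self) -> int:
        return len(self.gene_ids)

    def base_means(self) -> np.ndarray:
        """Per-gene mean parameter on the normalized (size-factor-free) scale."""
        if self.family == "normal":
            return self.params["mu"].copy()
        if self.family == "poisson":
            return self.params["rate"].copy()
        if self.family == "negbin":
            return self.params["q"].copy()
        raise ValueError(f"family {self.family!r} has no mean parameter")

    def with_base_means(self, means: np.ndarray) -> "MarginalModel":
        """Copy of the model with the mean parameter replaced (dispersion kept)."""
        means = np.asarray(means, dtype=float)
        if means.shape != (self.p,):
            raise ValueError("means must have one entry per gene")
        params = {k: v.copy() for k, v in self.params.items()}
        if self.family == "normal":
            params["mu"] = means
        elif self.family == "poisson":
            params["rate"] = means
        elif self.family == "negbin":
            params["q"] = means
        else:
            raise ValueError(f"family {self.family!r} has no mean parameter")
        return MarginalModel(
            family=self.family,
            gene_ids=self.gene_ids.copy(),
            params=params,
            degenerate=None if self.degenerate is None else self.degenerate.copy(),
        )

    def mean_variance(self, size_factor: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """Per-gene mean and variance implied by the fit at one size factor."""
        if self.family == "normal":
            return self.params["mu"].copy(), self.params["sigma"] ** 2
        if self.family == "poisson":
            mu = size_factor * self.params["rate"]
            return mu, mu.copy()
        if self.family == "negbin":
            mu = size_factor * self.params["q"]
            return mu, mu + self.params["alpha"] * mu**2
        if self.family == "empirical":
            vals, probs = self._empirical_arrays()
            means = np.array([np.sum(v * w) for v, w in zip(vals, probs)])
            second = np.array([np.sum(v**2 * w) for v, w in zip(vals, probs)])
            return means, second - means**2
        raise ValueError(f"unknown family {self.family!r}")

    def _empirical_arrays(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        vals = self.params["emp_values"]
        probs = self.params["emp_probs"]
        offs = self.params["emp_offsets"]
        out_v, out_p = [], []
        for i in range(self.p):
            lo, hi = offs[i], offs[i + 1]
            out_v.append(vals[lo:hi])
            out_p.append(probs[lo:hi])
        return out_v, out_p


@dataclass
class NormalizedMatrix:
    """Latent scores Z (p x n), rows row-centered, with provenance."""

    Z: np.ndarray
    marginals: MarginalModel | None = None

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("non-finite latent scores")

    @property
    def p(self) -> int:
        return self.Z.shape[0]

    @property
    def n(self) -> int:
        return self.Z.shape[1]


def estimate_size_factors(counts: CountsMatrix) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean one.

    For each gene with all-positive counts the per-sample ratio to the
    gene's geometric mean is formed; a sample's size factor is the
    median ratio over those genes.  Genes containing any zero are
    excluded from every sample's median.
    """
    if not counts.counts_mode:
        raise ValueError("size factors are defined for count matrices")
    X = counts.values
    eligible = np.all(X > 0, axis=1)
    if not np.any(eligible):
        raise ValueError(
            "no gene has all-positive counts; cannot compute median-of-ratios "
            "size factors"
        )
    logx = np.log(X[eligible])
    log_geomean = logx.mean(axis=1, keepdims=True)
    ratios = np.exp(logx - log_geomean)
    s = np.median(ratios, axis=0)
    s = s / np.exp(np.mean(np.log(s)))
    return s


def _nb_negloglik(log_alpha: float, y: np.ndarray, mu: np.ndarray) -> float:
    alpha = np.exp(log_alpha)
    r = 1.0 / alpha
    # NB log-pmf with mean mu, dispersion alpha, written via gammaln
    ll = (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    return -float(np.sum(ll))


def _fit_nb_dispersion(y: np.ndarray, s: np.ndarray, q: float) -> float:
    """Per-gene dispersion MLE (Nelder-Mead on log alpha, moment start)."""
    mu = s * q
    w = y / s
    var_w = float(np.var(w, ddof=1))
    mom = (var_w - q) / q**2 if q > 0 else 0.0
    start = np.log(max(mom, 1e-4))
    res = optimize.minimize(
        _nb_negloglik,
        x0=[start],
        args=(y, mu),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 200},
    )
    log_alpha = float(res.x[0]) if np.isfinite(res.fun) else start
    return max(float(np.exp(log_alpha)), MIN_DISPERSION)


def fit_marginals(
    counts: CountsMatrix,
    family: str,
    size_factors: np.ndarray | None = None,
) -> MarginalModel:
    """Fit one univariate distribution per gene.

    normal: sample mean and sd (ddof=1).  poisson / negbin: base mean is
    the average of size-factor-normalized counts; negbin dispersion is a
    per-gene maximum-likelihood estimate.  empirical: the observed value
    multiset.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
    X = counts.values
    p, n = X.shape
    if family in ("poisson", "negbin"):
        if size_factors is None:
            if family == "negbin":
                raise ValueError("negbin marginals require size factors")
            size_factors = np.ones(n)
        s = np.asarray(size_factors, dtype=float)
        if s.shape != (n,) or np.any(s <= 0):
            raise ValueError("size factors must be n positive reals")

    degenerate = np.ptp(X, axis=1) == 0
    params: dict = {}
    if family == "normal":
        params["mu"] = X.mean(axis=1)
        params["sigma"] = X.std(axis=1, ddof=1)
        if np.any(degenerate):
            warnings.warn(
                f"{int(degenerate.sum())} constant gene(s) have sd 0; they are "
                "simulated as constants and excluded from dependence fitting: "
                f"{list(counts.gene_ids[degenerate][:10])}",
                stacklevel=2,
            )
    elif family == "poisson":
        params["rate"] = (X / s).mean(axis=1)
    elif family == "negbin":
        q = (X / s).mean(axis=1)
        alpha = np.full(p, MIN_DISPERSION)
        for i in range(p):
            if q[i] > 0 and not degenerate[i]:
                alpha[i] = _fit_nb_dispersion(X[i], s, q[i])
        params["q"] = q
        params["alpha"] = alpha
    else:  # empirical
        emp_values, emp_probs, offsets = [], [], [0]
        for i in range(p):
            vals, cnt = np.unique(X[i], return_counts=True)
            emp_values.append(vals)
            emp_probs.append(cnt / n)
            offsets.append(offsets[-1] + len(vals))
        params["emp_values"] = np.concatenate(emp_values)
        params["emp_probs"] = np.concatenate(emp_probs)
        params["emp_offsets"] = np.asarray(offsets)

    return MarginalModel(
        family=family,
        gene_ids=counts.gene_ids.copy(),
        params=params,
        degenerate=degenerate,
    )


def _discrete_mid_u(
    cdf_at_x: np.ndarray,
    pmf_at_x: np.ndarray,
    randomized: bool,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Mid-probability u = F(x-) + pmf/2, or u ~ U(F(x-), F(x)) if randomized."""
    lower = cdf_at_x - pmf_at_x
    if randomized:
        if rng is None:
            raise ValueError("randomized transform needs an rng")
        return lower + pmf_at_x * rng.uniform(size=pmf_at_x.shape)
    return lower + 0.5 * pmf_at_x


def forward_transform(
    counts: CountsMatrix,
    marginals: MarginalModel,
    size_factors: np.ndarray | None = None,
    *,
    randomized: bool = False,
    rng: np.random.Generator | None = None,
    center: bool = True,
) -> NormalizedMatrix:
    """Map the reference matrix to latent normal scores Z.

    Continuous families use ``Z = Phi^-1(F(x))`` exactly; discrete
    families use the mid-probability transform.  ``u`` is clipped to
    ``[eps, 1-eps]`` before the normal quantile, and rows are centered
    to mean zero so the all-ones sample direction is an exact null
    vector of Z.
    """
    X = counts.values
    p, n = X.shape
    if marginals.p != p or not np.array_equal(marginals.gene_ids, counts.gene_ids):
        raise ValueError("marginals were fitted on a different gene set")
    fam = marginals.family
    if fam == "normal":
        sigma = marginals.params["sigma"]
        safe = np.where(sigma > 0, sigma, 1.0)
        Z = (X - marginals.params["mu"][:, None]) / safe[:, None]
        Z[sigma == 0] = 0.0
    elif fam in ("poisson", "negbin"):
        if size_factors is None:
            size_factors = np.ones(n)
        s = np.asarray(size_factors, dtype=float)
        if fam == "poisson":
            mu = np.outer(marginals.params["rate"], s)
            cdf = stats.poisson.cdf(X, mu)
            pmf = stats.poisson.pmf(X, mu)
        else:
            mu = np.outer(marginals.params["q"], s)
            r = 1.0 / marginals.params["alpha"]
            pr = r[:, None] / (r[:, None] + mu)
            cdf = stats.nbinom.cdf(X, r[:, None], pr)
            pmf = stats.nbinom.pmf(X, r[:, None], pr)
        u = _discrete_mid_u(cdf, pmf, randomized, rng)
        u = np.clip(u, CLIP_EPS, 1.0 - CLIP_EPS)
        Z = stats.norm.ppf(u)
    elif fam == "empirical":
        vals, probs = marginals._empirical_arrays()
        Z = np.empty_like(X)
        for i in range(p):
            idx = np.searchsorted(vals[i], X[i])
            if np.any(idx == len(vals[i])) or np.any(vals[i][idx] != X[i]):
                raise ValueError(
                    f"value outside the empirical support for gene "
                    f"{counts.gene_ids[i]!r}"
                )
            cum = np.cumsum(probs[i])
            u = _discrete_mid_u(cum[idx], probs[i][idx], randomized, rng)
            Z[i] = stats.norm.ppf(np.clip(u, CLIP_EPS, 1.0 - CLIP_EPS))
    else:  # pragma: no cover
        raise ValueError(f"unknown family {fam!r}")

    if marginals.degenerate is not None:
        Z[marginals.degenerate] = 0.0
    if center:
        Z = Z - Z.mean(axis=1, keepdims=True)
    return NormalizedMatrix(Z=Z, marginals=marginals)


def inverse_transform(
    z: np.ndarray,
    marginals: MarginalModel,
    size_factors: float | np.ndarray | None = None,
) -> np.ndarray:
    """Map latent normal scores back to the data scale: x = F^-1(Phi(z)).

    ``z`` may be a p-vector (one simulated sample) or a p x m matrix of
    m samples; ``size_factors`` is then a scalar or an m-vector.  The
    discrete quantile is the generalized inverse (smallest support value
    with CDF >= Phi(z)).
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite latent scores")
    squeeze = z.ndim == 1
    Zm = z[:, None] if squeeze else z
    p, m = Zm.shape
    if p != marginals.p:
        raise ValueError("score dimension does not match the fitted gene set")
    fam = marginals.family
    if fam in ("poisson", "negbin"):
        s = np.ones(m) if size_factors is None else np.atleast_1d(
            np.asarray(size_factors, dtype=float)
        )
        if s.shape == (1,) and m > 1:
            s = np.repeat(s, m)
        if s.shape != (m,) or np.any(s <= 0):
            raise ValueError("need one positive size factor per simulated sample")

    # clip away exact 0/1 so discrete quantiles stay finite even for
    # extreme scores (mirrors the forward-transform clipping)
    U = np.clip(stats.norm.cdf(Zm), CLIP_EPS, 1.0 - CLIP_EPS)
    if fam == "normal":
        X = marginals.params["mu"][:, None] + marginals.params["sigma"][:, None] * Zm
    elif fam == "poisson":
        mu = np.outer(marginals.params["rate"], s)
        X = stats.poisson.ppf(U, mu)
        X[mu == 0] = 0.0
    elif fam == "negbin":
        mu = np.outer(marginals.params["q"], s)
        alpha = marginals.params["alpha"]
        r = 1.0 / alpha
        pr = r[:, None] / (r[:, None] + mu)
        X = stats.nbinom.ppf(U, r[:, None], pr)
        X[mu == 0] = 0.0
    elif fam == "empirical":
        vals, probs = marginals._empirical_arrays()
        X = np.empty_like(Zm)
        for i in range(p):
            cum = np.cumsum(probs[i])
            cum[-1] = 1.0
            idx = np.searchsorted(cum, U[i], side="left")
            idx = np.minimum(idx, len(vals[i]) - 1)
            X[i] = vals[i][idx]
    else:  # pragma: no cover
        raise ValueError(f"unknown family {fam!r}")
    return X[:, 0] if squeeze else X
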