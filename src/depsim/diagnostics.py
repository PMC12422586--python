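"""Diagnostics comparing simulated datasets to their reference.

All diagnostics are pure functions of their inputs.  PCA-based
diagnostics work on ``log2(1 + size-factor-normalized counts)`` by
default (configurable); pairwise correlations are Pearson on the log
scale by default, Spearman behind a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .marginals import CountsMatrix
from .copula import SimulatedDataset

__all__ = [
    "circular_correlation",
    "mean_variance_comparison",
    "correlation_qq",
    "pc_projection",
    "pc_variance_spectrum",
    "eigenvalue_inflation_demo",
    "true_fdp",
]


def _values(data) -> np.ndarray:
    if isinstance(data, (CountsMatrix, SimulatedDataset)):
        return np.asarray(data.values, dtype=float)
    return np.asarray(data, dtype=float)


def _log_normalized(X: np.ndarray, size_factors: np.ndarray | None) -> np.ndarray:
    if size_factors is not None:
        X = X / np.asarray(size_factors, dtype=float)
    return np.log2(1.0 + X)


def _auto_size_factors(data) -> np.ndarray | None:
    """Median-of-ratios size factors estimated from the dataset itself.

    Every dataset (real or simulated) is normalized the same way before
    log-scale PCA/correlation diagnostics; continuous data (non-integer
    or negative values, or no all-positive gene) is left unnormalized.
    """
    X = _values(data)
    if np.any(X < 0) or not np.all(X == np.round(X)):
        return None
    pos = np.all(X > 0, axis=1)
    if not pos.any():
        return None
    logx = np.log(X[pos])
    ratios = np.exp(logx - logx.mean(axis=1, keepdims=True))
    s = np.median(ratios, axis=0)
    return s / np.exp(np.mean(np.log(s)))


def circular_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Circular correlation between two phase vectors (radians).

    rho = sum_{i<j} sin(x_i - x_j) sin(y_i - y_j) normalized by the
    root product of the two sums of squared sines.  Invariant to a
    common rotation of either argument; |rho| near 1 means the circular
    orderings agree (sign gives orientation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length phase vectors with n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite phases")
    dx = np.sin(x[:, None] - x[None, :])
    dy = np.sin(y[:, None] - y[None, :])
    iu = np.triu_indices(len(x), k=1)
    num = float(np.sum(dx[iu] * dy[iu]))
    den = float(np.sqrt(np.sum(dx[iu] ** 2) * np.sum(dy[iu] ** 2)))
    if den == 0.0:
        raise ValueError("degenerate phase vector (all pairwise sines zero)")
    return num / den


def mean_variance_comparison(real, sim) -> tuple[pd.DataFrame, dict]:
    """Per-gene mean/variance of real vs simulated data, with log-log fits.

    Returns the per-gene table and a summary dict with regression slope
    and intercept of log10(sim) on log10(real) for means and variances
    (genes positive in both are used for the fits).
    """
    Xr, Xs = _values(real), _values(sim)
    if Xr.shape[0] != Xs.shape[0]:
        raise ValueError("real and simulated data must share the gene set")
    table = pd.DataFrame(
        {
            "mean_real": Xr.mean(axis=1),
            "mean_sim": Xs.mean(axis=1),
            "var_real": Xr.var(axis=1, ddof=1),
            "var_sim": Xs.var(axis=1, ddof=1),
        }
    )
    summary = {}
    for stat in ("mean", "var"):
        a, b = table[f"{stat}_real"], table[f"{stat}_sim"]
        ok = (a > 0) & (b > 0)
        if ok.sum() >= 2 and np.ptp(np.log10(a[ok])) > 0:
            slope, intercept = np.polyfit(np.log10(a[ok]), np.log10(b[ok]), 1)
        else:
            slope, intercept = np.nan, np.nan
        summary[f"{stat}_slope"] = float(slope)
        summary[f"{stat}_intercept"] = float(intercept)
    return table, summary


def _pairwise_correlations(
    X: np.ndarray, method: str
) -> np.ndarray:
    if method == "spearman":
        X = stats.rankdata(X, axis=1)
    C = np.corrcoef(X)
    iu = np.triu_indices(X.shape[0], k=1)
    return C[iu]


def correlation_qq(
    real: CountsMatrix,
    sims: list,
    min_mean: float = 100.0,
    *,
    size_factors: np.ndarray | None = None,
    method: str = "pearson",
    log_scale: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Quantiles of pairwise gene-gene correlations, real vs simulated.

    Restricted to genes whose *reference* mean is at least ``min_mean``
    (default 100 reads).  Returns a table of matched sorted correlations
    (one column per dataset) and the median absolute correlation per
    dataset as a summary.
    """
    if min_mean < 0:
        raise ValueError("min_mean must be >= 0")
    Xr = _values(real)
    eligible = Xr.mean(axis=1) >= min_mean
    if eligible.sum() < 2:
        raise ValueError(
            f"fewer than 2 genes have reference mean >= {min_mean}"
        )

    def prep(data, sfs) -> np.ndarray:
        if sfs is None:
            sfs = _auto_size_factors(data)
        X = _values(data)[eligible]
        if sfs is not None and log_scale:
            return _log_normalized(X, np.asarray(sfs))
        return np.log2(1.0 + X) if log_scale else X

    cols = {
        "real": np.sort(_pairwise_correlations(prep(real, size_factors), method))
    }
    for idx, sim in enumerate(sims):
        label = f"sim_{idx}"
        cols[label] = np.sort(
            _pairwise_correlations(prep(sim, None), method)
        )
    table = pd.DataFrame(cols)
    summary = table.abs().median()
    summary.name = "median_abs_correlation"
    return table, summary


def pc_projection(
    real: CountsMatrix,
    sims: list,
    *,
    size_factors: np.ndarray | None = None,
    log_scale: bool = True,
    n_components: int = 2,
) -> pd.DataFrame:
    """Project all samples onto the top PCs of the *real* dataset.

    The PC weights and gene centering come from the real data only;
    simulated samples are projected with those fixed weights (so
    low-variance simulations cluster near the origin).
    """
    Xr = _values(real)
    if Xr.shape[0] < 2 or Xr.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")

    def prep(data, sfs=None):
        if not log_scale:
            return _values(data)
        if sfs is None:
            sfs = _auto_size_factors(data)
        return _log_normalized(_values(data), sfs)

    Tr = prep(real, size_factors)
    center = Tr.mean(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(Tr - center, full_matrices=False)
    W = U[:, :n_components]
    rows = []
    for label, data in [("real", Tr)] + [
        (f"sim_{i}", prep(d)) for i, d in enumerate(sims)
    ]:
        scores = W.T @ (data - center)
        for j in range(scores.shape[1]):
            rows.append(
                {"dataset": label, "sample": j,
                 **{f"PC{a + 1}": scores[a, j] for a in range(n_components)}}
            )
    return pd.DataFrame(rows)


def pc_variance_spectrum(
    datasets: list,
    *,
    log_scale: bool = True,
    n_components: int | None = None,
) -> pd.DataFrame:
    """Ordered PCA component variances, refit on each dataset separately."""
    rows = {}
    for idx, data in enumerate(datasets):
        X = _values(data)
        if X.shape[1] < 2:
            raise ValueError("each dataset needs at least 2 samples")
        T = _log_normalized(X, _auto_size_factors(data)) if log_scale else X
        T = T - T.mean(axis=1, keepdims=True)
        s = np.linalg.svd(T, compute_uv=False)
        var = s**2 / (T.shape[1] - 1)
        k = len(var) if n_components is None else min(n_components, len(var))
        rows[f"dataset_{idx}"] = var[:k]
    return pd.DataFrame.from_dict(rows, orient="index").T


def eigenvalue_inflation_demo(
    p: int = 100,
    n: int = 12,
    reps: int = 20,
    seed: int = 0,
    *,
    spikes: tuple = (10.0, 5.0),
) -> pd.DataFrame:
    """Why Sigma_sim := Sigma_hat_ref fails: simulated spectra are inflated.

    Draws one multivariate-normal reference (p genes, n samples) from a
    planted covariance (identity plus low-rank spikes), then simulates
    ``reps`` datasets of n samples using the *sample* covariance of the
    reference as the population covariance (dense, rank n-1 — a
    test-only path).  Returns the ordered eigenvalues of the reference
    sample covariance and of each simulated one: the top simulated
    eigenvalues systematically exceed the reference's and the trailing
    ones are depleted, because all simulated mass is squeezed into an
    (n-1)-dimensional hyperplane.
    """
    if p <= n:
        raise ValueError("the demonstration needs p > n")
    rng = np.random.default_rng(seed)
    r = len(spikes)
    Q, _ = np.linalg.qr(rng.standard_normal((p, r)))
    X = Q @ (np.sqrt(spikes)[:, None] * rng.standard_normal((r, n)))
    X += rng.standard_normal((p, n))
    Xc = X - X.mean(axis=1, keepdims=True)
    s_ref = np.linalg.svd(Xc, compute_uv=False)
    ref_eigs = np.zeros(min(p, n))
    ref_eigs[: len(s_ref)] = s_ref**2 / (n - 1)

    # dense factor: Sigma_sim = V diag(lam) V^T with lam the reference eigs
    U_ref, s_full, _ = np.linalg.svd(Xc, full_matrices=False)
    root = U_ref * (s_full / np.sqrt(n - 1))
    out = {"reference": ref_eigs}
    for b in range(reps):
        Y = root @ rng.standard_normal((root.shape[1], n))
        Yc = Y - Y.mean(axis=1, keepdims=True)
        s_sim = np.linalg.svd(Yc, compute_uv=False)
        eigs = np.zeros(min(p, n))
        eigs[: len(s_sim)] = s_sim**2 / (n - 1)
        out[f"sim_{b}"] = eigs
    return pd.DataFrame(out)


def true_fdp(truth, called_genes) -> float:
    """True false-discovery proportion of a set of called genes.

    The fraction of called genes absent from the injected truth; 0 when
    nothing is called (convention).
    """
    called = set(called_genes)
    if not called:
        return 0.0
    true_set = set(np.asarray(truth.gene_ids))
    false_calls = len(called - true_set)
    return false_calls / len(called)
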