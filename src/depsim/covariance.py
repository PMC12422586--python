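"""Choosing the simulation covariance Sigma_sim = D^2 + U W^2 U^T.

Four strategies, all producing the diagonal-plus-low-rank factors that
make O(pk) sampling possible:

* ``fit_independent`` — D only; genes are simulated independently.
* ``fit_pca`` — the quadratic form along each of the top-k left singular
  vectors of Z exactly matches the reference variance in that direction,
  and the diagonal of Sigma_sim matches the reference diagonal.
* ``fit_spiked_wishart`` — spike strengths w and noise scale c are fitted
  so that *simulated datasets of n-1 samples* reproduce, on average, the
  reference PCA spectrum.  The expected eigenvalues have no closed form,
  so they are estimated by an O((k+m)^3) Gram-reduction sampler and the
  parameters optimized by stochastic gradient descent.
* ``fit_corpcor`` — the James-Stein-type shrinkage covariance (sample
  correlations shrunk toward zero with weight lambda1, variances toward
  the median with weight lambda2), refactored into (D, U, W) form.

The sample-covariance divisor is n-1 throughout: Sigma_hat = Z Z^T/(n-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .marginals import NormalizedMatrix

__all__ = [
    "CovarianceFactors",
    "ReferenceSpectrum",
    "SpikedFit",
    "SGDConfig",
    "reference_spectrum",
    "fit_independent",
    "fit_pca",
    "fit_corpcor",
    "fit_spiked_wishart",
    "sample_spiked_eigenvalues",
]


@dataclass
class CovarianceFactors:
    """The (D, U, W) factorization of Sigma_sim = D^2 + U W^2 U^T.

    ``D`` and ``W`` hold the diagonals (p- and k-vectors); ``c`` is the
    spiked-Wishart noise scale when applicable.
    """

    D: np.ndarray
    U: np.ndarray
    W: np.ndarray
    k: int
    method: str
    c: float | None = None

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.U = np.asarray(self.U, dtype=float).reshape(len(self.D), -1)
        self.W = np.asarray(self.W, dtype=float).reshape(-1)
        if self.U.shape[1] != self.k or len(self.W) != self.k:
            raise ValueError("U/W shapes inconsistent with k")
        if np.any(self.D < 0) or np.any(self.W < 0):
            raise ValueError("D and W must be nonnegative")
        for arr in (self.D, self.U, self.W):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite covariance factors")

    @property
    def p(self) -> int:
        return len(self.D)

    def diagonal(self) -> np.ndarray:
        """diag(Sigma_sim) without forming the dense matrix."""
        return self.D**2 + (self.U**2) @ (self.W**2)

    def dense(self) -> np.ndarray:
        """Dense Sigma_sim; for small-p testing and diagnostics only."""
        return np.diag(self.D**2) + (self.U * self.W**2) @ self.U.T


@dataclass
class ReferenceSpectrum:
    """Thin SVD of the row-centered latent matrix Z.

    ``singular_values`` are the n-1 leading singular values (the n-th is
    exactly zero because rows are centered); eigenvalues of
    Sigma_hat_ref = Z Z^T/(n-1) are singular_values^2/(n-1).
    """

    singular_values: np.ndarray
    left_singular_vectors: np.ndarray
    n: int

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.singular_values**2 / (self.n - 1)


@dataclass
class SpikedFit:
    """Trace of the spiked-Wishart SGD fit."""

    target_spectrum: np.ndarray
    w: np.ndarray
    c: float
    loss_trace: np.ndarray
    seed: int
    #: initialization loss re-evaluated on the final shared base, so the
    #: guarantee loss_trace[-1] <= init_loss is a like-for-like comparison
    init_loss: float = np.inf


@dataclass
class SGDConfig:
    """Spiked-Wishart SGD settings.

    Parameters are optimized on the (log w^2, log c^2) scale with
    Adam-style steps; gradients are forward finite differences using
    common random numbers (the Monte-Carlo base variates are fixed
    within each iteration).
    """

    iterations: int = 500
    mc_reps: int = 25
    lr: float = 0.05
    lr_decay: float = 0.1  # final lr as a fraction of lr (cosine schedule)
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    fd_step: float = 1e-3
    final_reps: int = 250  # precision of the final candidate selection
    plateau_tol: float = 1e-12


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def reference_spectrum(Z: NormalizedMatrix) -> ReferenceSpectrum:
    """Thin SVD of Z; never materializes the p x p covariance."""
    M = Z.Z
    p, n = M.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    return ReferenceSpectrum(
        singular_values=s[: n - 1],
        left_singular_vectors=_fix_signs(U[:, : n - 1]),
        n=n,
    )


def _row_variances(Z: NormalizedMatrix) -> np.ndarray:
    # rows are centered, so this is diag(Z Z^T)/(n-1)
    return np.einsum("ij,ij->i", Z.Z, Z.Z) / (Z.n - 1)


def fit_independent(Z: NormalizedMatrix) -> CovarianceFactors:
    """Diagonal Sigma_sim: genes simulated independently."""
    D = np.sqrt(_row_variances(Z))
    return CovarianceFactors(
        D=D, U=np.empty((Z.p, 0)), W=np.empty(0), k=0, method="independent"
    )


def fit_pca(
    Z: NormalizedMatrix,
    k: int,
    *,
    target_scaling: str = "eigenvalue",
) -> CovarianceFactors:
    """Match the reference variance along the top-k singular directions.

    With U the top-k left singular vectors of Z, solves for w = diag(W^2)
    in A w = B with A_ij = delta_ij - sum_l U_li^2 U_lj^2 and
    B_i = v_i - sum_l U_li^2 (Sigma_hat_ref)_ll, then sets
    D_ii^2 = (Sigma_hat_ref)_ii - (U W^2 U^T)_ii.  The result satisfies
    u_i^T Sigma_sim u_i = v_i for i <= k and
    diag(Sigma_sim) = diag(Sigma_hat_ref).

    ``target_scaling`` selects the variance target v_i: "eigenvalue"
    (default) uses v_i = lambda_i^2/(n-1), the i-th eigenvalue of
    Sigma_hat_ref — the unique choice consistent with the diagonal
    constraint; "printed" uses lambda_i^2/(n-1)^2.
    """
    n = Z.n
    if not 1 <= k <= n - 2:
        raise ValueError(
            f"fit_pca needs 1 <= k <= n-2 (full-rank simulated data); "
            f"got k={k}, n={n}"
        )
    spec = reference_spectrum(Z)
    U = spec.left_singular_vectors[:, :k]
    lam = spec.singular_values[:k]
    if target_scaling == "eigenvalue":
        v = lam**2 / (n - 1)
    elif target_scaling == "printed":
        v = lam**2 / (n - 1) ** 2
    else:
        raise ValueError("target_scaling must be 'eigenvalue' or 'printed'")

    rowvar = _row_variances(Z)
    U2 = U**2
    A = np.eye(k) - U2.T @ U2
    B = v - U2.T @ rowvar
    # minimum-norm least squares: A can be singular when singular vectors
    # align exactly with coordinate axes (the equations are then degenerate)
    w = np.linalg.lstsq(A, B, rcond=None)[0]
    if np.any(w < 0):
        warnings.warn(
            f"fit_pca: {int((w < 0).sum())} negative low-rank weight(s) "
            "clamped to 0; the spectral match is no longer exact there",
            stacklevel=2,
        )
        w = np.maximum(w, 0.0)
    d2 = rowvar - U2 @ w
    if np.any(d2 < 0):
        warnings.warn(
            f"fit_pca: {int((d2 < 0).sum())} negative diagonal residual(s) "
            "floored at 0; diag(Sigma_sim) exceeds the reference there",
            stacklevel=2,
        )
        d2 = np.maximum(d2, 0.0)
    return CovarianceFactors(
        D=np.sqrt(d2), U=U, W=np.sqrt(w), k=k, method="pca"
    )


# ---------------------------------------------------------------------------
# spiked Wishart


def _bartlett_wishart(
    m: int, df: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """reps draws from Wishart_m(df, I), via the Bartlett factorization."""
    L = np.zeros((reps, m, m))
    rows, cols = np.tril_indices(m, k=-1)
    L[:, rows, cols] = rng.standard_normal((reps, len(rows)))
    idx = np.arange(m)
    chi2 = rng.chisquare(df - idx, size=(reps, m))
    L[:, idx, idx] = np.sqrt(chi2)
    return L @ np.swapaxes(L, 1, 2)


def _draw_base_variates(
    k: int, m: int, p: int, reps: int, rng: np.random.Generator
) -> dict:
    """Randomness shared across loss evaluations (common random numbers)."""
    base = {"Gk": rng.standard_normal((reps, k, m)) if k else None}
    df = p - k
    if df >= m:
        base["bulk"] = _bartlett_wishart(m, df, reps, rng)
    else:
        # too few bulk dimensions for a nonsingular Wishart: explicit draw
        H = rng.standard_normal((reps, df, m))
        base["bulk"] = np.swapaxes(H, 1, 2) @ H
    return base


def _spiked_eigs_from_base(
    wsq: np.ndarray, csq: float, base: dict, divisor: float
) -> np.ndarray:
    """Ordered (descending) eigenvalue samples of M/divisor.

    M = sum_i (w_i^2 + c^2) g_i g_i^T + c^2 * Wishart(p-k, I_m); the
    spike variances are w_i^2 + c^2 because the simulator's D = cI adds
    c^2 in the spike directions as well.
    """
    M = csq * base["bulk"]
    if base["Gk"] is not None and len(wsq):
        G = base["Gk"]
        scaled = (wsq + csq)[None, :, None] * G
        M = M + np.swapaxes(G, 1, 2) @ scaled
    eigs = np.linalg.eigvalsh(M / divisor)
    return eigs[:, ::-1]


def sample_spiked_eigenvalues(
    w: np.ndarray,
    c: float,
    p: int,
    m: int,
    reps: int,
    seed: int | np.random.Generator,
    *,
    divisor: float | None = None,
) -> np.ndarray:
    """Sample covariance eigenvalues under a spiked population covariance.

    The population covariance (dimension p) has k spike eigenvalues
    w_i^2 + c^2 and p-k bulk eigenvalues c^2 — the spectrum of
    Sigma_sim = c^2 I + U W^2 U^T.  Returns a (reps, m) array of the
    ordered nonzero eigenvalues of the sample covariance of m iid
    N(0, Sigma) columns, computed through the m x m Gram matrix
    M = A^T diag(w^2+c^2) A + c^2 * Wishart_m(p-k, I) at cost polynomial
    in k+m and independent of p.  ``divisor`` defaults to m; pass n-1 to
    match the reference-convention Sigma_hat = Z Z^T/(n-1).
    """
    w = np.asarray(w, dtype=float).reshape(-1)
    k = len(w)
    if p <= k:
        raise ValueError(f"need p > k, got p={p}, k={k}")
    if m < 1 or reps < 1:
        raise ValueError("m and reps must be >= 1")
    if c <= 0:
        raise ValueError("noise scale c must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = _draw_base_variates(k, m, p, reps, rng)
    div = float(m if divisor is None else divisor)
    return _spiked_eigs_from_base(w**2, c**2, base, div)


def fit_spiked_wishart(
    Z: NormalizedMatrix,
    k: int,
    *,
    seed: int = 0,
    sgd_config: SGDConfig | None = None,
) -> tuple[CovarianceFactors, SpikedFit]:
    """Fit (w, c) so simulated n-1-sample spectra match the reference.

    Minimizes sum_i (E[eig_i] - t_i)^2 where t_i are the eigenvalues of
    Sigma_hat_ref and E[eig_i] is the Monte-Carlo mean of the ordered
    eigenvalues of the simulated sample covariance (n-1 columns, divisor
    n-1).  U is fixed to the top-k left singular vectors of Z; D = cI.
    Deterministic given ``seed``.
    """
    cfg = sgd_config or SGDConfig()
    n = Z.n
    if not 1 <= k <= n - 1:
        raise ValueError(f"fit_spiked_wishart needs 1 <= k <= n-1, got k={k}")
    spec = reference_spectrum(Z)
    m = n - 1
    targets = spec.eigenvalues  # length n-1
    p = Z.p

    ss = np.random.SeedSequence(seed)
    iter_seeds = ss.spawn(cfg.iterations + 2)

    def loss(th: np.ndarray, base: dict) -> float:
        eigs = _spiked_eigs_from_base(np.exp(th[:k]), np.exp(th[k]), base, n - 1)
        return float(np.sum((eigs.mean(axis=0) - targets) ** 2))

    # Initialize on the (log w^2, log c^2) scale.  Spike strengths start
    # at the excess of each target over the pure-noise (c=1, no spike)
    # expected spectrum, so undetectable spikes start near zero instead
    # of chasing the Marchenko-Pastur bulk.
    rng = np.random.default_rng(iter_seeds[-2])
    bulk = _spiked_eigs_from_base(
        np.empty(0),
        1.0,
        _draw_base_variates(0, m, p, cfg.final_reps, rng),
        n - 1,
    ).mean(axis=0)
    theta = np.concatenate(
        [np.log(np.maximum(targets[:k] - bulk[:k], 0.01)), [0.0]]
    )

    theta_init = theta.copy()
    mom1 = np.zeros_like(theta)
    mom2 = np.zeros_like(theta)
    trace = np.empty(cfg.iterations + 1)
    best_theta, best_loss = theta.copy(), np.inf

    for it in range(cfg.iterations):
        rng = np.random.default_rng(iter_seeds[it])
        base = _draw_base_variates(k, m, p, cfg.mc_reps, rng)
        f0 = loss(theta, base)
        trace[it] = f0
        if f0 < best_loss:
            best_loss, best_theta = f0, theta.copy()
        grad = np.empty_like(theta)
        for j in range(len(theta)):
            th = theta.copy()
            th[j] += cfg.fd_step
            grad[j] = (loss(th, base) - f0) / cfg.fd_step
        mom1 = cfg.beta1 * mom1 + (1 - cfg.beta1) * grad
        mom2 = cfg.beta2 * mom2 + (1 - cfg.beta2) * grad**2
        m1 = mom1 / (1 - cfg.beta1 ** (it + 1))
        m2 = mom2 / (1 - cfg.beta2 ** (it + 1))
        frac = it / max(cfg.iterations - 1, 1)
        lr = cfg.lr * (
            cfg.lr_decay + (1 - cfg.lr_decay) * 0.5 * (1 + np.cos(np.pi * frac))
        )
        theta = theta - lr * m1 / (np.sqrt(m2) + cfg.adam_eps)

    # choose among initialization, best-seen and final iterate at higher
    # Monte-Carlo precision (shared fresh base: a fair comparison); this
    # also guarantees the returned loss never exceeds the initial one
    rng = np.random.default_rng(iter_seeds[-1])
    base = _draw_base_variates(k, m, p, cfg.final_reps, rng)
    candidates = [theta_init, best_theta, theta]
    losses = [loss(th, base) for th in candidates]
    pick = int(np.argmin(losses))
    best_theta, best_loss = candidates[pick].copy(), losses[pick]
    trace[-1] = best_loss
    if pick == 0 and best_loss > cfg.plateau_tol:
        warnings.warn(
            "fit_spiked_wishart: loss did not improve from initialization; "
            "returning the initial point (see SpikedFit.loss_trace)",
            stacklevel=2,
        )

    w = np.sqrt(np.exp(best_theta[:k]))
    c = float(np.sqrt(np.exp(best_theta[k])))
    U = spec.left_singular_vectors[:, :k]
    factors = CovarianceFactors(
        D=np.full(p, c), U=U, W=w, k=k, method="wishart", c=c
    )
    diag = factors.diagonal()
    if np.any(np.abs(diag - 1.0) > 0.10):
        warnings.warn(
            "fit_spiked_wishart: diag(Sigma_sim) deviates from 1 by more "
            "than 10% for some genes; marginal laws may be distorted",
            stacklevel=2,
        )
    fit = SpikedFit(
        target_spectrum=targets.copy(),
        w=w.copy(),
        c=c,
        loss_trace=trace,
        seed=seed,
        init_loss=losses[0],
    )
    return factors, fit


# ---------------------------------------------------------------------------
# corpcor (James-Stein shrinkage)


def shrinkage_intensities(Z: NormalizedMatrix) -> tuple[float, float]:
    """Analytic shrinkage weights (lambda1 for correlations, lambda2 for
    variances), computed in O(p n^2) without forming the p x p matrix.

    lambda1 = sum_{i!=j} Var_hat(r_ij) / sum_{i!=j} r_ij^2 and
    lambda2 = sum_i Var_hat(v_i) / sum_i (v_i - v_med)^2, both clamped
    to [0, 1]; Var_hat terms are the usual unbiased estimates of the
    sampling variance of correlations/variances.
    """
    M = Z.Z
    p, n = M.shape
    if n < 3:
        raise ValueError("shrinkage estimation needs n >= 3 samples")
    v = _row_variances(Z)
    if np.any(v == 0):
        raise ValueError("zero-variance gene passed to shrinkage estimation")

    Xs = (M / np.sqrt(v)[:, None]).T  # n x p, unit-variance columns
    G = Xs @ Xs.T  # n x n Gram
    frob_all = float(np.sum(G**2))  # sum_{ij} (sum_k x_ki x_kj)^2
    rowsq = np.einsum("ki,ki->k", Xs, Xs)  # per-sample sum of squares
    sum_w2_all = float(np.sum(rowsq**2))  # sum_{ij} sum_k w_kij^2

    # diagonal (i == j) pieces, removed from the pairwise sums
    sum_r2_diag = float(p)  # r_ii = 1
    w_diag = Xs**2  # w_kii
    var_diag = (
        n / (n - 1.0) ** 3 * np.sum((w_diag - w_diag.mean(axis=0)) ** 2, axis=0)
    )
    sum_r2 = frob_all / (n - 1.0) ** 2 - sum_r2_diag
    sum_w2 = sum_w2_all - float(np.sum(w_diag**2))
    sum_wbar2 = frob_all / n**2 - float(np.sum(w_diag.mean(axis=0) ** 2))
    sum_var = n / (n - 1.0) ** 3 * (sum_w2 - n * sum_wbar2)
    lam1 = 1.0 if sum_r2 <= 0 else float(np.clip(sum_var / sum_r2, 0.0, 1.0))

    z = (M**2).T  # n x p, z_ki = centered-squared values
    var_v = n / (n - 1.0) ** 3 * np.sum((z - z.mean(axis=0)) ** 2, axis=0)
    denom = float(np.sum((v - np.median(v)) ** 2))
    lam2 = 1.0 if denom <= 0 else float(np.clip(np.sum(var_v) / denom, 0.0, 1.0))
    return lam1, lam2


def fit_corpcor(
    Z: NormalizedMatrix,
    *,
    lambda1: float | None = None,
    lambda2: float | None = None,
) -> CovarianceFactors:
    """James-Stein shrinkage covariance in (D, U, W) form.

    The dense equivalent has diagonal v*_i = lambda2*v_med + (1-lambda2)*v_i
    and off-diagonal (1-lambda1)*r_ij*sqrt(v*_i v*_j).  Factored as
    D_ii^2 = lambda1 * v*_i, U = sqrt(1-lambda1) * S Z / sqrt(n-1) with
    S_ii^2 = v*_i / v_i, and W = I (k = n).  Explicit ``lambda1``/
    ``lambda2`` override the analytic estimates.
    """
    M = Z.Z
    p, n = M.shape
    v = _row_variances(Z)
    keep = v > 0
    if not np.all(keep):
        warnings.warn(
            f"fit_corpcor: {int((~keep).sum())} zero-variance gene(s) "
            "excluded from shrinkage and given D = U = 0",
            stacklevel=2,
        )
    sub = NormalizedMatrix(Z=M[keep], marginals=Z.marginals)
    if lambda1 is None or lambda2 is None:
        l1_est, l2_est = shrinkage_intensities(sub)
    lam1 = l1_est if lambda1 is None else float(lambda1)
    lam2 = l2_est if lambda2 is None else float(lambda2)
    if not (0 <= lam1 <= 1 and 0 <= lam2 <= 1):
        raise ValueError("shrinkage weights must lie in [0, 1]")

    vk = v[keep]
    v_med = float(np.median(vk))
    v_star = lam2 * v_med + (1.0 - lam2) * vk
    D = np.zeros(p)
    U = np.zeros((p, n))
    D[keep] = np.sqrt(lam1 * v_star)
    S = np.sqrt(v_star / vk)
    U[keep] = np.sqrt(1.0 - lam1) * (S[:, None] * M[keep]) / np.sqrt(n - 1.0)
    return CovarianceFactors(
        D=D, U=U, W=np.ones(n), k=n, method="corpcor"
    )
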