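# Methods

## Model

`depsim` simulates a p-gene expression vector by the Gaussian-copula
(NORTA) construction. Per gene i a univariate marginal with CDF F_i is
fitted to the reference matrix X (p×n). The reference is mapped to
latent scores Z_ij = Φ⁻¹(F_i(X_ij)); a covariance Σ_sim is chosen on
that latent scale; simulation draws z′ ~ N(0, Σ_sim) and outputs
x′_i = F_i⁻¹(Φ(z′_i)). Two assumptions follow from the construction:
dependence between genes is captured only up to a Gaussian copula
(monotone, elliptical dependence — no tail dependence, no nonlinear
structure), and the marginal law of each simulated gene equals the
fitted marginal only insofar as (Σ_sim)_ii ≈ 1, which every fitting
method targets and asserts (a warning fires beyond 10% deviation;
scores are never silently re-standardized).

Σ_sim is constrained to D² + UW²Uᵀ with D, W diagonal and U p×k,
k ≪ p. Sampling uses z′ = Dv + UWu with iid standard-normal u (k-dim)
and v (p-dim), which has exactly the required covariance; cost is
O(pk) per sample and no p×p object is ever formed. The diagonal term
injects gene-level independent noise that the rank-(n−1) sample
covariance lacks; without it, all simulated samples would lie in an
(n−1)-dimensional hyperplane and pairwise correlations would be far
too high (`diagnostics.eigenvalue_inflation_demo` reproduces this
failure mode: top eigenvalues of simulated sample covariances inflate,
trailing ones vanish).

## Marginal families

* **normal** — per-gene sample mean and sd (ddof 1). Genes with sd 0
  are flagged degenerate, simulated as the constant, and excluded from
  dependence fitting (their latent row is zero).
* **poisson** — rate q_i = mean of size-factor-normalized counts; the
  per-sample mean is s_j·q_i. (Size factors multiply the mean for both
  count families; Poisson is treated as the α→0 limit of the negative
  binomial, so both families share the offset convention.)
* **negbin** — mean s_j·q_i with q_i as above; variance μ + αμ². The
  dispersion α_i is a plain per-gene maximum-likelihood estimate
  (Nelder–Mead on log α, method-of-moments start, floor 10⁻⁸). No
  empirical-Bayes trend or shrinkage of dispersions is applied: the
  package needs one defensible dispersion per gene, not a moderated
  estimator, and the gene-wise MLE keeps the marginal fit
  self-contained. With only ~12 samples the raw MLE is noisier than a
  moderated estimate; users comparing against a specific DE pipeline's
  dispersions should expect small differences.
* **empirical** — the observed value multiset; the quantile is the
  generalized inverse (smallest support value with CDF ≥ u).

Size factors are median-of-ratios: per-sample medians of the ratio to
each gene's geometric mean, computed over genes with all-positive
counts, rescaled so their geometric mean is 1. Simulated samples get
size factors resampled with replacement from the reference ones
(seeded), or all 1 on request.

Discrete data is transformed with the deterministic mid-probability
(distributional) transform u = F(x−1) + P(x)/2 — reproducible and
unbiased in the mean of u; a randomized variant u ~ U(F(x−1), F(x)) is
available behind a flag. u is clipped to [10⁻¹², 1−10⁻¹²] before Φ⁻¹
so latent scores stay finite, and Φ(z) is clipped identically in the
inverse direction so discrete quantiles stay finite for extreme
scores. After the transform, rows of Z are centered to mean zero; this
makes the all-ones sample direction an exact null vector, so the n-th
singular value of Z is exactly 0 rather than approximately so.

## Covariance constructions

The sample-covariance divisor is n−1 throughout: Σ̂_ref = ZZᵀ/(n−1).
SVD left singular vectors are sign-fixed (largest-magnitude entry
positive) for reproducibility.

**PCA.** U holds the top-k left singular vectors of Z. The weights
w = diag(W²) solve Aw = B with A_ij = δ_ij − Σ_ℓ U²_ℓi U²_ℓj and
B_i = v_i − Σ_ℓ U²_ℓi (Σ̂_ref)_ℓℓ, and D²_ii = (Σ̂_ref)_ii − (UW²Uᵀ)_ii.
The variance target is v_i = λ_i²/(n−1), the i-th eigenvalue of
Σ̂_ref: a direct expansion of u_iᵀ(D² + UW²Uᵀ)u_i shows this is the
unique scaling for which the quadratic form along u_i equals the
reference variance in that direction *and* diag(Σ_sim) = diag(Σ̂_ref)
simultaneously (both hold to 10⁻⁸ in the acceptance checks). An
alternative scaling λ_i²/(n−1)², which arises if the target is read as
an eigenvalue of ZZᵀ/(n−1) scaled once more by (n−1), is available via
`target_scaling="printed"` but breaks the diagonal consistency. The
linear system is solved by minimum-norm least squares because A is
singular in the (measure-zero) case of coordinate-aligned singular
vectors. Negative solutions w_i are clamped to 0 and negative D²
floored at 0, each with a warning, since both break the exact match.
k must be ≤ n−2 so that the simulated data remain full rank.

**Spiked Wishart.** Here the goal is distributional: datasets of n−1
simulated columns should have, on average, the same ordered singular
values as Z. With D = cI and U fixed to the top-k singular vectors,
Σ_sim has spectrum {w_i² + c² (i ≤ k), c² (else)} — note the +c²: the
isotropic noise adds to the spike directions too. Because singular
values are rotation invariant, the simulated spectrum is that of a
spiked Wishart ensemble, sampled exactly through the m×m Gram matrix
M = Aᵀdiag(w²+c²)A + c²·B with B ~ Wishart_m(p−k, I) drawn by Bartlett
factorization — cost polynomial in k+m and independent of p (a dense
fallback covers p−k < m). The fit minimizes Σ_i (E[eig_i] − t_i)² over
(log w², log c²) where t_i are the eigenvalues of Σ̂_ref and E[·] is a
25-replicate Monte-Carlo mean, using Adam steps (lr 0.05, cosine decay
to 10%), forward finite differences, and common random numbers (the
base variates are fixed within each iteration, so each finite
difference is exact for that iteration's objective). 500 iterations by
default; all knobs sit in `SGDConfig`.

Initialization matters at omics scale: reference eigenvalues are
O(p/n) ≫ 1, so starting spikes at t_i − 1 would begin far outside the
basin and stall. Spikes therefore start at
max(t_i − E[pure-noise eig_i], 0.01), where the pure-noise ordered
means at c = 1 come from one cheap k = 0 pre-pass of the sampler; c²
starts at 1. The final parameters are chosen among {initialization,
best-seen iterate, final iterate} re-evaluated on a shared
higher-precision base (250 replicates), which also guarantees the
returned loss never exceeds the initial one.

Two inherent properties of this objective are worth knowing. First,
the expected *ordered* spectrum of the ensemble is smoother than any
single reference draw, whose eigenvalues carry Marchenko–Pastur-scale
fluctuations; the fit therefore has an irreducible residual of roughly
1–2% per singular value (verified by direct derivative-free
minimization of a fixed high-precision objective), and self-consistency
should be judged against the sampling spread of a single simulated
dataset, not against an arbitrarily precise mean. Second, on a
dependence-free reference the optimizer may assign a few small spikes
(w² far below the bulk scale) to individual eigenvalue fluctuations —
these are genuine minimizers, contribute negligibly to any gene's
variance, and leave the fitted c within a few percent of 1.

**corpcor (James–Stein shrinkage).** The shrinkage weights are the
analytic optima: λ₁ = Σ_{i≠j} V̂ar(r_ij) / Σ_{i≠j} r_ij² for
correlations and λ₂ = Σ_i V̂ar(v_i) / Σ_i (v_i − v_med)² for variances,
both clamped to [0, 1] and computed in O(pn²) via Gram-matrix
identities (no p×p intermediate). λ₂ is defined as 1 when all
variances are equal (shrinkage to the median is then a no-op). The σ
quantities in the construction are variances, not standard deviations:
with v*_i = λ₂v_med + (1−λ₂)v_i the factors D²_ii = λ₁v*_i,
U = √(1−λ₁)·S·Z/√(n−1) with S²_ii = v*_i/v_i, and W = I (k = n) make
the assembled Σ_sim equal the classical shrunk covariance — diagonal
v*_i, off-diagonal (1−λ₁)r_ij√(v*_iv*_j) — entrywise, which the test
suite verifies to 10⁻¹⁰ against the directly computed estimator. This
is the unique reading under which the assembled diagonal equals the
shrunk variance.

## Experiment designs

`inject_de` multiplies the base means of a seeded random fraction of
genes by 2^(±lfc), |lfc| ~ U(low, high), fair-coin sign (defaults: 5%,
0.2–2.0). Only genes with base mean > 0 are eligible — scaling a zero
mean is a no-op that would corrupt the truth table. Dispersions and
(for normal marginals) variances are left untouched: injected DE is a
pure mean shift, and a variance model for fold changes is outside this
package's scope. `with_group_means` builds one model per group (e.g.,
circadian time point) that *shares* the baseline CovarianceFactors
object — dependence and dispersions are fit once on the baseline group
— with base means replaced by the group's means computed on
size-factor-normalized counts (consistent with the q_i definition).
Samples are independent conditional on the group.

## Diagnostics

All diagnostics are pure functions. PCA-based diagnostics and pairwise
correlations work on log2(1 + size-factor-normalized counts); every
dataset, real or simulated, is normalized by its *own* median-of-ratios
size factors so the comparison is symmetric (continuous data is left
unnormalized; the transform and Pearson-vs-Spearman choice are
configurable flags, since log-scale Pearson is a convention rather
than a forced choice). The correlation QQ table restricts to genes
with reference mean ≥ 100 by default — correlation is only meaningful
in well-measured genes. The circular correlation between phase vectors
is ρ = Σ_{i<j} sin(X_i−X_j)sin(Y_i−Y_j) normalized by the root product
of squared-sine sums; it is invariant to common rotations, flips sign
under reflection, and errors on degenerate (constant-phase) input.
`eigenvalue_inflation_demo` plants identity-plus-two-spikes (strengths
10 and 5) as its multivariate-normal reference covariance — a
realistic correlation scale for the demonstration; the phenomenon it
shows is insensitive to this choice.

## Synthetic references

`make_fixture` generates NB counts through the package's own copula
mechanism with *planted* truth: a rank-r spiked latent correlation
(I + Σ w_j²u_ju_jᵀ standardized to unit diagonal; the effective
post-standardization directions are returned as truth), log-normal
base means (median 200, log-sd 1.5 — a bulk RNA-seq-like dynamic
range), log-normal dispersions (median 0.1), and log-normal size
factors (log-sd 0.2, geometric mean 1). Defaults are p = 2000, n = 12,
two spikes of strengths (5, 3): a dozen-sample bulk study with a few
dominant expression programs. What the fixture does not emulate:
outlier samples, batch structure, zero inflation beyond NB sampling,
gene-length effects, and non-Gaussian dependence — so passing fidelity
tests on fixtures demonstrates correctness of the machinery, not that
real tissue data meets the copula assumptions. Subspace recovery from
a fixture is limited by n: a planted spike is only recovered with high
cosine when its latent eigenvalue is large compared to p/(n−1), and
spikes of similar strength mix within the recovered subspace (tests
therefore compare principal angles, not individual vectors).

## Problem sizes and numerical choices

The test suite and acceptance script run at the scale the methods are
designed for where that is cheap (p = 2000, n = 12 for the
spiked-Wishart fit; p = 100, n = 12, 20 replicates for the inflation
demonstration; 2×10⁵ latent columns for the generation identity;
20,000 replicates for sampler-vs-brute-force agreement) and at reduced
gene counts (p = 120–250) for multi-method fidelity comparisons, which
are qualitative orderings rather than scale-sensitive quantities.
Statistical assertions use 3-SE bands with explicit multiplicity
allowances where hundreds of comparisons are made at once, and
Bonferroni correction across genes for distributional round-trip
tests. Monte-Carlo comparisons between two finite samples use pooled
two-sample KS tests at α = 0.01. All randomness flows from explicit
seeds through `numpy.random.Generator`/`SeedSequence`; batch
simulation derives per-replicate seeds as SeedSequence([root, b]) so
any replicate is reproducible in isolation.

## Known limitations

Gaussian-copula dependence only; a single scalar size factor per
sample (no gene-specific offsets); gene-wise NB dispersion without
moderation; the spiked-Wishart spectrum fit carries the irreducible
ordered-statistics bias described above; `fit_pca` can clamp weights
on references whose spectrum decays slowly (warned); and the archive
format stores dense U (p×k), which for corpcor means p×n — fine at
omics scale, but the corpcor factors are the least compact of the
three.
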