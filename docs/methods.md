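# Methods

## Model and data structure

Each subject carries a latent triple of log-times: the event of interest
*X*, dependent censoring *D* (terminal event) and independent censoring
*C*. The bivariate AFT model puts `X = Z'θ0 + ε^X`, `D = Z'η0 + ε^D` with
an arbitrary joint error distribution; given **Z**, *C* is independent of
(*X*, *D*), but *X* and *D* may be dependent. Only
(X̃, D̃, δ, Δ, **Z**) with X̃ = X∧D∧C, D̃ = D∧C, δ = I(X ≤ D̃),
Δ = I(D ≤ C) is observed, and the joint law is identifiable only on the
wedge X < D. All computation is on the log scale; the CSV loader offers an
optional log transform for raw-scale inputs (off by default).

## Estimating equations

* `S_n(η)`: unweighted (log-rank form) rank score on the terminal-event
  residuals D̃ − **Z**'η with indicator Δ. Risk sets use non-strict `≥`
  and include ties.
* `U_n^L(α)`: the same score on the globally artificially censored sample.
  With e = X̃ − **Z**'θ (event residual) and
  c = D̃ − **Z**'η − g(α), where g(α) = max_i{0, **Z**_i'(θ−η)}, the
  transformed data are X̃* = e∧c when δ = 1, else c, and
  δ̃* = δ·I(e ≤ c). This observable form equals the latent-variable
  definition because g ≥ **Z**_i'(θ−η) for every i; the equivalence is
  unit-tested against a latent-variable oracle using simulator-retained
  X, D, C.
* `U_n^P(α)`: Gehan-type pairwise U-statistic
  `2 n^{1/2}/(n(n−1)) Σ_{i<j} (Z_i − Z_j) φ_ij(α)` with pair offsets
  g_ij = max{0, Z_i'(θ−η), Z_j'(θ−η)}. Ties between two uncensored
  transformed times contribute 0 (non-strict `≤` in both indicator
  terms of φ). Pairwise offsets never exceed the global offset, so the
  pairwise transform censors no more events than the global one.

The inner loops (risk-set cumulations, pairwise φ accumulation) are
numba-compiled; the test suite checks them against plain-Python
double-loop oracles, including tied residuals.

## Solving nonsmooth equations

All three scores are step functions of the parameters, so exact zeros
typically do not exist and derivatives are unavailable. Estimates minimize
the squared Euclidean score norm by Nelder–Mead with:

* initial simplex edge 0.25 log-time units (fit), multi-start with up to 5
  jittered restarts (N(0, 0.5²) around the start) when the incumbent norm
  exceeds tolerance, plus one finer "polish" pass;
* a search box of ±5 log-time units around the start (the parameter is
  assumed interior to a compact set);
* convergence tolerance `max(1e−3, 2√(k/n))` on the score norm — event
  terms of the normalized scores are O(n^{−1/2}), so the best attainable
  plateau is a small multiple of that jump size;
* sequential estimation: η̂ from `S_n(η) = 0` first (started at 0), then
  θ̂^L and θ̂^P at fixed η̂ (started at η̂, including inside g and g_ij).

All tolerances, restart counts and the box half-width are configurable
(`SolverOptions`).

## Resampling covariance

The joint covariance of (η̂, θ̂^L, θ̂^P) is estimated by multiplier
perturbation: per-subject influence rows W_i = (W_i^(1), W_i^(2), W_i^(3))
are evaluated at the fit (martingale-decomposition terms of the two rank
scores; the pairwise row `(2/(n−1)) Σ_j (Z_i − Z_j) φ_ij`), and for each
of M draws the system `G_n(β) = −n^{−1/2} Σ_i W_i Q_i` with fresh i.i.d.
standard-normal Q is solved block-sequentially (η* first, warm-started at
the point estimates). Σ̂ is the empirical covariance (denominator M−1) of
the solved realizations. M = 500 by default; M = 200 is used in the
desk-scale studies below.

Two numerical conventions matter here:

* **Nearest root.** The artificially censored equations can possess
  spurious roots far from the point estimate. Perturbed solves therefore
  use a deliberately local search (initial simplex edge 0.12, jitter 0.15,
  no polish) so each draw returns the root in the basin of β̂ — the root
  the resampling expansion is about. A wide multi-start here fattens the
  draw tails and inflates the θ^L standard errors by ~15–25% without
  improving the achieved score norms.
* **Failed draws** (score norm above tolerance after one retry) are
  dropped and counted; fewer than 90% survivors raises an error. In the
  supported designs the success rate is ≈100%.

Draw SDs track the replication SDs of the estimators within 25% at
n = 150 (tested), and η* draws depend only on the η block of the
perturbation (the system is block-triangular).

## Optimal weighting

Because θ̂^L and θ̂^P share the same η̂ and data, their optimal
combination uses the precision matrix: invert the full 3k×3k Σ̂ and
extract the submatrix for the θ coordinates (this conditions on η̂,
unlike inverting a 2×2 covariance submatrix). Marginal weights
`ĉ_m = (h'Σ̂*_m h)^{−1} Σ̂*_m h` (h = (1,1)') combine coefficient m;
the joint contrast matrix `B̂ = {(E'Σ̂** E)^{−1} E'Σ̂**}'` handles all k
coefficients at once and reduces to the marginal weights when k = 1.
Weights sum to one per coefficient and may be negative (no clipping);
pairs outside [−5, 6] trigger an instability warning. A near-singular Σ̂
is ridge-regularized with ε = 1e−8·tr(Σ̂)/3k.

The standard error of a combination is not pinned down by the combination
itself; the default reports `√(c' V_m c)` with V_m the 2×2 **covariance**
submatrix of Σ̂ — valid for any weight pair — and the precision-form
alternative `√((h'Σ̂*_m h)^{−1})` (the variance the optimality argument
assigns to the optimum) is exposed behind a switch and in verbose output.
The two differ by O(sampling noise of Σ̂).

## Model checking

For each equation the observed score process
`n^{−1/2} Σ_i Z_i M̂_i(s)` cumulates covariate-weighted martingale
residuals over residual time, where the cumulative hazard is Nelson–Aalen
on the (transformed) residuals; both θ processes use the globally
transformed sample evaluated at α̂^L and α̂^P respectively. Its terminal
value equals the estimating-equation value at the fit (an exact identity,
tested), and per-subject residuals sum to zero at every grid point.
Bootstrap reference paths reuse the resampling draws and their
multipliers: multiplier-perturbed martingale integral at the fit plus the
observed-process shift between draw and fitted parameters. Sup-norm
statistics (Euclidean norm over coefficients by default, max-norm
switchable) give bootstrap p-values; the two event-of-interest tests are
Bonferroni-doubled.

**Known behavior:** at n ≈ 100–150 the test is conservative — under a
correctly specified model the null p-values concentrate around 0.8 rather
than being uniform, and the empirical size at level 0.05 is near 0. The
shift term only partially recenters the perturbed integral at these
sample sizes. Rejections are therefore trustworthy; non-rejection is
weak evidence.

## Simulator

Two families, both retaining latent X, D, C for oracle tests (never used
by estimators):

* `bvnormal`: (ε^X, ε^D) bivariate normal, means (0, 1.2), unit
  variances, correlation ρ; covariates Bernoulli(0.5);
  exp(C) ~ Uniform(0, 20).
* `gamma_frailty`: frailty ν ~ Gamma(mean 1, variance σ²) shared by the
  subject's two errors; exp(ε^X) ~ Exp(rate 4/ν),
  exp(ε^D) ~ Exp(rate 1/ν); σ² = 0 degenerates to independent
  exponentials. Defaults θ0 = (0.5, 1), η0 = (1, 0.5),
  Z1 ~ U(0,1), Z2 ~ Bernoulli(0.5), exp(C) ~ Uniform(0, 20).

These defaults are the supported study conditions. The generators emulate
heavy dependent censoring with moderate event rates; they do not emulate
covariate-dependent censoring laws, ties from coarse measurement, or
model misspecification, so passing tests demonstrate correctness under
the stated designs, not robustness beyond them. The bvnormal family
requires explicit true parameters (no canonical values are attached to
it).

`run_study` reports, per estimator and coefficient: Bias, MSE, SEE (mean
of resampling SEs), 95% normal-approximation Coverage, and the medians
Dmedian (error), Mediansq (squared error), Sdmedian (SE). MSE equals
Bias² + variance by construction (tested). Replication failures are
dropped and counted; more than 10% aborts the study.

## Problem sizes used in the shipped runs

The package's own study runs are sized for a single CPU:

* `scripts/acceptance.py`: point-estimator MSEs at 300 replications
  (n=300, σ²=0) and 500 replications (n=150, σ²=1) without resampling;
  resampling studies at 100 replications × 200 draws (σ²=0, n=150) and
  150 replications × 200 draws (σ²=1, n=150).
* test suite: the same designs at 60–150 replications × 150 draws.

Monte-Carlo noise at these scales is roughly ±5% (relative) on SEE-type
quantities, ±10–15% on MSEs, and ±0.025 on coverage proportions.

## Known limitations

* No left truncation, time-varying covariates, or interval censoring.
* The analytic (plug-in) covariance via the slope matrix is not provided;
  the resampling covariance is the only route (the slopes of nonsmooth
  rank scores would require numerical derivatives of step functions).
* Weighted-estimator SEs depend on the chosen formula (see above);
  both are computed, the covariance form is the default.
* The GOF test's conservatism at moderate n (above).
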