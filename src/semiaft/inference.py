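"""Point estimation and multiplier-resampling covariance.

The three rank scores are step functions of the parameters, so an exact
zero typically does not exist.  Estimates are defined as minimizers of
the squared Euclidean norm of the score, found by a derivative-free
Nelder-Mead simplex search with multi-start jitters; a solve is declared
converged when the attained norm falls below a tolerance scaled to the
score's jump size (which is O(n^{-1/2}) per event).

The joint covariance of ``(η̂, θ̂^L, θ̂^P)`` is estimated by perturbation
resampling: the score admits an influence decomposition
``G_n(β̂) ≈ n^{-1/2} Σ_i W_i``, and re-solving the perturbed system
``G_n(β) = -n^{-1/2} Σ_i W_i Q_i`` with i.i.d. standard-normal
multipliers ``Q_i`` reproduces the sampling distribution of the
estimator.  The empirical covariance of the solved realizations is the
covariance estimate used downstream for optimal weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize

from . import _kernels
from .artificial_censoring import _linear_pieces, transform_global
from .data_model import ParamAlpha, ParamBeta, SemicompetingDataset, validate
from .estimating_equations import score_eta, score_theta_L, score_theta_P

__all__ = [
    "SolverOptions", "FitResult", "PerturbationWeights", "ResamplingDraws",
    "CovarianceEstimate", "solve_equation", "fit", "perturbation_weights",
    "omega_hat", "resample", "covariance", "standard_errors", "default_tolerance",
]


class ResamplingQualityError(RuntimeError):
    """Too many perturbed solves failed to converge."""


def default_tolerance(n: int, k: int) -> float:
    """Convergence tolerance on the score norm.

    Individual event terms of the normalized scores are O(n^{-1/2}), so
    the best attainable plateau norm is a small multiple of
    sqrt(k) * n^{-1/2}; 2 sqrt(k/n) accepts plateaus within roughly two
    jump sizes of zero.
    """
    return max(1e-3, 2.0 * np.sqrt(k / n))


@dataclass
class SolverOptions:
    tol: float | None = None          # score-norm convergence tolerance
    restarts: int = 5                 # jittered restarts after the first attempt
    step: float = 0.25                # initial simplex edge (log-time units)
    xatol: float = 2e-3
    maxfev: int = 400
    box_halfwidth: float = 5.0        # search box around the starting point
    jitter: float = 0.5
    polish: bool = True               # rerun with a finer simplex around the incumbent
    M: int = 500                      # resampling draws
    success_floor: float = 0.9
    seed: int | None = None


def _score_closures(ds: SemicompetingDataset):
    """Allocation-light score evaluators used inside the solver loops."""
    y_x, y_d, delta, Delta, Z = ds.y_x, ds.y_d, ds.delta, ds.Delta, ds.Z

    def s_eta(eta):
        return _kernels.rank_score(y_d - Z @ eta, Delta, Z)

    def s_L(eta, theta):
        e = y_x - Z @ theta
        c = y_d - Z @ eta - max(0.0, np.max(Z @ (theta - eta)))
        delta_star = np.where((delta != 0) & (e <= c), 1.0, 0.0)
        x_star = np.where(delta != 0, np.minimum(e, c), c)
        return _kernels.rank_score(x_star, delta_star, Z)

    def s_P(eta, theta):
        e = y_x - Z @ theta
        b = y_d - Z @ eta
        v = np.maximum(0.0, Z @ (theta - eta))
        return _kernels.unp_score(e, b, v, delta, Z)

    return s_eta, s_L, s_P


@dataclass
class FitResult:
    eta_hat: np.ndarray
    theta_L_hat: np.ndarray
    theta_P_hat: np.ndarray
    score_norms: dict
    converged: dict
    n_restarts: dict
    tol: float

    @property
    def beta(self) -> ParamBeta:
        return ParamBeta(self.eta_hat, self.theta_L_hat, self.theta_P_hat)

    @property
    def alpha_L(self) -> ParamAlpha:
        return ParamAlpha(self.eta_hat, self.theta_L_hat)

    @property
    def alpha_P(self) -> ParamAlpha:
        return ParamAlpha(self.eta_hat, self.theta_P_hat)

    @property
    def all_converged(self) -> bool:
        return all(self.converged.values())

    def to_dict(self) -> dict:
        return {
            "eta_hat": self.eta_hat.tolist(),
            "theta_L_hat": self.theta_L_hat.tolist(),
            "theta_P_hat": self.theta_P_hat.tolist(),
            "score_norms": {k: float(v) for k, v in self.score_norms.items()},
            "converged": {k: bool(v) for k, v in self.converged.items()},
            "n_restarts": {k: int(v) for k, v in self.n_restarts.items()},
        }


@dataclass
class PerturbationWeights:
    """Stacked per-subject influence rows ``W_i = (W_i^(1), W_i^(2), W_i^(3))``."""

    W: np.ndarray  # n x 3k
    k: int

    @property
    def n(self) -> int:
        return self.W.shape[0]


@dataclass
class ResamplingDraws:
    draws: np.ndarray          # M_success x 3k solved realizations
    Q: np.ndarray              # M_success x n multipliers (kept for model checking)
    M_requested: int
    M_success: int
    seed: int | None

    @property
    def k(self) -> int:
        return self.draws.shape[1] // 3


@dataclass
class CovarianceEstimate:
    sigma: np.ndarray          # 3k x 3k
    k: int
    condition_number: float = field(default=np.nan)

    def block(self, a: int, b: int) -> np.ndarray:
        """Block (a, b) with 0 = η, 1 = θ^L, 2 = θ^P."""
        k = self.k
        return self.sigma[a * k:(a + 1) * k, b * k:(b + 1) * k]


def _nm_once(f: Callable, start: np.ndarray, step: float, xatol: float, maxfev: int):
    start = np.asarray(start, dtype=float)
    p = start.size
    simplex = np.vstack([start, start + step * np.eye(p)])
    res = minimize(f, start, method="Nelder-Mead",
                   options={"initial_simplex": simplex, "xatol": xatol,
                            "fatol": 1e-12, "maxfev": maxfev})
    return res.x, float(res.fun)


def solve_equation(score_fn: Callable[[np.ndarray], np.ndarray], start: np.ndarray,
                   opts: SolverOptions | None = None,
                   rng: np.random.Generator | None = None):
    """Minimize ``||score_fn(x)||`` by multi-start Nelder-Mead.

    Returns ``(root, norm, converged, n_restarts)`` where ``norm`` is the
    Euclidean score norm at the returned point and ``converged`` is true
    iff ``norm <= opts.tol``.
    """
    opts = opts or SolverOptions()
    tol = opts.tol if opts.tol is not None else 1e-3
    rng = rng or np.random.default_rng(0)
    start = np.atleast_1d(np.asarray(start, dtype=float))
    box = opts.box_halfwidth

    def f(x):
        if np.max(np.abs(x - start)) > box:
            return 1e6 + float(np.sum((x - start) ** 2))
        s = score_fn(x)
        return float(s @ s)

    best_x, best_f = _nm_once(f, start, opts.step, opts.xatol, opts.maxfev)
    used = 0
    while best_f > tol ** 2 and used < opts.restarts:
        used += 1
        x0 = start + rng.normal(0.0, opts.jitter, size=start.size)
        x, fv = _nm_once(f, x0, opts.step, opts.xatol, opts.maxfev)
        if fv < best_f:
            best_x, best_f = x, fv
    if opts.polish:
        x, fv = _nm_once(f, best_x, opts.step / 5.0, opts.xatol / 2.0, opts.maxfev)
        if fv < best_f:
            best_x, best_f = x, fv
    norm = float(np.sqrt(best_f))
    return best_x, norm, norm <= tol, used


def fit(ds: SemicompetingDataset, opts: SolverOptions | None = None,
        estimators: tuple = ("L", "P")) -> FitResult:
    """Sequential point estimation: η̂ first, then θ̂^L and/or θ̂^P at fixed η̂.

    ``estimators`` selects which θ equations to solve ("L", "P"); the η
    equation is always solved.  Skipped estimators are returned as NaN.
    """
    validate(ds)
    if np.any(np.ptp(ds.Z, axis=0) == 0):
        raise ValueError("non-identifiable design: a covariate column is constant")
    opts = opts or SolverOptions()
    n, k = ds.n, ds.k
    tol = opts.tol if opts.tol is not None else default_tolerance(n, k)
    local = SolverOptions(**{**opts.__dict__, "tol": tol})
    rng = np.random.default_rng(opts.seed if opts.seed is not None else 12345)
    s_eta, s_L, s_P = _score_closures(ds)

    eta_hat, norm_eta, conv_eta, r_eta = solve_equation(s_eta, np.zeros(k), local, rng)

    results = {"theta_L": (np.full(k, np.nan), np.nan, False, 0),
               "theta_P": (np.full(k, np.nan), np.nan, False, 0)}
    if "L" in estimators:
        results["theta_L"] = solve_equation(lambda x: s_L(eta_hat, x), eta_hat, local, rng)
    if "P" in estimators:
        results["theta_P"] = solve_equation(lambda x: s_P(eta_hat, x), eta_hat, local, rng)
    (tL, nL, cL, rL), (tP, nP, cP, rP) = results["theta_L"], results["theta_P"]
    return FitResult(
        eta_hat=eta_hat, theta_L_hat=np.asarray(tL), theta_P_hat=np.asarray(tP),
        score_norms={"eta": norm_eta, "theta_L": nL, "theta_P": nP},
        converged={"eta": conv_eta,
                   "theta_L": cL if "L" in estimators else True,
                   "theta_P": cP if "P" in estimators else True},
        n_restarts={"eta": r_eta, "theta_L": rL, "theta_P": rP},
        tol=tol)


def perturbation_weights(ds: SemicompetingDataset, fit_result: FitResult) -> PerturbationWeights:
    """Influence rows of the three scores, evaluated at the fitted parameters.

    ``W_i^(1)`` and ``W_i^(2)`` are the martingale-decomposition terms of
    the rank scores (terminal event at η̂, transformed event of interest
    at α̂^L); ``W_i^(3) = (2/(n-1)) Σ_j (Z_i - Z_j) φ_ij(α̂^P)``.
    """
    W1 = _kernels.rank_influence(ds.y_d - ds.Z @ fit_result.eta_hat, ds.Delta, ds.Z)
    ts = transform_global(ds, fit_result.alpha_L)
    W2 = _kernels.rank_influence(ts.x_star, ts.delta_star, ds.Z)
    e, b, v = _linear_pieces(ds, fit_result.alpha_P)
    W3 = _kernels.w3_rows(e, b, v, ds.delta, ds.Z)
    return PerturbationWeights(W=np.hstack([W1, W2, W3]), k=ds.k)


def omega_hat(pw: PerturbationWeights) -> np.ndarray:
    """Score covariance estimate ``Ω̂ = n^{-1} Σ_i W_i W_i'``."""
    return pw.W.T @ pw.W / pw.n


def resample(ds: SemicompetingDataset, fit_result: FitResult, M: int = 500,
             seed: int | None = None, opts: SolverOptions | None = None) -> ResamplingDraws:
    """Solve the multiplier-perturbed system for ``M`` draws.

    Each draw samples ``Q_1..Q_n ~ N(0,1)``, forms the fixed right-hand
    side ``r = -n^{-1/2} Σ_i W_i Q_i`` and solves block-sequentially:
    η* from ``S_n(η) = r_η``, then θ^L* and θ^P* at fixed η*, each
    warm-started at the point estimate.  Draws whose solves miss the
    tolerance are dropped; fewer than ``success_floor * M`` survivors
    raise :class:`ResamplingQualityError`.
    """
    if M < 2:
        raise ValueError("need M >= 2 resampling draws")
    opts = opts or SolverOptions()
    n, k = ds.n, ds.k
    tol = opts.tol if opts.tol is not None else default_tolerance(n, k)
    # Perturbed solves target the root nearest the point estimate: the
    # artificially censored equations can have spurious distant plateaus, so
    # draws use a small simplex and jitter to stay in the basin of beta-hat.
    local = SolverOptions(**{**opts.__dict__, "tol": tol, "restarts": 1, "step": 0.12,
                             "jitter": 0.15, "xatol": 8e-3, "maxfev": 250, "polish": False})
    rng = np.random.default_rng(seed)
    pw = perturbation_weights(ds, fit_result)
    s_eta, s_L, s_P = _score_closures(ds)
    sqrt_n = np.sqrt(n)
    draws, qs = [], []
    for _ in range(M):
        Q = rng.standard_normal(n)
        r = -(pw.W.T @ Q) / sqrt_n
        r1, r2, r3 = r[:k], r[k:2 * k], r[2 * k:]
        eta_s, _, ok1, _ = solve_equation(
            lambda x: s_eta(x) - r1, fit_result.eta_hat, local, rng)
        tL_s, _, ok2, _ = solve_equation(
            lambda x: s_L(eta_s, x) - r2, fit_result.theta_L_hat, local, rng)
        tP_s, _, ok3, _ = solve_equation(
            lambda x: s_P(eta_s, x) - r3, fit_result.theta_P_hat, local, rng)
        if ok1 and ok2 and ok3:
            draws.append(np.concatenate([eta_s, tL_s, tP_s]))
            qs.append(Q)
    M_success = len(draws)
    if M_success < opts.success_floor * M:
        raise ResamplingQualityError(
            f"only {M_success}/{M} perturbed solves converged (floor {opts.success_floor:.0%})")
    return ResamplingDraws(draws=np.asarray(draws), Q=np.asarray(qs),
                           M_requested=M, M_success=M_success, seed=seed)


def covariance(draws: ResamplingDraws) -> CovarianceEstimate:
    """Empirical covariance Σ̂ of the solved realizations (ddof = 1)."""
    if draws.M_success < 2:
        raise ValueError("need at least 2 successful draws")
    sigma = np.cov(draws.draws, rowvar=False, ddof=1)
    sigma = np.atleast_2d(sigma)
    sigma = (sigma + sigma.T) / 2.0
    cond = float(np.linalg.cond(sigma))
    if cond > 1e10:
        import warnings
        warnings.warn(f"resampling covariance is near rank-deficient (cond={cond:.2e})")
    return CovarianceEstimate(sigma=sigma, k=draws.k, condition_number=cond)


def standard_errors(cov: CovarianceEstimate) -> dict:
    """Square roots of the diagonal blocks of Σ̂, per estimator."""
    d = np.diag(cov.sigma)
    if np.any(d < 0):
        raise ValueError("negative diagonal in covariance estimate")
    k = cov.k
    se = np.sqrt(d)
    return {"eta": se[:k], "theta_L": se[k:2 * k], "theta_P": se[2 * k:]}
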