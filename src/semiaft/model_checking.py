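"""Goodness of fit via martingale-residual score processes.

For each of the three fitted equations the cumulative covariate-weighted
martingale-residual process (the "observed score process") fluctuates
around zero when the log-linear model is correctly specified, and its
terminal value reproduces the estimating-equation value at the fit.  The
null distribution of the supremum statistic is approximated by
multiplier-bootstrapped processes reusing the resampling draws and their
normal multipliers: each bootstrap path is the multiplier-perturbed
martingale integral plus the shift of the observed process between the
draw parameters and the fitted parameters.

Both θ processes use the globally transformed sample — evaluated at
α̂^L or α̂^P respectively — mirroring how a single cause-specific hazard
underlies each equation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .artificial_censoring import transform_global
from .data_model import ParamAlpha, SemicompetingDataset
from .inference import FitResult, ResamplingDraws

__all__ = ["ScoreProcess", "GofResult", "nelson_aalen", "martingale_residuals",
           "observed_score_process", "bootstrap_processes", "gof_test"]

_WHICH = ("eta", "theta_L", "theta_P")


@dataclass(frozen=True)
class ScoreProcess:
    """A k-vector step-function process over residual time."""

    jump_points: np.ndarray    # sorted residual grid (event times)
    values: np.ndarray         # (G, k) values at each jump point (right-continuous)
    which: str

    def evaluate(self, s) -> np.ndarray:
        """Step-function value at time(s) s (0 before the first jump)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        idx = np.searchsorted(self.jump_points, s, side="right") - 1
        out = np.zeros((s.size, self.values.shape[1]))
        ok = idx >= 0
        out[ok] = self.values[idx[ok]]
        return out

    def sup_norm(self, norm: str = "euclidean") -> float:
        if self.values.size == 0:
            return 0.0
        if norm == "euclidean":
            return float(np.max(np.linalg.norm(self.values, axis=1)))
        if norm == "max":
            return float(np.max(np.abs(self.values)))
        raise ValueError(f"unknown norm {norm!r}")


@dataclass
class GofResult:
    sup_stats: dict            # which -> observed sup statistic
    pvalues: dict              # {"p1", "p2", "p3"}
    pvalues_adjusted: dict     # Bonferroni over the two θ tests
    M: int
    process_bundle: dict       # which -> (observed ScoreProcess, list of bootstrap paths)


def _residual_data(ds: SemicompetingDataset, fit_result: FitResult, which: str):
    """Residual times and event indicators feeding the process ``which``."""
    if which == "eta":
        return ds.y_d - ds.Z @ fit_result.eta_hat, np.asarray(ds.Delta, dtype=float)
    if which == "theta_L":
        ts = transform_global(ds, fit_result.alpha_L)
    elif which == "theta_P":
        ts = transform_global(ds, fit_result.alpha_P)
    else:
        raise ValueError(f"unknown process {which!r}")
    return ts.x_star, ts.delta_star


def nelson_aalen(times: np.ndarray, indicators: np.ndarray):
    """Nelson-Aalen cumulative hazard on residual time.

    Returns ``(grid, dLambda, Lambda)`` where ``grid`` holds the distinct
    event times, ``dLambda`` the increments (events / at-risk, risk sets
    by non-strict >=) and ``Lambda`` their cumulative sum.
    """
    times = np.asarray(times, dtype=float)
    indicators = np.asarray(indicators, dtype=float)
    if not np.all(np.isfinite(times)):
        raise ValueError("non-finite residual times")
    grid = np.unique(times[indicators != 0])
    if grid.size == 0:
        return grid, np.empty(0), np.empty(0)
    events = np.array([indicators[times == t].sum() for t in grid])
    at_risk = np.array([(times >= t).sum() for t in grid])
    dL = events / at_risk
    return grid, dL, np.cumsum(dL)


def martingale_residuals(ds: SemicompetingDataset, fit_result: FitResult,
                         which: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject martingale residuals evaluated on the event grid.

    Returns ``(grid, Mhat)`` with ``Mhat[i, g] = N_i(t_g) - Σ_{u<=t_g}
    I{e_i >= u} dΛ̂(u)``.  Rows sum to ~0 at the last grid point.
    """
    e, d = _residual_data(ds, fit_result, which)
    grid, dL, _ = nelson_aalen(e, d)
    n, G = e.shape[0], grid.size
    if G == 0:
        return grid, np.zeros((n, 0))
    N = (d[:, None] != 0) & (e[:, None] <= grid[None, :])
    at_risk = e[:, None] >= grid[None, :]
    compensator = np.cumsum(at_risk * dL[None, :], axis=1)
    return grid, N.astype(float) - compensator


def observed_score_process(ds: SemicompetingDataset, fit_result: FitResult,
                           which: str) -> ScoreProcess:
    """Observed process ``n^{-1/2} Σ_i Z_i M̂_i(s)`` on the event grid."""
    grid, Mhat = martingale_residuals(ds, fit_result, which)
    values = (ds.Z.T @ Mhat).T / np.sqrt(ds.n)
    return ScoreProcess(jump_points=grid, values=values, which=which)


def _risk_stats(e, grid, weights):
    """Σ_i w_i I{e_i >= u} for each grid point u (w may be a vector or matrix)."""
    w = np.atleast_2d(np.asarray(weights, dtype=float).T).T  # (n, p)
    order = np.argsort(e)
    cum = np.cumsum(w[order], axis=0)
    total = cum[-1]
    # number with e < u:
    below = np.searchsorted(e[order], grid, side="left")
    out = np.empty((grid.size, w.shape[1]))
    for g, b in enumerate(below):
        out[g] = total - (cum[b - 1] if b > 0 else 0.0)
    return out


def _perturbed_integral(ds, e, d, Q) -> np.ndarray:
    """Grid values of n^{-1/2} Σ_i Q_i ∫_{-inf}^s {Z_i - Zbar(w)} dM̂_i(w)."""
    grid, dL, _ = nelson_aalen(e, d)
    G, k, n = grid.size, ds.k, ds.n
    if G == 0:
        return grid, np.zeros((0, k))
    riskZ = _risk_stats(e, grid, ds.Z)                  # (G, k)
    riskN = _risk_stats(e, grid, np.ones(n))[:, 0]      # (G,)
    Zbar = riskZ / riskN[:, None]
    # event part: Σ over event residuals <= s of Q_i d_i (Z_i - Zbar(e_i))
    pos = np.searchsorted(grid, e)  # event residuals lie on the grid where d != 0
    ev = np.zeros((G, k))
    for i in range(n):
        if d[i] != 0:
            ev[pos[i]] += Q[i] * d[i] * (ds.Z[i] - Zbar[pos[i]])
    # compensator part: Σ_{u<=s} dΛ(u) Σ_i Q_i I(e_i>=u)(Z_i - Zbar(u))
    QZrisk = _risk_stats(e, grid, Q[:, None] * ds.Z)
    Qrisk = _risk_stats(e, grid, Q)[:, 0]
    comp = dL[:, None] * (QZrisk - Qrisk[:, None] * Zbar)
    return grid, np.cumsum(ev - comp, axis=0) / np.sqrt(n)


def _draw_params(fit_result: FitResult, draw: np.ndarray, which: str) -> FitResult:
    k = fit_result.eta_hat.shape[0]
    return FitResult(eta_hat=draw[:k], theta_L_hat=draw[k:2 * k], theta_P_hat=draw[2 * k:],
                     score_norms={}, converged={}, n_restarts={}, tol=fit_result.tol)


def bootstrap_processes(ds: SemicompetingDataset, fit_result: FitResult,
                        draws: ResamplingDraws, which: str,
                        n_paths: int | None = None,
                        rng: np.random.Generator | None = None) -> list[ScoreProcess]:
    """Multiplier-bootstrap paths of the score process ``which``.

    One path per retained draw (or a random subset of ``n_paths`` for
    plotting): the perturbed martingale integral at the fit, using that
    draw's multipliers, plus the observed-process shift between the draw
    parameters and the fitted parameters, all on the union grid.
    """
    if draws.Q.shape[0] != draws.draws.shape[0] or draws.Q.shape[1] != ds.n:
        raise ValueError("resampling draws do not match this dataset")
    e, d = _residual_data(ds, fit_result, which)
    obs = observed_score_process(ds, fit_result, which)
    idx = np.arange(draws.M_success)
    if n_paths is not None and n_paths < idx.size:
        rng = rng or np.random.default_rng(0)
        idx = np.sort(rng.choice(idx, size=n_paths, replace=False))
    paths = []
    for j in idx:
        Q = draws.Q[j]
        grid1, term1 = _perturbed_integral(ds, e, d, Q)
        shifted = observed_score_process(ds, _draw_params(fit_result, draws.draws[j], which), which)
        grid = np.unique(np.concatenate([grid1, shifted.jump_points, obs.jump_points]))
        t1 = ScoreProcess(grid1, term1, which).evaluate(grid)
        vals = t1 + shifted.evaluate(grid) - obs.evaluate(grid)
        paths.append(ScoreProcess(jump_points=grid, values=vals, which=which))
    return paths


def gof_test(ds: SemicompetingDataset, fit_result: FitResult, draws: ResamplingDraws,
             M: int | None = None, norm: str = "euclidean") -> GofResult:
    """Sup-norm lack-of-fit tests for the three equations.

    p-values are the bootstrap exceedance fractions
    ``p = M^{-1} Σ_j I{sup||path_j|| >= sup||observed||}``; the two
    event-of-interest tests are Bonferroni-adjusted (doubled, capped at 1).
    """
    M_use = draws.M_success if M is None else min(M, draws.M_success)
    sub = ResamplingDraws(draws=draws.draws[:M_use], Q=draws.Q[:M_use],
                          M_requested=M_use, M_success=M_use, seed=draws.seed)
    sup_stats, pvals, bundle = {}, {}, {}
    for which in _WHICH:
        obs = observed_score_process(ds, fit_result, which)
        paths = bootstrap_processes(ds, fit_result, sub, which)
        obs_sup = obs.sup_norm(norm)
        boot_sups = np.array([p.sup_norm(norm) for p in paths])
        sup_stats[which] = obs_sup
        pvals[which] = float(np.mean(boot_sups >= obs_sup)) if M_use else np.nan
        bundle[which] = (obs, paths)
    pvalues = {"p1": pvals["eta"], "p2": pvals["theta_L"], "p3": pvals["theta_P"]}
    adjusted = {"p2": min(1.0, 2 * pvals["theta_L"]), "p3": min(1.0, 2 * pvals["theta_P"])}
    return GofResult(sup_stats=sup_stats, pvalues=pvalues,
                     pvalues_adjusted=adjusted, M=M_use, process_bundle=bundle)
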