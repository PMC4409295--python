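"""Synthetic semicompeting-risks data and full simulation studies.

Two data-generating designs are provided:

* ``bvnormal``: log-times ``X = Z'θ0 + ε^X``, ``D = Z'η0 + ε^D`` with
  bivariate-normal errors, means (0, 1.2), unit variances and correlation
  ρ; covariates are Bernoulli(0.5); independent censoring
  ``C = log(U)``, ``U ~ Uniform(0, 20)``.
* ``gamma_frailty``: a shared Gamma frailty ν with mean 1 and variance σ²
  scales two exponential original-scale errors, ``exp(ε^X) ~ Exp(rate
  4/ν)`` and ``exp(ε^D) ~ Exp(rate 1/ν)``; σ² = 0 degenerates to
  independent exponentials (ν ≡ 1).  Defaults: θ0 = (0.5, 1),
  η0 = (1, 0.5), Z1 ~ Uniform(0, 1), Z2 ~ Bernoulli(0.5), and the same
  uniform censoring law.

Both generators retain the latent log-times X, D, C on the dataset (for
oracle checks only).  ``run_study`` loops simulate → fit → resample →
weight and summarizes bias, MSE, mean/median standard errors and
normal-approximation coverage per estimator and coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import SemicompetingDataset, validate
from .inference import SolverOptions, covariance, fit, resample, standard_errors
from .weighting import weighted_estimates

__all__ = ["SimulationDesign", "SimulationSummary", "simulate_bvnormal",
           "simulate_gamma_frailty", "simulate", "run_study", "SCENARIOS"]

_METRICS = ("Bias", "MSE", "SEE", "Coverage", "Dmedian", "Mediansq", "Sdmedian")


@dataclass
class SimulationDesign:
    family: str                      # "bvnormal" | "gamma_frailty"
    n: int
    theta0: np.ndarray
    eta0: np.ndarray
    dependence: float = 0.0          # rho (bvnormal) or sigma^2 (gamma_frailty)

    def __post_init__(self):
        self.theta0 = np.atleast_1d(np.asarray(self.theta0, dtype=float))
        self.eta0 = np.atleast_1d(np.asarray(self.eta0, dtype=float))
        if self.n < 10:
            raise ValueError("need n >= 10")
        if self.family == "bvnormal" and not -1 <= self.dependence <= 1:
            raise ValueError("correlation must lie in [-1, 1]")
        if self.family == "gamma_frailty" and self.dependence < 0:
            raise ValueError("frailty variance must be nonnegative")


@dataclass
class SimulationSummary:
    table: pd.DataFrame              # tidy: estimator, coefficient, metric, value
    estimates: dict                  # estimator -> (reps, k) array
    ses: dict                        # estimator -> (reps, k) array (NaN if M=0)
    n_reps_done: int
    n_failures: int
    design: SimulationDesign
    seed: int | None = None
    resample_success: list = field(default_factory=list)

    def metric(self, estimator: str, metric: str, coefficient: int) -> float:
        t = self.table
        row = t[(t.estimator == estimator) & (t.metric == metric)
                & (t.coefficient == coefficient)]
        return float(row.value.iloc[0])


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _assemble(X, D, C, Z) -> SemicompetingDataset:
    y_d = np.minimum(D, C)
    y_x = np.minimum(X, y_d)
    delta = (X <= y_d).astype(float)
    Delta = (D <= C).astype(float)
    ds = SemicompetingDataset(y_x=y_x, y_d=y_d, delta=delta, Delta=Delta, Z=Z,
                              latent={"X": X, "D": D, "C": C})
    return validate(ds)


def simulate_bvnormal(n: int, rho: float, theta0, eta0, seed=None) -> SemicompetingDataset:
    """Bivariate-normal-error design; covariates Bernoulli(0.5)."""
    rng = _rng(seed)
    theta0 = np.atleast_1d(np.asarray(theta0, dtype=float))
    eta0 = np.atleast_1d(np.asarray(eta0, dtype=float))
    k = theta0.size
    Z = rng.binomial(1, 0.5, size=(n, k)).astype(float)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    eps = rng.multivariate_normal([0.0, 1.2], cov, size=n)
    X = Z @ theta0 + eps[:, 0]
    D = Z @ eta0 + eps[:, 1]
    C = np.log(rng.uniform(0.0, 20.0, size=n))
    return _assemble(X, D, C, Z)


def simulate_gamma_frailty(n: int, sigma2: float, theta0=(0.5, 1.0),
                           eta0=(1.0, 0.5), seed=None) -> SemicompetingDataset:
    """Shared gamma-frailty exponential design with Z1 ~ U(0,1), Z2 ~ Bern(0.5)."""
    rng = _rng(seed)
    theta0 = np.atleast_1d(np.asarray(theta0, dtype=float))
    eta0 = np.atleast_1d(np.asarray(eta0, dtype=float))
    if theta0.size != 2:
        raise ValueError("the gamma-frailty design uses two covariates")
    Z = np.column_stack([rng.uniform(0.0, 1.0, size=n),
                         rng.binomial(1, 0.5, size=n).astype(float)])
    if sigma2 == 0:
        nu = np.ones(n)
    else:
        nu = rng.gamma(shape=1.0 / sigma2, scale=sigma2, size=n)
    # exponential with rate 4/nu has scale nu/4
    eps_X = np.log(rng.exponential(scale=nu / 4.0))
    eps_D = np.log(rng.exponential(scale=nu))
    X = Z @ theta0 + eps_X
    D = Z @ eta0 + eps_D
    C = np.log(rng.uniform(0.0, 20.0, size=n))
    return _assemble(X, D, C, Z)


def simulate(design: SimulationDesign, seed=None) -> SemicompetingDataset:
    if design.family == "bvnormal":
        return simulate_bvnormal(design.n, design.dependence, design.theta0, design.eta0, seed)
    if design.family == "gamma_frailty":
        return simulate_gamma_frailty(design.n, design.dependence, design.theta0,
                                      design.eta0, seed)
    raise ValueError(f"unknown simulation family {design.family!r}")


def run_study(design: SimulationDesign, n_reps: int = 500, M: int = 500,
              level: float = 0.95, seed: int | None = None,
              estimators: Sequence[str] = ("theta_L", "theta_P", "theta_MWE", "theta_JWE"),
              solver: SolverOptions | None = None,
              max_failure_rate: float = 0.1) -> SimulationSummary:
    """Monte-Carlo study of the selected estimators under ``design``.

    With ``M == 0`` only point estimates are recorded (SEE, coverage and
    Sdmedian are NaN).  Replications whose fit or resampling fails are
    dropped and counted; more than ``max_failure_rate`` failures aborts.
    """
    estimators = tuple(estimators)
    need_weights = any(e in estimators for e in ("theta_MWE", "theta_JWE"))
    need_P = need_weights or "theta_P" in estimators
    need_L = need_weights or "theta_L" in estimators
    if M > 0:
        need_P = need_L = True  # the joint perturbed system involves all blocks
    fit_which = ("L" if need_L else "") + ("P" if need_P else "")
    z = norm.ppf(0.5 + level / 2.0)
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(2 * n_reps) % (2 ** 31)
    k = design.theta0.size
    est = {e: [] for e in estimators}
    ses = {e: [] for e in estimators}
    resample_success = []
    failures = 0
    for r in range(n_reps):
        ds = simulate(design, int(rep_seeds[2 * r]))
        try:
            fr = fit(ds, solver, estimators=tuple(fit_which))
            rec_est, rec_se = {}, {}
            if M > 0:
                draws = resample(ds, fr, M=M, seed=int(rep_seeds[2 * r + 1]), opts=solver)
                cov = covariance(draws)
                se = standard_errors(cov)
                rec_se["theta_L"], rec_se["theta_P"] = se["theta_L"], se["theta_P"]
                if need_weights:
                    we = weighted_estimates(fr, cov)
                    rec_est["theta_MWE"], rec_est["theta_JWE"] = we.theta_MWE, we.theta_JWE
                    rec_se["theta_MWE"], rec_se["theta_JWE"] = we.se_MWE, we.se_JWE
                resample_success.append(draws.M_success)
            elif need_weights:  # weights need the resampling covariance
                rec_est["theta_MWE"] = rec_est["theta_JWE"] = np.full(k, np.nan)
            rec_est["theta_L"], rec_est["theta_P"] = fr.theta_L_hat, fr.theta_P_hat
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            failures += 1
            if failures > max_failure_rate * n_reps:
                raise RuntimeError(f"more than {max_failure_rate:.0%} of replications failed")
            continue
        for e in estimators:
            est[e].append(rec_est[e])
            ses[e].append(rec_se.get(e, np.full(k, np.nan)))
    est = {e: np.asarray(v) for e, v in est.items()}
    ses = {e: np.asarray(v) for e, v in ses.items()}
    rows = []
    for e in estimators:
        err = est[e] - design.theta0[None, :]
        se_arr = ses[e]
        for m in range(k):
            vals = {
                "Bias": np.mean(err[:, m]),
                "MSE": np.mean(err[:, m] ** 2),
                "SEE": np.mean(se_arr[:, m]) if M > 0 else np.nan,
                "Coverage": (np.mean(np.abs(err[:, m]) <= z * se_arr[:, m])
                             if M > 0 else np.nan),
                "Dmedian": np.median(err[:, m]),
                "Mediansq": np.median(err[:, m] ** 2),
                "Sdmedian": np.median(se_arr[:, m]) if M > 0 else np.nan,
            }
            for metric in _METRICS:
                rows.append({"estimator": e, "coefficient": m, "metric": metric,
                             "value": vals[metric]})
    table = pd.DataFrame(rows)
    return SimulationSummary(table=table, estimates=est, ses=ses,
                             n_reps_done=n_reps - failures, n_failures=failures,
                             design=design, seed=seed, resample_success=resample_success)


# named study scenarios: gamma-frailty design at its default true parameters
SCENARIOS = {
    "frailty_s0_n150": SimulationDesign("gamma_frailty", 150, (0.5, 1.0), (1.0, 0.5), 0.0),
    "frailty_s0_n300": SimulationDesign("gamma_frailty", 300, (0.5, 1.0), (1.0, 0.5), 0.0),
    "frailty_s1_n150": SimulationDesign("gamma_frailty", 150, (0.5, 1.0), (1.0, 0.5), 1.0),
    "frailty_s1_n300": SimulationDesign("gamma_frailty", 300, (0.5, 1.0), (1.0, 0.5), 1.0),
}
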