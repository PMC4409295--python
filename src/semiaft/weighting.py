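"""Optimal linear combination of the two artificial-censoring estimators.

Neither the global-offset estimator θ̂^L nor the pairwise estimator θ̂^P
dominates the other in standard error, so the two are combined per
coefficient with weights summing to one, chosen to minimize the variance
of the combination.  Because both θ estimators are built on the same η̂,
the weights are computed from the inverse of the *joint* 3k x 3k
covariance Σ̂ of (η̂, θ̂^L, θ̂^P) — the precision matrix carries the
conditioning on η̂ — not from the inverse of a 2x2 covariance submatrix.

Marginal approach: for coefficient m, extract the 2x2 submatrix Σ̂*_m of
Σ̂^{-1} at the (θ^L_m, θ^P_m) rows/columns and take
``ĉ_m = (h' Σ̂*_m h)^{-1} Σ̂*_m h`` with h = (1, 1)'.

Joint approach: extract the 2k x 2k submatrix Σ̂** of Σ̂^{-1} for
(θ^L, θ^P), stack two identities into E (2k x k) and form
``B̂ = {(E' Σ̂** E)^{-1} E' Σ̂**}'``; coefficient m combines with the pair
(B̂[m, m], B̂[k+m, m]).  With a single covariate the two approaches
coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .inference import CovarianceEstimate, FitResult

__all__ = ["WeightedEstimates", "marginal_weights", "joint_weights",
           "combine", "weighted_se", "weighted_estimates"]


@dataclass
class WeightedEstimates:
    c_marginal: np.ndarray     # k x 2 weight pairs (c_m1, c_m2)
    B: np.ndarray              # 2k x k contrast matrix
    theta_MWE: np.ndarray
    theta_JWE: np.ndarray
    se_MWE: np.ndarray
    se_JWE: np.ndarray
    se_MWE_precision: np.ndarray   # alternative precision-form SEs
    diagnostics: dict

    def to_dict(self) -> dict:
        return {
            "theta_MWE": self.theta_MWE.tolist(),
            "theta_JWE": self.theta_JWE.tolist(),
            "se_MWE": self.se_MWE.tolist(),
            "se_JWE": self.se_JWE.tolist(),
            "c_marginal": self.c_marginal.tolist(),
            "B": self.B.tolist(),
        }


def _precision(cov: CovarianceEstimate) -> tuple[np.ndarray, dict]:
    """Invert Σ̂, ridge-regularizing if it is numerically singular."""
    sigma = cov.sigma
    diag = {"regularized": False}
    try:
        prec = np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        prec = None
    if prec is None or not np.all(np.isfinite(prec)):
        eps = 1e-8 * np.trace(sigma) / sigma.shape[0]
        warnings.warn("singular covariance; applying ridge regularization")
        prec = np.linalg.inv(sigma + eps * np.eye(sigma.shape[0]))
        diag["regularized"] = True
    return prec, diag


def marginal_weights(cov: CovarianceEstimate, m: int) -> np.ndarray:
    """Weight pair ``(ĉ_m1, ĉ_m2)`` for coefficient m (0-based); sums to 1."""
    k = cov.k
    if not 0 <= m < k:
        raise IndexError(f"coefficient index {m} out of range for k={k}")
    prec, _ = _precision(cov)
    idx = [k + m, 2 * k + m]
    sub = prec[np.ix_(idx, idx)]
    h = np.ones(2)
    c = sub @ h / (h @ sub @ h)
    return c


def joint_weights(cov: CovarianceEstimate) -> np.ndarray:
    """Contrast matrix ``B̂ = {(E' Σ̂** E)^{-1} E' Σ̂**}'`` (2k x k).

    Column m satisfies B̂[m, m] + B̂[k+m, m] = 1 and, for p != m,
    B̂[p, m] + B̂[k+p, m] = 0.
    """
    k = cov.k
    prec, _ = _precision(cov)
    sub = prec[k:, k:]  # 2k x 2k block for (theta_L, theta_P)
    E = np.vstack([np.eye(k), np.eye(k)])
    B = np.linalg.solve(E.T @ sub @ E, E.T @ sub).T
    return B


def combine(fit_result: FitResult, c_marginal: np.ndarray, B: np.ndarray):
    """Weighted point estimates ``(θ̂^MWE, θ̂^JWE)`` from the two weight sets."""
    tL, tP = fit_result.theta_L_hat, fit_result.theta_P_hat
    k = tL.shape[0]
    c_marginal = np.atleast_2d(c_marginal)
    theta_MWE = c_marginal[:, 0] * tL + c_marginal[:, 1] * tP
    theta_JWE = np.array([B[m, m] * tL[m] + B[k + m, m] * tP[m] for m in range(k)])
    return theta_MWE, theta_JWE


def weighted_se(cov: CovarianceEstimate, weights: np.ndarray,
                form: str = "covariance") -> np.ndarray:
    """Standard errors of the per-coefficient weighted combinations.

    ``form="covariance"`` (default): SE_m = sqrt(c_m' V_m c_m) with V_m the
    2x2 covariance submatrix of Σ̂ for (θ̂^L_m, θ̂^P_m) — valid for any
    weight pair.  ``form="precision"``: sqrt((h' Σ̂*_m h)^{-1}), the
    variance the optimal-combination theory assigns to the optimum.
    """
    k = cov.k
    weights = np.atleast_2d(weights)
    prec, _ = _precision(cov)
    out = np.empty(k)
    for m in range(k):
        idx = [k + m, 2 * k + m]
        if form == "covariance":
            V = cov.sigma[np.ix_(idx, idx)]
            q = weights[m] @ V @ weights[m]
            if q < 0:
                raise ValueError("negative variance quadratic form; covariance estimate broken")
            out[m] = np.sqrt(q)
        elif form == "precision":
            sub = prec[np.ix_(idx, idx)]
            h = np.ones(2)
            out[m] = np.sqrt(1.0 / (h @ sub @ h))
        else:
            raise ValueError(f"unknown SE form {form!r}")
    return out


def weighted_estimates(fit_result: FitResult, cov: CovarianceEstimate) -> WeightedEstimates:
    """Full weighting pipeline: weights, combined estimates and their SEs."""
    k = cov.k
    c_marg = np.vstack([marginal_weights(cov, m) for m in range(k)])
    B = joint_weights(cov)
    theta_MWE, theta_JWE = combine(fit_result, c_marg, B)
    pairs_J = np.vstack([[B[m, m], B[k + m, m]] for m in range(k)])
    diagnostics = {"condition_number": cov.condition_number,
                   "unstable_weights": bool(np.any((c_marg < -5) | (c_marg > 6)))}
    if diagnostics["unstable_weights"]:
        warnings.warn("marginal weights outside [-5, 6]; covariance may be unstable")
    return WeightedEstimates(
        c_marginal=c_marg, B=B, theta_MWE=theta_MWE, theta_JWE=theta_JWE,
        se_MWE=weighted_se(cov, c_marg, "covariance"),
        se_JWE=weighted_se(cov, pairs_J, "covariance"),
        se_MWE_precision=weighted_se(cov, c_marg, "precision"),
        diagnostics=diagnostics)
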