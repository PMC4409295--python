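"""Rank-based estimating equations for the semicompeting-risks AFT model.

Three scores are stacked:

* ``S_n(η)``: log-rank score for the terminal-event regression, built on
  residuals ``D~_i - Z_i'η`` with indicator Δ (the terminal time is
  subject only to independent censoring, so ordinary rank regression
  applies);
* ``U_n^L(α)``: the same score applied to the globally artificially
  censored sample (event of interest);
* ``U_n^P(α)``: Gehan-type pairwise U-statistic
  ``2 n^{1/2} / (n(n-1)) Σ_{i<j} (Z_i - Z_j) φ_ij(α)`` using the pairwise
  transforms.

All risk sets use non-strict ``≥`` (ties at risk).  Each score carries
its printed normalization, so values are O(1) in n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .artificial_censoring import _linear_pieces, transform_global
from .data_model import ParamAlpha, ParamBeta, SemicompetingDataset

__all__ = ["ScoreValue", "score_eta", "score_theta_L", "score_theta_P", "stacked_score"]


@dataclass(frozen=True)
class ScoreValue:
    """A score evaluation; ``value`` includes the printed normalization."""

    value: np.ndarray
    which: str


def score_eta(ds: SemicompetingDataset, eta: np.ndarray) -> ScoreValue:
    """Terminal-event rank score ``S_n(η)``."""
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    if eta.shape[0] != ds.k:
        raise ValueError(f"eta has length {eta.shape[0]}, expected {ds.k}")
    resid = ds.y_d - ds.Z @ eta
    return ScoreValue(_kernels.rank_score(resid, ds.Delta, ds.Z), "eta")


def score_theta_L(ds: SemicompetingDataset, alpha: ParamAlpha) -> ScoreValue:
    """Global artificial-censoring score ``U_n^L(α)``."""
    ts = transform_global(ds, alpha)
    return ScoreValue(_kernels.rank_score(ts.x_star, ts.delta_star, ds.Z), "theta_L")


def score_theta_P(ds: SemicompetingDataset, alpha: ParamAlpha) -> ScoreValue:
    """Pairwise artificial-censoring score ``U_n^P(α)``."""
    e, b, v = _linear_pieces(ds, alpha)
    return ScoreValue(_kernels.unp_score(e, b, v, ds.delta, ds.Z), "theta_P")


def stacked_score(ds: SemicompetingDataset, beta: ParamBeta) -> ScoreValue:
    """Joint score ``G_n(β) = [S_n(η)', U_n^L(η, θ^L)', U_n^P(η, θ^P)']'``."""
    s1 = score_eta(ds, beta.eta).value
    s2 = score_theta_L(ds, ParamAlpha(beta.eta, beta.theta_L)).value
    s3 = score_theta_P(ds, ParamAlpha(beta.eta, beta.theta_P)).value
    return ScoreValue(np.concatenate([s1, s2, s3]), "stacked")
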