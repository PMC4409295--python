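"""Artificial-censoring transforms for semicompeting-risks AFT estimation.

The event-of-interest residual ``X - Z'θ`` cannot be compared directly
across subjects because its at-risk process depends on the dependent
censoring residual ``D - Z'η``.  Artificial censoring restores an
exchangeable censoring mechanism by additionally censoring every subject
at ``D~ - Z'η - g``, where the offset ``g ≥ max_i Z_i'(θ - η) ∨ 0``
guarantees the extra censoring bound is at least as severe for every
subject.  Two offsets are used:

* a single global offset ``g(α) = max_i {0, Z_i'(θ - η)}`` (one-sample
  transform feeding a log-rank-type score), and
* pairwise offsets ``g_ij(α) = max{0, Z_i'(θ-η), Z_j'(θ-η)}`` (less
  censoring per comparison, feeding a Gehan-type pairwise score).

Although the definitions involve the latent X, D, C, both transforms are
functions of the observables only: with ``e_i = y_x_i - Z_i'θ`` and
``c_i = y_d_i - Z_i'η - g``, the transformed time is ``e_i ∧ c_i`` when
δ_i = 1 and ``c_i`` otherwise, and the transformed indicator is
``δ_i I(e_i ≤ c_i)``.  (When δ_i = 0 the latent ``X_i - Z_i'θ`` exceeds
``y_d_i - Z_i'θ ≥ c_i`` because ``g ≥ Z_i'(θ - η)``, so the minimum is
attained at ``c_i`` and the subject is censored either way.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ParamAlpha, SemicompetingDataset

__all__ = [
    "TransformedSample", "global_offset", "pairwise_offset",
    "transform_global", "transform_pairwise", "pairwise_indicator",
]


@dataclass(frozen=True)
class TransformedSample:
    """Globally transformed residual data ``(X~*_i(α), δ~*_i(α))``."""

    x_star: np.ndarray
    delta_star: np.ndarray


def _check_dims(ds: SemicompetingDataset, alpha: ParamAlpha) -> None:
    if alpha.k != ds.k:
        raise ValueError(f"parameter length {alpha.k} does not match k={ds.k}")


def _linear_pieces(ds: SemicompetingDataset, alpha: ParamAlpha):
    """Per-subject residual pieces e, b, v shared by both transforms."""
    e = ds.y_x - ds.Z @ alpha.theta
    b = ds.y_d - ds.Z @ alpha.eta
    v = np.maximum(0.0, ds.Z @ (alpha.theta - alpha.eta))
    return e, b, v


def global_offset(ds: SemicompetingDataset, alpha: ParamAlpha) -> float:
    """Global offset ``g(α) = max_i {0, Z_i'(θ - η)}`` (always ≥ 0)."""
    _check_dims(ds, alpha)
    return float(np.max(np.maximum(0.0, ds.Z @ (alpha.theta - alpha.eta))))


def pairwise_offset(ds: SemicompetingDataset, alpha: ParamAlpha, i: int, j: int) -> float:
    """Pair offset ``g_ij(α) = max{0, Z_i'(θ-η), Z_j'(θ-η)}``."""
    _check_dims(ds, alpha)
    if i == j:
        raise IndexError("pairwise offset requires i != j")
    u = ds.Z[[i, j]] @ (alpha.theta - alpha.eta)  # IndexError on bad index
    return float(max(0.0, u[0], u[1]))


def _apply(e, c, delta):
    """Observable-form transform at censoring bound c."""
    delta_star = np.where((delta != 0) & (e <= c), 1.0, 0.0)
    x_star = np.where(delta != 0, np.minimum(e, c), c)
    return x_star, delta_star


def transform_global(ds: SemicompetingDataset, alpha: ParamAlpha) -> TransformedSample:
    """Apply the global artificial-censoring transform to every subject."""
    _check_dims(ds, alpha)
    e, b, v = _linear_pieces(ds, alpha)
    c = b - np.max(v)
    x_star, delta_star = _apply(e, c, ds.delta)
    return TransformedSample(x_star=x_star, delta_star=delta_star)


def transform_pairwise(ds: SemicompetingDataset, alpha: ParamAlpha, i: int, j: int):
    """Transformed ``(X~*_{i(j)}, δ~*_{i(j)})`` of subject i within pair (i, j)."""
    g = pairwise_offset(ds, alpha, i, j)
    e_i = float(ds.y_x[i] - ds.Z[i] @ alpha.theta)
    c_i = float(ds.y_d[i] - ds.Z[i] @ alpha.eta - g)
    if ds.delta[i] != 0:
        return min(e_i, c_i), int(e_i <= c_i)
    return c_i, 0


def pairwise_indicator(ds: SemicompetingDataset, alpha: ParamAlpha, i: int, j: int) -> int:
    """Antisymmetric pair score ``φ_ij(α) ∈ {-1, 0, 1}``.

    ``φ_ij = δ~*_{i(j)} I{X~*_{i(j)} ≤ X~*_{j(i)}} - δ~*_{j(i)} I{X~*_{j(i)} ≤ X~*_{i(j)}}``;
    a tie between two uncensored transformed times contributes 0.
    """
    x_ij, d_ij = transform_pairwise(ds, alpha, i, j)
    x_ji, d_ji = transform_pairwise(ds, alpha, j, i)
    return int(d_ij * (x_ij <= x_ji) - d_ji * (x_ji <= x_ij))
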