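"""Container and I/O for semicompeting-risks records.

A semicompeting-risks sample consists, for each subject, of an observed
first-event time ``X~ = X ∧ D ∧ C`` (progression censored by either the
terminal event D or independent censoring C), an observed terminal time
``D~ = D ∧ C``, the event indicator ``δ = I(X ≤ D~)``, the terminal
indicator ``Δ = I(D ≤ C)`` and a covariate vector Z.  All times are kept
on the logarithmic scale internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["SemicompetingDataset", "ParamAlpha", "ParamBeta", "load_dataset", "validate", "write_dataset"]


class ValidationError(ValueError):
    """A dataset invariant is violated."""


@dataclass(frozen=True)
class SemicompetingDataset:
    """Log-scale semicompeting-risks data for ``n`` subjects, ``k`` covariates.

    Attributes
    ----------
    y_x : observed first-event times ``X~_i`` (log scale), shape (n,).
    y_d : observed terminal times ``D~_i`` (log scale), shape (n,).
    delta : event indicators ``δ_i = I(X_i ≤ D~_i)``, 0/1, shape (n,).
    Delta : terminal indicators ``Δ_i = I(D_i ≤ C_i)``, 0/1, shape (n,).
    Z : covariate matrix, shape (n, k).
    ids : optional subject labels.
    latent : optional dict with latent log-times ``X``, ``D``, ``C``;
        populated only by the simulator for oracle checks, never consumed
        by any estimator.
    """

    y_x: np.ndarray
    y_d: np.ndarray
    delta: np.ndarray
    Delta: np.ndarray
    Z: np.ndarray
    ids: Sequence | None = None
    latent: dict | None = field(default=None, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "y_x", np.asarray(self.y_x, dtype=float))
        object.__setattr__(self, "y_d", np.asarray(self.y_d, dtype=float))
        object.__setattr__(self, "delta", np.asarray(self.delta, dtype=float))
        object.__setattr__(self, "Delta", np.asarray(self.Delta, dtype=float))
        Z = np.asarray(self.Z, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        object.__setattr__(self, "Z", Z)

    @property
    def n(self) -> int:
        return self.y_x.shape[0]

    @property
    def k(self) -> int:
        return self.Z.shape[1]

    def without_latent(self) -> "SemicompetingDataset":
        return replace(self, latent=None)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_x": self.y_x, "time_d": self.y_d,
                           "delta": self.delta.astype(int), "Delta": self.Delta.astype(int)})
        for j in range(self.k):
            df[f"z{j + 1}"] = self.Z[:, j]
        if self.ids is not None:
            df.insert(0, "id", list(self.ids))
        return df


@dataclass(frozen=True)
class ParamAlpha:
    """Regression parameter ``α = (η^T, θ^T)^T`` for one artificial-censoring fit."""

    eta: np.ndarray
    theta: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "eta", np.atleast_1d(np.asarray(self.eta, dtype=float)))
        object.__setattr__(self, "theta", np.atleast_1d(np.asarray(self.theta, dtype=float)))
        if self.eta.shape != self.theta.shape:
            raise ValidationError("eta and theta must have the same length")
        if not (np.all(np.isfinite(self.eta)) and np.all(np.isfinite(self.theta))):
            raise ValidationError("non-finite parameter entries")

    @property
    def k(self) -> int:
        return self.eta.shape[0]


@dataclass(frozen=True)
class ParamBeta:
    """Stacked parameter ``β = (η^T, (θ^L)^T, (θ^P)^T)^T`` of length 3k."""

    eta: np.ndarray
    theta_L: np.ndarray
    theta_P: np.ndarray

    def __post_init__(self):
        for name in ("eta", "theta_L", "theta_P"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if not (self.eta.shape == self.theta_L.shape == self.theta_P.shape):
            raise ValidationError("eta, theta_L, theta_P must have equal length")

    @property
    def k(self) -> int:
        return self.eta.shape[0]

    def stacked(self) -> np.ndarray:
        return np.concatenate([self.eta, self.theta_L, self.theta_P])

    @classmethod
    def from_stacked(cls, vec: np.ndarray) -> "ParamBeta":
        vec = np.asarray(vec, dtype=float)
        if vec.size % 3:
            raise ValidationError("stacked parameter length must be divisible by 3")
        k = vec.size // 3
        return cls(vec[:k], vec[k:2 * k], vec[2 * k:])


def validate(ds: SemicompetingDataset) -> SemicompetingDataset:
    """Check every dataset invariant; return ``ds`` unchanged if all hold.

    Raises :class:`ValidationError` naming the first offending row otherwise.
    """
    n = ds.n
    if n < 2:
        raise ValidationError(f"need at least 2 subjects, got n={n}")
    if ds.k < 1:
        raise ValidationError("need at least one covariate column")
    for name in ("y_x", "y_d", "delta", "Delta", "Z"):
        arr = getattr(ds, name)
        if arr.shape[0] != n:
            raise ValidationError(f"column {name!r} has length {arr.shape[0]}, expected {n}")
        if not np.all(np.isfinite(arr)):
            idx = int(np.flatnonzero(~np.all(np.isfinite(np.atleast_2d(arr.T)), axis=0))[0])
            raise ValidationError(f"missing or non-finite value in {name!r} at row {idx}")
    for name in ("delta", "Delta"):
        arr = getattr(ds, name)
        bad = np.flatnonzero(~np.isin(arr, (0.0, 1.0)))
        if bad.size:
            raise ValidationError(f"{name!r} must be 0/1; row {int(bad[0])} has value {arr[bad[0]]}")
    bad = np.flatnonzero(ds.y_x > ds.y_d + 1e-12)
    if bad.size:
        raise ValidationError(f"y_x > y_d at row {int(bad[0])} (X~ = X∧D∧C cannot exceed D~ = D∧C)")
    bad = np.flatnonzero((ds.delta == 0) & (ds.y_x != ds.y_d))
    if bad.size:
        raise ValidationError(
            f"delta=0 but y_x != y_d at row {int(bad[0])} (unobserved X implies X~ = D~)")
    return ds


_REQUIRED = ("time_x", "time_d", "delta", "Delta")


def load_dataset(path, column_map: Mapping[str, str] | None = None,
                 covariates: Sequence[str] | None = None,
                 log_transform: bool = False) -> SemicompetingDataset:
    """Read a semicompeting-risks CSV into a validated dataset.

    Parameters
    ----------
    path : CSV file with a header row.
    column_map : mapping from the logical names ``time_x``, ``time_d``,
        ``delta``, ``Delta`` to the column names in the file.  Identity by
        default.
    covariates : covariate column names, in order.  Defaults to every
        column not mapped to a logical role (and not ``id``).
    log_transform : if true, ``time_x`` and ``time_d`` are original-scale
        times (must be strictly positive) and are log-transformed.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cmap = dict(column_map or {})
    resolved = {logical: cmap.get(logical, logical) for logical in _REQUIRED}
    missing = [c for c in resolved.values() if c not in df.columns]
    if missing:
        raise KeyError(f"missing required column(s) {missing}; available: {list(df.columns)}")
    if covariates is None:
        used = set(resolved.values()) | {"id"}
        covariates = [c for c in df.columns if c not in used]
    else:
        missing = [c for c in covariates if c not in df.columns]
        if missing:
            raise KeyError(f"missing covariate column(s) {missing}")
    if not covariates:
        raise KeyError("no covariate columns found")
    y_x = df[resolved["time_x"]].to_numpy(dtype=float)
    y_d = df[resolved["time_d"]].to_numpy(dtype=float)
    if log_transform:
        for name, arr in (("time_x", y_x), ("time_d", y_d)):
            bad = np.flatnonzero(~(arr > 0))
            if bad.size:
                raise ValidationError(f"log_transform requires positive {name}; row {int(bad[0])}")
        y_x, y_d = np.log(y_x), np.log(y_d)
    ds = SemicompetingDataset(
        y_x=y_x, y_d=y_d,
        delta=df[resolved["delta"]].to_numpy(dtype=float),
        Delta=df[resolved["Delta"]].to_numpy(dtype=float),
        Z=df[list(covariates)].to_numpy(dtype=float),
        ids=df["id"].tolist() if "id" in df.columns else None,
    )
    return validate(ds)


def write_dataset(ds: SemicompetingDataset, path) -> None:
    """Write a dataset to CSV (log-scale times, full float precision)."""
    ds.to_frame().to_csv(path, index=False, float_format="%.17g")
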