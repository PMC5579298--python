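"""Reduce cross-basis coefficients to one-dimensional summaries.

The fitted exposure-lag-response surface is collapsed in two directions:

* overall cumulative exposure-response — sum the lag basis over integer
  lags 0..L, giving a curve on the exposure basis alone;
* lag-response at a fixed exposure value — contrast the exposure basis at
  that value against the centering value, giving a curve on the lag basis.

Both are linear maps of the cross-basis coefficients, so covariances
transform as ``M V M'``.  Centering is a contrast applied at prediction
time; no refit is needed to change the reference value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .basis import SplineSpec, eval_basis, lag_basis_matrix
from .city_models import CityFit

__all__ = ["ReducedCurve", "LagCurve", "reduce_overall_cumulative",
           "reduce_lag_specific", "predict_rr"]


@dataclass
class ReducedCurve:
    """Overall-cumulative coefficients on the exposure basis."""

    coef: np.ndarray
    vcov: np.ndarray
    var_spec: SplineSpec
    center: float | None = None
    kind: str = "overall_cumulative"

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.vcov = np.asarray(self.vcov, dtype=float)
        if self.coef.size != self.var_spec.dim:
            raise ValueError("coef / var basis dimension mismatch")
        if self.vcov.shape != (self.coef.size, self.coef.size):
            raise ValueError("vcov not conformable")
        if not np.allclose(self.vcov, self.vcov.T, atol=1e-8):
            raise ValueError("vcov not symmetric")

    def centered_at(self, center: float) -> "ReducedCurve":
        return replace(self, center=float(center))

    def to_dict(self) -> dict:
        return {
            "coef": self.coef.tolist(),
            "vcov": self.vcov.tolist(),
            "var_spec": self.var_spec.to_dict(),
            "center": self.center,
            "kind": self.kind,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReducedCurve":
        return cls(
            coef=np.asarray(d["coef"], dtype=float),
            vcov=np.asarray(d["vcov"], dtype=float),
            var_spec=SplineSpec.from_dict(d["var_spec"]),
            center=d.get("center"),
            kind=d.get("kind", "overall_cumulative"),
        )


@dataclass
class LagCurve:
    """Lag-response coefficients at a fixed exposure value."""

    coef: np.ndarray
    vcov: np.ndarray
    lag_spec: SplineSpec
    at_value: float
    max_lag: int

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.vcov = np.asarray(self.vcov, dtype=float)
        if self.coef.size != self.lag_spec.dim:
            raise ValueError("coef / lag basis dimension mismatch")


def _reduction_matrix(fit: CityFit) -> np.ndarray:
    """M: (var_dim x var_dim*lag_dim) summing the lag basis over 0..L."""
    spec = fit.spec
    C = lag_basis_matrix(spec)          # (L+1) x lag_dim
    w = C.sum(axis=0)                   # lag_dim
    M = np.zeros((spec.var_dim, spec.dim))
    for j in range(spec.var_dim):
        M[j, j * spec.lag_dim:(j + 1) * spec.lag_dim] = w
    return M


def reduce_overall_cumulative(fit: CityFit) -> ReducedCurve:
    """Collapse a cross-basis fit to the overall cumulative curve by summing
    lag-specific contributions over integer lags 0..max_lag."""
    if fit.coef.size != fit.spec.dim:
        raise ValueError("fit coefficients do not match basis metadata")
    M = _reduction_matrix(fit)
    return ReducedCurve(
        coef=M @ fit.coef,
        vcov=M @ fit.vcov @ M.T,
        var_spec=fit.spec.var_spec,
    )


def reduce_lag_specific(fit: CityFit, at_value: float, center: float | None = None) -> LagCurve:
    """Lag-response curve at exposure ``at_value`` relative to ``center``."""
    if center is None:
        raise ValueError("curve must be centered")
    spec = fit.spec
    r = eval_basis(np.array([at_value, center]), spec.var_spec)
    contrast = r[0] - r[1]              # var_dim
    N = np.zeros((spec.lag_dim, spec.dim))
    for j in range(spec.var_dim):
        N[:, j * spec.lag_dim:(j + 1) * spec.lag_dim] = contrast[j] * np.eye(spec.lag_dim)
    return LagCurve(
        coef=N @ fit.coef,
        vcov=N @ fit.vcov @ N.T,
        lag_spec=spec.lag_spec,
        at_value=float(at_value),
        max_lag=spec.max_lag,
    )


def log_rr(curve: ReducedCurve, values, center: float | None = None) -> np.ndarray:
    """Cumulative log relative risk at ``values`` relative to ``center``."""
    center = curve.center if center is None else center
    if center is None:
        raise ValueError("curve must be centered")
    values = np.atleast_1d(np.asarray(values, dtype=float))
    R = eval_basis(values, curve.var_spec)
    Rc = eval_basis(np.array([center]), curve.var_spec)
    return (R - Rc) @ curve.coef


def predict_rr(
    curve: ReducedCurve,
    values,
    center: float | None = None,
    level: float = 0.95,
):
    """Relative risk with pointwise normal-approximation CIs.

    ``RR(x) = exp([R(x) - R(center)] . coef)``; the delta-method variance is
    the quadratic form of the same contrast in the coefficient covariance.
    Returns ``(rr, rr_low, rr_high)`` arrays; RR at the center is exactly 1.
    """
    center = curve.center if center is None else center
    if center is None:
        raise ValueError("curve must be centered")
    values = np.atleast_1d(np.asarray(values, dtype=float))
    R = eval_basis(values, curve.var_spec)
    Rc = eval_basis(np.array([center]), curve.var_spec)
    D = R - Rc
    fit = D @ curve.coef
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", D, curve.vcov, D), 0.0))
    z = stats.norm.ppf(0.5 + level / 2)
    return np.exp(fit), np.exp(fit - z * se), np.exp(fit + z * se)
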