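"""Exposure and lag spline bases and their cross-basis tensor product.

A distributed-lag non-linear model represents the exposure-lag-response
surface as a tensor product of two one-dimensional bases: an
exposure-response basis ``R`` evaluated at the exposure value and a
lag-response basis ``C`` evaluated at integer lags ``0..L``.  The design
matrix ("cross-basis") row for day ``t`` has entries

    Z[t, (j, k)] = sum_l R_j(x[t - l]) * C_k(l),   l = 0..L

laid out var-major: all lag columns of the first exposure-basis function,
then the second, and so on.  The first ``L`` rows have insufficient lag
history and are flagged missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SplineSpec",
    "CrossBasisSpec",
    "CrossBasis",
    "percentile_knots",
    "log_spaced_lag_knots",
    "eval_basis",
    "build_crossbasis",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

SplineKind = Literal["bspline_quadratic", "natural_cubic", "linear", "constant"]


@dataclass(frozen=True)
class SplineSpec:
    """One-dimensional basis specification.

    Parameters
    ----------
    kind
        ``bspline_quadratic`` — degree-2 B-spline without its constant
        column (dimension = 2 + number of internal knots);
        ``natural_cubic`` — cubic spline linear beyond the boundary knots
        (dimension = #knots + 1, plus 1 if ``intercept``);
        ``linear`` — the identity column (dimension 1).
    internal_knots
        Strictly increasing knot locations, strictly inside ``boundary``.
    boundary
        Pair ``(lower, upper)`` of boundary knots.
    intercept
        Whether the basis spans the constant function explicitly.
        Only meaningful for ``natural_cubic`` here; must be False for
        ``linear``.
    """

    kind: SplineKind
    internal_knots: tuple[float, ...] = ()
    boundary: tuple[float, float] = (0.0, 1.0)
    intercept: bool = False

    def __post_init__(self) -> None:
        knots = tuple(float(k) for k in self.internal_knots)
        object.__setattr__(self, "internal_knots", knots)
        lo, hi = float(self.boundary[0]), float(self.boundary[1])
        object.__setattr__(self, "boundary", (lo, hi))
        if not lo < hi:
            raise ValueError(f"boundary must satisfy lower < upper, got {self.boundary}")
        if any(k2 <= k1 for k1, k2 in zip(knots, knots[1:])):
            raise ValueError("internal_knots must be strictly increasing")
        if knots and (knots[0] <= lo or knots[-1] >= hi):
            raise ValueError("internal_knots must lie strictly inside boundary")
        if self.kind == "linear" and (knots or self.intercept):
            raise ValueError("linear basis takes no knots and no intercept")
        if self.kind == "constant" and knots:
            raise ValueError("constant basis takes no knots")

    @property
    def dim(self) -> int:
        if self.kind in ("linear", "constant"):
            return 1
        if self.kind == "bspline_quadratic":
            return 2 + len(self.internal_knots)
        if self.kind == "natural_cubic":
            return len(self.internal_knots) + 1 + (1 if self.intercept else 0)
        raise ValueError(f"unknown spline kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "internal_knots": list(self.internal_knots),
            "boundary": list(self.boundary),
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(
            kind=d["kind"],
            internal_knots=tuple(d.get("internal_knots", ())),
            boundary=tuple(d.get("boundary", (0.0, 1.0))),
            intercept=bool(d.get("intercept", False)),
        )


@dataclass(frozen=True)
class CrossBasisSpec:
    """Cross-basis specification: exposure basis, lag basis, maximum lag."""

    var_spec: SplineSpec
    lag_spec: SplineSpec
    max_lag: int

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        for k in self.lag_spec.internal_knots:
            if not 0.0 < k < self.max_lag:
                raise ValueError("lag knots must lie in (0, max_lag)")

    @property
    def var_dim(self) -> int:
        return self.var_spec.dim

    @property
    def lag_dim(self) -> int:
        return self.lag_spec.dim

    @property
    def dim(self) -> int:
        return self.var_dim * self.lag_dim

    def to_dict(self) -> dict:
        return {
            "var_spec": self.var_spec.to_dict(),
            "lag_spec": self.lag_spec.to_dict(),
            "max_lag": self.max_lag,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CrossBasisSpec":
        return cls(
            var_spec=SplineSpec.from_dict(d["var_spec"]),
            lag_spec=SplineSpec.from_dict(d["lag_spec"]),
            max_lag=int(d["max_lag"]),
        )


@dataclass
class CrossBasis:
    """Lag-embedded tensor-product design matrix plus its metadata.

    ``matrix`` has one row per day and ``var_dim * lag_dim`` columns in
    var-major order.  Rows with incomplete lag history (the first
    ``max_lag`` days, and any day whose lag window touches a missing
    exposure) are NaN.
    """

    matrix: np.ndarray
    spec: CrossBasisSpec
    attached_series_id: str | None = None

    @property
    def var_dim(self) -> int:
        return self.spec.var_dim

    @property
    def lag_dim(self) -> int:
        return self.spec.lag_dim

    @property
    def complete_rows(self) -> np.ndarray:
        """Boolean mask of rows with full lag history and no missing input."""
        return ~np.isnan(self.matrix).any(axis=1)


# ---------------------------------------------------------------------------
# Knot placement
# ---------------------------------------------------------------------------

def percentile_knots(values: Sequence[float], percentiles: Sequence[float]) -> list[float]:
    """Empirical-percentile knot locations (linear interpolation between
    order statistics, the "type 7" convention).

    Raises on an all-missing series ("empty exposure series") and on
    coincident knots ("degenerate knots"), which downstream spline
    construction could not survive.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("empty exposure series")
    p = np.asarray(percentiles, dtype=float)
    if np.any(p <= 0) or np.any(p >= 100):
        raise ValueError("percentiles must lie in (0, 100)")
    if np.any(np.diff(p) <= 0):
        raise ValueError("percentiles must be strictly increasing")
    knots = np.percentile(x, p)  # numpy default = linear interpolation
    if np.any(np.diff(knots) <= 0):
        raise ValueError("degenerate knots")
    return [float(k) for k in knots]


def log_spaced_lag_knots(max_lag: int, n_knots: int) -> list[float]:
    """Lag knots equally spaced on the log scale over (1, max_lag):
    ``k_i = exp(i * log(max_lag) / (n_knots + 1))`` for ``i = 1..n_knots``.
    """
    if max_lag < 2:
        raise ValueError("max_lag must be >= 2")
    if n_knots < 1:
        raise ValueError("n_knots must be >= 1")
    if n_knots >= max_lag:
        raise ValueError("n_knots must be smaller than max_lag")
    i = np.arange(1, n_knots + 1)
    return [float(v) for v in np.exp(i * np.log(max_lag) / (n_knots + 1))]


# ---------------------------------------------------------------------------
# Basis evaluation
# ---------------------------------------------------------------------------

def _clamp(x: np.ndarray, spec: SplineSpec, policy: str) -> np.ndarray:
    if policy == "none":  # extrapolate freely (used for shape checks)
        return x
    lo, hi = spec.boundary
    out_of_range = (x < lo) | (x > hi)
    if np.any(out_of_range & ~np.isnan(x)):
        if policy == "strict":
            raise ValueError("values outside basis boundary under strict policy")
        warnings.warn(
            f"{int(np.sum(out_of_range & ~np.isnan(x)))} value(s) outside basis "
            f"boundary [{lo}, {hi}] clamped",
            stacklevel=3,
        )
        x = np.clip(x, lo, hi)
    return x


def _bspline_full(x: np.ndarray, spec: SplineSpec, degree: int) -> np.ndarray:
    lo, hi = spec.boundary
    t = np.concatenate(
        [[lo] * (degree + 1), list(spec.internal_knots), [hi] * (degree + 1)]
    )
    dm = BSpline.design_matrix(x, t, degree, extrapolate=False).toarray()
    return dm


def _natural_cubic(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    # Truncated-power natural cubic basis (linear beyond boundary knots):
    # 1, x, then d_k(x) - d_{K-1}(x) for k = 1..K-2, where
    # d_k(x) = ((x - xi_k)^3_+ - (x - xi_K)^3_+) / (xi_K - xi_k)
    # and xi_1..xi_K are boundary + internal knots in increasing order.
    xi = np.array([spec.boundary[0], *spec.internal_knots, spec.boundary[1]])
    K = xi.size

    def d(k: int) -> np.ndarray:
        num = np.maximum(x - xi[k], 0.0) ** 3 - np.maximum(x - xi[K - 1], 0.0) ** 3
        return num / (xi[K - 1] - xi[k])

    cols = [np.ones_like(x), x]
    dK1 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dK1)
    B = np.column_stack(cols)
    if not spec.intercept:
        B = B[:, 1:]
    return B


def eval_basis(x: Sequence[float], spec: SplineSpec, *, policy: str = "clamp") -> np.ndarray:
    """Evaluate a one-dimensional basis at ``x``.

    Missing (NaN) inputs yield NaN rows.  Values outside the boundary are
    clamped with a warning (``policy='clamp'``, the default) or raise
    (``policy='strict'``).
    """
    x = np.asarray(x, dtype=float)
    if spec.kind == "linear":
        return x.reshape(-1, 1).copy()
    if spec.kind == "constant":
        out = np.ones((x.size, 1))
        out[np.isnan(x), :] = np.nan
        return out
    missing = np.isnan(x)
    xc = _clamp(np.where(missing, spec.boundary[0], x), spec, policy)

    if spec.kind == "bspline_quadratic":
        B = _bspline_full(xc, spec, degree=2)
        if not spec.intercept:
            B = B[:, 1:]
    elif spec.kind == "natural_cubic":
        B = _natural_cubic(xc, spec)
    else:
        raise ValueError(f"unknown spline kind {spec.kind!r}")
    B[missing, :] = np.nan
    if B.shape[1] != spec.dim:
        raise AssertionError(f"basis dimension {B.shape[1]} != spec dim {spec.dim}")
    return B


def lag_basis_matrix(spec: CrossBasisSpec) -> np.ndarray:
    """Lag basis evaluated at integer lags ``0..max_lag``: shape (L+1, lag_dim)."""
    lags = np.arange(spec.max_lag + 1, dtype=float)
    return eval_basis(lags, spec.lag_spec)


def build_crossbasis(
    x: Sequence[float],
    spec: CrossBasisSpec,
    *,
    series_id: str | None = None,
) -> CrossBasis:
    """Build the lag-embedded tensor-product design matrix for series ``x``.

    Column ``(j, k)`` of row ``t`` is ``sum_l R_j(x[t-l]) C_k(l)``; columns
    are var-major.  Any missing lagged exposure makes the whole row missing.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    L = spec.max_lag
    if n <= L:
        raise ValueError("series shorter than max_lag + 1")

    R = eval_basis(x, spec.var_spec)          # n x var_dim (NaN rows where x missing)
    C = lag_basis_matrix(spec)                # (L+1) x lag_dim

    # lag-embedding: E[t, l] = row index t-l, valid only for t >= L
    Z = np.full((n, spec.var_dim * spec.lag_dim), np.nan)
    idx = np.arange(L, n)
    # lagged var-basis values: shape (n-L, L+1, var_dim)
    lag_idx = idx[:, None] - np.arange(L + 1)[None, :]
    R_lagged = R[lag_idx, :]                  # (n-L, L+1, var_dim)
    # Z_block[t, j, k] = sum_l R_lagged[t, l, j] * C[l, k]
    blocks = np.einsum("tlj,lk->tjk", R_lagged, C)
    Z[L:, :] = blocks.reshape(n - L, -1)
    return CrossBasis(matrix=Z, spec=spec, attached_series_id=series_id)


# ---------------------------------------------------------------------------
# Default specifications used in the analysis
# ---------------------------------------------------------------------------

def temperature_crossbasis_spec(tmean: Sequence[float]) -> CrossBasisSpec:
    """Default temperature cross-basis: quadratic B-spline of exposure with
    internal knots at the 10th/75th/90th percentiles and boundary at the
    observed range; natural cubic lag spline with intercept and three
    log-spaced knots over a 28-day lag period.
    """
    t = np.asarray(tmean, dtype=float)
    t = t[~np.isnan(t)]
    var = SplineSpec(
        kind="bspline_quadratic",
        internal_knots=tuple(percentile_knots(t, [10, 75, 90])),
        boundary=(float(t.min()), float(t.max())),
    )
    lag = SplineSpec(
        kind="natural_cubic",
        internal_knots=tuple(log_spaced_lag_knots(28, 3)),
        boundary=(0.0, 28.0),
        intercept=True,
    )
    return CrossBasisSpec(var_spec=var, lag_spec=lag, max_lag=28)


def dtr_crossbasis_spec(dtr: Sequence[float]) -> CrossBasisSpec:
    """Default DTR cross-basis: linear exposure-response; natural cubic lag
    spline with intercept and two log-spaced knots over a 14-day lag period.
    """
    d = np.asarray(dtr, dtype=float)
    d = d[~np.isnan(d)]
    var = SplineSpec(kind="linear", boundary=(float(d.min()), float(d.max())))
    lag = SplineSpec(
        kind="natural_cubic",
        internal_knots=tuple(log_spaced_lag_knots(14, 2)),
        boundary=(0.0, 14.0),
        intercept=True,
    )
    return CrossBasisSpec(var_spec=var, lag_spec=lag, max_lag=14)
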