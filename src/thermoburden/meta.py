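"""Multivariate random-effects meta-regression with REML and BLUPs.

Each city contributes a k-vector of reduced cross-basis coefficients
``y_i`` with known within-city covariance ``S_i``.  The model is

    y_i ~ N(B x_i, S_i + Psi)

where ``x_i`` are the meta-predictors (intercept, city average
temperature, temperature range, country indicators), ``B`` the k x p
fixed-effect matrix and ``Psi`` the k x k between-city covariance.

``Psi`` is estimated by restricted maximum likelihood with the fixed
effects profiled out by generalized least squares; positive
semidefiniteness is enforced by optimizing over the Cholesky factor of
``Psi``.  Best linear unbiased predictions shrink each city's estimate
toward its meta-regression prediction in proportion to the relative size
of within- and between-city variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MetaInput",
    "MetaFit",
    "BlupSet",
    "fit_mvmeta",
    "cochran_q",
    "i_squared",
    "compute_blups",
]

_LOG2PI = np.log(2 * np.pi)


@dataclass
class MetaInput:
    """City-level estimates, covariances and meta-predictors.

    ``y`` is (n, k); ``S`` is (n, k, k); ``X`` is the (n, p) design of
    meta-predictors including the intercept column.
    """

    y: np.ndarray
    S: np.ndarray
    X: np.ndarray
    city_ids: list[str] | None = None
    predictor_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim == 2:  # k = 1 given as (n, 1) variances
            self.S = self.S.reshape(self.S.shape[0], 1, 1)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n, k = self.y.shape
        if self.S.shape != (n, k, k):
            raise ValueError(f"S must be (n, k, k) = ({n}, {k}, {k})")
        if self.X.shape[0] != n:
            raise ValueError("X row count must match number of cities")
        for i in range(n):
            if not np.allclose(self.S[i], self.S[i].T, atol=1e-8):
                raise ValueError(f"S[{i}] not symmetric")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def k(self) -> int:
        return self.y.shape[1]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_predictors(
        cls,
        y: np.ndarray,
        S: np.ndarray,
        avg_temp: np.ndarray | None = None,
        temp_range: np.ndarray | None = None,
        country: list[str] | None = None,
        city_ids: list[str] | None = None,
    ) -> "MetaInput":
        """Build the design with intercept + optional average temperature,
        temperature range and reference-coded country indicators."""
        y = np.atleast_2d(np.asarray(y, dtype=float))
        n = y.shape[0]
        cols = [np.ones(n)]
        names = ["intercept"]
        if avg_temp is not None:
            cols.append(np.asarray(avg_temp, dtype=float))
            names.append("avg_temp")
        if temp_range is not None:
            cols.append(np.asarray(temp_range, dtype=float))
            names.append("temp_range")
        if country is not None:
            levels = sorted(set(country))
            for lev in levels[1:]:  # first level is the reference
                cols.append(np.array([1.0 if c == lev else 0.0 for c in country]))
                names.append(f"country_{lev}")
        X = np.column_stack(cols)
        return cls(y=y, S=S, X=X, city_ids=city_ids, predictor_names=names)


@dataclass
class MetaFit:
    """Fitted meta-regression: fixed effects, Psi, heterogeneity, fit info."""

    fixed_effects: np.ndarray       # (k, p)
    fixed_vcov: np.ndarray          # (k*p, k*p), vec ordered predictor-major per outcome
    psi: np.ndarray                 # (k, k)
    Q: float
    df_Q: int
    I2: float
    loglik: float
    method: str
    converged: bool
    predictor_names: list[str] | None = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Fixed-effect prediction for one predictor row (length p)."""
        return self.fixed_effects @ np.asarray(x, dtype=float)

    def predict_vcov(self, x: np.ndarray) -> np.ndarray:
        """Covariance of the fixed-effect prediction at predictor row x."""
        x = np.asarray(x, dtype=float)
        k = self.fixed_effects.shape[0]
        U = np.kron(x[None, :], np.eye(k))  # (k, k*p)
        return U @ self.fixed_vcov @ U.T


@dataclass
class BlupSet:
    """Per-city BLUP coefficient vectors and covariances."""

    blup: np.ndarray                # (n, k)
    blup_vcov: np.ndarray           # (n, k, k)
    city_ids: list[str] | None = None


# ---------------------------------------------------------------------------
# Internal linear algebra
# ---------------------------------------------------------------------------

def _gls(y, S, X, psi):
    """Profiled GLS of the fixed effects for a given Psi.

    Returns (theta_hat, A_inv, residuals, Sigma_invs) with theta = vec of
    the k x p fixed-effect matrix (predictor-major per outcome).
    """
    n, k = y.shape
    p = X.shape[1]
    A = np.zeros((k * p, k * p))
    b = np.zeros(k * p)
    Sigma_invs = np.empty((n, k, k))
    for i in range(n):
        Sig = S[i] + psi
        Sig_inv = np.linalg.inv(Sig)
        Sigma_invs[i] = Sig_inv
        U = np.kron(X[i][None, :], np.eye(k))   # (k, k*p)
        A += U.T @ Sig_inv @ U
        b += U.T @ Sig_inv @ y[i]
    A_inv = np.linalg.inv(A)
    theta = A_inv @ b
    resid = np.empty_like(y)
    for i in range(n):
        U = np.kron(X[i][None, :], np.eye(k))
        resid[i] = y[i] - U @ theta
    return theta, A_inv, resid, Sigma_invs


def _neg_restricted_loglik(chol_params, y, S, X, reml):
    n, k = y.shape
    L = np.zeros((k, k))
    L[np.tril_indices(k)] = chol_params
    psi = L @ L.T
    try:
        theta, A_inv, resid, Sig_invs = _gls(y, S, X, psi)
    except np.linalg.LinAlgError:
        return 1e10
    ll = 0.0
    for i in range(n):
        sign, logdet = np.linalg.slogdet(S[i] + psi)
        if sign <= 0:
            return 1e10
        ll -= 0.5 * (logdet + resid[i] @ Sig_invs[i] @ resid[i] + k * _LOG2PI)
    if reml:
        sign, logdet_A = np.linalg.slogdet(np.linalg.inv(A_inv))
        ll -= 0.5 * logdet_A
        ll += 0.5 * A_inv.shape[0] * _LOG2PI  # REML constant, conventional
    return -ll


def _standardize(X):
    """Center/scale non-intercept columns; return (Z, transform info)."""
    X = X.copy()
    p = X.shape[1]
    means = np.zeros(p)
    scales = np.ones(p)
    for j in range(p):
        col = X[:, j]
        if np.allclose(col, col[0]):
            continue  # intercept or constant column
        means[j] = col.mean()
        sd = col.std(ddof=0)
        scales[j] = sd if sd > 0 else 1.0
        X[:, j] = (col - means[j]) / scales[j]
    return X, means, scales


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def fit_mvmeta(input: MetaInput, method: str = "reml") -> MetaFit:
    """Fit the multivariate random-effects meta-regression.

    ``method`` is ``'reml'`` (default) or ``'ml'``.  The between-city
    covariance is optimized over its Cholesky factor with quasi-Newton
    iterations; meta-predictors are standardized internally for optimizer
    stability and results are mapped back to the original scale.
    """
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    y, S = input.y, input.S
    n, k, p = input.n, input.k, input.p
    if n <= p:
        raise ValueError("need more cities than meta-predictors")

    Z, means, scales = _standardize(input.X)
    reml = method == "reml"

    # start value: moment-based between-city covariance
    resid0 = y - y.mean(axis=0)
    emp = resid0.T @ resid0 / max(n - 1, 1) - S.mean(axis=0)
    evals, evecs = np.linalg.eigh((emp + emp.T) / 2)
    psi0 = evecs @ np.diag(np.maximum(evals, 1e-6)) @ evecs.T
    L0 = np.linalg.cholesky(psi0 + 1e-8 * np.eye(k))
    x0 = L0[np.tril_indices(k)]

    res = optimize.minimize(
        _neg_restricted_loglik,
        x0,
        args=(y, S, Z, reml),
        method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    if not res.success and res.status not in (2,):  # 2 = precision loss, accept
        # one restart from zero heterogeneity before giving up
        res2 = optimize.minimize(
            _neg_restricted_loglik,
            np.full_like(x0, 1e-4),
            args=(y, S, Z, reml),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        if res2.fun < res.fun:
            res = res2
        if not res.success:
            raise RuntimeError(f"meta-regression did not converge: {res.message}")

    L = np.zeros((k, k))
    L[np.tril_indices(k)] = res.x
    psi = L @ L.T

    theta_z, A_inv_z, _, _ = _gls(y, S, Z, psi)

    # back-transform: theta is vec over (k per predictor), U_i = x_i' (x) I_k,
    # so theta = [b_pred0 (k), b_pred1 (k), ...].  On the original scale:
    # b_j = bz_j / s_j for non-intercept, b_0 = bz_0 - sum_j bz_j m_j / s_j.
    Bz = theta_z.reshape(p, k).T       # (k, p)
    # z_j = (x_j - m_j)/s_j  =>  X beta = Z gamma with beta = G gamma:
    # beta_j = gamma_j / s_j, beta_0 = gamma_0 - sum_j gamma_j m_j / s_j
    G = np.eye(p)
    for j in range(1, p):
        G[j, j] = 1.0 / scales[j]
        G[0, j] = -means[j] / scales[j]
    B = Bz @ G.T
    # vcov of theta on original scale: theta = (G (x) I_k) theta_z ordering
    Gk = np.kron(G, np.eye(k))
    fixed_vcov = Gk @ A_inv_z @ Gk.T

    # heterogeneity from the fixed-effects-only fit (Psi = 0)
    Q, df_Q, _ = cochran_q(input)
    I2 = i_squared(Q, df_Q)

    return MetaFit(
        fixed_effects=B,
        fixed_vcov=fixed_vcov,
        psi=psi,
        Q=Q,
        df_Q=df_Q,
        I2=I2,
        loglik=-res.fun,
        method=method,
        converged=True,
        predictor_names=input.predictor_names,
    )


# backwards-compatible alias matching the estimation method in the name
fit_mvmeta_reml = fit_mvmeta


def cochran_q(input: MetaInput, fit: MetaFit | None = None) -> tuple[float, int, float]:
    """Multivariate Cochran Q: weighted residual sum of squares about the
    fixed-effects-only (Psi = 0) GLS fit.  Returns (Q, df, p-value)."""
    y, S, X = input.y, input.S, input.X
    n, k, p = input.n, input.k, input.p
    for i in range(n):
        if np.linalg.matrix_rank(S[i]) < k:
            raise np.linalg.LinAlgError(f"singular within-city covariance S[{i}]")
    _, _, resid, Sig_invs = _gls(y, S, X, np.zeros((k, k)))
    Q = float(sum(resid[i] @ Sig_invs[i] @ resid[i] for i in range(n)))
    df = k * (n - p)
    pval = float(stats.chi2.sf(Q, df)) if df > 0 else np.nan
    return Q, df, pval


def i_squared(Q: float, df: int) -> float:
    """Higgins I^2 heterogeneity index in percent: max(0, (Q - df)/Q) * 100."""
    if Q < 0:
        raise ValueError("Q must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    if Q == 0:
        return 0.0
    return float(max(0.0, (Q - df) / Q) * 100.0)


def compute_blups(input: MetaInput, fit: MetaFit) -> BlupSet:
    """Best linear unbiased predictions for every city.

    ``blup_i = X_i b + Psi (Psi + S_i)^{-1} (y_i - X_i b)`` — a convex
    shrinkage of the city estimate toward its meta-prediction.  The
    reported covariance combines the conditional prediction variance
    ``Psi - Psi (Psi + S_i)^{-1} Psi`` with the propagated fixed-effect
    uncertainty.
    """
    y, S, X = input.y, input.S, input.X
    n, k, p = input.n, input.k, input.p
    psi = fit.psi
    blup = np.empty((n, k))
    bv = np.empty((n, k, k))
    for i in range(n):
        mean_i = fit.fixed_effects @ X[i]
        M = psi + S[i]
        if np.linalg.matrix_rank(M) < k:
            raise np.linalg.LinAlgError(f"singular Psi + S[{i}]")
        W = psi @ np.linalg.inv(M)          # shrinkage weight toward the data
        blup[i] = mean_i + W @ (y[i] - mean_i)
        pred_v = fit.predict_vcov(X[i])
        IW = np.eye(k) - W
        bv[i] = psi - W @ psi + IW @ pred_v @ IW.T
        bv[i] = (bv[i] + bv[i].T) / 2
    return BlupSet(blup=blup, blup_vcov=bv, city_ids=input.city_ids)
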