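"""SIMPLS partial least squares regression for a single response.

De Jong's SIMPLS builds latent variables directly from the deflated
cross-product vector s = Xc' yc (Xc, yc column-centred; no unit-variance
scaling, the chemometric convention for absorbance spectra).  Each step
takes the dominant direction of s (for one response, s itself), forms a
unit-norm score t = Xc r / ||Xc r||, extracts x- and y-loadings, and
deflates s against the orthonormal basis of x-loadings so that successive
scores are exactly orthogonal.  For a single response SIMPLS and NIPALS
PLS1 span identical prediction spaces.

The model stores the whole coefficient path, so predictions at any number
of latent variables (LVs) up to ``n_lv_max`` come from one fit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PLSModel", "fit_simpls", "predict", "select_latent_variables", "export_coefficients"]

_RANK_TOL = 1e-12


@dataclass
class PLSModel:
    """Fitted SIMPLS calibration state.

    Attributes
    ----------
    x_mean, y_mean : centring vector / scalar.
    weights : (p, A) matrix R mapping centred X to scores, T = Xc R.
    scores : (n, A) orthonormal score matrix T.
    x_loadings : (p, A) matrix P = Xc' T.
    y_loadings : (A,) vector q = yc' T.
    coefficient_path : (A, p) array; row k-1 holds the regression
        coefficients using the first k latent variables.
    n_lv_max : number of latent variables actually extracted.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    coefficient_path: np.ndarray
    n_lv_max: int
    metadata: dict = field(default_factory=dict)

    def coefficients(self, n_lv: int) -> np.ndarray:
        if not 1 <= n_lv <= self.n_lv_max:
            raise ValueError(f"n_lv must be in [1, {self.n_lv_max}], got {n_lv}")
        return self.coefficient_path[n_lv - 1]

    def to_json(self) -> str:
        payload = {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "coefficient_path": self.coefficient_path.tolist(),
            "n_lv_max": self.n_lv_max,
            "metadata": self.metadata,
        }
        return json.dumps(payload)


def fit_simpls(X: np.ndarray, y: np.ndarray, n_lv_max: int) -> PLSModel:
    """Fit a SIMPLS model with up to ``n_lv_max`` latent variables.

    Predictors are centred only; zero-variance columns are retained and
    receive zero weight.  If the centred predictor matrix has rank below
    ``n_lv_max`` the path is truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-d")
    n, p = X.shape
    if n != y.size:
        raise ValueError(f"X has {n} rows but y has {y.size} entries")
    if n < 2:
        raise ValueError("need at least two samples")
    if n_lv_max < 1:
        raise ValueError("n_lv_max must be >= 1")
    requested = int(n_lv_max)
    n_lv_max = min(requested, n - 1, p)

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    if not np.any(yc):
        raise ValueError("response has zero variance")

    s = Xc.T @ yc
    scale = np.linalg.norm(s)
    R = np.empty((p, n_lv_max))
    T = np.empty((n, n_lv_max))
    P = np.empty((p, n_lv_max))
    q = np.empty(n_lv_max)
    V = np.empty((p, n_lv_max))  # orthonormal loading basis used for deflation

    a = 0
    while a < n_lv_max:
        r = s.copy()
        t = Xc @ r
        t -= t.mean()  # guard against centring drift
        norm_t = np.linalg.norm(t)
        if norm_t <= _RANK_TOL * max(scale, 1.0):
            break  # rank of Xc along y exhausted
        t /= norm_t
        r /= norm_t
        p_a = Xc.T @ t
        q_a = float(yc @ t)
        # Orthonormalise the loading against the existing basis, twice, to
        # resist drift on collinear spectral channels.
        v = p_a.copy()
        for _ in range(2):
            if a:
                v -= V[:, :a] @ (V[:, :a].T @ v)
        norm_v = np.linalg.norm(v)
        if norm_v <= _RANK_TOL * max(np.linalg.norm(p_a), 1.0):
            break
        v /= norm_v
        R[:, a], T[:, a], P[:, a], q[a], V[:, a] = r, t, p_a, q_a, v
        a += 1
        s = s - V[:, :a] @ (V[:, :a].T @ s)

    if a == 0:
        raise ValueError("no latent variable could be extracted (X'y is zero)")
    if a < min(requested, n - 1, p):
        warnings.warn(
            f"requested {requested} latent variables but rank supports only {a}; truncating",
            RuntimeWarning,
        )
    R, T, P, q = R[:, :a], T[:, :a], P[:, :a], q[:a]
    path = np.cumsum(R * q, axis=1).T  # row k-1: R[:, :k] @ q[:k]
    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=R,
        scores=T,
        x_loadings=P,
        y_loadings=q,
        coefficient_path=path,
        n_lv_max=a,
    )


def predict(model: PLSModel, X_new: np.ndarray, n_lv: int) -> np.ndarray:
    """Predict the response at ``n_lv`` latent variables."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"expected {model.x_mean.size} predictors, got {X_new.shape[1]}"
        )
    beta = model.coefficients(n_lv)
    return (X_new - model.x_mean) @ beta + model.y_mean


def select_latent_variables(rmsecv_by_lv: np.ndarray) -> int:
    """Number of latent variables minimising RMSECV (1-based; ties -> fewer LVs)."""
    curve = np.asarray(rmsecv_by_lv, dtype=float)
    if curve.ndim != 1 or curve.size == 0:
        raise ValueError("rmsecv_by_lv must be a nonempty vector")
    if np.any(curve < 0) or np.any(~np.isfinite(curve)):
        raise ValueError("rmsecv values must be finite and nonnegative")
    return int(np.argmin(curve)) + 1  # argmin returns the first minimum


def export_coefficients(model: PLSModel, n_lv: int, grid) -> pd.DataFrame:
    """Per-channel regression coefficients at ``n_lv`` LVs against wavenumber."""
    wn = np.asarray(getattr(grid, "values", grid), dtype=float)
    beta = model.coefficients(n_lv)
    if wn.size != beta.size:
        raise ValueError("grid length does not match the number of predictors")
    return pd.DataFrame({"wavenumber_cm1": wn, "coefficient": beta})
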