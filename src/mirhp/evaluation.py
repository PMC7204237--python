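"""Validation machinery and chemometric figures of merit.

Two validation schemes are provided:

* ``random_cross_validate`` — a repeated random k-fold scheme (default 10
  splits x 10 iterations).  Within an iteration every observation is held
  out exactly once; RMSE and R^2 are computed on the pooled out-of-fold
  predictions of that iteration at every candidate LV count, then averaged
  over iterations (RMSECV, R^2CV).
* ``external_cross_validate`` — a single random split into quarters; each
  quarter in turn is held out, the LV count is re-selected by an inner
  random CV on the remaining three quarters (no selection leakage), and the
  per-quarter RMSE/R^2 are averaged (RMSEV, R^2V).

Figures of merit: MSEP = sum (O_i - P_i)^2 / n and its square root;
R^2 = 1 - SSE/SST; Lin's concordance correlation coefficient (precision and
accuracy against the 45-degree line, population moments); and RPD, the
ratio of the reference SD to the prediction error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .pls import fit_simpls, predict, select_latent_variables

__all__ = [
    "CVResult",
    "msep",
    "rmsep",
    "r_squared",
    "lin_ccc",
    "rpd",
    "random_cross_validate",
    "external_cross_validate",
]


def _paired(obs, pred) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(obs, dtype=float).ravel()
    p = np.asarray(pred, dtype=float).ravel()
    if o.size != p.size:
        raise ValueError(f"length mismatch: {o.size} observed vs {p.size} predicted")
    if o.size == 0:
        raise ValueError("empty vectors")
    return o, p


def msep(obs, pred) -> float:
    """Mean squared error of prediction, sum((O-P)^2)/n."""
    o, p = _paired(obs, pred)
    return float(np.mean((o - p) ** 2))


def rmsep(obs, pred) -> float:
    """Root mean squared error of prediction."""
    return float(np.sqrt(msep(obs, pred)))


def r_squared(obs, pred) -> float:
    """Coefficient of determination, 1 - SSE/SST (may be negative)."""
    o, p = _paired(obs, pred)
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined: observed values are constant")
    return 1.0 - float(np.sum((o - p) ** 2)) / sst


def lin_ccc(obs, pred) -> float:
    """Lin's concordance correlation coefficient (population moments).

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2), combining
    precision (correlation) with accuracy (distance from the identity line).
    """
    o, p = _paired(obs, pred)
    if o.size < 2:
        raise ValueError("CCC requires at least two pairs")
    mx, my = o.mean(), p.mean()
    sx2 = float(np.mean((o - mx) ** 2))
    sy2 = float(np.mean((p - my) ** 2))
    sxy = float(np.mean((o - mx) * (p - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        return 1.0  # both series constant and identical: perfect concordance
    if sx2 == 0 and sy2 == 0:
        warnings.warn("both series constant with differing means; CCC set to 0", RuntimeWarning)
        return 0.0
    return 2.0 * sxy / denom


def rpd(reference_sd: float, rmse: float) -> float:
    """Ratio of performance to deviation: reference SD / prediction RMSE."""
    if rmse <= 0:
        raise ValueError(f"rmse must be > 0, got {rmse}")
    if reference_sd < 0:
        raise ValueError(f"reference_sd must be >= 0, got {reference_sd}")
    return float(reference_sd) / float(rmse)


@dataclass
class CVResult:
    """Outcome of a cross-validation run.

    ``rmse_by_lv``/``r2_by_lv`` are averages over iterations (random scheme)
    or quarters (external scheme).  ``oof_predictions`` has shape
    (n_iterations, n_lv, n) for the random scheme — out-of-fold predictions
    of every observation at every LV count — and (n,) at the per-quarter
    chosen LV for the external scheme.
    """

    scheme: str
    fold_assignments: np.ndarray
    oof_predictions: np.ndarray
    rmse_by_lv: np.ndarray
    r2_by_lv: np.ndarray
    lv_range: np.ndarray
    chosen_lv: int
    rmse_cv: float
    r2_cv: float
    chosen_lv_per_fold: list = field(default_factory=list)

    def pooled_oof(self, n_lv: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(iteration, observation) indices pooled into flat (obs_idx, pred) pairs
        at the given LV count (default: the chosen one)."""
        if self.oof_predictions.ndim == 1:
            n = self.oof_predictions.size
            return np.arange(n), self.oof_predictions
        if n_lv is None:
            n_lv = self.chosen_lv
        j = int(np.flatnonzero(self.lv_range == n_lv)[0])
        preds = self.oof_predictions[:, j, :]  # (iters, n)
        n = preds.shape[1]
        idx = np.tile(np.arange(n), preds.shape[0])
        return idx, preds.ravel()

    def to_json(self) -> str:
        return json.dumps(
            {
                "scheme": self.scheme,
                "fold_assignments": self.fold_assignments.tolist(),
                "rmse_by_lv": self.rmse_by_lv.tolist(),
                "r2_by_lv": self.r2_by_lv.tolist(),
                "lv_range": self.lv_range.tolist(),
                "chosen_lv": self.chosen_lv,
                "rmse_cv": self.rmse_cv,
                "r2_cv": self.r2_cv,
                "chosen_lv_per_fold": list(self.chosen_lv_per_fold),
            }
        )


def _resolve_lv_range(lv_range, n: int, p: int, heldout: int) -> np.ndarray:
    cap = min(20, n - heldout - 1, p)
    if lv_range is None:
        lv = np.arange(1, cap + 1)
    else:
        lv = np.asarray(list(lv_range), dtype=int)
        lv = lv[lv <= cap]
    if lv.size == 0:
        raise ValueError("empty latent-variable range after capping by rank")
    return lv


def _fold_partition(rng: np.random.Generator, n: int, n_splits: int) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return np.array_split(perm, n_splits)


def random_cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_splits: int = 10,
    n_iterations: int = 10,
    lv_range=None,
    seed: int = 0,
) -> CVResult:
    """Repeated random k-fold cross-validation of a SIMPLS calibration.

    Deterministic for a fixed seed: iteration i uses the permutation drawn
    from ``numpy.random.default_rng(seed)`` on its i-th call, partitioned
    into ``n_splits`` near-equal folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < n_splits:
        raise ValueError(f"need at least n_splits={n_splits} samples, got {n}")
    max_fold = int(np.ceil(n / n_splits))
    lv = _resolve_lv_range(lv_range, n, p, heldout=max_fold)

    rng = np.random.default_rng(seed)
    assignments = np.empty((n_iterations, n), dtype=int)
    oof = np.empty((n_iterations, lv.size, n))
    rmse_iter = np.empty((n_iterations, lv.size))
    r2_iter = np.empty((n_iterations, lv.size))

    for it in range(n_iterations):
        folds = _fold_partition(rng, n, n_splits)
        for f, idx in enumerate(folds):
            assignments[it, idx] = f
            train = np.setdiff1d(np.arange(n), idx)
            model = fit_simpls(X[train], y[train], n_lv_max=int(lv.max()))
            for j, k in enumerate(lv):
                k_eff = min(int(k), model.n_lv_max)
                oof[it, j, idx] = predict(model, X[idx], k_eff)
        for j in range(lv.size):
            rmse_iter[it, j] = rmsep(y, oof[it, j])
            r2_iter[it, j] = r_squared(y, oof[it, j])

    rmse_by_lv = rmse_iter.mean(axis=0)
    r2_by_lv = r2_iter.mean(axis=0)
    chosen = select_latent_variables(rmse_by_lv)
    chosen_lv = int(lv[chosen - 1])
    return CVResult(
        scheme="random_10x10" if (n_splits, n_iterations) == (10, 10) else "random_kfold",
        fold_assignments=assignments,
        oof_predictions=oof,
        rmse_by_lv=rmse_by_lv,
        r2_by_lv=r2_by_lv,
        lv_range=lv,
        chosen_lv=chosen_lv,
        rmse_cv=float(rmse_by_lv[chosen - 1]),
        r2_cv=float(r2_by_lv[chosen - 1]),
    )


def external_cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_quarters: int = 4,
    lv_range=None,
    seed: int = 0,
    inner_splits: int = 10,
    inner_iterations: int = 10,
) -> CVResult:
    """External validation on a single random partition into quarters.

    For each held-out quarter the LV count is selected by an inner random
    cross-validation on the calibration three-quarters, the model refitted,
    and the quarter predicted.  RMSEV and R^2V are the means of the four
    per-quarter values.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < n_quarters:
        raise ValueError(f"need at least {n_quarters} samples, got {n}")
    rng = np.random.default_rng(seed)
    quarters = _fold_partition(rng, n, n_quarters)
    max_fold = int(np.ceil(n / n_quarters))
    lv = _resolve_lv_range(lv_range, n, p, heldout=max_fold)

    assignments = np.empty(n, dtype=int)
    oof = np.empty(n)
    rmse_q = np.empty(n_quarters)
    r2_q = np.empty(n_quarters)
    chosen_per_quarter: list[int] = []
    for f, idx in enumerate(quarters):
        assignments[idx] = f
        train = np.setdiff1d(np.arange(n), idx)
        inner = random_cross_validate(
            X[train],
            y[train],
            n_splits=inner_splits,
            n_iterations=inner_iterations,
            lv_range=lv,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        k = inner.chosen_lv
        chosen_per_quarter.append(k)
        model = fit_simpls(X[train], y[train], n_lv_max=int(lv.max()))
        oof[idx] = predict(model, X[idx], min(k, model.n_lv_max))
        rmse_q[f] = rmsep(y[idx], oof[idx])
        r2_q[f] = r_squared(y[idx], oof[idx])

    return CVResult(
        scheme="external_4fold" if n_quarters == 4 else "external_kfold",
        fold_assignments=assignments,
        oof_predictions=oof,
        rmse_by_lv=rmse_q,  # per-quarter values for audit
        r2_by_lv=r2_q,
        lv_range=lv,
        chosen_lv=int(np.median(chosen_per_quarter)),
        rmse_cv=float(rmse_q.mean()),
        r2_cv=float(r2_q.mean()),
        chosen_lv_per_fold=chosen_per_quarter,
    )
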