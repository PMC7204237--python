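"""End-to-end orchestration of the four heat-production models.

L1 regresses HP/mBW on daily milk yield alone (ordinary least squares);
M1/M2/M3 are SIMPLS calibrations on the fused AM/PM spectra (plain average,
average x daily yield, yield-weighted average).  Each PLS run follows the
same path: absorbance transform, region selection, optional outlier screen,
fusion, 10x10 random cross-validation over the LV range, LV selection at
the RMSECV minimum, calibration statistics at the chosen LV, external
4-fold validation with inner LV re-selection, CCC on the pooled
cross-validated predictions and RPD against the reference SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import spectra as sp
from .calorimetry import brouwer_heat_production, metabolic_body_weight
from .evaluation import (
    CVResult,
    external_cross_validate,
    lin_ccc,
    r_squared,
    random_cross_validate,
    rmsep,
    rpd,
)
from .pls import PLSModel, fit_simpls, predict

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "model",
    "n_obs",
    "lv",
    "r2_cal",
    "rmsep_cal",
    "r2_cv",
    "rmsecv",
    "r2_v",
    "rmsev",
    "ccc",
    "rpd",
]


@dataclass
class LinearModelFit:
    """Univariate OLS of HP/mBW on daily milk yield (the L1 model)."""

    intercept: float
    slope: float  # kJ kg^-0.75 per L
    residual_sd: float
    r2: float

    def predict(self, milk_yield: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(milk_yield, dtype=float)


@dataclass
class ModelReportRow:
    """One Table-style report row: calibration, cross- and external validation."""

    model: str
    n_obs: int
    lv: Optional[int]
    r2_cal: float
    rmsep_cal: float
    r2_cv: Optional[float] = None
    rmsecv: Optional[float] = None
    r2_v: Optional[float] = None
    rmsev: Optional[float] = None
    ccc: Optional[float] = None
    rpd: Optional[float] = None
    cv_result: Optional[CVResult] = field(default=None, repr=False, compare=False)
    external_result: Optional[CVResult] = field(default=None, repr=False, compare=False)
    pls_model: Optional[PLSModel] = field(default=None, repr=False, compare=False)


def fit_l1(milk_yield: np.ndarray, hp_per_mbw: np.ndarray) -> LinearModelFit:
    """Ordinary least squares of HP/mBW on daily milk yield."""
    x = np.asarray(milk_yield, dtype=float).ravel()
    y = np.asarray(hp_per_mbw, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("milk_yield and hp_per_mbw length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("milk yield is constant; slope is unidentifiable")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    resid = res.resid
    return LinearModelFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        residual_sd=float(np.std(resid, ddof=2)),
        r2=float(res.rsquared),
    )


def _design_matrix(dataset, mode, config):
    """Fused predictor matrix, response vector and retained grid for a mode."""
    rows, y, kept = [], [], []
    grid_r = None
    for obs in dataset:
        if obs.am is None or obs.pm is None:
            logger.warning("cow-day %s %s missing a session; skipped", obs.cow_id, obs.date)
            continue
        cds = sp.build_cow_day_spectrum(
            obs.am, obs.pm, mode, regions=config.regions, m3_divisor=config.m3_divisor
        )
        grid_r = cds.grid
        x_row = cds.spectrum
        if config.append_yield_column:
            x_row = np.append(x_row, cds.daily_yield)
        rows.append(x_row)
        y.append(brouwer_heat_production(obs.gas) / metabolic_body_weight(obs.bw))
        kept.append(obs)
    if len(rows) < 10:
        raise ValueError(f"only {len(rows)} usable cow-days; need at least 10")
    return np.vstack(rows), np.asarray(y), grid_r, kept


def run_model(dataset, mode: str, config, seed: Optional[int] = None) -> ModelReportRow:
    """Run one PLS model (M1/M2/M3) end-to-end and return its report row.

    ``config`` is a :class:`mirhp.io.RunConfig`; ``seed`` overrides
    ``config.seed`` when given.
    """
    if mode not in ("M1", "M2", "M3"):
        raise ValueError(f"mode must be one of M1/M2/M3, got {mode!r}")
    seed = config.seed if seed is None else seed
    X, y, grid_r, kept = _design_matrix(dataset, mode, config)

    if config.outlier_screen:
        n_lv_out = min(config.outlier_n_lv, X.shape[0] // 3, X.shape[1])
        flags, _ = sp.detect_spectral_outliers(
            X, y, n_lv=n_lv_out, alpha=config.outlier_alpha
        )
        if flags.any():
            logger.info("%s: %d spectral outliers flagged", mode, int(flags.sum()))
        if config.drop_outliers and flags.any():
            X, y = X[~flags], y[~flags]

    lv_range = range(config.lv_range[0], config.lv_range[1] + 1)
    cv = random_cross_validate(
        X,
        y,
        n_splits=config.cv_splits,
        n_iterations=config.cv_iterations,
        lv_range=lv_range,
        seed=seed,
    )
    lv = cv.chosen_lv
    model = fit_simpls(X, y, n_lv_max=int(cv.lv_range.max()))
    fitted = predict(model, X, min(lv, model.n_lv_max))
    ext = external_cross_validate(
        X,
        y,
        n_quarters=config.cv_quarters,
        lv_range=lv_range,
        seed=seed + 104729,  # distinct stream for the external partition
        inner_splits=config.cv_splits,
        inner_iterations=config.cv_iterations,
    )
    obs_idx, oof = cv.pooled_oof(lv)
    if config.ccc_on == "cross_validation":
        ccc = lin_ccc(y[obs_idx], oof)
    else:
        ccc = lin_ccc(y, fitted)
    reference_sd = float(np.std(y, ddof=1))
    rpd_rmse = cv.rmse_cv if config.rpd_denominator == "rmsecv" else _sep(y[obs_idx], oof)
    return ModelReportRow(
        model=mode,
        n_obs=int(y.size),
        lv=lv,
        r2_cal=r_squared(y, fitted),
        rmsep_cal=rmsep(y, fitted),
        r2_cv=cv.r2_cv,
        rmsecv=cv.rmse_cv,
        r2_v=ext.r2_cv,
        rmsev=ext.rmse_cv,
        ccc=ccc,
        rpd=rpd(reference_sd, rpd_rmse),
        cv_result=cv,
        external_result=ext,
        pls_model=model,
    )


def _sep(obs, pred) -> float:
    """Bias-corrected standard error of prediction."""
    o = np.asarray(obs, float)
    p = np.asarray(pred, float)
    bias = (p - o).mean()
    return float(np.sqrt(np.mean((p - o - bias) ** 2)))


def run_l1(dataset) -> ModelReportRow:
    """Run the yield-only L1 model and return its report row."""
    yields = np.array([obs.daily_yield for obs in dataset])
    y = np.array(
        [
            brouwer_heat_production(obs.gas) / metabolic_body_weight(obs.bw)
            for obs in dataset
        ]
    )
    fit = fit_l1(yields, y)
    fitted = fit.predict(yields)
    return ModelReportRow(
        model="L1",
        n_obs=int(y.size),
        lv=None,
        r2_cal=fit.r2,
        rmsep_cal=rmsep(y, fitted),
        ccc=lin_ccc(y, fitted),
    )


def run_all(dataset, config, seed: Optional[int] = None) -> list[ModelReportRow]:
    """Run L1, M1, M2 and M3 on one dataset."""
    rows = [run_l1(dataset)]
    for mode in ("M1", "M2", "M3"):
        rows.append(run_model(dataset, mode, config, seed=seed))
    return rows


def build_report(rows) -> tuple[pd.DataFrame, str]:
    """Assemble report rows into a DataFrame and an aligned text table.

    Column order mirrors the calibration / cross-validation / external
    validation layout, with CCC and RPD appended.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("no report rows")
    frame = pd.DataFrame(
        [{c: getattr(r, c) for c in REPORT_COLUMNS} for r in rows]
    )[REPORT_COLUMNS]
    buf = StringIO()
    frame_fmt = frame.copy()
    for col in frame_fmt.columns:
        if col in ("lv", "n_obs"):
            frame_fmt[col] = frame_fmt[col].map(
                lambda v: "" if pd.isna(v) else f"{int(v)}"
            )
        elif frame_fmt[col].dtype.kind == "f":
            frame_fmt[col] = frame_fmt[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.3f}" if abs(v) < 10 else f"{v:.1f}"
            )
    frame_fmt.to_string(buf, index=False)
    return frame, buf.getvalue()
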