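"""Milk mid-infrared spectral preprocessing and spectrum/yield fusion.

A MilkoScan-style FTIR instrument reports one transmittance spectrum per
milking on a fixed wavenumber grid (here 925-5008 cm^-1, 1060 channels).
Preprocessing follows the standard chemometric path:

1. transmittance -> absorbance, A = log10(1/T);
2. retention of the informative regions 968-1577, 1720-1808 and
   2564-2965 cm^-1 (fat, protein and lactose bands), discarding the
   water-saturated and O-H bending channels;
3. optional gap-difference derivative pre-treatment;
4. robust Mahalanobis outlier screening in PLS score space.

The AM and PM spectra of a cow-day are fused into a single predictor
spectrum in one of three ways:

* M1 - plain average (a_am + a_pm)/2: energy *density* only;
* M2 - average multiplied by the daily yield: density x quantity;
* M3 - average of the yield-multiplied session spectra
  (a_am*y_am + a_pm*y_pm)/2: session-weighted density x quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from sklearn.covariance import MinCovDet

#: Informative regions (cm^-1) retained for model development: milk fat,
#: protein and lactose bands, excluding water absorption.
DEFAULT_REGIONS: tuple[tuple[float, float], ...] = (
    (968.0, 1577.0),
    (1720.0, 1808.0),
    (2564.0, 2965.0),
)


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly increasing wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("grid must be a 1-d vector with at least two points")
        if np.any(values <= 0):
            raise ValueError("wavenumbers must be positive")
        if np.any(np.diff(values) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")

    def __len__(self) -> int:
        return int(self.values.size)

    @classmethod
    def uniform(cls, lo: float, hi: float, n_points: int) -> "WavenumberGrid":
        return cls(np.linspace(lo, hi, n_points))


@dataclass
class MilkingRecord:
    """One milking session: yield plus a spectrum aligned to a grid."""

    cow_id: str
    date: str  # ISO-8601
    session: Literal["AM", "PM"]
    milk_yield: float  # L
    spectrum: np.ndarray
    grid: WavenumberGrid
    scale: Literal["transmittance", "absorbance"] = "transmittance"

    def __post_init__(self) -> None:
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        if self.session not in ("AM", "PM"):
            raise ValueError(f"session must be 'AM' or 'PM', got {self.session!r}")
        if self.milk_yield < 0:
            raise ValueError(f"milk_yield must be >= 0, got {self.milk_yield}")
        if self.spectrum.shape != (len(self.grid),):
            raise ValueError("spectrum length must equal grid length")
        if self.scale == "transmittance":
            bad = np.flatnonzero((self.spectrum <= 0) | (self.spectrum > 1))
            if bad.size:
                raise ValueError(
                    f"transmittance out of (0, 1] at channel {bad[0]}"
                )

    def absorbance(self) -> np.ndarray:
        if self.scale == "absorbance":
            return self.spectrum
        return to_absorbance(self.spectrum)


@dataclass
class CowDaySpectrum:
    """Fused per-cow-day predictor spectrum on the retained grid."""

    cow_id: str
    date: str
    mode: Literal["M1", "M2", "M3"]
    spectrum: np.ndarray
    grid: WavenumberGrid
    daily_yield: float


def to_absorbance(transmittance: np.ndarray) -> np.ndarray:
    """Element-wise absorbance A = log10(1/T) of a transmittance vector.

    T must lie in (0, 1]; the offending channel index is reported otherwise.
    """
    t = np.asarray(transmittance, dtype=float)
    bad = np.flatnonzero((t <= 0) | (t > 1) | ~np.isfinite(t))
    if bad.size:
        raise ValueError(
            f"transmittance must be in (0, 1]; channel {bad[0]} has value {t[bad[0]]!r}"
        )
    return -np.log10(t)


def from_absorbance(absorbance: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_absorbance`: T = 10^(-A)."""
    return np.power(10.0, -np.asarray(absorbance, dtype=float))


def region_mask(grid: WavenumberGrid, regions: Sequence[tuple[float, float]]) -> np.ndarray:
    """Boolean mask of channels inside any closed [lo, hi] interval."""
    regions = sorted((float(lo), float(hi)) for lo, hi in regions)
    for lo, hi in regions:
        if lo > hi:
            raise ValueError(f"region ({lo}, {hi}) has lower > upper")
    for (_, hi_prev), (lo_next, _) in zip(regions, regions[1:]):
        if lo_next <= hi_prev:
            raise ValueError("regions must be non-overlapping")
    wn = grid.values
    mask = np.zeros(wn.size, dtype=bool)
    for lo, hi in regions:
        mask |= (wn >= lo) & (wn <= hi)
    return mask


def select_regions(
    grid: WavenumberGrid,
    spectrum: np.ndarray,
    regions: Sequence[tuple[float, float]] = DEFAULT_REGIONS,
) -> tuple[WavenumberGrid, np.ndarray]:
    """Keep exactly the channels whose wavenumber lies in a retained region.

    Regions are closed intervals; channel order is preserved and the
    operation is idempotent.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape[-1] != len(grid):
        raise ValueError("spectrum length must equal grid length")
    mask = region_mask(grid, regions)
    if not mask.any():
        raise ValueError("no channels retained by the requested regions")
    return WavenumberGrid(grid.values[mask]), spectrum[..., mask]


def apply_derivative(spectrum: np.ndarray, order: int = 1, gap: int = 1) -> np.ndarray:
    """Gap-difference derivative pre-treatment of given order (1 or 2).

    A linear operator; the output is shorter than the input by order*gap
    channels.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    if gap < 1:
        raise ValueError(f"gap must be >= 1, got {gap}")
    s = np.asarray(spectrum, dtype=float)
    if s.shape[-1] <= order * gap:
        raise ValueError(
            f"spectrum of length {s.shape[-1]} too short for order {order}, gap {gap}"
        )
    for _ in range(order):
        s = s[..., gap:] - s[..., :-gap]
    return s


def detect_spectral_outliers(
    spectra: np.ndarray,
    response: np.ndarray,
    n_lv: int = 10,
    alpha: float = 0.025,
    random_state: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Robust Mahalanobis outlier screen in SIMPLS score space.

    Fits a SIMPLS model with ``n_lv`` components, estimates a robust
    centre/scatter of the score matrix by the minimum covariance determinant
    (coverage fraction 0.75), and flags rows whose squared Mahalanobis
    distance exceeds the chi-squared(n_lv) quantile at 1 - alpha.

    Returns
    -------
    flags : boolean array, True for flagged rows.
    distances : squared robust Mahalanobis distances.
    """
    from .pls import fit_simpls  # local import avoids a module cycle

    X = np.asarray(spectra, dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    if X.shape[0] < 3 * n_lv:
        raise ValueError(
            f"need at least {3 * n_lv} rows for n_lv={n_lv}, got {X.shape[0]}"
        )
    model = fit_simpls(X, y, n_lv_max=n_lv)
    scores = model.scores
    k = scores.shape[1]
    mcd = MinCovDet(support_fraction=0.75, random_state=random_state).fit(scores)
    cov = mcd.covariance_
    # Guard against a singular robust scatter on (near-)collinear scores.
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        ridge = 1e-10 * np.trace(cov) / k
        warnings.warn("robust score covariance singular; adding ridge", RuntimeWarning)
        cov = cov + ridge * np.eye(k)
        np.linalg.cholesky(cov)  # still singular -> raise
    diff = scores - mcd.location_
    d2 = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
    threshold = stats.chi2.ppf(1.0 - alpha, df=k)
    return d2 > threshold, d2


def _check_pair(a_am: np.ndarray, a_pm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a_am = np.asarray(a_am, dtype=float)
    a_pm = np.asarray(a_pm, dtype=float)
    if a_am.shape != a_pm.shape:
        raise ValueError("AM and PM spectra must share one grid (length mismatch)")
    return a_am, a_pm


def combine_m1(a_am: np.ndarray, a_pm: np.ndarray) -> np.ndarray:
    """M1: plain average of the AM and PM absorbance spectra."""
    a_am, a_pm = _check_pair(a_am, a_pm)
    return 0.5 * (a_am + a_pm)


def combine_m2(a_am: np.ndarray, a_pm: np.ndarray, y_am: float, y_pm: float) -> np.ndarray:
    """M2: averaged spectrum multiplied by the daily milk yield."""
    if y_am < 0 or y_pm < 0:
        raise ValueError("session yields must be >= 0")
    return combine_m1(a_am, a_pm) * (y_am + y_pm)


def combine_m3(
    a_am: np.ndarray,
    a_pm: np.ndarray,
    y_am: float,
    y_pm: float,
    divisor: Literal["two", "total_yield"] = "two",
) -> np.ndarray:
    """M3: average of the yield-multiplied session spectra.

    With the default ``divisor='two'`` the session spectra are multiplied by
    their own yields and plainly averaged, retaining yield magnitude (the
    spectrum then encodes quantity as well as density).  ``'total_yield'``
    instead normalises by y_am + y_pm, a true weighted mean.
    """
    a_am, a_pm = _check_pair(a_am, a_pm)
    if y_am < 0 or y_pm < 0:
        raise ValueError("session yields must be >= 0")
    weighted = a_am * y_am + a_pm * y_pm
    if divisor == "two":
        return weighted / 2.0
    if divisor == "total_yield":
        total = y_am + y_pm
        if total <= 0:
            raise ValueError("total yield must be > 0 for divisor='total_yield'")
        return weighted / total
    raise ValueError(f"unknown divisor {divisor!r}")


def build_cow_day_spectrum(
    am: MilkingRecord,
    pm: MilkingRecord,
    mode: Literal["M1", "M2", "M3"],
    regions: Sequence[tuple[float, float]] = DEFAULT_REGIONS,
    m3_divisor: Literal["two", "total_yield"] = "two",
) -> CowDaySpectrum:
    """Fuse one AM/PM milking pair into a retained-region predictor spectrum."""
    if (am.cow_id, am.date) != (pm.cow_id, pm.date):
        raise ValueError("AM and PM records must belong to the same cow-day")
    grid_r, a_am = select_regions(am.grid, am.absorbance(), regions)
    _, a_pm = select_regions(pm.grid, pm.absorbance(), regions)
    if mode == "M1":
        combined = combine_m1(a_am, a_pm)
    elif mode == "M2":
        combined = combine_m2(a_am, a_pm, am.milk_yield, pm.milk_yield)
    elif mode == "M3":
        combined = combine_m3(a_am, a_pm, am.milk_yield, pm.milk_yield, divisor=m3_divisor)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CowDaySpectrum(
        cow_id=am.cow_id,
        date=am.date,
        mode=mode,
        spectrum=combined,
        grid=grid_r,
        daily_yield=am.milk_yield + pm.milk_yield,
    )
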