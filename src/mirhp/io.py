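"""Readers, writers and run configuration.

Two CSV tables feed the pipeline:

* spectra (wide, one row per milking): ``cow_id, date, session,
  milk_yield_l, scale`` followed by one column per channel named
  ``wn_<wavenumber>`` (4 significant digits), in strictly increasing
  wavenumber order;
* calorimetry (one row per cow-day): ``cow_id, date, bw_kg, v_o2_l,
  v_co2_l, v_ch4_l`` and optionally ``nu_g`` — when absent, urinary N is
  assumed at 150 g/d and the record flagged as such.

All outputs written by the package round-trip through these readers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .calorimetry import NU_DEFAULT_G, GasExchange
from .records import CowDayObservation
from .spectra import DEFAULT_REGIONS, MilkingRecord, WavenumberGrid

SPECTRA_META_COLUMNS = ["cow_id", "date", "session", "milk_yield_l", "scale"]


@dataclass
class RunConfig:
    """Configuration of a model-fitting run.

    Defaults follow the study conventions: the three retained spectral
    regions, LV search over 1..20, 10x10 random CV, external validation in
    quarters, outlier screening in report-only mode, M3 divided by two, R^2
    as 1 - SSE/SST, RPD against RMSECV, assumed Nu of 150 g/d.
    """

    regions: tuple = DEFAULT_REGIONS
    lv_range: tuple[int, int] = (1, 20)
    cv_splits: int = 10
    cv_iterations: int = 10
    cv_quarters: int = 4
    seed: int = 0
    outlier_screen: bool = True
    outlier_n_lv: int = 10
    outlier_alpha: float = 0.025
    drop_outliers: bool = False
    m3_divisor: str = "two"  # or "total_yield"
    append_yield_column: bool = False
    r2_definition: str = "one_minus_sse_sst"
    rpd_denominator: str = "rmsecv"  # or "sep"
    ccc_on: str = "cross_validation"  # or "calibration"
    nu_default: float = NU_DEFAULT_G

    def __post_init__(self) -> None:
        lo, hi = self.lv_range
        if not 1 <= lo <= hi:
            raise ValueError(f"lv_range invalid: {self.lv_range}")
        if self.m3_divisor not in ("two", "total_yield"):
            raise ValueError(f"m3_divisor must be 'two' or 'total_yield', got {self.m3_divisor!r}")
        if self.rpd_denominator not in ("rmsecv", "sep"):
            raise ValueError(f"rpd_denominator invalid: {self.rpd_denominator!r}")
        if self.ccc_on not in ("cross_validation", "calibration"):
            raise ValueError(f"ccc_on invalid: {self.ccc_on!r}")
        self.regions = tuple((float(lo_), float(hi_)) for lo_, hi_ in self.regions)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "regions" in data:
            data["regions"] = tuple(tuple(r) for r in data["regions"])
        if "lv_range" in data:
            data["lv_range"] = tuple(data["lv_range"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["regions"] = [list(r) for r in self.regions]
        d["lv_range"] = list(self.lv_range)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _channel_name(wn: float) -> str:
    return f"wn_{float(f'{wn:.4g}'):g}"


def write_spectra_csv(records: Sequence[MilkingRecord], path) -> None:
    """Write milking records as a wide spectra CSV."""
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    grid = records[0].grid
    columns = SPECTRA_META_COLUMNS + [_channel_name(w) for w in grid.values]
    rows = []
    for rec in records:
        if len(rec.grid) != len(grid) or not np.allclose(rec.grid.values, grid.values):
            raise ValueError("all records must share one wavenumber grid")
        rows.append(
            [rec.cow_id, rec.date, rec.session, rec.milk_yield, rec.scale]
            + list(rec.spectrum)
        )
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_spectra_csv(path) -> list[MilkingRecord]:
    """Read a wide spectra CSV into milking records, validating the schema."""
    frame = pd.read_csv(path)
    missing = [c for c in SPECTRA_META_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"spectra CSV missing columns: {missing}")
    channel_cols = [c for c in frame.columns if c.startswith("wn_")]
    if not channel_cols:
        raise ValueError("spectra CSV has no wn_<wavenumber> channel columns")
    try:
        wns = np.array([float(c[3:]) for c in channel_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric channel column name: {exc}") from exc
    if np.any(np.diff(wns) <= 0):
        raise ValueError("channel columns must be in strictly increasing wavenumber order")
    grid = WavenumberGrid(wns)
    seen: set[tuple] = set()
    records = []
    for i, row in frame.iterrows():
        key = (row["cow_id"], row["date"], row["session"])
        if key in seen:
            raise ValueError(f"row {i}: duplicate (cow, date, session) {key}")
        seen.add(key)
        scale = row["scale"]
        if scale not in ("transmittance", "absorbance"):
            raise ValueError(f"row {i}: unknown scale {scale!r}")
        spectrum = row[channel_cols].to_numpy(dtype=float)
        if not np.all(np.isfinite(spectrum)):
            bad = channel_cols[int(np.flatnonzero(~np.isfinite(spectrum))[0])]
            raise ValueError(f"row {i}: non-numeric value in channel {bad}")
        if scale == "transmittance":
            bad_idx = np.flatnonzero((spectrum <= 0) | (spectrum > 1))
            if bad_idx.size:
                raise ValueError(
                    f"row {i}: transmittance out of (0, 1] in channel "
                    f"{channel_cols[int(bad_idx[0])]}"
                )
        if row["milk_yield_l"] < 0:
            raise ValueError(f"row {i}: negative milk yield")
        records.append(
            MilkingRecord(
                cow_id=str(row["cow_id"]),
                date=str(row["date"]),
                session=str(row["session"]),  # type: ignore[arg-type]
                milk_yield=float(row["milk_yield_l"]),
                spectrum=spectrum,
                grid=grid,
                scale=scale,
            )
        )
    return records


CALORIMETRY_COLUMNS = ["cow_id", "date", "bw_kg", "v_o2_l", "v_co2_l", "v_ch4_l"]


def write_calorimetry_csv(observations: Sequence[CowDayObservation], path) -> None:
    """Write cow-day body weight and gas exchange as a calorimetry CSV."""
    rows = [
        {
            "cow_id": o.cow_id,
            "date": o.date,
            "bw_kg": o.bw,
            "v_o2_l": o.gas.v_o2,
            "v_co2_l": o.gas.v_co2,
            "v_ch4_l": o.gas.v_ch4,
            "nu_g": o.gas.nu,
        }
        for o in observations
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_calorimetry_csv(path, nu_default: float = NU_DEFAULT_G) -> pd.DataFrame:
    """Read a calorimetry CSV; absent nu_g is filled with the 150 g/d assumption."""
    frame = pd.read_csv(path)
    missing = [c for c in CALORIMETRY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"calorimetry CSV missing columns: {missing}")
    for col in ("bw_kg", "v_o2_l", "v_co2_l", "v_ch4_l"):
        bad = frame.index[(frame[col] < 0) | frame[col].isna()]
        if len(bad):
            raise ValueError(f"row {bad[0]}: {col} must be a nonnegative number")
    if "nu_g" not in frame.columns:
        frame["nu_g"] = nu_default
        frame["nu_assumed"] = True
    else:
        assumed = frame["nu_g"].isna()
        frame.loc[assumed, "nu_g"] = nu_default
        frame["nu_assumed"] = assumed
    frame["date"] = frame["date"].astype(str)
    frame["cow_id"] = frame["cow_id"].astype(str)
    return frame


def write_ground_truth_csv(truths, path) -> None:
    pd.DataFrame(
        [
            {
                "cow_id": t.cow_id,
                "date": t.date,
                "hp_total_kj": t.hp_total,
                "hp_per_mbw": t.hp_per_mbw,
                "fat_gkg": t.fat,
                "protein_gkg": t.protein,
                "lactose_gkg": t.lactose,
            }
            for t in truths
        ]
    ).to_csv(path, index=False)


def assemble_cow_days(
    milkings: Sequence[MilkingRecord], calorimetry: pd.DataFrame
) -> list[CowDayObservation]:
    """Join milking records with calorimetry rows into cow-day observations.

    Cow-days missing either milking session or the calorimetry row are
    dropped (not imputed).
    """
    by_key: dict[tuple, dict] = {}
    for rec in milkings:
        by_key.setdefault((rec.cow_id, rec.date), {})[rec.session] = rec
    observations = []
    for _, row in calorimetry.iterrows():
        pair = by_key.get((row["cow_id"], row["date"]))
        if not pair or "AM" not in pair or "PM" not in pair:
            continue
        gas = GasExchange(
            v_o2=float(row["v_o2_l"]),
            v_co2=float(row["v_co2_l"]),
            v_ch4=float(row["v_ch4_l"]),
            nu=float(row["nu_g"]),
            nu_assumed=bool(row.get("nu_assumed", False)),
        )
        observations.append(
            CowDayObservation(
                cow_id=str(row["cow_id"]),
                date=str(row["date"]),
                bw=float(row["bw_kg"]),
                am=pair["AM"],
                pm=pair["PM"],
                gas=gas,
            )
        )
    return observations


def write_provenance(path: Path, config: RunConfig, seed: int, extra: dict | None = None):
    import mirhp

    payload = {
        "package": "mirhp",
        "version": getattr(mirhp, "__version__", "unknown"),
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": seed,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))
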