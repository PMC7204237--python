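"""Cow-day observation container pairing milkings with calorimetry."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .calorimetry import GasExchange
from .spectra import MilkingRecord


@dataclass
class CowDayObservation:
    """One cow on one day: body weight, AM/PM milkings and gas exchange.

    ``bw`` is the (mean) body weight in kg used for mBW normalisation;
    callers with separate pre/post-chamber weighings should average before
    constructing the record.
    """

    cow_id: str
    date: str  # ISO-8601
    bw: float  # kg
    am: MilkingRecord
    pm: MilkingRecord
    gas: GasExchange
    hp_total: Optional[float] = None  # kJ/d ground truth when known

    def __post_init__(self) -> None:
        if self.bw <= 0:
            raise ValueError(f"body weight must be > 0, got {self.bw}")
        for rec, session in ((self.am, "AM"), (self.pm, "PM")):
            if rec.session != session:
                raise ValueError(f"expected a {session} record, got {rec.session}")
            if (rec.cow_id, rec.date) != (self.cow_id, self.date):
                raise ValueError("milking record cow/date mismatch")

    @property
    def daily_yield(self) -> float:
        """Total daily milk yield in litres (AM + PM)."""
        return self.am.milk_yield + self.pm.milk_yield
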