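"""Dosing regimens.

The study design is cyclic: pemetrexed (PEM) 35 mg/kg i.p. three times
daily at a 4 h interval on the first two days of each cycle (six doses
per cycle, giving ~48 h of continuous exposure given PEM's ~35 min
half-life in mice), and osimertinib (OSI) 1 mg/kg orally once daily.
Strategies differ only in when OSI starts within each cycle:

* ``control``    - no drug,
* ``PEM``        - PEM alone,
* ``OSI``        - OSI alone, daily from cycle start,
* ``concurrent`` - PEM as above plus OSI daily from cycle start,
* ``sequential`` - PEM as above plus OSI daily starting ``interval_h``
  hours after the cycle's first PEM dose (48 h is the paper-of-record
  interval; 0 h reduces to ``concurrent``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

STRATEGIES = ("control", "PEM", "OSI", "concurrent", "sequential")

PEM_TID_HOURS = (0.0, 4.0, 8.0, 24.0, 28.0, 32.0)  # within-cycle PEM doses
DEFAULT_PEM_DOSE = 35.0   # mg/kg
DEFAULT_OSI_DOSE = 1.0    # mg/kg


@dataclass(frozen=True)
class DoseEvent:
    time: float          # h since simulation start
    drug: str            # "PEM" or "OSI"
    amount: float        # mg/kg

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")
        if self.drug not in ("PEM", "OSI"):
            raise ValueError(f"unknown drug {self.drug!r}")


@dataclass(frozen=True)
class Regimen:
    events: tuple[DoseEvent, ...]
    strategy_label: str = "custom"
    interval_h: float = 0.0
    n_cycles: int = 1
    cycle_length_days: float = 7.0

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if times != sorted(times):
            object.__setattr__(self, "events",
                               tuple(sorted(self.events, key=lambda e: e.time)))
        if self.interval_h < 0:
            raise ValueError("interval_h must be >= 0")

    @property
    def end_time(self) -> float:
        return self.n_cycles * self.cycle_length_days * 24.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": [e.time for e in self.events],
             "drug": [e.drug for e in self.events],
             "amount_mg_per_kg": [e.amount for e in self.events]})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **meta) -> "Regimen":
        events = tuple(DoseEvent(float(r.time_h), str(r.drug),
                                 float(r.amount_mg_per_kg))
                       for r in df.itertuples())
        return cls(events=events, **meta)


def build_regimen(strategy: str,
                  interval_h: float = 48.0,
                  pem_dose: float = DEFAULT_PEM_DOSE,
                  osi_dose: float = DEFAULT_OSI_DOSE,
                  n_cycles: int = 3,
                  cycle_length_days: float = 7.0) -> Regimen:
    """Construct the cyclic dosing schedule for a strategy label."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; "
                         f"expected one of {STRATEGIES}")
    if strategy == "concurrent":
        interval_h = 0.0
    cycle_h = cycle_length_days * 24.0
    events: list[DoseEvent] = []
    for c in range(n_cycles):
        start = c * cycle_h
        if strategy in ("PEM", "concurrent", "sequential"):
            for t in PEM_TID_HOURS:
                events.append(DoseEvent(start + t, "PEM", pem_dose))
        if strategy in ("OSI", "concurrent", "sequential"):
            osi_start = 0.0 if strategy == "OSI" else interval_h
            t = osi_start
            while t < cycle_h:
                events.append(DoseEvent(start + t, "OSI", osi_dose))
                t += 24.0
    return Regimen(events=tuple(sorted(events, key=lambda e: e.time)),
                   strategy_label=strategy,
                   interval_h=0.0 if strategy == "control" else interval_h,
                   n_cycles=n_cycles,
                   cycle_length_days=cycle_length_days)
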