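"""Activity-restriction hours (h_r) and scenario comparisons.

h_r counts the hours in a 24 x 365 year when operative temperature strictly
exceeds the taxon's voluntary thermal maximum (VTmax) — hours in which a
non-thermoregulating animal at the surface would be forced to suspend
activity. Scenario deltas compare a future climate against the current one
at the same site for the same taxon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .ectotherm import OperativeSeries
from .microclimate import HOURS_PER_YEAR

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RestrictionRecord:
    site_id: str
    taxon: str
    scenario: str
    h_r: int

    def __post_init__(self) -> None:
        if not 0 <= self.h_r <= HOURS_PER_YEAR:
            raise ValueError(f"h_r out of range: {self.h_r}")


@dataclass(frozen=True)
class ScenarioComparison:
    """Change in restriction hours between a current/future scenario pair.

    percent_change is None when the current h_r is zero (relative change
    undefined); delta_hr is always defined.
    """

    site_id: str
    taxon: str
    scenario_current: str
    scenario_future: str
    delta_hr: int
    percent_change: Optional[float]


def hours_of_restriction(series: Union[OperativeSeries, np.ndarray], vtmax: float) -> int:
    """Count hours with Te strictly above vtmax (ties count as available time)."""
    te = series.te if isinstance(series, OperativeSeries) else np.asarray(series, dtype=float)
    if te.shape != (HOURS_PER_YEAR,):
        raise ValueError(f"Te series must have {HOURS_PER_YEAR} hours, got {te.shape}")
    return int(np.count_nonzero(te > vtmax))


def percent_change(current: float, future: float) -> Optional[float]:
    """100 * (future - current) / current, or None when current is zero."""
    if current == 0:
        return None
    return 100.0 * (future - current) / current


def delta_hr(current: RestrictionRecord, future: RestrictionRecord) -> ScenarioComparison:
    """Future-minus-current restriction hours for one site and taxon."""
    if current.site_id != future.site_id or current.taxon != future.taxon:
        raise ValueError(
            f"mismatched records: ({current.site_id}, {current.taxon}) vs "
            f"({future.site_id}, {future.taxon})"
        )
    delta = future.h_r - current.h_r
    pct = percent_change(current.h_r, future.h_r)
    if pct is None:
        log.warning(
            "site %s taxon %s: current h_r is 0, percent change undefined",
            current.site_id,
            current.taxon,
        )
    return ScenarioComparison(
        site_id=current.site_id,
        taxon=current.taxon,
        scenario_current=current.scenario,
        scenario_future=future.scenario,
        delta_hr=delta,
        percent_change=pct,
    )
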