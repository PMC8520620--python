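"""Collapse daily exposure histories into multi-day analysis periods.

Analysis periods of ``d`` days are formed backward from the case day: period
``j`` covers days ``j*d .. j*d + d - 1`` before (and including) the case day,
so period 0 always ends at the case day.  Only complete periods are kept; the
oldest leftover days are dropped.  Four rules map a period's days to a binary
exposure status:

=============  ===================  =========================================
Definition     Case period          Control periods
=============  ===================  =========================================
I              last (newest) day    last (newest) day
II             last (newest) day    exposed iff at least half the days are
III            last (newest) day    exposed iff at least one day is
IV             any one day          exposed iff at least one day is
=============  ===================  =========================================

"At least half" is read literally: a period is exposed when
``2 * exposed_days >= d`` (so a 2-day period with 1 exposed day is exposed).
The confounder, when present, is aggregated by the same rule as the exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CaseCrossoverDataset, CaseSeries
from .exceptions import ValidationError

__all__ = ["AggregationSpec", "aggregate_periods", "aggregate_history"]

_DEFINITIONS = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class AggregationSpec:
    days_per_period: int
    definition: str = "I"

    def __post_init__(self):
        if self.days_per_period < 1:
            raise ValidationError("days_per_period must be >= 1")
        if self.definition not in _DEFINITIONS:
            raise ValidationError(
                f"definition must be one of {_DEFINITIONS}, got {self.definition!r}"
            )


def _aggregate_matrix(values: np.ndarray, spec: AggregationSpec) -> np.ndarray:
    """Apply the aggregation rule to an (n, total_days) daily matrix.

    Day index is the lag before the case day, so index 0 is the case day and
    the *newest* day of analysis period j is day ``j*d``.
    """
    d = spec.days_per_period
    total = values.shape[1]
    n_periods = total // d
    if n_periods < 1:
        raise ValidationError(
            f"days_per_period={d} exceeds the {total} available days"
        )
    block = values[:, : n_periods * d].reshape(values.shape[0], n_periods, d)
    newest_day = block[:, :, 0]
    counts = block.sum(axis=2)
    if spec.definition == "I":
        return newest_day
    if spec.definition == "II":
        out = (2 * counts >= d).astype(np.int64)
        out[:, 0] = newest_day[:, 0]
        return out
    if spec.definition == "III":
        out = (counts >= 1).astype(np.int64)
        out[:, 0] = newest_day[:, 0]
        return out
    return (counts >= 1).astype(np.int64)  # Definition IV


def aggregate_periods(
    daily: CaseCrossoverDataset, spec: AggregationSpec
) -> CaseCrossoverDataset:
    """Aggregate a day-level dataset into ``floor((M_daily + 1) / d)``
    analysis periods under the requested exposure definition."""
    x = _aggregate_matrix(daily.exposures, spec)
    z = (
        _aggregate_matrix(daily.confounders, spec)
        if daily.has_confounder
        else None
    )
    cases = []
    for i, c in enumerate(daily.cases):
        cases.append(
            CaseSeries(
                c.case_id,
                tuple(x[i]),
                None if z is None else tuple(z[i]),
                c.weight_multiplicity,
            )
        )
    return CaseCrossoverDataset(cases)


def aggregate_history(history, spec: AggregationSpec) -> tuple[int, ...]:
    """Aggregate a single daily history (used to build pattern tables on the
    same analysis-period scale as an aggregated dataset)."""
    arr = np.asarray(history, dtype=np.int64)[None, :]
    return tuple(_aggregate_matrix(arr, spec)[0])
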