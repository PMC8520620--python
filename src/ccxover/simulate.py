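"""Cyclic-exposure dynamic population and expected-count case generation.

The study conditions emulated here are a dynamic population on a fixed drug
cycle (by default 7 days with doses on days 1 and 4) in which the exposed
fraction is the same on every calendar day (stationarity, hence pairwise
exchangeability and no exposure time trend).  The population consists of one
subgroup per cycle phase plus a *stopper* subgroup A (ceases treatment at the
case period) and a *starter* subgroup H (first dose at the case period); A
and H replace the two realisations of the phase that would otherwise be
exposed at the case period, which keeps the day-specific exposed fraction
exactly constant.

Cases are generated as expected counts rather than sampled: a subgroup of
size N contributes ``N * r0`` cases when unexposed at the case period and
``N * RR * r0`` when exposed, which makes the binary-exposure results
bit-deterministic.  Only the optional time-varying confounder states at
control periods are random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import CaseCrossoverDataset, CaseSeries, PatternProbabilityTable
from .exceptions import ValidationError

__all__ = [
    "CyclicPopulationSpec",
    "OutcomeSpec",
    "Subgroup",
    "build_cyclic_population",
    "expected_cases",
    "expected_cases_with_confounder",
    "pattern_table_from_population",
    "motivating_population",
    "scenario_population",
    "scenario_dataset",
]


@dataclass(frozen=True)
class CyclicPopulationSpec:
    """Defines the cyclic treatment pattern and population layout.

    Defaults are the study conditions used throughout: a 7-day cycle with
    drug on days 1 and 4, subgroups of 10,000 patients, and 21 daily control
    periods (three full cycles).
    """

    cycle_length: int = 7
    exposed_days: frozenset[int] = frozenset({1, 4})
    n_per_subgroup: int = 10_000
    n_control_periods: int = 21
    include_stopper: bool = True
    include_starter: bool = True

    def __post_init__(self):
        object.__setattr__(self, "exposed_days", frozenset(int(d) for d in self.exposed_days))
        if self.cycle_length < 2:
            raise ValidationError("cycle_length must be at least 2")
        if not self.exposed_days:
            raise ValidationError("exposed_days must be nonempty")
        if any(d < 1 or d > self.cycle_length for d in self.exposed_days):
            raise ValidationError("exposed_days must lie within 1..cycle_length")
        if len(self.exposed_days) == self.cycle_length:
            raise ValidationError("exposed_days must not cover the whole cycle")
        if self.n_per_subgroup < 1 or self.n_control_periods < 1:
            raise ValidationError("n_per_subgroup and n_control_periods must be >= 1")
        if self.include_stopper != self.include_starter:
            raise ValidationError(
                "no stationary assignment exists with a stopper but no starter "
                "(or vice versa): the rate of stopping must equal the rate of starting"
            )


@dataclass(frozen=True)
class OutcomeSpec:
    """Event-rate model: rate ``r0`` per unexposed period, multiplied by the
    rate ratio ``RR`` when exposed, and (confounder scenario) by ``RRz`` when
    the binary time-varying confounder is positive.  ``f0``/``f1`` are the
    population probabilities that the confounder is positive in an unexposed/
    exposed period; the confounder state at each control period is drawn
    independently from Bernoulli(f0) or Bernoulli(f1) using ``seed``.
    """

    r0: float = 0.001
    RR: float = 4.0
    RRz: float | None = None
    f0: float = 0.2
    f1: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.r0 < 1:
            raise ValidationError("r0 must be in (0, 1)")
        if self.RR <= 0 or (self.RRz is not None and self.RRz <= 0):
            raise ValidationError("rate ratios must be positive")
        if not (0 <= self.f0 <= 1 and 0 <= self.f1 <= 1):
            raise ValidationError("f0 and f1 must be in [0, 1]")


@dataclass(frozen=True)
class Subgroup:
    label: str
    history: tuple[int, ...]  # exposure at m = 0..M
    size: int


def _phase_history(case_day: int, cycle_length: int, exposed_days: frozenset[int], M: int):
    """Exposure history (m = 0..M) of a patient whose case day is cycle day
    ``case_day`` (1-based) and who follows the cycle throughout."""
    days = [((case_day - 1 - m) % cycle_length) + 1 for m in range(M + 1)]
    return tuple(1 if d in exposed_days else 0 for d in days)


def build_cyclic_population(spec: CyclicPopulationSpec) -> list[Subgroup]:
    """Construct the stationary subgroup histories.

    Without stopper/starter, the population is one ongoing subgroup per cycle
    phase (their histories are the cyclic shifts of the dosing pattern).  With
    them, the phase whose case day is the *first* exposed day of the cycle is
    realised twice instead of as an ongoing subgroup: once as the stopper A
    (its cyclic history with the case period forced unexposed) and once as
    the starter H (exposed at the case period only).  Every calendar day is
    then exposed in exactly ``len(exposed_days)`` of the
    ``cycle_length + 1`` subgroups, so the exposed fraction is constant.
    """
    C, M = spec.cycle_length, spec.n_control_periods
    N = spec.n_per_subgroup
    subgroups: list[Subgroup] = []
    if spec.include_stopper:
        base_day = min(spec.exposed_days)
        base = _phase_history(base_day, C, spec.exposed_days, M)
        stopper = (0,) + base[1:]
        starter = (1,) + (0,) * M
        ongoing_days = [d for d in range(1, C + 1) if d != base_day]
        labels = [chr(ord("B") + i) for i in range(len(ongoing_days))]
        subgroups.append(Subgroup("A", stopper, N))
        for lab, d in zip(labels, ongoing_days):
            subgroups.append(Subgroup(lab, _phase_history(d, C, spec.exposed_days, M), N))
        subgroups.append(Subgroup(chr(ord("B") + len(ongoing_days)), starter, N))
    else:
        for i, d in enumerate(range(1, C + 1)):
            subgroups.append(
                Subgroup(chr(ord("A") + i), _phase_history(d, C, spec.exposed_days, M), N)
            )
    # stationarity check: identical exposed fraction on every day
    hist = np.array([s.history for s in subgroups])
    sizes = np.array([s.size for s in subgroups])
    exposed_per_day = (hist * sizes[:, None]).sum(axis=0)
    if len(set(exposed_per_day.tolist())) != 1:
        raise ValidationError(
            "no stationary assignment exists for this cycle specification"
        )
    return subgroups


def motivating_population(M: int = 3, n_per_subgroup: int = 10_000) -> list[Subgroup]:
    """The 2-days-on / 1-day-off worked example: a 3-day cycle with doses on
    days 1 and 2 and no stoppers or starters, so only the three cyclic shifts
    of the dosing pattern occur."""
    spec = CyclicPopulationSpec(
        cycle_length=3,
        exposed_days=frozenset({1, 2}),
        n_per_subgroup=n_per_subgroup,
        n_control_periods=M,
        include_stopper=False,
        include_starter=False,
    )
    return build_cyclic_population(spec)


def _expected_count(value: float, context: str) -> int:
    rounded = round(value)
    if abs(value - rounded) > 1e-9 or rounded < 0:
        raise ValidationError(
            f"expected case count {value} for {context} is not a nonnegative "
            "integer; adjust n_per_subgroup or r0"
        )
    return int(rounded)


def expected_cases(
    population: Sequence[Subgroup], outcome: OutcomeSpec
) -> CaseCrossoverDataset:
    """Deterministic expected-count case dataset for the binary-exposure-only
    scenario: each subgroup contributes ``N * r0 * RR**x0`` cases carrying its
    own history, emitted as one record with that multiplicity."""
    if outcome.RRz is not None:
        raise ValidationError(
            "expected_cases is for the binary-exposure-only scenario; "
            "use expected_cases_with_confounder when RRz is set"
        )
    cases = []
    for sg in population:
        rate = outcome.r0 * (outcome.RR if sg.history[0] == 1 else 1.0)
        count = _expected_count(sg.size * rate, f"subgroup {sg.label}")
        if count > 0:
            cases.append(CaseSeries(sg.label, sg.history, None, count))
    return CaseCrossoverDataset(cases)


def expected_cases_with_confounder(
    population: Sequence[Subgroup], outcome: OutcomeSpec
) -> CaseCrossoverDataset:
    """Expected-count cases under the confounder scenario.

    Each subgroup splits into two case strata by confounder status at the
    case period, with expected counts ``N * r0 * RR**x0 * (1 - f_x0)`` for
    ``z0 = 0`` and ``N * r0 * RR**x0 * RRz * f_x0`` for ``z0 = 1`` (``f_x0``
    is ``f1`` when exposed at the case period, ``f0`` otherwise).  Strata are
    expanded into individual cases so every case receives its own independent
    Bernoulli confounder draws at the control periods.
    """
    if outcome.RRz is None:
        raise ValidationError("confounder scenario requires RRz")
    rng = np.random.default_rng(outcome.seed)
    cases = []
    for sg in population:
        x0 = sg.history[0]
        f = outcome.f1 if x0 == 1 else outcome.f0
        base = sg.size * outcome.r0 * (outcome.RR if x0 == 1 else 1.0)
        for z0 in (0, 1):
            expected = base * (outcome.RRz * f if z0 == 1 else (1.0 - f))
            count = _expected_count(expected, f"subgroup {sg.label}, z0={z0}")
            p_z = np.where(
                np.array(sg.history[1:]) == 1, outcome.f1, outcome.f0
            )
            for k in range(count):
                z_ctrl = (rng.random(len(p_z)) < p_z).astype(int)
                cases.append(
                    CaseSeries(
                        f"{sg.label}-z{z0}-{k:03d}",
                        sg.history,
                        (z0,) + tuple(z_ctrl),
                        1,
                    )
                )
    return CaseCrossoverDataset(cases)


def scenario_population(scenario: str, M: int | None = None) -> list[Subgroup]:
    """Named study populations.

    ``cyclic``/``confounded``: the default 8-subgroup cyclic population (7-day
    cycle, doses on days 1 and 4, stopper and starter, N = 10,000 per
    subgroup; default M = 21 daily control periods).  ``motivating``: the
    3-pattern 2-on/1-off example (default M = 3).
    """
    scenario = scenario.lower()
    if scenario in ("cyclic", "confounded"):
        return build_cyclic_population(
            CyclicPopulationSpec(n_control_periods=21 if M is None else M)
        )
    if scenario == "motivating":
        return motivating_population(M=3 if M is None else M)
    raise ValidationError(f"unknown scenario {scenario!r}")


def scenario_dataset(
    scenario: str, M: int | None = None, seed: int = 0
) -> CaseCrossoverDataset:
    """Expected-count case dataset for a named scenario.

    ``cyclic`` and ``motivating`` are deterministic (binary exposure only,
    r0 = 0.001, RR = 4); ``confounded`` adds the binary time-varying confounder
    (RRz = 2, f0 = 0.2, f1 = 0.4) whose control-period states depend on
    ``seed``.
    """
    population = scenario_population(scenario, M)
    if scenario.lower() == "confounded":
        return expected_cases_with_confounder(
            population, OutcomeSpec(RRz=2.0, seed=seed)
        )
    return expected_cases(population, OutcomeSpec())


def pattern_table_from_population(
    population: Sequence[Subgroup],
) -> PatternProbabilityTable:
    """Population exposure-sequence probabilities: each distinct history is
    assigned its population share.  For confounder scenarios the table covers
    exposure sequences only; the confounder is modelled separately as
    independent Bernoulli given exposure (matching the generator)."""
    total = sum(sg.size for sg in population)
    entries: dict[tuple[int, ...], float] = {}
    for sg in population:
        entries[sg.history] = entries.get(sg.history, 0.0) + sg.size / total
    return PatternProbabilityTable(entries)
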