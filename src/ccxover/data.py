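"""Core data containers for case-crossover analyses.

A case-crossover study compares each case's exposure at the period in which
the outcome occurred (the *case period*, index ``m = 0``) with the same
person's exposure at ``M`` earlier *control periods* (``m = 1..M``, counted
backward in time).  All estimators in this package operate on a
:class:`CaseCrossoverDataset`, a rectangular collection of binary exposure
histories with an optional binary time-varying confounder and per-case
frequency multiplicities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, ValidationError

__all__ = [
    "CaseSeries",
    "CaseCrossoverDataset",
    "DiscordanceSummary",
    "WeightSet",
    "PatternProbabilityTable",
    "EstimateResult",
    "summarize_discordance",
    "read_dataset",
    "write_dataset",
]


def _check_binary(values: Sequence[int], what: str, case_id) -> tuple[int, ...]:
    out = []
    for v in values:
        iv = int(v)
        if iv not in (0, 1) or iv != v:
            raise ValidationError(
                f"case {case_id!r}: {what} value {v!r} is not binary (0/1)"
            )
        out.append(iv)
    return tuple(out)


@dataclass(frozen=True)
class CaseSeries:
    """One case's exposure (and optional confounder) history.

    ``exposures[m]`` is the binary exposure at period ``m``; ``m = 0`` is the
    case period and larger ``m`` lie further back in time.
    ``weight_multiplicity`` is a frequency weight: the number of identical
    cases this record represents (used by the deterministic expected-count
    simulation so one row per distinct history suffices).
    """

    case_id: object
    exposures: tuple[int, ...]
    confounders: tuple[int, ...] | None = None
    weight_multiplicity: int = 1

    def __post_init__(self):
        exp = _check_binary(self.exposures, "exposure", self.case_id)
        object.__setattr__(self, "exposures", exp)
        if len(exp) < 2:
            raise ValidationError(
                f"case {self.case_id!r}: history must have at least 2 periods"
            )
        if self.confounders is not None:
            con = _check_binary(self.confounders, "confounder", self.case_id)
            if len(con) != len(exp):
                raise ValidationError(
                    f"case {self.case_id!r}: confounder history length "
                    f"{len(con)} != exposure history length {len(exp)}"
                )
            object.__setattr__(self, "confounders", con)
        if int(self.weight_multiplicity) != self.weight_multiplicity or self.weight_multiplicity < 1:
            raise ValidationError(
                f"case {self.case_id!r}: weight_multiplicity must be a positive integer"
            )
        object.__setattr__(self, "weight_multiplicity", int(self.weight_multiplicity))

    @property
    def M(self) -> int:
        """Number of control periods."""
        return len(self.exposures) - 1

    def is_concordant(self) -> bool:
        """True when all periods share one exposure status (no information)."""
        return len(set(self.exposures)) == 1


class CaseCrossoverDataset:
    """A collection of :class:`CaseSeries` sharing a common ``M``.

    Internally stores exposures (and confounders, when present on every case)
    as dense integer arrays of shape ``(n_cases, M + 1)`` for vectorised
    estimation; the per-case multiplicities act as frequency weights in every
    estimator.
    """

    def __init__(self, cases: Iterable[CaseSeries]):
        cases = list(cases)
        if not cases:
            raise ValidationError("dataset must contain at least one case")
        M = cases[0].M
        for c in cases:
            if c.M != M:
                raise ValidationError(
                    f"case {c.case_id!r} has M={c.M}, expected M={M}"
                )
        with_conf = [c.confounders is not None for c in cases]
        self._cases = tuple(cases)
        self.M = M
        self.has_confounder = all(with_conf)
        self.case_ids = [c.case_id for c in cases]
        self.exposures = np.array([c.exposures for c in cases], dtype=np.int64)
        self.multiplicity = np.array(
            [c.weight_multiplicity for c in cases], dtype=np.int64
        )
        if self.has_confounder:
            self.confounders = np.array(
                [c.confounders for c in cases], dtype=np.int64
            )
        else:
            self.confounders = None

    # -- basic container behaviour -------------------------------------------------
    @property
    def cases(self) -> tuple[CaseSeries, ...]:
        return self._cases

    def __len__(self) -> int:
        return len(self._cases)

    def __iter__(self):
        return iter(self._cases)

    @property
    def n_cases(self) -> int:
        """Number of case records (each may carry a multiplicity > 1)."""
        return len(self._cases)

    @property
    def n_effective(self) -> int:
        """Total number of cases counting multiplicities."""
        return int(self.multiplicity.sum())

    def drop_confounder(self) -> "CaseCrossoverDataset":
        """Return a copy with the confounder column removed."""
        return CaseCrossoverDataset(
            CaseSeries(c.case_id, c.exposures, None, c.weight_multiplicity)
            for c in self._cases
        )

    def expand_multiplicities(self) -> "CaseCrossoverDataset":
        """Return an equivalent dataset with every multiplicity equal to 1."""
        out = []
        for c in self._cases:
            for k in range(c.weight_multiplicity):
                cid = c.case_id if c.weight_multiplicity == 1 else f"{c.case_id}#{k}"
                out.append(CaseSeries(cid, c.exposures, c.confounders, 1))
        return CaseCrossoverDataset(out)

    def subset(self, indices: Sequence[int]) -> "CaseCrossoverDataset":
        return CaseCrossoverDataset(self._cases[i] for i in indices)

    # -- tabular round trip --------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (case, period), ordered by (case_id, period)."""
        rows = []
        for c in self._cases:
            for m in range(self.M + 1):
                row = {"case_id": c.case_id, "period": m, "exposure": c.exposures[m]}
                if self.has_confounder:
                    row["confounder"] = c.confounders[m]
                if (self.multiplicity != 1).any():
                    row["multiplicity"] = c.weight_multiplicity
                rows.append(row)
        df = pd.DataFrame(rows)
        return df.sort_values(["case_id", "period"], kind="stable").reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CaseCrossoverDataset":
        required = {"case_id", "period", "exposure"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"missing required columns: {sorted(missing)}")
        has_conf = "confounder" in df.columns
        has_mult = "multiplicity" in df.columns
        M = int(df["period"].max())
        expected = list(range(M + 1))
        cases = []
        for cid, grp in df.groupby("case_id", sort=True):
            periods = grp["period"].astype(int).tolist()
            if sorted(periods) != expected:
                dup = len(periods) != len(set(periods))
                kind = "duplicate" if dup else "missing"
                raise ValidationError(
                    f"case {cid!r}: {kind} periods; expected exactly 0..{M}"
                )
            grp = grp.sort_values("period")
            conf = grp["confounder"].tolist() if has_conf else None
            if has_mult:
                mults = set(grp["multiplicity"].astype(int))
                if len(mults) != 1:
                    raise ValidationError(
                        f"case {cid!r}: inconsistent multiplicity values"
                    )
                mult = mults.pop()
            else:
                mult = 1
            cases.append(CaseSeries(cid, tuple(grp["exposure"]), conf and tuple(conf), mult))
        return cls(cases)


def read_dataset(path, **read_csv_kwargs) -> CaseCrossoverDataset:
    """Read a long-format CSV (``case_id,period,exposure[,confounder][,multiplicity]``)."""
    df = pd.read_csv(path, **read_csv_kwargs)
    return CaseCrossoverDataset.from_frame(df)


def write_dataset(dataset: CaseCrossoverDataset, path) -> None:
    """Write a dataset to CSV in the long format accepted by :func:`read_dataset`."""
    dataset.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class DiscordanceSummary:
    """Sufficient statistics of the weighting method.

    ``a1`` counts discordant cases exposed at the case period (each with at
    least one unexposed control period); ``a0`` counts discordant cases
    unexposed at the case period.  ``sum_PT10`` / ``sum_PT01`` are the total
    unexposed (resp. exposed) control person-time accumulated by those cases,
    and ``pi10 = mean_PT01 / mean_PT10`` estimates the odds that the case
    period is exposed versus unexposed under pairwise exchangeability.
    """

    a1: int
    a0: int
    sum_PT10: int
    sum_PT01: int
    n_concordant_dropped: int

    @property
    def mean_PT10(self) -> float:
        return self.sum_PT10 / self.a1 if self.a1 > 0 else math.nan

    @property
    def mean_PT01(self) -> float:
        return self.sum_PT01 / self.a0 if self.a0 > 0 else math.nan

    @property
    def pi10(self) -> float:
        """Relative case-period exposure probability pi1/pi0."""
        if min(self.a1, self.a0, self.sum_PT10, self.sum_PT01) <= 0:
            raise DegenerateDataError(
                "pi10 undefined: requires a1 > 0, a0 > 0 and positive "
                f"person-time sums (a1={self.a1}, a0={self.a0}, "
                f"sum_PT10={self.sum_PT10}, sum_PT01={self.sum_PT01})"
            )
        return self.mean_PT01 / self.mean_PT10


def summarize_discordance(
    dataset: CaseCrossoverDataset, strict: bool = True
) -> DiscordanceSummary:
    """Count discordant cases and their discordant control person-time.

    Concordant cases (all periods exposed or all unexposed) carry no
    information and are tallied in ``n_concordant_dropped``.  Multiplicities
    are honoured: a record representing k identical cases counts k times.

    With ``strict=True`` a :class:`DegenerateDataError` is raised when either
    discordance direction is empty (``a1 == 0`` or ``a0 == 0``), because the
    weighting method's pi10 is then undefined.  Estimators that can report an
    infinite odds ratio instead call with ``strict=False``.
    """
    x = dataset.exposures
    mult = dataset.multiplicity
    x0 = x[:, 0]
    n_unexp_ctrl = (x[:, 1:] == 0).sum(axis=1)
    n_exp_ctrl = (x[:, 1:] == 1).sum(axis=1)
    is_a1 = (x0 == 1) & (n_unexp_ctrl > 0)
    is_a0 = (x0 == 0) & (n_exp_ctrl > 0)
    concordant = ~(is_a1 | is_a0)
    summary = DiscordanceSummary(
        a1=int(mult[is_a1].sum()),
        a0=int(mult[is_a0].sum()),
        sum_PT10=int((mult[is_a1] * n_unexp_ctrl[is_a1]).sum()),
        sum_PT01=int((mult[is_a0] * n_exp_ctrl[is_a0]).sum()),
        n_concordant_dropped=int(mult[concordant].sum()),
    )
    if strict and (summary.a1 == 0 or summary.a0 == 0):
        raise DegenerateDataError(
            "no discordant information in one direction: "
            f"a1={summary.a1}, a0={summary.a0}, "
            f"n_concordant_dropped={summary.n_concordant_dropped}"
        )
    return summary


@dataclass(frozen=True)
class WeightSet:
    """Per-case denominator weights of the weighted conditional likelihood.

    Every exposed period of the case gets weight ``w1 = pi10 / m1`` and every
    unexposed period ``w0 = 1 / m0``, where ``m1``/``m0`` count the case's
    exposed/unexposed periods including the case period.  Consequently
    ``w1 * m1 = pi10`` and ``w0 * m0 = 1`` exactly.
    """

    case_id: object
    m1: int
    m0: int
    w1: float
    w0: float


class PatternProbabilityTable:
    """Sparse map from full exposure sequences to population probabilities.

    Keys are length-``(M + 1)`` binary tuples ordered by period index
    (``m = 0`` first); sequences absent from the table have probability 0.
    Sub-normalised tables are permitted: only probability ratios enter the
    permutation likelihood.
    """

    def __init__(self, entries: Mapping[tuple[int, ...], float]):
        if not entries:
            raise ValidationError("pattern table must have at least one entry")
        lengths = {len(k) for k in entries}
        if len(lengths) != 1:
            raise ValidationError("all sequences must share one length")
        self.sequence_length = lengths.pop()
        clean = {}
        for seq, p in entries.items():
            seq = tuple(int(v) for v in seq)
            if any(v not in (0, 1) for v in seq):
                raise ValidationError(f"non-binary sequence {seq}")
            if p < 0:
                raise ValidationError(f"negative probability for {seq}")
            if p > 0:
                clean[seq] = clean.get(seq, 0.0) + float(p)
        total = sum(clean.values())
        if total > 1 + 1e-9:
            raise ValidationError(f"probabilities sum to {total} > 1")
        self.entries = clean

    def probability(self, seq: Sequence[int]) -> float:
        return self.entries.get(tuple(int(v) for v in seq), 0.0)

    def __len__(self) -> int:
        return len(self.entries)

    def items(self):
        return self.entries.items()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sequence": "".join(str(v) for v in seq), "probability": p}
            for seq, p in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PatternProbabilityTable":
        entries = {
            tuple(int(ch) for ch in str(row.sequence)): float(row.probability)
            for row in df.itertuples()
        }
        return cls(entries)

    @classmethod
    def read_csv(cls, path) -> "PatternProbabilityTable":
        return cls.from_frame(pd.read_csv(path, dtype={"sequence": str}))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class EstimateResult:
    """A fitted odds-ratio estimate with interval and diagnostics.

    ``beta`` is the log odds ratio for the exposure; ``gamma`` the optional
    log odds ratio for the time-varying confounder.  ``ci_kind`` records how
    the interval on the OR scale was obtained.
    """

    method: str
    beta: float
    gamma: float | None = None
    var_beta: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    ci_kind: str = "none"
    n_informative: int = 0
    converged: bool = True
    diagnostics: list[str] = field(default_factory=list)

    @property
    def or_exposure(self) -> float:
        return math.exp(self.beta)

    @property
    def or_confounder(self) -> float | None:
        return None if self.gamma is None else math.exp(self.gamma)
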