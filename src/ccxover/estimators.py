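"""Case-crossover odds-ratio estimators.

Four estimators are provided as scikit-learn style classes (``fit(X)``,
fitted attributes with trailing underscores), where ``X`` is a
:class:`~ccxover.data.CaseCrossoverDataset` or an equivalent long-format
DataFrame:

``ConditionalLogitOR``
    Standard conditional logistic regression for 1:M matched sets.  Biased
    when the within-subject exposure history is autocorrelated (unless only
    one control period is used).

``MantelHaenszelOR``
    The matched Mantel-Haenszel odds ratio, i.e. the ratio of total unexposed
    control person-time among exposed-at-case cases to total exposed control
    person-time among unexposed-at-case cases.  Unbiased under pairwise
    exchangeability.  Optional per-case stratification by a binary
    time-varying confounder (Maclure's recommendation), which deletes control
    periods whose confounder status differs from the case period's.

``WeightedGreenlandOR``
    The weighting method: estimates the relative case-period exposure
    probability pi10 from discordant person-time, weights every exposed
    period by ``pi10 / m1`` and every unexposed period by ``1 / m0``, and
    maximises Greenland's weighted conditional likelihood.  For a single
    binary exposure this has the closed form ``(a1 / a0) / pi10`` (identical
    to the Mantel-Haenszel point estimate); with a binary time-varying
    confounder the weighted likelihood is maximised in (beta, gamma) with the
    weights still computed from the exposure alone.

``VinesFarringtonOR``
    The permutation likelihood, which weights each within-subject arrangement
    of the observed period values by its population probability.  Requires a
    table of population exposure-sequence probabilities and is subject to a
    positivity condition.

Module-level functions (``fit_scl``, ``fit_mh``, ``fit_greenland``,
``fit_vf``, ``bootstrap_percentiles``, ``diagnose_bias``) are thin wrappers
over these classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from math import comb
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, clone

from ._clogit import fit_conditional_logit
from .data import (
    CaseCrossoverDataset,
    DiscordanceSummary,
    EstimateResult,
    PatternProbabilityTable,
    WeightSet,
    summarize_discordance,
)
from .exceptions import (
    DegenerateDataError,
    NoInformativeCasesError,
    ValidationError,
)

__all__ = [
    "ConditionalLogitOR",
    "MantelHaenszelOR",
    "WeightedGreenlandOR",
    "VinesFarringtonOR",
    "compute_weights",
    "bootstrap_percentiles",
    "diagnose_bias",
    "BiasDiagnosis",
    "fit_scl",
    "fit_mh",
    "fit_greenland",
    "fit_vf",
]


def _as_dataset(X) -> CaseCrossoverDataset:
    if isinstance(X, CaseCrossoverDataset):
        return X
    if isinstance(X, pd.DataFrame):
        return CaseCrossoverDataset.from_frame(X)
    raise ValidationError(
        "X must be a CaseCrossoverDataset or a long-format DataFrame"
    )


def _wald_ci(beta: float, var: float, level: float) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var)
    return math.exp(beta - half), math.exp(beta + half)


class _CaseCrossoverEstimator(BaseEstimator):
    """Shared fit plumbing: dataset coercion and result unpacking."""

    def fit(self, X, y=None):
        dataset = _as_dataset(X)
        result = self._fit_dataset(dataset)
        self.result_ = result
        self.beta_ = result.beta
        self.or_ = result.or_exposure
        self.gamma_ = result.gamma
        self.or_confounder_ = result.or_confounder
        self.var_beta_ = result.var_beta
        self.ci_ = (result.ci_low, result.ci_high)
        self.n_informative_ = result.n_informative
        self.converged_ = result.converged
        return self

    def fit_result(self, X) -> EstimateResult:
        return self.fit(X).result_

    def _fit_dataset(self, dataset: CaseCrossoverDataset) -> EstimateResult:
        raise NotImplementedError


def _build_covariates(dataset: CaseCrossoverDataset, adjust_confounder: bool):
    x = dataset.exposures[:, :, None].astype(float)
    if adjust_confounder:
        if not dataset.has_confounder:
            raise ValidationError(
                "adjust_confounder=True requires a confounder on every case"
            )
        z = dataset.confounders[:, :, None].astype(float)
        return np.concatenate([x, z], axis=2)
    return x


class ConditionalLogitOR(_CaseCrossoverEstimator):
    """Standard conditional logistic regression (1:M matched sets).

    Parameters
    ----------
    adjust_confounder : include the binary time-varying confounder with its
        own log odds ratio gamma.
    max_iter, tol : Newton-Raphson controls (tolerance on parameter change).
    ci_level : coverage of the Wald interval from the observed information.
    """

    def __init__(self, adjust_confounder=False, max_iter=100, tol=1e-10, ci_level=0.95):
        self.adjust_confounder = adjust_confounder
        self.max_iter = max_iter
        self.tol = tol
        self.ci_level = ci_level

    def _fit_dataset(self, dataset):
        covs = _build_covariates(dataset, self.adjust_confounder)
        informative = (covs != covs[:, :1, :]).any(axis=(1, 2))
        if not informative.any():
            raise DegenerateDataError("every case is concordant in all covariates")
        res = fit_conditional_logit(
            covs[informative],
            dataset.multiplicity[informative],
            tol=self.tol,
            max_iter=self.max_iter,
        )
        diagnostics = []
        beta = float(res.theta[0])
        var = None
        ci_low = ci_high = None
        ci_kind = "none"
        if res.separated:
            beta = math.inf if res.theta[0] > 0 else -math.inf
            diagnostics.append(
                "separation: score monotone in beta, infinite estimate"
            )
        elif res.cov is not None:
            var = float(res.cov[0, 0])
            ci_low, ci_high = _wald_ci(beta, var, self.ci_level)
            ci_kind = "wald"
        if not res.converged and not res.separated:
            diagnostics.append(f"did not converge in {res.n_iter} iterations")
        return EstimateResult(
            method="SCL",
            beta=beta,
            gamma=float(res.theta[1]) if self.adjust_confounder else None,
            var_beta=var,
            ci_low=ci_low,
            ci_high=ci_high,
            ci_kind=ci_kind,
            n_informative=int(dataset.multiplicity[informative].sum()),
            converged=res.converged,
            diagnostics=diagnostics,
        )


def _rbg_variance(strata: np.ndarray) -> float | None:
    """Robins-Breslow-Greenland variance of the log Mantel-Haenszel OR.

    ``strata`` holds one row per case: (a, b, c, d, mult) where the case row
    of the 2x2 table is (a, b) = (exposed, unexposed) with one subject and
    the control row (c, d) = (exposed periods, unexposed periods).  For 1:1
    matched data this reduces exactly to 1/a1 + 1/a0.
    """
    a, b, c, d, mult = strata.T
    n = a + b + c + d
    P = (a + d) / n
    Q = (b + c) / n
    R = a * d / n
    S = b * c / n
    sR, sS = float((mult * R).sum()), float((mult * S).sum())
    if sR <= 0 or sS <= 0:
        return None
    term1 = float((mult * P * R).sum()) / (2 * sR**2)
    term2 = float((mult * (P * S + Q * R)).sum()) / (2 * sR * sS)
    term3 = float((mult * Q * S).sum()) / (2 * sS**2)
    return term1 + term2 + term3


class MantelHaenszelOR(_CaseCrossoverEstimator):
    """Matched Mantel-Haenszel odds ratio.

    The point estimate is ``sum_i PT10_i / sum_i PT01_i`` (unexposed control
    person-time of exposed-at-case cases over exposed control person-time of
    unexposed-at-case cases).  The confidence interval uses the
    Robins-Breslow-Greenland variance of the log MH odds ratio over the
    per-case 2x2 strata, which coincides with ``1/a1 + 1/a0`` when M = 1.

    With ``stratify_by_confounder=True``, control periods whose confounder
    status differs from the case period's are deleted first (which can itself
    introduce bias; the weighting method avoids this).
    """

    def __init__(self, stratify_by_confounder=False, ci_level=0.95):
        self.stratify_by_confounder = stratify_by_confounder
        self.ci_level = ci_level

    def _fit_dataset(self, dataset):
        x = dataset.exposures
        mult = dataset.multiplicity
        diagnostics = []
        if self.stratify_by_confounder:
            if not dataset.has_confounder:
                raise ValidationError(
                    "stratify_by_confounder=True requires a confounder"
                )
            z = dataset.confounders
            keep = z[:, 1:] == z[:, :1]  # control periods matching case-period z
            diagnostics.append("stratified by confounder status (Maclure)")
        else:
            keep = np.ones_like(x[:, 1:], dtype=bool)
        x0 = x[:, 0]
        exp_ctrl = ((x[:, 1:] == 1) & keep).sum(axis=1)
        unexp_ctrl = ((x[:, 1:] == 0) & keep).sum(axis=1)
        is_a1 = (x0 == 1) & (unexp_ctrl > 0)
        is_a0 = (x0 == 0) & (exp_ctrl > 0)
        s10 = int((mult[is_a1] * unexp_ctrl[is_a1]).sum())
        s01 = int((mult[is_a0] * exp_ctrl[is_a0]).sum())
        a1 = int(mult[is_a1].sum())
        a0 = int(mult[is_a0].sum())
        if s10 == 0 and s01 == 0:
            raise DegenerateDataError("no discordant person-time in either direction")
        var = None
        ci_low = ci_high = None
        ci_kind = "none"
        if s01 == 0:
            beta = math.inf
            diagnostics.append("zero denominator person-time: infinite estimate")
        elif s10 == 0:
            beta = -math.inf
            diagnostics.append("zero numerator person-time: estimate is zero")
        else:
            beta = math.log(s10 / s01)
            strata = np.column_stack(
                [x0, 1 - x0, exp_ctrl, unexp_ctrl, mult]
            ).astype(float)
            informative = is_a1 | is_a0
            var = _rbg_variance(strata[informative])
            if var is not None:
                ci_low, ci_high = _wald_ci(beta, var, self.ci_level)
                ci_kind = "wald"
        return EstimateResult(
            method="MH_stratified" if self.stratify_by_confounder else "MH",
            beta=beta,
            var_beta=var,
            ci_low=ci_low,
            ci_high=ci_high,
            ci_kind=ci_kind,
            n_informative=a1 + a0,
            converged=True,
            diagnostics=diagnostics,
        )


def compute_weights(
    summary: DiscordanceSummary, dataset: CaseCrossoverDataset
) -> list[WeightSet | None]:
    """Per-case denominator weights ``(w1, w0) = (pi10 / m1, 1 / m0)``.

    Returns a list aligned with ``dataset.cases``; concordant cases (which
    carry no weights and drop out of the weighted likelihood) map to None.
    """
    pi10 = summary.pi10  # raises DegenerateDataError when undefined
    out: list[WeightSet | None] = []
    for c in dataset.cases:
        m1 = sum(c.exposures)
        m0 = len(c.exposures) - m1
        if m1 == 0 or m0 == 0:
            out.append(None)
        else:
            out.append(WeightSet(c.case_id, m1, m0, pi10 / m1, 1.0 / m0))
    return out


class WeightedGreenlandOR(_CaseCrossoverEstimator):
    """The weighting method for case-crossover data.

    Point estimation proceeds by (1) estimating the relative case-period
    exposure probability ``pi10`` from discordant person-time, (2) weighting
    each period of each discordant case by ``pi10 / m1`` (exposed) or
    ``1 / m0`` (unexposed), and (3) maximising the weighted conditional
    likelihood, where the weights enter the denominator as log offsets.  For
    a single binary exposure the maximum has the closed form
    ``(a1 / a0) / pi10``, and both routes are computed and cross-checked;
    with ``adjust_confounder=True`` the weighted likelihood is maximised in
    (beta, gamma) with the weights still based on the exposure alone.

    The model-based variance ``1/a1 + 1/a0`` (binary-only) and the Wald
    interval treat pi10 as fixed.  Set ``n_bootstrap > 0`` for a percentile
    interval that resamples cases and re-estimates pi10 in every replicate,
    which accounts for the uncertainty of the weights.

    ``weighting="unit"`` forces every weight to 1, reducing the model to
    standard conditional logistic regression (useful for sensitivity checks).
    """

    def __init__(
        self,
        adjust_confounder=False,
        weighting="pi10",
        n_bootstrap=0,
        seed=0,
        ci_level=0.95,
        max_iter=100,
        tol=1e-10,
    ):
        self.adjust_confounder = adjust_confounder
        self.weighting = weighting
        self.n_bootstrap = n_bootstrap
        self.seed = seed
        self.ci_level = ci_level
        self.max_iter = max_iter
        self.tol = tol

    def _point_fit(self, dataset: CaseCrossoverDataset) -> EstimateResult:
        if self.weighting not in ("pi10", "unit"):
            raise ValidationError("weighting must be 'pi10' or 'unit'")
        diagnostics = []
        if self.weighting == "pi10":
            summary = summarize_discordance(dataset, strict=True)
            weights = compute_weights(summary, dataset)
        else:
            summary = summarize_discordance(dataset, strict=False)
            weights = [
                None if c.is_concordant() else WeightSet(c.case_id, 0, 0, 1.0, 1.0)
                for c in dataset.cases
            ]
        keep = [i for i, w in enumerate(weights) if w is not None]
        sub = dataset.subset(keep)
        covs = _build_covariates(sub, self.adjust_confounder)
        logw = np.where(
            sub.exposures == 1,
            np.array([[math.log(weights[i].w1)] for i in keep]),
            np.array([[math.log(weights[i].w0)] for i in keep]),
        )
        res = fit_conditional_logit(
            covs, sub.multiplicity, log_weights=logw, tol=self.tol, max_iter=self.max_iter
        )
        beta = float(res.theta[0])
        gamma = float(res.theta[1]) if self.adjust_confounder else None
        var = None
        if self.adjust_confounder:
            if res.cov is not None:
                var = float(res.cov[0, 0])
        elif self.weighting == "pi10":
            # closed form and its pi10-fixed variance; the iterative route
            # must agree (consistency check on the implementation)
            beta_closed = math.log((summary.a1 / summary.a0) / summary.pi10)
            if abs(beta - beta_closed) > 1e-6:
                diagnostics.append(
                    f"offset fit ({beta:.8f}) deviates from closed form "
                    f"({beta_closed:.8f})"
                )
            beta = beta_closed
            var = 1.0 / summary.a1 + 1.0 / summary.a0
        elif res.cov is not None:
            var = float(res.cov[0, 0])
        if var is not None:
            ci_low, ci_high = _wald_ci(beta, var, self.ci_level)
            ci_kind = "wald"
        else:
            ci_low = ci_high = None
            ci_kind = "none"
        return EstimateResult(
            method="Greenland" if self.weighting == "pi10" else "Greenland(unit)",
            beta=beta,
            gamma=gamma,
            var_beta=var,
            ci_low=ci_low,
            ci_high=ci_high,
            ci_kind=ci_kind,
            n_informative=int(sub.multiplicity.sum()),
            converged=res.converged,
            diagnostics=diagnostics,
        )

    def _fit_dataset(self, dataset):
        result = self._point_fit(dataset)
        if self.n_bootstrap and self.n_bootstrap > 0:
            point = clone(self).set_params(n_bootstrap=0)
            low, high, record = bootstrap_percentiles(
                dataset,
                lambda ds: point.fit_result(ds).or_exposure,
                n_replicates=self.n_bootstrap,
                seed=self.seed,
            )
            result.ci_low, result.ci_high = low, high
            result.ci_kind = "bootstrap_percentile"
            if record["n_failed"]:
                result.diagnostics.append(
                    f"bootstrap: {record['n_failed']} of {self.n_bootstrap} "
                    "replicates had undefined pi10 and were skipped"
                )
        return result


def _comb_or_zero(n: int, k: int) -> int:
    if k < 0 or n < 0 or k > n:
        return 0
    return comb(n, k)


class VinesFarringtonOR(_CaseCrossoverEstimator):
    """Permutation likelihood weighted by population sequence probabilities.

    Each case's likelihood term compares the probability mass of the
    within-subject arrangements of its observed period values that match the
    observed case-period value against all arrangements supported by the
    ``patterns`` table (the constant permutation-multiplicity factor cancels,
    so distinct arrangements suffice; these are enumerated here by grouping
    on the case-period value with exact combinatorial counts).  Cases whose
    numerator support or its complement is empty fail the positivity
    condition and are excluded with a diagnostic.

    With ``adjust_confounder=True`` the joint (exposure, confounder) sequence
    probability factorises as the exposure-sequence probability times
    independent Bernoulli confounder terms, with P(z=1) equal to
    ``confounder_probs = (f0, f1)`` in unexposed/exposed periods.
    """

    def __init__(
        self,
        patterns: PatternProbabilityTable = None,
        adjust_confounder=False,
        confounder_probs=(0.2, 0.4),
        max_iter=100,
        tol=1e-10,
        ci_level=0.95,
    ):
        self.patterns = patterns
        self.adjust_confounder = adjust_confounder
        self.confounder_probs = confounder_probs
        self.max_iter = max_iter
        self.tol = tol
        self.ci_level = ci_level

    def _case_value_mass(self, case) -> dict[tuple, float]:
        """Total supported-arrangement probability by case-period value."""
        pat = self.patterns
        x = case.exposures
        n1 = sum(x)
        n0 = len(x) - n1
        mass: dict[tuple, float] = {}
        if not self.adjust_confounder:
            for seq, p in pat.items():
                if sum(seq) != n1:
                    continue
                key = (seq[0],)
                mass[key] = mass.get(key, 0.0) + p
            return mass
        f0, f1 = self.confounder_probs
        z = case.confounders
        n11 = sum(1 for xm, zm in zip(x, z) if xm == 1 and zm == 1)
        n01 = sum(1 for xm, zm in zip(x, z) if xm == 0 and zm == 1)
        qprob = (
            f1**n11 * (1 - f1) ** (n1 - n11) * f0**n01 * (1 - f0) ** (n0 - n01)
        )
        for seq, p in pat.items():
            if sum(seq) != n1:
                continue
            if seq[0] == 1:
                # distribute the observed z values over the arrangement's
                # exposed/unexposed positions; counts split by z at period 0
                c_z1 = _comb_or_zero(n1 - 1, n11 - 1) * _comb_or_zero(n0, n01)
                c_z0 = _comb_or_zero(n1 - 1, n11) * _comb_or_zero(n0, n01)
                pairs = [((1, 1), c_z1), ((1, 0), c_z0)]
            else:
                c_z1 = _comb_or_zero(n1, n11) * _comb_or_zero(n0 - 1, n01 - 1)
                c_z0 = _comb_or_zero(n1, n11) * _comb_or_zero(n0 - 1, n01)
                pairs = [((0, 1), c_z1), ((0, 0), c_z0)]
            for key, count in pairs:
                if count > 0 and qprob > 0:
                    mass[key] = mass.get(key, 0.0) + p * qprob * count
        return mass

    def _fit_dataset(self, dataset):
        if self.patterns is None:
            raise ValidationError("a PatternProbabilityTable is required")
        if self.patterns.sequence_length != dataset.M + 1:
            raise ValidationError(
                f"pattern table covers sequences of length "
                f"{self.patterns.sequence_length}, dataset has {dataset.M + 1} periods"
            )
        if self.adjust_confounder and not dataset.has_confounder:
            raise ValidationError("adjust_confounder=True requires a confounder")
        p_dim = 2 if self.adjust_confounder else 1
        rows_cov, rows_logw, rows_mult = [], [], []
        n_excluded = 0
        n_unsupported = 0
        max_rows = 4 if self.adjust_confounder else 2
        for case in dataset.cases:
            mass = self._case_value_mass(case)
            obs = (
                (case.exposures[0], case.confounders[0])
                if self.adjust_confounder
                else (case.exposures[0],)
            )
            w_obs = mass.get(obs, 0.0)
            w_rest = sum(p for v, p in mass.items() if v != obs)
            if w_obs <= 0:
                n_unsupported += case.weight_multiplicity
                continue
            if w_rest <= 0:
                n_excluded += case.weight_multiplicity
                continue
            values = [obs] + sorted(v for v in mass if v != obs and mass[v] > 0)
            cov = np.zeros((max_rows, p_dim))
            logw = np.full(max_rows, -np.inf)
            for r, v in enumerate(values):
                cov[r, :] = v
                logw[r] = math.log(mass[v])
            rows_cov.append(cov)
            rows_logw.append(logw)
            rows_mult.append(case.weight_multiplicity)
        diagnostics = []
        if n_excluded:
            diagnostics.append(
                f"positivity: {n_excluded} cases had no supported arrangement "
                "with a different case-period value and were excluded"
            )
        if n_unsupported:
            diagnostics.append(
                f"{n_unsupported} cases had an observed value with zero "
                "arrangement probability and were excluded"
            )
        if not rows_cov:
            raise NoInformativeCasesError(
                "the positivity condition failed for every case; the "
                "permutation likelihood cannot be maximised"
            )
        res = fit_conditional_logit(
            np.stack(rows_cov),
            np.array(rows_mult, dtype=float),
            log_weights=np.stack(rows_logw),
            tol=self.tol,
            max_iter=self.max_iter,
        )
        beta = float(res.theta[0])
        var = float(res.cov[0, 0]) if res.cov is not None else None
        if res.separated:
            beta = math.inf if res.theta[0] > 0 else -math.inf
            var = None
            diagnostics.append("separation: infinite estimate")
        if var is not None:
            ci_low, ci_high = _wald_ci(beta, var, self.ci_level)
            ci_kind = "wald"
        else:
            ci_low = ci_high = None
            ci_kind = "none"
        return EstimateResult(
            method="VF",
            beta=beta,
            gamma=float(res.theta[1]) if self.adjust_confounder else None,
            var_beta=var,
            ci_low=ci_low,
            ci_high=ci_high,
            ci_kind=ci_kind,
            n_informative=int(sum(rows_mult)),
            converged=res.converged,
            diagnostics=diagnostics,
        )


def bootstrap_percentiles(
    dataset: CaseCrossoverDataset,
    estimator: Callable[[CaseCrossoverDataset], float],
    n_replicates: int = 1000,
    seed: int = 0,
    percentiles: tuple[float, float] = (2.5, 97.5),
) -> tuple[float, float, dict]:
    """Case-resampling percentile interval.

    Cases are expanded to unit multiplicity and resampled with replacement;
    ``estimator`` maps each replicate dataset to an odds ratio (any
    weight/pi10 estimation happens inside it, so weight uncertainty is
    propagated).  Replicates where the estimator raises a degenerate-data or
    positivity error are recorded and skipped.  Deterministic given ``seed``.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    expanded = dataset.expand_multiplicities()
    n = len(expanded)
    rng = np.random.default_rng(seed)
    values = []
    n_failed = 0
    for _ in range(n_replicates):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(float(estimator(expanded.subset(idx))))
        except (DegenerateDataError, NoInformativeCasesError):
            n_failed += 1
    record = {
        "n_replicates": n_replicates,
        "n_success": len(values),
        "n_failed": n_failed,
        "values": values,
    }
    if n_failed > 0.10 * n_replicates:
        record["warning"] = (
            f"{n_failed}/{n_replicates} replicates failed; percentile "
            "interval may be unreliable"
        )
    if not values:
        raise DegenerateDataError("every bootstrap replicate failed")
    low, high = np.percentile(values, percentiles)
    return float(low), float(high), record


@dataclass
class BiasDiagnosis:
    """Comparison of the standard conditional-logistic and Mantel-Haenszel
    odds ratios; a large relative discrepancy signals bias from
    within-subject exposure dependency."""

    or_scl: float
    or_mh: float
    relative_discrepancy: float
    threshold: float
    flagged: bool


def diagnose_bias(
    dataset: CaseCrossoverDataset, threshold_fraction: float = 0.10
) -> BiasDiagnosis:
    """Flag likely bias when |OR_SCL - OR_MH| / OR_MH exceeds the threshold.

    Confounders are ignored in this comparison (both odds ratios are crude);
    they can be adjusted for afterwards with the weighting method.
    """
    crude = dataset.drop_confounder() if dataset.has_confounder else dataset
    or_scl = ConditionalLogitOR().fit(crude).or_
    or_mh = MantelHaenszelOR().fit(crude).or_
    disc = abs(or_scl - or_mh) / or_mh
    return BiasDiagnosis(
        or_scl=or_scl,
        or_mh=or_mh,
        relative_discrepancy=disc,
        threshold=threshold_fraction,
        flagged=disc > threshold_fraction,
    )


# ----------------------------------------------------------------------------
# thin functional wrappers
# ----------------------------------------------------------------------------

def fit_scl(dataset, adjust_confounder=False, **kwargs) -> EstimateResult:
    return ConditionalLogitOR(adjust_confounder=adjust_confounder, **kwargs).fit_result(dataset)


def fit_mh(dataset, stratify_by_confounder=False, **kwargs) -> EstimateResult:
    return MantelHaenszelOR(stratify_by_confounder=stratify_by_confounder, **kwargs).fit_result(dataset)


def fit_greenland(dataset, adjust_confounder=False, **kwargs) -> EstimateResult:
    return WeightedGreenlandOR(adjust_confounder=adjust_confounder, **kwargs).fit_result(dataset)


def fit_vf(dataset, patterns, adjust_confounder=False, **kwargs) -> EstimateResult:
    return VinesFarringtonOR(
        patterns=patterns, adjust_confounder=adjust_confounder, **kwargs
    ).fit_result(dataset)
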