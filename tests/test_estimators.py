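"""Estimator behaviour: worked examples, identities, and degeneracies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccxover import (
    CaseCrossoverDataset,
    CaseSeries,
    ConditionalLogitOR,
    DegenerateDataError,
    MantelHaenszelOR,
    NoInformativeCasesError,
    PatternProbabilityTable,
    VinesFarringtonOR,
    WeightedGreenlandOR,
    bootstrap_percentiles,
    compute_weights,
    diagnose_bias,
    fit_greenland,
    fit_mh,
    fit_scl,
    fit_vf,
    summarize_discordance,
)
from ccxover.simulate import (
    pattern_table_from_population,
    scenario_dataset,
    scenario_population,
)

MOTIVATING_OR = (7 + math.sqrt(145)) / 6  # root of 3*psi^2 - 7*psi - 8 = 0


def random_discordant_dataset(draw, max_cases=10, max_m=4):
    m = draw(st.integers(1, max_m))
    n = draw(st.integers(2, max_cases))
    cases = [
        CaseSeries(i, tuple(draw(st.integers(0, 1)) for _ in range(m + 1)),
                   None, draw(st.integers(1, 3)))
        for i in range(n)
    ]
    return CaseCrossoverDataset(cases)


class TestConditionalLogit:
    def test_motivating_example_underestimates_true_or(self, motivating):
        result = fit_scl(motivating)
        assert result.or_exposure == pytest.approx(MOTIVATING_OR, abs=1e-8)
        assert round(result.or_exposure, 1) == 3.2  # true OR is 4

    def test_cyclic_m21_overestimates(self, cyclic_21):
        assert fit_scl(cyclic_21).or_exposure == pytest.approx(6.02, abs=0.005)

    def test_m1_reduces_to_discordant_pair_ratio(self):
        ds = scenario_dataset("cyclic", 1)
        assert fit_scl(ds).or_exposure == pytest.approx(4.0, abs=1e-9)

    def test_separation_flagged(self):
        ds = CaseCrossoverDataset(
            [CaseSeries("a", (1, 0, 0)), CaseSeries("b", (1, 0, 0))]
        )
        result = fit_scl(ds)
        assert math.isinf(result.or_exposure)
        assert any("separation" in d for d in result.diagnostics)

    def test_sklearn_interface(self, motivating):
        est = ConditionalLogitOR(tol=1e-8)
        assert est.get_params()["tol"] == 1e-8
        fitted = est.fit(motivating.to_frame())  # DataFrame input
        assert fitted.or_ == pytest.approx(MOTIVATING_OR, rel=1e-6)
        assert fitted.converged_ and fitted.ci_[0] < fitted.or_ < fitted.ci_[1]


class TestWeights:
    def test_toy_weight_values(self, toy3):
        summary = summarize_discordance(toy3)
        weights = compute_weights(summary, toy3)
        wa = weights[0]  # case A: m1=2, m0=1
        assert (wa.m1, wa.m0) == (2, 1)
        assert wa.w1 == pytest.approx((2 / 3) / 2) and wa.w0 == 1.0
        assert wa.w1 * wa.m1 == pytest.approx(summary.pi10)
        assert wa.w0 * wa.m0 == 1.0

    def test_symmetric_case(self):
        ds = CaseCrossoverDataset(
            [CaseSeries("a", (1, 0)), CaseSeries("b", (0, 1))]
        )
        summary = summarize_discordance(ds)
        assert summary.pi10 == 1.0
        w = compute_weights(summary, ds)[0]
        assert w.w1 == w.w0

    def test_concordant_cases_have_no_weights(self, toy3):
        ds = CaseCrossoverDataset(list(toy3.cases) + [CaseSeries("d", (1, 1, 1))])
        weights = compute_weights(summarize_discordance(ds), ds)
        assert weights[-1] is None


class TestGreenlandWeighting:
    def test_toy_closed_form(self, toy3):
        result = fit_greenland(toy3)
        assert result.or_exposure == pytest.approx(3.0, abs=1e-12)

    def test_cyclic_unbiased_for_every_m(self):
        for m in range(1, 22):
            ds = scenario_dataset("cyclic", m)
            assert fit_greenland(ds).or_exposure == pytest.approx(4.0, abs=1e-6), m

    def test_null_dataset(self):
        ds = CaseCrossoverDataset(
            [CaseSeries("a", (1, 0)), CaseSeries("b", (0, 1))]
        )
        assert fit_greenland(ds).or_exposure == pytest.approx(1.0)

    def test_variance_at_m1_is_matched_pair_variance(self):
        ds = scenario_dataset("cyclic", 1)
        result = fit_greenland(ds)
        assert result.var_beta == pytest.approx(1 / 80 + 1 / 20)

    def test_unit_weights_reproduce_scl(self, cyclic_21):
        unit = WeightedGreenlandOR(weighting="unit").fit(cyclic_21)
        assert unit.beta_ == pytest.approx(fit_scl(cyclic_21).beta, abs=1e-8)

    def test_degenerate_data_raises(self):
        ds = CaseCrossoverDataset([CaseSeries("a", (1, 0)), CaseSeries("b", (1, 0))])
        with pytest.raises(DegenerateDataError):
            fit_greenland(ds)

    @settings(deadline=None, max_examples=50)
    @given(data=st.data())
    def test_identity_with_mantel_haenszel(self, data):
        """Closed-form weighting estimate equals the person-time ratio."""
        ds = random_discordant_dataset(data.draw)
        try:
            g = fit_greenland(ds)
        except DegenerateDataError:
            return
        mh = fit_mh(ds)
        assert g.beta == pytest.approx(mh.beta, abs=1e-10)

    def test_m1_collapse_all_three_equal(self):
        ds = scenario_dataset("cyclic", 1)
        scl, mh, g = fit_scl(ds), fit_mh(ds), fit_greenland(ds)
        assert scl.beta == pytest.approx(mh.beta, abs=1e-9)
        assert mh.beta == pytest.approx(g.beta, abs=1e-12)

    def test_adjusted_fit_recovers_exposure_and_confounder_effects(self):
        values = [
            fit_greenland(scenario_dataset("confounded", 21, seed=s), adjust_confounder=True)
            for s in range(5)
        ]
        ors = [v.or_exposure for v in values]
        orzs = [v.or_confounder for v in values]
        assert abs(np.mean(ors) - 4.0) < 0.15
        assert 1.5 < np.mean(orzs) < 2.5


class TestMantelHaenszel:
    def test_cyclic_m1_point_and_interval(self):
        result = fit_mh(scenario_dataset("cyclic", 1))
        assert result.or_exposure == pytest.approx(4.0)
        assert result.ci_low == pytest.approx(2.45, abs=0.005)
        assert result.ci_high == pytest.approx(6.53, abs=0.005)

    def test_toy_person_time_ratio(self, toy3):
        assert fit_mh(toy3).or_exposure == pytest.approx(3.0)

    def test_ignoring_confounder_overestimates(self):
        ds = scenario_dataset("confounded", 21, seed=2).drop_confounder()
        assert fit_mh(ds).or_exposure == pytest.approx(14 / 3, abs=1e-12)

    def test_stratification_deletes_mismatched_control_periods(self):
        ds = CaseCrossoverDataset(
            [
                CaseSeries("a", (1, 0, 0), (1, 1, 0)),
                CaseSeries("b", (0, 1, 1), (0, 0, 1)),
            ]
        )
        result = fit_mh(ds, stratify_by_confounder=True)
        # a keeps control period 1 only (PT10=1); b keeps period 1 only (PT01=1)
        assert result.or_exposure == pytest.approx(1.0)

    def test_zero_denominator_gives_infinite_estimate(self):
        ds = CaseCrossoverDataset(
            [CaseSeries("a", (1, 0, 0), None, 3), CaseSeries("b", (0, 0, 0))]
        )
        result = fit_mh(ds)
        assert math.isinf(result.or_exposure)
        assert any("infinite" in d for d in result.diagnostics)


class TestVinesFarrington:
    def test_cyclic_m3_with_population_table(self):
        ds = scenario_dataset("cyclic", 3)
        table = pattern_table_from_population(scenario_population("cyclic", 3))
        assert fit_vf(ds, table).or_exposure == pytest.approx(4.0, abs=1e-9)

    @pytest.mark.parametrize("m", [7, 10, 14, 17, 21])
    def test_positivity_fails_for_whole_cycles(self, m):
        ds = scenario_dataset("cyclic", m)
        table = pattern_table_from_population(scenario_population("cyclic", m))
        with pytest.raises(NoInformativeCasesError):
            fit_vf(ds, table)

    @pytest.mark.parametrize("m", [1, 2, 3, 4, 5, 6, 8, 9, 11, 12, 13])
    def test_unbiased_where_positivity_holds(self, m):
        ds = scenario_dataset("cyclic", m)
        table = pattern_table_from_population(scenario_population("cyclic", m))
        assert fit_vf(ds, table).or_exposure == pytest.approx(4.0, abs=1e-6)

    def test_global_exchangeability_reduces_to_scl(self):
        import itertools

        rng = np.random.default_rng(7)
        m, p = 3, 0.3
        ds = CaseCrossoverDataset(
            [CaseSeries(i, tuple((rng.random(m + 1) < p).astype(int)))
             for i in range(60)]
        )
        table = PatternProbabilityTable(
            {
                seq: p ** sum(seq) * (1 - p) ** (m + 1 - sum(seq))
                for seq in itertools.product((0, 1), repeat=m + 1)
            }
        )
        assert fit_vf(ds, table).beta == pytest.approx(fit_scl(ds).beta, abs=1e-8)

    def test_parameter_recovery_under_global_exchangeability(self):
        """With iid exposure both likelihoods are consistent for the true OR."""
        import itertools

        rng = np.random.default_rng(123)
        m, p, true_or = 3, 0.3, 2.0
        # sample case-period exposure from the case distribution induced by
        # an OR of 2, control exposures iid Bernoulli(p)
        p_case = true_or * p / (true_or * p + (1 - p))
        n = 4000
        x0 = (rng.random(n) < p_case).astype(int)
        ctrl = (rng.random((n, m)) < p).astype(int)
        ds = CaseCrossoverDataset(
            [CaseSeries(i, (int(x0[i]),) + tuple(ctrl[i])) for i in range(n)]
        )
        table = PatternProbabilityTable(
            {
                seq: p ** sum(seq) * (1 - p) ** (m + 1 - sum(seq))
                for seq in itertools.product((0, 1), repeat=m + 1)
            }
        )
        scl, vf = fit_scl(ds), fit_vf(ds, table)
        se = math.sqrt(scl.var_beta)
        assert abs(scl.beta - math.log(true_or)) < 3 * se
        assert abs(vf.beta - math.log(true_or)) < 3 * se

    def test_confounder_variant_near_truth(self):
        ds = scenario_dataset("confounded", 3, seed=5)
        table = pattern_table_from_population(scenario_population("confounded", 3))
        result = fit_vf(ds, table, adjust_confounder=True, confounder_probs=(0.2, 0.4))
        assert 3.0 < result.or_exposure < 5.5
        assert 1.0 < result.or_confounder < 3.5

    def test_table_length_mismatch_rejected(self, cyclic_21):
        table = pattern_table_from_population(scenario_population("cyclic", 3))
        with pytest.raises(Exception, match="length"):
            fit_vf(cyclic_21, table)


class TestBootstrap:
    @staticmethod
    def _or_g(ds):
        return fit_greenland(ds).or_exposure

    def test_single_replicate_degenerate_interval(self, cyclic_21):
        low, high, record = bootstrap_percentiles(cyclic_21, self._or_g, 1, seed=3)
        assert low == high == record["values"][0]

    def test_seed_determinism(self, cyclic_21):
        a = bootstrap_percentiles(cyclic_21, self._or_g, 50, seed=9)
        b = bootstrap_percentiles(cyclic_21, self._or_g, 50, seed=9)
        assert a[:2] == b[:2] and a[2]["values"] == b[2]["values"]

    def test_cyclic_interval_brackets_truth(self, cyclic_21):
        low, high, _ = bootstrap_percentiles(cyclic_21, self._or_g, 1000, seed=0)
        assert low < 4.0 < high
        assert low == pytest.approx(2.85, abs=0.5)
        assert high == pytest.approx(5.66, abs=0.7)


class TestBiasDiagnostic:
    def test_flagged_when_discrepant(self, cyclic_21):
        report = diagnose_bias(cyclic_21)
        assert report.relative_discrepancy == pytest.approx(0.505, abs=0.01)
        assert report.flagged

    def test_not_flagged_at_m1(self):
        report = diagnose_bias(scenario_dataset("cyclic", 1))
        assert report.relative_discrepancy == pytest.approx(0.0, abs=1e-9)
        assert not report.flagged

    def test_threshold_contract(self, cyclic_21):
        assert not diagnose_bias(cyclic_21, threshold_fraction=0.6).flagged


class TestBiasProperties:
    def test_scl_bias_exceeds_ten_percent_for_m6_and_m_ge_8(self):
        for m in [6] + list(range(8, 22)):
            or_scl = fit_scl(scenario_dataset("cyclic", m)).or_exposure
            assert abs(or_scl - 4.0) / 4.0 > 0.10, m

    def test_scl_bias_grows_with_study_period(self, cyclic_21):
        values = [
            fit_scl(scenario_dataset("cyclic", m)).or_exposure for m in (21, 69, 139)
        ]
        assert values[0] < values[1] < values[2]
        assert values[1] == pytest.approx(7.92, abs=0.01)
        assert values[2] == pytest.approx(8.71, abs=0.01)
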