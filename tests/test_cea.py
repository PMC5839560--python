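"""CER/ICER arithmetic, dominance, period aggregation, CE plane, Cochran's Q."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pharmcare_cea.cea import (
    Strategy,
    ThresholdConfig,
    ce_plane,
    cer,
    cochran_q,
    icer,
    period_aggregate,
    period_outcome_matrix,
)
from pharmcare_cea.costing import CohortYearSummary
from pharmcare_cea.errors import UndefinedResultError, ValidationError
from pharmcare_cea.report import reference_year_strategies


def summary(year, period, mean, prop):
    return CohortYearSummary(year=year, period=period,
                             mean_cost_per_patient=mean, sd_cost=0.0,
                             overall_cost=mean * 104, controlled_prop=prop,
                             n_complete=51, n_patients=104)


class TestCER:
    @pytest.mark.parametrize("cost,effect,expected", [
        (407.91, 0.98, 416.23),    # intervention year
        (100.0, 1.0, 100.0),
        (214.96, 0.93, 231.14),    # post-PC period
    ])
    def test_published_values(self, cost, effect, expected):
        assert cer(Strategy("s", cost, effect)) == pytest.approx(expected, abs=0.05)

    def test_zero_effect_undefined(self):
        with pytest.raises(UndefinedResultError):
            cer(Strategy("s", 10.0, 0.0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(cost=st.floats(0, 1e4), effect=st.floats(1e-3, 1.0))
    def test_cer_times_effect_is_cost(self, cost, effect):
        s = Strategy("s", cost, effect)
        assert cer(s) * effect == pytest.approx(cost, rel=1e-9, abs=1e-9)


class TestICER:
    def test_pc_year_vs_2006(self):
        c = icer(Strategy("2009", 407.91, 0.98), Strategy("2006", 188.89, 0.56))
        assert c.icer == pytest.approx(521.48, abs=0.05)
        assert c.dominance == "trade_off_ne"

    def test_dominant_2010_vs_2008(self):
        c = icer(Strategy("2010", 208.42, 0.98), Strategy("2008", 218.67, 0.64))
        assert c.icer == pytest.approx(-30.14, abs=0.05)
        assert c.dominance == "dominant"
        assert c.below_threshold

    def test_self_comparison_undefined(self):
        s = Strategy("s", 100.0, 0.5)
        c = icer(s, s)
        assert c.delta_cost == 0 and c.delta_effect == 0 and c.icer is None

    def test_zero_effect_gain_classified_by_cost(self):
        c = icer(Strategy("a", 120.0, 0.5), Strategy("b", 100.0, 0.5))
        assert c.icer is None and c.dominance == "dominated"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(c1=st.floats(0, 1e4), e1=st.floats(0.01, 0.99),
           c2=st.floats(0, 1e4), e2=st.floats(0.01, 0.99))
    def test_antisymmetry(self, c1, e1, c2, e2):
        """Swapping strategies negates the deltas and preserves the ICER."""
        a, b = Strategy("a", c1, e1), Strategy("b", c2, e2)
        fwd, rev = icer(a, b), icer(b, a)
        assert rev.delta_cost == pytest.approx(-fwd.delta_cost)
        assert rev.delta_effect == pytest.approx(-fwd.delta_effect)
        if fwd.icer is not None:
            assert rev.icer == pytest.approx(fwd.icer, rel=1e-9, abs=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(c1=st.floats(0, 1e4), e1=st.floats(0, 1),
           c2=st.floats(0, 1e4), e2=st.floats(0, 1))
    def test_dominance_exclusive(self, c1, e1, c2, e2):
        c = icer(Strategy("a", c1, e1), Strategy("b", c2, e2))
        assert c.dominance in {"dominant", "dominated", "trade_off_ne", "trade_off_sw"}

    def test_threshold_flag_uses_printed_threshold(self):
        thr = ThresholdConfig()
        ok = icer(Strategy("pc", 407.91, 0.982), Strategy("pre", 198.37, 0.544), thr)
        assert ok.below_threshold and ok.icer < thr.threshold

    def test_threshold_recomputation_warning(self):
        with pytest.warns(UserWarning):
            ThresholdConfig(gdp_per_capita=10_000.0, multiplier=3,
                            threshold=31_000.0)


class TestPeriodAggregate:
    PRE = [summary(2006, "pre_pc", 188.89, 0.56),
           summary(2007, "pre_pc", 187.55, 0.60),
           summary(2008, "pre_pc", 218.67, 0.64)]

    def test_pre_pc_period_with_published_effect(self):
        s = period_aggregate(self.PRE, "pre_pc", period_effect=0.544)
        assert s.cost == pytest.approx(198.37, abs=0.005)
        assert s.effect == 0.544

    def test_effect_defaults_to_mean_of_years(self):
        s = period_aggregate(self.PRE, "pre_pc")
        assert s.effect == pytest.approx(0.60)

    def test_single_year_period_is_identity(self):
        s = period_aggregate([summary(2009, "pc", 407.91, 0.98)], "pc")
        assert (s.cost, s.effect) == (407.91, 0.98)

    def test_post_pc_period(self):
        post = [summary(2010, "post_pc", 208.42, 0.98),
                summary(2011, "post_pc", 224.52, 0.88),
                summary(2012, "post_pc", 211.92, 0.88)]
        s = period_aggregate(post, "post_pc", period_effect=0.93)
        assert s.cost == pytest.approx(214.96, abs=0.05)

    def test_empty_period_rejected(self):
        with pytest.raises(ValidationError):
            period_aggregate(self.PRE, "pc")


class TestCEPlane:
    def test_quadrants_of_study_years(self):
        s = reference_year_strategies()
        plane = ce_plane([(s[2010], s[2008]), (s[2009], s[2006])])
        by_label = plane.set_index("label")
        assert by_label.loc["2010", "dominance"] == "dominant"
        assert by_label.loc["2010", "delta_cost"] < 0
        assert by_label.loc["2010", "delta_effect"] > 0
        assert by_label.loc["2009", "dominance"] == "trade_off_ne"

    def test_base_vs_base_is_origin(self):
        s = Strategy("s", 50.0, 0.5)
        plane = ce_plane([(s, s)])
        assert plane.loc[0, "delta_cost"] == 0 and plane.loc[0, "delta_effect"] == 0


class TestCochranQ:
    MATRIX = np.array([[1, 1, 1], [1, 0, 0], [1, 1, 0], [1, 0, 0]])

    def test_frozen_value_from_direct_formula(self):
        """Hand evaluation: C=(4,2,1), R=(3,1,2,1), N=7 gives Q = 14/3."""
        q = cochran_q(self.MATRIX)
        assert q.statistic == pytest.approx(14 / 3, rel=1e-12)
        assert q.df == 2 and not q.significant

    def test_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import cochrans_q
        rng = np.random.default_rng(6)
        x = (rng.random((30, 3)) < [0.5, 0.9, 0.9]).astype(int)
        expected = cochrans_q(x, return_object=False)[0]
        assert cochran_q(x).statistic == pytest.approx(expected, rel=1e-10)

    def test_identical_columns_give_zero(self):
        x = np.tile(np.array([[1], [0], [1], [1]]), (1, 3))
        assert cochran_q(x).statistic == 0.0

    def test_row_and_column_order_invariance(self):
        q = cochran_q(self.MATRIX).statistic
        rng = np.random.default_rng(0)
        for _ in range(5):
            rows = rng.permutation(4)
            cols = rng.permutation(3)
            assert cochran_q(self.MATRIX[rows][:, cols]).statistic == pytest.approx(q)

    def test_significance_threshold_for_three_conditions(self):
        # 5.99 is the chi-square 95th percentile at df = 2
        x = np.array([[1, 0, 0]] * 9 + [[1, 1, 1]] * 3)
        q = cochran_q(x)
        assert q.statistic > 5.99 and q.significant

    def test_all_ones_matrix_is_homogeneous(self):
        q = cochran_q(np.ones((4, 3)))
        assert q.statistic == 0.0 and not q.significant

    def test_non_binary_rejected(self):
        with pytest.raises(ValidationError):
            cochran_q(np.array([[1, 2], [0, 1]]))


class TestPeriodOutcomeMatrix:
    def test_majority_rule_and_matched_design(self):
        import pandas as pd
        frame = pd.DataFrame({
            "patient_id": [1] * 7 + [2] * 3,
            "year": list(range(2006, 2013)) + [2006, 2007, 2008],
            "controlled": [0, 0, 1, 1, 1, 1, 0] + [1, 1, 1],
        })
        period_map = {y: ("pre_pc" if y < 2009 else "pc" if y == 2009
                          else "post_pc") for y in range(2006, 2013)}
        m = period_outcome_matrix(frame, period_map)
        # patient 2 lacks pc/post-pc data and is dropped
        assert m.shape == (1, 3)
        assert m.tolist() == [[0.0, 1.0, 1.0]]
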