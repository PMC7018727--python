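import numpy as np
import pandas as pd
import pytest
from scipy.stats import linregress

from cinpipe.mitosis import fate_summary, frequency_regression, timing_summary
from cinpipe.simulate import FateModel, simulate_mitosis_cohort


def fate_table(rows):
    """rows: (annotations, terminal_fate) pairs -> minimal fate table."""
    return pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(len(rows))],
        "sample": "S", "condition": "untreated",
        "duration_min": 30.0,
        "annotations": [a for a, _ in rows],
        "terminal_fate": [f for _, f in rows],
    })


class TestTimingSummary:
    def test_symmetric_three_point_sample(self):
        s = timing_summary([10, 20, 30], min_n=1)
        assert s.mean == 20 and s.variance == 100 and s.skewness == 0

    def test_all_equal_sample_is_degenerate(self):
        s = timing_summary([25.0] * 10, min_n=1)
        assert s.variance == 0 and s.skewness == 0 and s.degenerate

    def test_exponential_skewness_matches_closed_form(self):
        rng = np.random.default_rng(1)
        s = timing_summary(rng.exponential(1.0, 100_000))
        assert abs(s.skewness - 2.0) < 0.05

    def test_percentile_ordering_invariant(self):
        rng = np.random.default_rng(2)
        s = timing_summary(rng.lognormal(3.5, 0.6, 500))
        assert s.p10 <= s.iqr_low <= s.median <= s.iqr_high <= s.p90

    def test_small_cohort_flagged_not_rejected(self):
        s = timing_summary([10, 20, 30, 40], min_n=100)
        assert s.low_n and s.n == 4

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            timing_summary([])


class TestFrequencyRegression:
    def test_flat_distribution_has_near_zero_slope(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 100, 200_000)
        _, slope, _, _ = frequency_regression(x, bin_width=10)
        assert abs(slope) < 1e-5

    def test_hand_computed_triangular_profile(self):
        # counts 5,4,3,2,1 in bins [0,10)...[40,50); OLS oracle on 5 points
        durations = []
        for k, c in enumerate([5, 4, 3, 2, 1]):
            durations += [k * 10 + 5.0] * c
        hist, slope, intercept, r2 = frequency_regression(durations, bin_width=10)
        mids = np.array([5.0, 15, 25, 35, 45])
        rel = np.array([5, 4, 3, 2, 1]) / 15
        expected = linregress(mids, rel)
        assert slope == pytest.approx(expected.slope)
        assert intercept == pytest.approx(expected.intercept)
        assert r2 == pytest.approx(expected.rvalue ** 2)

    def test_single_occupied_bin_is_an_error(self):
        with pytest.raises(ValueError):
            frequency_regression([11.0, 12.0, 13.0], bin_width=100)


class TestFateSummary:
    def test_all_normal_divisions(self):
        t = fate_table([("", "division")] * 10)
        comp = fate_summary(t)
        assert comp.pie_triple == (100.0, 0.0, 0.0)
        assert comp.abnormal_pct == 0.0

    def test_premature_anaphase_fixture_returns_12_pct(self):
        rows = [("premature_anaphase", "division")] * 12 + [("", "division")] * 88
        comp = fate_summary(fate_table(rows))
        assert comp.error_pct["premature_anaphase"] == pytest.approx(12.0)

    def test_bridge_plus_lagging_counts_as_other_defects(self):
        rows = [("anaphase_bridge;lagging_chromosome", "division"),
                ("anaphase_bridge", "division"),
                ("", "division"),
                ("", "division")]
        comp = fate_summary(fate_table(rows))
        assert comp.pie_triple == (50.0, 25.0, 25.0)

    def test_pie_triple_sums_to_100(self):
        rng = np.random.default_rng(4)
        anns = ["", "anaphase_bridge", "lagging_chromosome",
                "anaphase_bridge;multipolar"]
        rows = [(anns[i], "division") for i in rng.integers(0, 4, 97)]
        comp = fate_summary(fate_table(rows))
        assert sum(comp.pie_triple) == pytest.approx(100.0, abs=0.01)

    def test_interphase_cells_excluded_from_mitotic_denominator(self):
        rows = [("anaphase_bridge", "division")] * 2 + \
               [("", "interphase_no_mitosis")] * 6 + [("", "division")] * 2
        comp = fate_summary(fate_table(rows))
        assert comp.n_cells == 10 and comp.n_mitoses == 4
        assert comp.abnormal_pct == pytest.approx(50.0)
        assert comp.fate_pct["interphase_no_mitosis"] == pytest.approx(60.0)

    def test_record_order_and_doubling_invariance(self):
        rows = [("anaphase_bridge", "division"), ("", "division"),
                ("", "slippage"), ("multipolar", "death_in_mitosis")]
        t = fate_table(rows)
        base = fate_summary(t)
        shuffled = fate_summary(t.sample(frac=1, random_state=0))
        doubled = fate_summary(pd.concat([t, t], ignore_index=True))
        for other in (shuffled, doubled):
            assert other.pie_triple == base.pie_triple
            assert other.fate_pct == base.fate_pct
            assert other.error_pct == base.error_pct

    def test_no_matching_records_names_the_filter(self):
        with pytest.raises(ValueError, match="OCM99"):
            fate_summary(fate_table([("", "division")]), sample="OCM99")


class TestCrossModuleConsistency:
    def test_more_abnormal_mitoses_lengthen_mean_duration(self):
        # abnormal categories get a longer log-mean; cohorts with higher
        # abnormal probability should take longer on average
        dur = {"normal": (np.log(40), 0.3), "lagging_chromosome": (np.log(120), 0.3)}
        lo = simulate_mitosis_cohort(
            FateModel({"normal": 0.9, "lagging_chromosome": 0.1}, dur), 2000, seed=5)
        hi = simulate_mitosis_cohort(
            FateModel({"normal": 0.4, "lagging_chromosome": 0.6}, dur), 2000, seed=5)
        assert hi["duration_min"].mean() > lo["duration_min"].mean()
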