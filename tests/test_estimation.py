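"""Weighted prevalence, benchmark averaging and effectiveness measures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from survrake import (
    MISSING,
    BenchmarkTable,
    average_benchmarks,
    effectiveness_summary,
    margin_of_error_summary,
    weighted_prevalence,
)
from survrake.datasets import cohort_counts, expand_counts
from survrake.estimation import PrevalenceTable


def make_prev(char, cats, ests, halfwidth=1.0, scheme="s"):
    rows = [
        {
            "category": c,
            "n": 0,
            "estimate": e,
            "se": halfwidth / 1.96,
            "lower": e - halfwidth,
            "upper": e + halfwidth,
            "margin_of_error": halfwidth,
        }
        for c, e in zip(cats, ests)
    ]
    return PrevalenceTable(char, scheme, pd.DataFrame(rows), n=100)


class TestWeightedPrevalence:
    def test_published_male_percentage_and_ci(self):
        # 117,969 of 255,365 male -> 46.2 (46.0, 46.4) at one decimal
        sample = expand_counts(cohort_counts(), "sex")
        t = weighted_prevalence(sample, None, "sex")
        male = t.row("Male")
        assert round(male["estimate"], 1) == 46.2
        assert round(male["lower"], 1) == 46.0
        assert round(male["upper"], 1) == 46.4

    def test_single_category_degenerate(self):
        t = weighted_prevalence(pd.DataFrame({"x": ["a"] * 9}), None, "x")
        row = t.row("a")
        assert row["estimate"] == 100.0
        assert row["se"] == 0.0

    def test_four_unit_toy_hand_computation(self):
        sample = pd.DataFrame({"y": ["1", "0", "0", "1"]})
        w = np.array([1.0, 1.0, 2.0, 4.0])
        t = weighted_prevalence(sample, w, "y")
        row = t.row("1")
        p = 5 / 8
        assert row["estimate"] == pytest.approx(100 * p)
        resid = w * (np.array([1, 0, 0, 1]) - p) / w.sum()
        var = 4 / 3 * (resid**2).sum()
        assert row["se"] == pytest.approx(100 * np.sqrt(var))
        crit = stats.t.ppf(0.975, 3)
        assert row["upper"] == pytest.approx(
            min(100.0, 100 * p + crit * 100 * np.sqrt(var))
        )

    def test_uniform_weights_reproduce_unweighted(self, biased_sample):
        t_none = weighted_prevalence(biased_sample, None, "education")
        t_unif = weighted_prevalence(
            biased_sample, np.full(len(biased_sample), 7.3), "education"
        )
        pd.testing.assert_frame_equal(t_none.table, t_unif.table)

    def test_categories_sum_to_100(self, biased_sample):
        t = weighted_prevalence(biased_sample, None, "age_group")
        assert t.table["estimate"].sum() == pytest.approx(100.0)

    def test_missing_reported_as_own_category(self):
        sample = pd.DataFrame({"x": ["a", "a", MISSING, "b"]})
        t = weighted_prevalence(sample, None, "x")
        assert t.row(MISSING)["estimate"] == pytest.approx(25.0)

    def test_zero_total_weight_rejected(self):
        with pytest.raises(ValueError):
            weighted_prevalence(pd.DataFrame({"x": []}), None, "x")

    def test_coverage_at_nominal_level(self, rng):
        """95% CIs cover the true proportion ~95% of the time (SRS case)."""
        p_true, n, reps = 0.3, 300, 400
        hits = 0
        for _ in range(reps):
            y = rng.random(n) < p_true
            t = weighted_prevalence(pd.DataFrame({"x": np.where(y, "a", "b")}), None, "x")
            row = t.row("a")
            hits += row["lower"] <= 100 * p_true <= row["upper"]
        assert hits / reps == pytest.approx(0.95, abs=0.03)


class TestBenchmarkAveraging:
    def _bench(self, ests, source="b", ci=True):
        df = pd.DataFrame(
            {
                "characteristic": "x",
                "category": [f"c{i}" for i in range(len(ests))],
                "estimate": ests,
            }
        )
        if ci:
            df["lower"] = [e - 1 for e in ests]
            df["upper"] = [e + 1 for e in ests]
        return BenchmarkTable(source, df)

    def test_identical_tables_unchanged(self):
        b = self._bench([10.0, 20.0])
        out = average_benchmarks([b, b])
        assert out.table["estimate"].tolist() == [10.0, 20.0]
        assert out.has_ci

    def test_arithmetic_mean(self):
        out = average_benchmarks([self._bench([10.0]), self._bench([14.0])])
        assert out.table["estimate"].tolist() == [12.0]

    def test_missing_cis_drop_cis(self):
        out = average_benchmarks(
            [self._bench([10.0]), self._bench([14.0]), self._bench([12.0], ci=False)]
        )
        assert not out.has_ci
        assert "lower" not in out.table.columns

    def test_category_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different categories"):
            average_benchmarks([self._bench([10.0]), self._bench([10.0, 20.0])])


class TestEffectiveness:
    def test_moved_closer_for_smoking_style_row(self):
        # benchmark 13.9, unweighted 7.2, raked 9.5: the raked estimate moved
        # strictly closer, so the category counts toward measure 3
        bench = BenchmarkTable(
            "NDSHS",
            pd.DataFrame(
                {"characteristic": ["smoking"], "category": ["current"],
                 "estimate": [13.9], "lower": [12.7], "upper": [15.2]}
            ),
        )
        un = [make_prev("smoking", ["current"], [7.2], halfwidth=0.1, scheme="unweighted")]
        wt = {"full_raking": [make_prev("smoking", ["current"], [9.5], halfwidth=0.2)]}
        s = effectiveness_summary(bench, un, wt)
        assert s.row("full_raking")["moved_closer"] == 1

    def test_identical_weighted_scores_zero_moved_closer(self):
        bench = BenchmarkTable(
            "b",
            pd.DataFrame(
                {"characteristic": ["x"], "category": ["a"], "estimate": [10.0],
                 "lower": [9.0], "upper": [11.0]}
            ),
        )
        un = [make_prev("x", ["a"], [12.0], scheme="unweighted")]
        wt = {"w": [make_prev("x", ["a"], [12.0])]}
        s = effectiveness_summary(bench, un, wt)
        assert s.row("w")["moved_closer"] == 0

    def test_three_category_toy(self):
        bench = BenchmarkTable(
            "b",
            pd.DataFrame(
                {"characteristic": "x", "category": ["a", "b", "c"],
                 "estimate": [10.0, 20.0, 70.0],
                 "lower": [9.0, 19.0, 69.0], "upper": [11.0, 21.0, 71.0]}
            ),
        )
        un = [make_prev("x", ["a", "b", "c"], [12.0, 18.0, 70.0], scheme="unweighted")]
        wt = {"w": [make_prev("x", ["a", "b", "c"], [11.0, 19.0, 70.0])]}
        s = effectiveness_summary(bench, un, wt)
        row = s.row("w")
        assert row["moved_closer"] == 2
        assert row["abs_diff_median"] == 1.0

    def test_overlap_is_closed_interval(self):
        bench = BenchmarkTable(
            "b",
            pd.DataFrame(
                {"characteristic": ["x"], "category": ["a"], "estimate": [10.0],
                 "lower": [9.0], "upper": [11.0]}
            ),
        )
        # study CI exactly touches the benchmark upper bound
        un = [make_prev("x", ["a"], [12.0], halfwidth=1.0, scheme="unweighted")]
        s = effectiveness_summary(bench, un, {})
        assert s.row("unweighted")["overlap"] == 1

    def test_overlap_not_computed_without_benchmark_cis(self):
        bench = BenchmarkTable(
            "anhs",
            pd.DataFrame(
                {"characteristic": ["x"], "category": ["a"], "estimate": [10.0]}
            ),
        )
        un = [make_prev("x", ["a"], [12.0], scheme="unweighted")]
        s = effectiveness_summary(bench, un, {})
        assert np.isnan(s.row("unweighted")["overlap"])

    def test_missing_category_excluded(self):
        bench = BenchmarkTable(
            "b",
            pd.DataFrame(
                {"characteristic": ["x"], "category": ["a"], "estimate": [10.0],
                 "lower": [9.0], "upper": [11.0]}
            ),
        )
        un = [make_prev("x", ["a", MISSING], [12.0, 5.0], scheme="unweighted")]
        s = effectiveness_summary(bench, un, {})
        assert s.n_categories == 1

    def test_no_common_categories_rejected(self):
        bench = BenchmarkTable(
            "b",
            pd.DataFrame(
                {"characteristic": ["y"], "category": ["q"], "estimate": [10.0]}
            ),
        )
        un = [make_prev("x", ["a"], [12.0], scheme="unweighted")]
        with pytest.raises(ValueError, match="no common categories"):
            effectiveness_summary(bench, un, {})


class TestMarginOfError:
    def test_single_estimate(self):
        t = make_prev("x", ["a"], [50.0], halfwidth=2.0)
        out = margin_of_error_summary({"s": [t]})
        assert out["s"] == 2.0

    def test_mean_across_categories(self):
        t1 = make_prev("x", ["a"], [50.0], halfwidth=0.1)
        t2 = make_prev("y", ["b"], [50.0], halfwidth=0.3)
        out = margin_of_error_summary({"s": [t1, t2]})
        assert out["s"] == pytest.approx(0.2)

    def test_more_raking_constraints_do_not_shrink_margins(
        self, biased_sample, population_bundle
    ):
        """Full raking's margins of error are >= post-stratification's on
        average: more constraints mean more weight variation."""
        from survrake import JointCellTable, poststratify, rake, weighted_prevalence
        from survrake.datasets import BASIC_CHARACTERISTICS

        pop_fu, margins, _ = population_bundle
        cells = JointCellTable.from_sample(pop_fu, BASIC_CHARACTERISTICS)
        w_ps = poststratify(biased_sample, cells)
        w_full = rake(biased_sample, margins)
        outcomes = ["current_smoker", "fair_poor_health", "obese"]
        tables = {
            "poststrat": [weighted_prevalence(biased_sample, w_ps, o) for o in outcomes],
            "full": [weighted_prevalence(biased_sample, w_full, o) for o in outcomes],
        }
        moe = margin_of_error_summary(tables)
        assert moe["full"] >= moe["poststrat"]
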