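"""Post-stratification, raking, trimming and diagnostics.

The brute-force IPF oracle used here scales a dense contingency table one
margin at a time with explicit Python loops — independent of the production
raking path, which works on unit records with vectorised bincounts.
"""

import numpy as np
import pandas as pd
import pytest

from survrake import (
    MISSING,
    JointCellTable,
    MarginSet,
    PostStratifier,
    Raker,
    RakingConfig,
    WeightVector,
    exclude_missing,
    poststratify,
    rake,
    trim_weights,
    weight_diagnostics,
)
from survrake.weighting import RakingError, trim_bounds


def brute_force_ipf(table: np.ndarray, margins: list[np.ndarray],
                    tol: float = 1e-12, max_iter: int = 10_000) -> np.ndarray:
    """Classical IPF on a dense array, one axis at a time, looped naively."""
    t = table.astype(float).copy()
    for _ in range(max_iter):
        for axis, target in enumerate(margins):
            current = t.sum(axis=tuple(a for a in range(t.ndim) if a != axis))
            for j in range(t.shape[axis]):
                sl = [slice(None)] * t.ndim
                sl[axis] = j
                if current[j] > 0:
                    t[tuple(sl)] *= target[j] / current[j]
        ok = True
        for axis, target in enumerate(margins):
            current = t.sum(axis=tuple(a for a in range(t.ndim) if a != axis))
            if np.max(np.abs(current - target)) > tol:
                ok = False
        if ok:
            return t
    raise RuntimeError("oracle IPF did not converge")


class TestPostStratification:
    def test_single_cell(self):
        cells = JointCellTable(
            ["g"], pd.DataFrame({"g": ["all"], "count": [100.0]}), 100.0
        )
        sample = pd.DataFrame({"g": ["all"] * 10})
        wv = poststratify(sample, cells)
        assert np.allclose(wv.weights, 10.0)

    def test_two_cell_hand_computation(self):
        cells = JointCellTable(
            ["g"], pd.DataFrame({"g": ["a", "b"], "count": [80.0, 20.0]}), 100.0
        )
        sample = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5})
        wv = poststratify(sample, cells)
        assert np.allclose(wv.weights[:5], 16.0)
        assert np.allclose(wv.weights[5:], 4.0)
        shares = pd.Series(wv.weights).groupby(sample["g"]).sum() / wv.weights.sum()
        assert shares.tolist() == pytest.approx([0.8, 0.2])

    def test_empty_populated_cell_is_an_error(self):
        cells = JointCellTable(
            ["g"], pd.DataFrame({"g": ["a", "b"], "count": [80.0, 20.0]}), 100.0
        )
        sample = pd.DataFrame({"g": ["a"] * 5})
        with pytest.raises(RakingError, match="no sampled units"):
            poststratify(sample, cells)

    def test_weighted_joint_distribution_matches_population(self, toy_sample):
        pop = pd.concat([toy_sample] * 3, ignore_index=True)
        cells = JointCellTable.from_sample(pop, ["sex", "area"])
        est = PostStratifier(cells).fit(toy_sample)
        w = pd.Series(est.weights_)
        joint = w.groupby([toy_sample["sex"], toy_sample["area"]]).sum()
        pop_joint = pop.groupby(["sex", "area"]).size().astype(float)
        pd.testing.assert_series_equal(
            joint.sort_index(), pop_joint.sort_index(), check_names=False
        )

    def test_sklearn_param_interface(self):
        est = PostStratifier()
        assert "cells" in est.get_params()
        est.set_params(cells=None)
        with pytest.raises(RakingError):
            est.fit(pd.DataFrame({"g": ["a"]}))


class TestRaking:
    def test_fixed_point_sample_margins_equal_targets(self):
        sample = pd.DataFrame({"sex": ["M"] * 6 + ["F"] * 4})
        margins = MarginSet("t", 100.0, {"sex": pd.Series({"M": 60.0, "F": 40.0})})
        wv = rake(sample, margins)
        assert np.allclose(wv.weights, 10.0)
        assert wv.iterations == 1
        assert wv.trim_count == 0

    def test_2x2_agrees_with_brute_force_oracle(self):
        sample = pd.DataFrame(
            {"r": ["r1", "r1", "r2", "r2"], "c": ["c1", "c2", "c1", "c2"]}
        )
        margins = MarginSet(
            "t", 100.0,
            {"r": pd.Series({"r1": 60.0, "r2": 40.0}),
             "c": pd.Series({"c1": 70.0, "c2": 30.0})},
        )
        wv = rake(
            sample, margins,
            config=RakingConfig(tolerance=1e-12, trim_and_rerake_cycles=0),
        )
        oracle = brute_force_ipf(
            np.ones((2, 2)), [np.array([60.0, 40.0]), np.array([70.0, 30.0])]
        )
        got = wv.weights.reshape(2, 2)  # rows r1,r1? -> (r1c1, r1c2, r2c1, r2c2)
        assert np.max(np.abs(got - oracle)) < 1e-8

    @pytest.mark.parametrize("perm_seed", [0, 1, 2])
    def test_sweep_order_invariance_three_characteristics(self, perm_seed, rng):
        n = 400
        sample = pd.DataFrame(
            {
                "a": rng.choice(["a1", "a2", "a3"], n),
                "b": rng.choice(["b1", "b2"], n),
                "c": rng.choice(["c1", "c2", "c3", "c4"], n),
            }
        )
        tot = 10_000.0
        shares = {
            "a": {"a1": 0.2, "a2": 0.5, "a3": 0.3},
            "b": {"b1": 0.6, "b2": 0.4},
            "c": {"c1": 0.1, "c2": 0.2, "c3": 0.3, "c4": 0.4},
        }
        margins = {k: pd.Series(v) * tot for k, v in shares.items()}
        order = list(margins)
        np.random.default_rng(perm_seed).shuffle(order)
        m1 = MarginSet("t", tot, margins)
        m2 = MarginSet("t", tot, {k: margins[k] for k in order})
        cfg = RakingConfig(tolerance=1e-10, trim_and_rerake_cycles=0)
        w1 = rake(sample, m1, config=cfg).weights
        w2 = rake(sample, m2, config=cfg).weights
        assert np.max(np.abs(w1 - w2)) < 1e-6 * tot / len(sample)

    def test_raking_on_joint_cells_equals_poststratification(self, toy_sample):
        pop = pd.concat([toy_sample] * 5, ignore_index=True)
        cells = JointCellTable.from_sample(pop, ["sex", "area"])
        ps = poststratify(toy_sample, cells)
        # one characteristic whose categories are the cross-classification cells
        cell_id_pop = pop["sex"] + "|" + pop["area"]
        cell_id_sample = toy_sample["sex"] + "|" + toy_sample["area"]
        margins = MarginSet(
            "t", float(len(pop)),
            {"cell": cell_id_pop.value_counts().sort_index().astype(float)},
        )
        rk = rake(cell_id_sample.rename("cell").to_frame(), margins)
        assert np.allclose(rk.weights, ps.weights)

    def test_margins_match_targets_at_convergence(self, biased_sample, population_bundle):
        _, margins, _ = population_bundle
        wv = rake(biased_sample, margins)
        for char in margins.characteristics:
            target = margins.margins[char]
            got = pd.Series(wv.weights).groupby(biased_sample[char]).sum()
            rel = ((got - target).abs() / target).max()
            assert rel < 1e-5
        assert wv.weights.sum() == pytest.approx(margins.population_total, rel=1e-6)

    def test_empty_target_category_errors(self):
        sample = pd.DataFrame({"sex": ["M"] * 5})
        margins = MarginSet("t", 100.0, {"sex": pd.Series({"M": 60.0, "F": 40.0})})
        with pytest.raises(RakingError, match="no sampled units"):
            rake(sample, margins)

    def test_missing_values_must_be_excluded_first(self):
        sample = pd.DataFrame({"sex": ["M", "F", MISSING]})
        margins = MarginSet("t", 10.0, {"sex": pd.Series({"M": 6.0, "F": 4.0})})
        with pytest.raises(RakingError, match="exclude_missing"):
            rake(sample, margins)

    def test_nonconvergence_reports_worst_margin(self):
        sample = pd.DataFrame(
            {"a": ["a1", "a2"], "b": ["b1", "b2"]}
        )
        # structurally incompatible: a1 must carry 90 but its only unit is b1,
        # which must carry 10
        margins = MarginSet(
            "t", 100.0,
            {"a": pd.Series({"a1": 90.0, "a2": 10.0}),
             "b": pd.Series({"b1": 10.0, "b2": 90.0})},
        )
        with pytest.raises(RakingError, match="did not converge"):
            rake(sample, margins, config=RakingConfig(max_iterations=50))


class TestTrimming:
    def test_degenerate_iqr_trims_outlier_to_median(self):
        wv = WeightVector(np.array([1.0, 1, 1, 1, 100]), "raking")
        out = trim_weights(wv, 6.0)
        assert out.trim_bound == 1.0
        assert out.weights.tolist() == [1, 1, 1, 1, 1]
        assert out.trim_count == 1

    def test_equal_weights_untouched(self):
        wv = WeightVector(np.full(8, 3.0), "raking")
        out = trim_weights(wv)
        assert out.trim_count == 0
        assert np.allclose(out.weights, 3.0)

    def test_type7_quartiles_give_bound_15(self):
        # median 3, IQR 2 under linear-interpolation quartiles -> bound 3+6*2=15
        lo, hi = trim_bounds(np.array([1.0, 2, 3, 4, 5]), 6.0)
        assert hi == 15.0
        out = trim_weights(WeightVector(np.array([1.0, 2, 3, 4, 5]), "raking"), 6.0)
        assert out.trim_count == 0

    def test_lower_bound_inert_when_nonpositive(self):
        w = np.array([1.0, 1, 1, 1, 100])
        lo, hi = trim_bounds(w, 6.0)
        assert lo <= 0 or lo <= w.min()  # lower rule cannot fire here
        out = trim_weights(WeightVector(w, "raking"), 6.0)
        assert (out.weights > 0).all()

    def test_rake_trim_cycle_respects_bound(self, rng):
        # one rare category forces a large weight that must be trimmed
        n = 200
        sample = pd.DataFrame({"g": ["a"] * (n - 1) + ["b"]})
        margins = MarginSet(
            "t", 1000.0, {"g": pd.Series({"a": 500.0, "b": 500.0})}
        )
        with pytest.warns(RuntimeWarning):
            wv = rake(sample, margins, config=RakingConfig(trim_and_rerake_cycles=2))
        assert wv.trim_count > 0
        assert not wv.within_trim_bound


class TestTrimmingProperties:
    """Invariants of the trim rule over arbitrary positive weight vectors."""

    from hypothesis import given, settings, strategies as st

    @given(
        st.lists(st.floats(min_value=0.01, max_value=1e6), min_size=2, max_size=50)
    )
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_trimmed_weights_within_bound_and_positive(self, ws):
        wv = WeightVector(np.array(ws), "raking")
        out = trim_weights(wv, 6.0)
        lo, hi = trim_bounds(np.array(ws), 6.0)
        assert (out.weights <= hi + 1e-9).all()
        assert (out.weights > 0).all()
        # trimming never reorders weights
        assert (np.argsort(out.weights, kind="stable")
                == np.argsort(np.clip(ws, max(lo, 0), hi), kind="stable")).all()

    @given(st.floats(min_value=0.01, max_value=100.0), st.integers(2, 30))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_equal_weights_are_a_fixed_point(self, w, n):
        wv = WeightVector(np.full(n, w), "raking")
        out = trim_weights(wv)
        assert np.allclose(out.weights, w)
        assert out.trim_count == 0


class TestExclusionsAndDiagnostics:
    def test_exclusion_arithmetic(self):
        n, n_missing = 1000, 37
        df = pd.DataFrame({"sex": ["M"] * n})
        df.loc[: n_missing - 1, "sex"] = MISSING
        out, count = exclude_missing(df, ["sex"])
        assert count == n_missing
        assert len(out) == n - n_missing

    def test_no_missing_is_identity(self):
        df = pd.DataFrame({"sex": ["M", "F"]})
        out, count = exclude_missing(df, ["sex"])
        assert count == 0
        pd.testing.assert_frame_equal(out, df)

    def test_all_missing_empty_table_then_raking_fails_cleanly(self):
        df = pd.DataFrame({"sex": [MISSING, MISSING]})
        out, count = exclude_missing(df, ["sex"])
        assert count == 2 and len(out) == 0
        margins = MarginSet("t", 10.0, {"sex": pd.Series({"M": 10.0})})
        with pytest.raises(RakingError):
            rake(out, margins)

    def test_uniform_weights_diagnostics(self):
        d = weight_diagnostics(np.full(7, 10.0))
        assert d["cv"] == 0
        assert d["design_effect"] == 1
        assert d["sum"] == 70

    def test_two_point_diagnostics(self):
        d = weight_diagnostics(np.array([1.0, 3.0]))
        assert d["cv"] == pytest.approx(0.5)
        assert d["design_effect"] == pytest.approx(1.25)

    def test_post_trim_max_at_most_bound(self):
        w = np.array([1.0, 1, 2, 3, 50.0])
        out = trim_weights(WeightVector(w, "raking"), 6.0)
        assert weight_diagnostics(out)["max"] <= out.trim_bound
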