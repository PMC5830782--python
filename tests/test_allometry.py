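import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import pouchyoung as py
from pouchyoung.allometry import THYLACINE_PUBLISHED


def series(component, points):
    return [py.ProportionPoint(age, component, pct) for age, pct in points]


class TestProportions:
    def test_percent_of_trunk(self):
        assert py.percent_trunk_length(58, 100) == pytest.approx(58)
        assert py.percent_trunk_length(42.5, 42.5) == pytest.approx(100)
        # neonate forelimb at 58% of trunk length
        assert py.percent_trunk_length(0.58 * 31.0, 31.0) == pytest.approx(58)

    def test_nonpositive_trunk_rejected(self):
        with pytest.raises(py.DomainError):
            py.percent_trunk_length(10, 0)


class TestCrossover:
    def test_published_limb_series_cross_just_before_eight_weeks(self):
        fore = series("forelimb", [(5.25, 60), (9.5, 65)])
        hind = series("hindlimb", [(5.25, 55), (9.5, 68)])
        cross = py.crossover_time(fore, hind)
        assert cross.age == pytest.approx(7.90625)
        assert not cross.tangent
        assert round(cross.age) == 8

    def test_identical_series_never_cross(self):
        a = series("forelimb", [(1, 50), (2, 60)])
        b = series("hindlimb", [(1, 50), (2, 60)])
        assert py.crossover_time(a, b) is None

    def test_parallel_series_never_cross(self):
        a = series("forelimb", [(1, 50), (2, 60)])
        b = series("hindlimb", [(1, 40), (2, 50)])
        assert py.crossover_time(a, b) is None

    def test_touch_without_crossing_reports_tangent(self):
        a = series("forelimb", [(1, 50), (2, 55), (3, 50)])
        b = series("hindlimb", [(1, 45), (2, 55), (3, 45)])
        cross = py.crossover_time(a, b)
        assert cross == py.Crossover(2.0, tangent=True)

    def test_mismatched_stage_grids_rejected(self):
        a = series("forelimb", [(1, 50), (2, 60)])
        b = series("hindlimb", [(1, 40), (3, 50)])
        with pytest.raises(py.ValidationError, match="grid"):
            py.crossover_time(a, b)

    @given(
        st.lists(
            st.tuples(st.floats(10, 90), st.floats(10, 90)),
            min_size=2,
            max_size=6,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_crossover_is_antisymmetric(self, pcts):
        ages = list(range(1, len(pcts) + 1))
        a = series("forelimb", list(zip(ages, (p[0] for p in pcts))))
        b = series("hindlimb", list(zip(ages, (p[1] for p in pcts))))
        ab = py.crossover_time(a, b)
        ba = py.crossover_time(b, a)
        assert ab == ba


class TestRMAFit:
    def test_exact_line(self):
        res = py.rma_fit([0, 1, 2], [0, 2, 4])
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_sd_ratio_slope(self):
        res = py.rma_fit([0, 1, 2], [0, 1, 3])
        assert res.slope == pytest.approx(math.sqrt(21 / 9), abs=1e-4)
        assert res.intercept == pytest.approx(-0.194192, abs=1e-6)

    def test_constant_axis_is_degenerate(self):
        with pytest.raises(py.DomainError):
            py.rma_fit([1, 1, 1], [0, 1, 2])

    def test_negative_correlation_gives_negative_slope(self):
        res = py.rma_fit([0, 1, 2, 3], [3.0, 2.1, 0.9, 0.1])
        assert res.slope < 0

    @given(
        arrays(float, 8, elements=st.floats(-3, 3)),
        arrays(float, 8, elements=st.floats(-3, 3)),
    )
    @settings(max_examples=120, deadline=None)
    def test_matches_ols_oracle_and_axis_swap(self, x, y):
        # independent oracle: RMA slope equals OLS slope divided by |r|
        if np.std(x, ddof=1) < 1e-6 or np.std(y, ddof=1) < 1e-6:
            return
        r = np.corrcoef(x, y)[0, 1]
        if abs(r) < 1e-6:
            return
        ols_slope = np.polyfit(x, y, 1)[0]
        res = py.rma_fit(x, y)
        assert res.slope == pytest.approx(ols_slope / abs(r), abs=1e-10, rel=1e-10)
        assert py.rma_fit(y, x).slope == pytest.approx(1 / res.slope, rel=1e-12)

    @given(st.floats(-5, 5), st.floats(-5, 5))
    @settings(max_examples=40, deadline=None)
    def test_slope_invariant_under_axis_shifts(self, dx, dy):
        x = np.array([0.1, 0.9, 2.2, 3.0, 4.1])
        y = np.array([0.3, 1.2, 2.4, 3.8, 4.7])
        base = py.rma_fit(x, y).slope
        assert py.rma_fit(x + dx, y + dy).slope == pytest.approx(base, rel=1e-12)


class TestRMABootstrap:
    def test_collinear_data_has_degenerate_ci(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = py.rma_bootstrap(x, 1.2 * x + 0.3, n_boot=500, seed=0)
        assert res.ci_low == res.ci_high == pytest.approx(res.slope)
        assert res.allometry_class == "positive"

    def test_fixed_seed_is_deterministic(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 4, 13)
        y = 0.6 + 1.2 * x + rng.normal(0, 0.05, 13)
        a = py.rma_bootstrap(x, y, n_boot=1000, seed=42)
        b = py.rma_bootstrap(x, y, n_boot=1000, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        c = py.rma_bootstrap(x, y, n_boot=1000, seed=43)
        assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(7)
        for rep in range(5):
            x = rng.uniform(0, 3, 10)
            y = 0.2 + 0.9 * x + rng.normal(0, 0.2, 10)
            res = py.rma_bootstrap(x, y, n_boot=1000, seed=rep)
            assert res.ci_low <= res.slope <= res.ci_high

    def test_bias_corrected_interval_available(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 4, 13)
        y = 0.6 + 1.2 * x + rng.normal(0, 0.05, 13)
        res = py.rma_bootstrap(x, y, n_boot=2000, seed=1, ci_method="bca")
        assert res.ci_low <= res.slope <= res.ci_high

    def test_too_few_points_rejected(self):
        with pytest.raises(py.ValidationError):
            py.rma_bootstrap([0, 1], [0, 1], seed=0)


class TestClassification:
    @pytest.mark.parametrize(
        "slope,ci,expected",
        [
            (1.198, (1.154, 1.242), "positive"),   # thylacine humerus
            (1.240, (0.974, 1.347), "isometry"),   # black bear humerus
            (0.800, (0.738, 0.875), "negative"),   # wildebeest humerus
        ],
    )
    def test_ci_rule_matches_published_labels(self, slope, ci, expected):
        res = py.RMAResult(
            "humerus", slope, 0.0, 0.99, 13, ci_low=ci[0], ci_high=ci[1],
            n_boot=10_000, ci_source="bootstrap",
        )
        assert py.classify_allometry(res) == expected

    @pytest.mark.parametrize(
        "slope,expected", [(1.2, "positive"), (0.8, "negative"), (1.0, "isometry")]
    )
    def test_slope_only_rule_without_ci(self, slope, expected):
        res = py.RMAResult("femur", slope, 0.0, 0.95, 20, ci_source="absent")
        assert py.classify_allometry(res) == expected


class TestComparisonTable:
    def own_results(self):
        out = []
        for bone in ("humerus", "radius", "femur", "tibia"):
            x = np.array([0.0, 1.0, 2.0, 3.0])
            out.append(py.rma_bootstrap(x, 1.2 * x + 0.6, n_boot=200, seed=0, bone=bone))
        return out

    def test_four_own_plus_ten_literature_rows(self):
        lit = py.literature_rows("humerus") + py.literature_rows("radius")[:1]
        assert len(lit) == 10
        table = py.build_comparison_table(self.own_results(), lit)
        assert len(table) == 14
        assert (table["reference"] == "this study").sum() == 4

    def test_own_rows_alone(self):
        assert len(py.build_comparison_table(self.own_results())) == 4

    def test_duplicate_taxon_bone_collides(self):
        lit = py.literature_rows("humerus")
        with pytest.raises(py.ValidationError, match="duplicate"):
            py.build_comparison_table(self.own_results(), lit + lit[:1])

    def test_packaged_literature_labels_are_verbatim(self):
        # published slope-only labels are stored, not recomputed: the same
        # slope-only rule cannot reproduce e.g. opossum radius 0.85 -> iso
        # alongside possum humerus 0.887 -> negative
        rows = {(r.taxon, r.bone): r for r in py.literature_rows()}
        assert rows[("Monodelphis domestica", "radius")].allometry_class == "isometry"
        assert rows[("Trichosurus vulpecula", "humerus")].allometry_class == "negative"
        assert len(py.literature_rows()) == 35

    def test_text_rendering_reports_published_thylacine_slopes(self):
        table = py.build_comparison_table([], THYLACINE_PUBLISHED)
        text = py.render_comparison_text(table)
        assert "1.198" in text and "1.403" in text
        assert "nd" not in text.splitlines()[2]
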