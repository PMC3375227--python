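"""Dominance, front extraction vs brute force, screening, trade-off geometry."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promiscreen import (
    ActivityTable,
    PointSet,
    TradeoffLine,
    dominates,
    fit_tradeoff_line,
    max_connecting_line,
    pareto_front,
    pareto_front_brute_force,
    pareto_mask,
    screening_round,
    triangle_statistic,
)


def _pointset(values, scale="log"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return PointSet(
        ids=list(range(len(values))),
        values=values,
        objectives=[f"obj{k}" for k in range(values.shape[1])],
        scale=scale,
    )


# three-variant worked example: b is dominated by a; a and c trade off
THREE_VARIANT_EXAMPLE = {"a": (2.0, 3.0), "b": (1.0, 1.0), "c": (3.0, 1.5)}


class TestDominance:
    def test_three_variant_example(self):
        assert dominates(THREE_VARIANT_EXAMPLE["a"], THREE_VARIANT_EXAMPLE["b"])
        assert not dominates(THREE_VARIANT_EXAMPLE["c"], THREE_VARIANT_EXAMPLE["a"])
        assert not dominates(THREE_VARIANT_EXAMPLE["a"], THREE_VARIANT_EXAMPLE["c"])

    def test_point_never_dominates_itself(self):
        x = (1.5, 2.5)
        assert not dominates(x, x)

    def test_weak_mode_requires_one_strict_gain(self):
        assert dominates((2, 2), (2, 1), weak=True)
        assert not dominates((2, 2), (2, 2), weak=True)
        assert not dominates((2, 2), (2, 1))  # strict mode: ties block

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dominates((1, 2), (1, 2, 3))


class TestFrontExtraction:
    def test_three_variant_front(self):
        ps = PointSet(
            ids=list(THREE_VARIANT_EXAMPLE),
            values=np.array(list(THREE_VARIANT_EXAMPLE.values())),
            objectives=["primary", "promiscuous"],
        )
        front = pareto_front(ps)
        assert set(front.ids) == {"a", "c"}

    def test_identical_points_all_retained(self):
        ps = _pointset([[1, 1]] * 4)
        assert len(pareto_front(ps)) == 4

    def test_sweep_matches_brute_force_oracle(self, rng):
        for trial in range(100):
            n = int(rng.integers(2, 2001))
            k = int(rng.integers(2, 5))
            vals = rng.normal(size=(n, k))
            if trial % 7 == 0:  # inject coordinate ties
                vals = np.round(vals, 1)
            mask = pareto_mask(vals)
            if n <= 300:  # brute force on the smaller instances
                oracle = pareto_front_brute_force(_pointset(vals))
                assert sorted(oracle.ids) == sorted(np.flatnonzero(mask))
            # front members never dominate each other
            fr = vals[mask]
            assert not any(
                dominates(fr[i], fr[j])
                for i in range(len(fr))
                for j in range(len(fr))
                if i != j
            ) or len(fr) < 2

    def test_every_excluded_point_is_dominated(self, rng):
        vals = rng.normal(size=(300, 2))
        mask = pareto_mask(vals)
        fr = vals[mask]
        for v in vals[~mask]:
            assert any(dominates(f, v) for f in fr)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(-50, 50), st.integers(-50, 50), st.integers(-50, 50)
            ),
            min_size=1,
            max_size=60,
        )
    )
    def test_idempotence_property(self, pts):
        ps = _pointset(np.array(pts, dtype=float))
        front = pareto_front(ps)
        again = pareto_front(front)
        assert sorted(map(tuple, again.values)) == sorted(map(tuple, front.values))

    def test_dominated_point_never_changes_front(self, rng):
        vals = rng.normal(size=(50, 2))
        front = pareto_front(_pointset(vals))
        worst = vals.min(axis=0) - 1.0
        extended = np.vstack([vals, worst])
        front2 = pareto_front(_pointset(extended))
        assert sorted(map(tuple, front.values)) == sorted(map(tuple, front2.values))

    def test_globally_dominating_point_becomes_sole_member(self, rng):
        vals = rng.normal(size=(50, 2))
        best = vals.max(axis=0) + 1.0
        front = pareto_front(_pointset(np.vstack([vals, best])))
        assert len(front) == 1
        np.testing.assert_array_equal(front.values[0], best)


class TestScreeningRound:
    def _measured(self, genotypes):
        return ActivityTable(
            genotypes=genotypes,
            activities=pd.DataFrame(
                {
                    "primary": np.arange(len(genotypes), dtype=float),
                    "promiscuous": -np.arange(len(genotypes), dtype=float),
                }
            ),
        )

    def test_all_candidates_measured_gives_empty_request(self):
        measured = self._measured([(0, 0), (1, 0)])
        req = screening_round(measured, [(0, 0), (1, 0)])
        assert len(req) == 0

    def test_request_contains_only_new_candidates(self):
        measured = self._measured([(0, 0), (1, 0)])
        req = screening_round(measured, [(1, 0), (0, 1), (1, 1), (0, 1)])
        assert req["genotype"].tolist() == ["01", "11"]

    def test_merged_expansion_matches_counts(self):
        """29 measured + 11 new candidates merge to a 40-variant table."""
        from promiscreen import enumerate_library

        lib = enumerate_library(10)
        measured = self._measured(lib[:29])
        new = self._measured(lib[29:40])
        merged = measured.merged_with(new)
        assert len(merged) == 40

    def test_round_two_front_dominates_or_equals_round_one(self, rng):
        """Adding non-dominated candidates never degrades the measured front."""
        vals = rng.normal(size=(60, 2))
        first = _pointset(vals[:40])
        full = _pointset(vals)
        f1 = pareto_front(first)
        f2 = pareto_front(full)
        # every round-1 front point is dominated by or present in round 2
        for v in f1.values:
            assert any(
                np.allclose(v, w) or dominates(w, v) for w in f2.values
            )


class TestTradeoffLine:
    def test_two_points_interpolated_exactly(self):
        front = _pointset([[0.0, 1.0], [1.0, 0.0]], scale="linear")
        line = fit_tradeoff_line(front)
        assert line.slope == pytest.approx(-1.0)
        assert line.intercept == pytest.approx(1.0)
        assert line.rss == pytest.approx(0.0, abs=1e-12)

    def test_collinear_front_has_zero_residual(self):
        x = np.linspace(0.1, 0.9, 7)
        front = _pointset(np.column_stack([x, 1 - x]), scale="linear")
        line = fit_tradeoff_line(front)
        assert line.rss == pytest.approx(0.0, abs=1e-12)

    def test_log_scale_rejected(self):
        front = _pointset([[0, 1], [1, 0]], scale="log")
        with pytest.raises(ValueError):
            fit_tradeoff_line(front)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            fit_tradeoff_line(_pointset([[1, 1]], scale="linear"))

    def test_max_connecting_line_joins_axis_maxima(self):
        pts = _pointset([[0.8, 0.1], [0.2, 0.4], [0.5, 0.2]], scale="linear")
        line = max_connecting_line(pts)
        assert line(0.0) == pytest.approx(0.4)
        assert line(0.8) == pytest.approx(0.0, abs=1e-12)


class TestTriangleStatistic:
    def test_empty_set_rejected_but_zero_below_gives_one(self):
        pts = _pointset([[2.0, 2.0]], scale="linear")
        line = TradeoffLine(slope=-1.0, intercept=1.0)
        stat = triangle_statistic(pts, line)
        assert stat.count_below == 0
        assert stat.null_probability == 1.0

    def test_forty_points_below_line_closed_form(self, rng):
        x = rng.uniform(0, 1, 40)
        y = (1 - x) * rng.uniform(0, 1, 40)  # strictly inside the triangle
        pts = _pointset(np.column_stack([x, y]), scale="linear")
        stat = triangle_statistic(pts, TradeoffLine(-1.0, 1.0))
        assert stat.ndp == 40
        assert stat.count_below == 40
        assert stat.null_probability == pytest.approx(9.094947e-13, rel=1e-6)

    def test_boundary_points_count_at_zero_tolerance(self):
        pts = _pointset([[0.5, 0.5]], scale="linear")
        stat = triangle_statistic(pts, TradeoffLine(-1.0, 1.0))
        assert stat.count_below == 1
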