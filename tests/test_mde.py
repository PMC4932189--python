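"""MDE binning, smoothing, stratification and the recency-bias truncation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdeflux import (
    DispersalEvent,
    EventTable,
    MDESeries,
    TimeGrid,
    avian_bias_cutoff,
    compute_mde,
    round_interval,
    smooth_series,
    stratified_mde,
    truncate_series,
)
from conftest import random_table
from oracles import naive_mde_counts


def ev(eid, old, young, direction="asia_to_india", taxon="plant"):
    return DispersalEvent(eid, "ds", taxon, direction, old, young)


def ascending(series: MDESeries) -> np.ndarray:
    """Values indexed by age 0..t_max (series are stored oldest-first)."""
    return series.values[::-1]


class TestRoundInterval:
    @pytest.mark.parametrize(
        "old, young, expected",
        [
            (2.4, 0.6, (1, 2)),
            (5.0, 5.0, (5, 5)),
            (3.5, 0.5, (1, 4)),  # half-away-from-zero ties
            (0.4, 0.0, (0, 0)),
            (69.5, 68.49, (68, 70)),
        ],
    )
    def test_nearest_million_with_tie_rule(self, old, young, expected):
        assert round_interval(ev("x", old, young)) == expected

    @settings(max_examples=100, deadline=None)
    @given(young=st.floats(0, 200), width=st.floats(0, 100))
    def test_rounding_is_monotone_on_bounds(self, young, width):
        y, o = round_interval(ev("x", young + width, young))
        assert y <= o


class TestComputeMDE:
    def test_empty_table_gives_zero_series(self):
        s = compute_mde(EventTable(), TimeGrid(10))
        assert np.all(s.values == 0) and len(s.values) == 11

    def test_single_event_covers_its_rounded_slices(self):
        s = compute_mde(EventTable([ev("a", 2.4, 0.6)]), TimeGrid(10))
        vals = ascending(s)
        assert list(vals) == [0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0]

    def test_two_overlapping_events_sum(self):
        table = EventTable([ev("a", 5.0, 0.0), ev("b", 3.0, 2.0)])
        vals = ascending(compute_mde(table, TimeGrid(5)))
        assert list(vals) == [1, 1, 2, 2, 1, 1]

    def test_event_above_span_dropped_with_warning(self):
        table = EventTable([ev("a", 80.0, 75.0), ev("b", 72.0, 65.0)])
        with pytest.warns(UserWarning, match="older than the 70"):
            s = compute_mde(table, TimeGrid(70))
        vals = ascending(s)
        # straddling event clipped to [65, 70]; the other excluded entirely
        assert vals[65:71].tolist() == [1] * 6
        assert vals.sum() == 6

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(0, 60))
    def test_matches_bruteforce_double_loop(self, seed, n):
        import warnings

        table = random_table(np.random.default_rng(seed), n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = ascending(compute_mde(table, TimeGrid(70)))
        expected = naive_mde_counts([round_interval(e) for e in table], 70)
        assert got.tolist() == expected

    def test_mass_identity(self, rng):
        table = random_table(rng, 40)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = compute_mde(table, TimeGrid(70))
        expected = 0
        for e in table:
            y, o = round_interval(e)
            if y > 70:
                continue
            expected += min(o, 70) - y + 1
        assert s.values.sum() == expected

    def test_constant_age_shift_translates_series(self):
        base = [ev(f"e{i}", 10.0 + i, 5.0 + i) for i in range(5)]
        shifted = [ev(f"e{i}", 13.0 + i, 8.0 + i) for i in range(5)]
        a = ascending(compute_mde(EventTable(base), TimeGrid(70)))
        b = ascending(compute_mde(EventTable(shifted), TimeGrid(70)))
        assert a[5:60].tolist() == b[8:63].tolist()


class TestSmoothing:
    def test_constant_series_is_fixed_point(self):
        g = TimeGrid(20)
        s = MDESeries(g, g.ages, np.full(21, 3.0))
        out = smooth_series(s, 5)
        assert np.allclose(out.values, 3.0)
        assert out.stage == "smoothed"

    def test_impulse_spreads_to_window_mean(self):
        g = TimeGrid(20)
        vals = np.zeros(21)
        vals[10] = 5.0
        out = smooth_series(MDESeries(g, g.ages, vals), 5)
        assert np.allclose(out.values[8:13], 1.0)
        assert np.allclose(out.values[:8], 0.0) and np.allclose(out.values[13:], 0.0)

    def test_window_one_is_identity(self, rng):
        g = TimeGrid(30)
        vals = rng.poisson(4, size=31).astype(float)
        out = smooth_series(MDESeries(g, g.ages, vals), 1)
        assert np.array_equal(out.values, vals)

    def test_edges_use_truncated_windows(self):
        g = TimeGrid(4)
        out = smooth_series(MDESeries(g, g.ages, np.array([1.0, 2, 3, 4, 5])), 3)
        assert np.allclose(out.values, [1.5, 2.0, 3.0, 4.0, 4.5])

    @pytest.mark.parametrize("w", [0, 2, 4])
    def test_even_or_nonpositive_window_rejected(self, w):
        g = TimeGrid(10)
        s = MDESeries(g, g.ages, np.zeros(11))
        with pytest.raises(ValueError, match="odd"):
            smooth_series(s, w)


class TestStratified:
    def test_direction_strata_sum_to_pooled(self, rng):
        table = random_table(rng, 50)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pooled = compute_mde(table, TimeGrid(70))
            strata = stratified_mde(table, TimeGrid(70), by="direction")
        total = sum(s.values for s in strata.values())
        assert np.array_equal(total, pooled.values)

    def test_taxon_strata_sum_to_pooled(self, rng):
        table = random_table(rng, 50)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pooled = compute_mde(table, TimeGrid(70))
            strata = stratified_mde(table, TimeGrid(70), by="taxon")
        assert len(strata) == 8
        total = sum(s.values for s in strata.values())
        assert np.array_equal(total, pooled.values)

    def test_single_direction_table_gives_one_zero_stratum(self):
        table = EventTable([ev("a", 3.0, 1.0, direction="india_to_asia")])
        strata = stratified_mde(table, TimeGrid(10), by="direction")
        assert np.all(strata["asia_to_india"].values == 0)
        assert strata["india_to_asia"].values.sum() == 3


class TestBiasCutoffAndTruncation:
    def mk(self, vals_ascending, t_max=10):
        g = TimeGrid(t_max)
        return MDESeries(g, g.ages, np.asarray(vals_ascending, float)[::-1])

    def test_no_crossing_returns_zero(self):
        avian = self.mk([0] * 11)
        non = self.mk([5] * 11)
        assert avian_bias_cutoff(avian, non) == 0

    def test_crossing_found_at_youngest_sign_change(self):
        avian = self.mk(list(range(10, -1, -1)))   # 10..0 by age ascending
        non = self.mk(list(range(0, 11)))          # 0..10
        assert avian_bias_cutoff(avian, non) == 5

    def test_identical_series_gives_zero(self):
        s = self.mk([1, 2, 3, 2, 1, 0, 0, 1, 2, 3, 4])
        assert avian_bias_cutoff(s, self.mk([1, 2, 3, 2, 1, 0, 0, 1, 2, 3, 4])) == 0

    def test_plateau_resolves_to_youngest_point(self):
        # avian above non-avian for ages 0-2, tied 3-5, below for 6+
        avian = self.mk([9, 9, 9, 5, 5, 5, 1, 1, 1, 1, 1])
        non = self.mk([4, 4, 4, 5, 5, 5, 8, 8, 8, 8, 8])
        assert avian_bias_cutoff(avian, non) == 3

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            avian_bias_cutoff(self.mk([0] * 11), self.mk([0] * 6, t_max=5))

    def test_truncation_drops_young_slices(self):
        s = self.mk(list(range(11)))
        out = truncate_series(s, 7)
        assert out.ages.tolist() == [10, 9, 8, 7]
        assert out.values.tolist() == [10, 9, 8, 7]
        assert out.truncation_age == 7

    def test_truncation_at_zero_keeps_everything(self):
        s = self.mk(list(range(11)))
        out = truncate_series(s, 0)
        assert np.array_equal(out.values, s.values)

    def test_truncation_at_t_max_leaves_single_point(self):
        out = truncate_series(self.mk(list(range(11))), 10)
        assert out.ages.tolist() == [10]

    def test_truncation_beyond_grid_rejected(self):
        with pytest.raises(ValueError, match="outside the grid"):
            truncate_series(self.mk([0] * 11), 11)
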