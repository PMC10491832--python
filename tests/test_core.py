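"""Unit and property tests for the separation statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sepscreen import (
    Direction,
    PercentileGrid,
    TwoSampleData,
    directional_separation,
    percentile,
    separation_statistic,
)
from _oracles import oracle_direction, oracle_separation

# Values on a 1/1000 lattice: distinct inputs stay distinct under the
# monotone transforms used below, so strict inequalities survive rounding.
lattice_values = st.lists(
    st.integers(0, 1000).map(lambda k: k / 1000), min_size=2, max_size=12
)


@pytest.mark.parametrize(
    ("values", "p", "expected"),
    [
        ([10, 20, 30, 40], 0, 10),  # minimum by definition
        ([10, 20, 30, 40], 100, 40),  # maximum by definition
        ([10, 20, 30, 40], 50, 20),  # ceil(0.5 * 4) = rank 2
        ([10, 20, 30, 40], 51, 30),  # ceil(0.51 * 4) = rank 3
        ([5], 37, 5),  # singleton: every percentile is the value
        ([3, 1, 2], 67, 3),  # unsorted input, ceil(0.67 * 3) = rank 3
    ],
)
def test_percentile_nearest_rank(values, p, expected):
    assert percentile(values, p) == expected


@pytest.mark.parametrize(
    ("values", "p"),
    [([], 50), ([1, 2], -1), ([1, 2], 101), ([1, 2], 49.5)],
)
def test_percentile_rejects_invalid_input(values, p):
    with pytest.raises(ValueError):
        percentile(values, p)


@given(values=lattice_values, p=st.integers(0, 100))
@settings(max_examples=200, derandomize=True)
def test_percentile_is_an_observed_value(values, p):
    assert percentile(values, p) in values


class TestDirectionalSeparation:
    def test_complete_separation_reaches_100(self):
        data = TwoSampleData([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        assert directional_separation(data, Direction.F_GT_M) == 100

    def test_identical_sets_floor_at_50(self):
        vals = [i / 10 for i in range(1, 11)]
        data = TwoSampleData(vals, list(vals))
        for direction in Direction:
            assert directional_separation(data, direction) == 50

    def test_partial_overlap_matches_frozen_oracle_value(self):
        # brute-force grid scan of every p in 50..100 gives 80 here
        data = TwoSampleData([0.1, 0.2, 0.3, 0.4, 0.6], [0.5, 0.7, 0.8, 0.9, 1.0])
        assert directional_separation(data, Direction.F_GT_M) == 80
        assert directional_separation(data, Direction.M_GT_F) == 50


class TestSeparationStatistic:
    def test_males_higher_complete_separation(self):
        res = separation_statistic(TwoSampleData([0.7, 0.8, 0.9], [0.1, 0.2, 0.3]))
        assert res.s == 100
        assert res.direction is Direction.M_GT_F

    def test_identical_distributions_score_50(self):
        vals = [round(0.05 * i, 2) for i in range(1, 21)]  # 20 distinct values
        res = separation_statistic(TwoSampleData(vals, list(vals)))
        assert res.s == 50

    def test_overlapping_samples_match_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        vm = rng.uniform(0.2, 0.7, 8).round(3)
        vf = rng.uniform(0.3, 0.8, 8).round(3)
        res = separation_statistic(TwoSampleData(vm, vf))
        s, s_m, s_f, count = oracle_separation(list(vm), list(vf))
        assert (res.s, res.s_m_gt_f, res.s_f_gt_m, res.selector_count) == (s, s_m, s_f, count)

    def test_degenerate_constant_groups(self):
        res = separation_statistic(TwoSampleData([0.5] * 5, [0.5] * 5))
        assert res.s == 50
        res = separation_statistic(TwoSampleData([0.9] * 5, [0.1] * 5))
        assert res.s == 100
        assert res.direction is Direction.M_GT_F


@given(values_m=lattice_values, values_f=lattice_values)
@settings(max_examples=300, derandomize=True)
def test_statistic_always_within_50_100(values_m, values_f):
    res = separation_statistic(TwoSampleData(values_m, values_f, unit="fraction"))
    assert 50 <= res.s <= 100
    assert res.s == max(res.s_m_gt_f, res.s_f_gt_m)


@given(values_m=lattice_values, values_f=lattice_values)
@settings(max_examples=200, derandomize=True)
def test_matches_brute_force_oracle(values_m, values_f):
    res = separation_statistic(TwoSampleData(values_m, values_f, unit="fraction"))
    s, s_m, s_f, count = oracle_separation(values_m, values_f)
    assert (res.s, res.s_m_gt_f, res.s_f_gt_m, res.selector_count) == (s, s_m, s_f, count)
    assert res.direction.value == oracle_direction(values_m, values_f)


@given(values_m=lattice_values, values_f=lattice_values)
@settings(max_examples=150, derandomize=True)
def test_rank_invariance_under_monotone_transforms(values_m, values_f):
    base = separation_statistic(TwoSampleData(values_m, values_f, unit="fraction"))
    for transform in (lambda x: x**2, np.sqrt, lambda x: 0.5 * x + 0.25):
        tm = transform(np.asarray(values_m))
        tf = transform(np.asarray(values_f))
        res = separation_statistic(TwoSampleData(tm, tf, unit="fraction"))
        assert res.s == base.s
        assert res.direction is base.direction
        assert res.selector_count == base.selector_count


@given(
    pooled=st.lists(st.integers(0, 1000).map(lambda k: k / 1000),
                    min_size=4, max_size=20, unique=True),
    data=st.data(),
)
@settings(max_examples=150, derandomize=True)
def test_label_symmetry_flips_direction(pooled, data):
    """With tie-free pooled values a group swap preserves S, swaps the two
    branch statistics and flips the direction label."""
    split = data.draw(st.integers(2, len(pooled) - 2))
    vm, vf = pooled[:split], pooled[split:]
    res = separation_statistic(TwoSampleData(vm, vf, unit="fraction"))
    swp = separation_statistic(TwoSampleData(vf, vm, unit="fraction"))
    assert swp.s == res.s
    assert (swp.s_m_gt_f, swp.s_f_gt_m) == (res.s_f_gt_m, res.s_m_gt_f)
    assert swp.direction is res.direction.flipped()


@given(values_m=lattice_values, values_f=lattice_values)
@settings(max_examples=200, derandomize=True)
def test_complete_separation_characterization(values_m, values_f):
    res = separation_statistic(TwoSampleData(values_m, values_f, unit="fraction"))
    disjoint = max(values_m) < min(values_f) or max(values_f) < min(values_m)
    assert (res.s == 100) == disjoint


@given(
    values_m=st.lists(st.integers(0, 300).map(lambda k: k / 1000), min_size=2, max_size=10),
    values_f=st.lists(st.integers(0, 300).map(lambda k: k / 1000), min_size=2, max_size=10),
)
@settings(max_examples=100, derandomize=True)
def test_shift_monotonicity_of_f_branch(values_m, values_f):
    """Raising every value of group F by a constant never decreases the
    F>M branch statistic."""
    prev = -1
    for c in np.linspace(0.0, 0.7, 8):
        shifted = [v + c for v in values_f]
        res = separation_statistic(TwoSampleData(values_m, shifted, unit="fraction"))
        assert res.s_f_gt_m >= prev
        prev = res.s_f_gt_m


class TestTwoSampleData:
    def test_percent_scale_auto_normalized(self):
        data = TwoSampleData([10, 20, 30], [40, 50, 60])
        assert data.values_m.max() <= 1.0
        np.testing.assert_allclose(data.values_m, [0.1, 0.2, 0.3])

    def test_auto_unit_is_decided_on_pooled_values(self):
        # one group below 1 does not get rescaled independently
        data = TwoSampleData([0.5, 0.8], [40, 60])
        np.testing.assert_allclose(data.values_m, [0.005, 0.008])

    @pytest.mark.parametrize(
        ("vm", "vf"),
        [([], [0.1, 0.2]), ([0.1, np.nan], [0.2, 0.3]), ([-0.1, 0.2], [0.2, 0.3])],
    )
    def test_invalid_groups_rejected(self, vm, vf):
        with pytest.raises(ValueError):
            TwoSampleData(vm, vf, unit="fraction")

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            PercentileGrid(lo=60, hi=40)
        with pytest.raises(ValueError):
            PercentileGrid(lo=-1, hi=100)
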