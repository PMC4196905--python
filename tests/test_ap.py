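import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cindy.ap import (
    DegenerateProfileWarning,
    FastInfo,
    build_partition,
    estimate_cmi,
    estimate_mi,
    mi_from_partition,
    rank_transform,
    uniformity_test,
)
from conftest import gaussian_pair


class TestRankTransform:
    def test_permutation_of_1_to_n(self, rng):
        v = rng.standard_normal(101)
        r = rank_transform(v)
        assert sorted(r.values) == list(range(1, 102))

    def test_monotone_invariance(self, rng):
        v = rng.standard_normal(50)
        assert np.array_equal(rank_transform(v).values, rank_transform(np.exp(v)).values)

    def test_ties_deterministic_per_seed(self):
        v = np.array([1.0, 2.0, 2.0, 2.0, 3.0])
        a = rank_transform(v, seed=7).values
        b = rank_transform(v, seed=7).values
        c = rank_transform(v, seed=8).values
        assert np.array_equal(a, b)
        assert sorted(c) == [1, 2, 3, 4, 5]
        assert a[0] == 1 and a[4] == 5  # untied positions keep their order

    def test_constant_profile_degenerate(self):
        with pytest.warns(DegenerateProfileWarning):
            r = rank_transform(np.ones(10))
        assert r.degenerate
        assert sorted(r.values) == list(range(1, 11))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            rank_transform(np.array([1.0, 2.0]))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            rank_transform(np.array([1.0, np.nan, 2.0]))

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 60))
    def test_property_always_permutation(self, seed, n):
        v = np.random.default_rng(seed).integers(0, 5, size=n).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateProfileWarning)
            r = rank_transform(v, seed=seed)
        assert sorted(r.values) == list(range(1, n + 1))


class TestUniformityTest:
    def test_exact_uniformity_never_splits(self):
        assert uniformity_test([25, 25, 25, 25], alpha=0.05) is False

    def test_maximal_nonuniformity_splits(self):
        assert uniformity_test([100, 0, 0, 0], alpha=0.05) is True

    def test_moderate_imbalance_below_critical(self):
        # chi-square statistic 2.0 < 7.815 (df = 3)
        assert uniformity_test([30, 20, 25, 25], alpha=0.05) is False

    def test_zero_total_never_splits(self):
        assert uniformity_test([0, 0, 0, 0], alpha=0.05) is False

    def test_alpha_monotonicity(self):
        counts = [40, 20, 20, 20]
        assert uniformity_test(counts, alpha=0.2) or not uniformity_test(counts, alpha=0.01)


def _partition_is_tiling(part):
    """Cells are pairwise disjoint and cover rank space exactly."""
    d = part.dimension
    volume = 0
    for i in range(part.n_cells):
        v = 1
        for k in range(d):
            lo, hi = part.bounds[i, 2 * k], part.bounds[i, 2 * k + 1]
            assert lo < hi
            v *= hi - lo
        volume += v
    assert volume == part.n ** d
    for i in range(part.n_cells):
        for j in range(i + 1, min(i + 20, part.n_cells)):
            overlap = all(
                part.bounds[i, 2 * k] < part.bounds[j, 2 * k + 1]
                and part.bounds[j, 2 * k] < part.bounds[i, 2 * k + 1]
                for k in range(d)
            )
            assert not overlap


class TestBuildPartition:
    def test_counts_sum_to_n(self, rng):
        x = rank_transform(rng.standard_normal(200)).values
        y = rank_transform(rng.standard_normal(200)).values
        part = build_partition((x, y))
        assert part.counts.sum() == 200

    def test_cells_tile_rank_space_2d(self, rng):
        u = rng.standard_normal(300)
        part = build_partition(
            (rank_transform(u).values, rank_transform(u + 0.3 * rng.standard_normal(300)).values)
        )
        assert part.n_cells > 1
        _partition_is_tiling(part)

    def test_cells_tile_rank_space_3d(self, rng):
        z = rng.standard_normal(400)
        x = rank_transform(z + 0.5 * rng.standard_normal(400)).values
        y = rank_transform(z + 0.5 * rng.standard_normal(400)).values
        part = build_partition((x, y, rank_transform(z).values))
        _partition_is_tiling(part)
        assert part.nxz is not None and part.nyz is not None

    def test_bad_dimension(self, rng):
        x = rank_transform(rng.standard_normal(10)).values
        with pytest.raises(ValueError):
            build_partition((x,))

    def test_length_mismatch(self, rng):
        x = rank_transform(rng.standard_normal(10)).values
        y = rank_transform(rng.standard_normal(12)).values
        with pytest.raises(ValueError):
            build_partition((x, y))


class TestMi:
    def test_independent_near_zero(self):
        x, y = gaussian_pair(0.0, 500, seed=11)
        est = estimate_mi(rank_transform(x), rank_transform(y))
        assert est.kind == "MI2"
        assert est.value < 0.05

    def test_gaussian_accuracy_grid(self):
        for rho in (0.3, 0.6, 0.9):
            true = -0.5 * math.log(1 - rho**2)
            vals = []
            for s in range(10):
                x, y = gaussian_pair(rho, 2000, seed=100 + s)
                vals.append(estimate_mi(rank_transform(x), rank_transform(y)).value)
            assert abs(np.mean(vals) - true) < 0.1, f"rho={rho}"

    def test_non_negative_and_symmetric_formula(self, rng):
        x = rank_transform(rng.standard_normal(150)).values
        y = rank_transform(rng.standard_normal(150)).values
        assert estimate_mi(x, y).value >= 0.0

    def test_monotone_invariance(self, rng):
        v = rng.standard_normal(400)
        w = v + rng.standard_normal(400)
        a = estimate_mi(rank_transform(v), rank_transform(w)).value
        b = estimate_mi(rank_transform(np.exp(v)), rank_transform(w**3)).value
        assert a == b

    def test_fastinfo_matches_estimate(self, rng):
        x = rank_transform(rng.standard_normal(500)).values
        y = rank_transform(rng.standard_normal(500) + 0.5 * x / 500).values
        assert FastInfo().mi(x, y) == estimate_mi(x, y).value

    @settings(max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_property_nonnegative(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(10, 200))
        x = rank_transform(r.standard_normal(n), seed=seed).values
        y = rank_transform(r.standard_normal(n), seed=seed + 1).values
        assert estimate_mi(x, y).value >= 0.0


class TestCmi:
    def test_conditional_independence(self):
        # estimate is a mean over seeds: the single-draw spread straddles the
        # bound even though the estimator is well inside it on average
        mis, cmis = [], []
        for s in range(10):
            r = np.random.default_rng(70 + s)
            m = r.standard_normal(1000)
            tf = m + 0.7 * r.standard_normal(1000)
            tg = m + 0.7 * r.standard_normal(1000)
            rm, rt, rg = (rank_transform(v) for v in (m, tf, tg))
            mis.append(estimate_mi(rt, rg).value)
            cmis.append(estimate_cmi(rt, rg, rm).value)
        assert np.mean(mis) > 0.2
        assert np.mean(cmis) < 0.05

    def test_partial_correlation_oracle(self):
        true = -0.5 * math.log(1 - 0.25)  # ~0.1438
        vals = []
        for s in range(10):
            r = np.random.default_rng(200 + s)
            z = r.standard_normal(2000)
            uv = r.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=2000)
            vals.append(
                estimate_cmi(
                    rank_transform(z + uv[:, 0]),
                    rank_transform(z + uv[:, 1]),
                    rank_transform(z),
                ).value
            )
        assert abs(np.mean(vals) - true) < 0.05

    def test_fastinfo_matches_estimate(self, rng):
        x = rank_transform(rng.standard_normal(300)).values
        y = rank_transform(rng.standard_normal(300)).values
        z = rank_transform(rng.standard_normal(300)).values
        assert FastInfo().cmi(x, y, z) == estimate_cmi(x, y, z).value

    def test_degenerate_flag_propagates(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateProfileWarning)
            m = rank_transform(np.ones(50))
        t = rank_transform(np.arange(50.0))
        g = rank_transform(np.arange(50.0)[::-1])
        assert estimate_cmi(t, g, m).degenerate


def test_mi_from_partition_zero_clamp(rng):
    x = rank_transform(rng.standard_normal(20)).values
    y = rank_transform(rng.standard_normal(20)).values
    part = build_partition((x, y))
    assert mi_from_partition(part) >= 0.0
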