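import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from samgsr.io_genesets import GeneSetCollection
from samgsr.samgs import (
    benjamini_hochberg,
    choose_s0,
    permutation_null,
    pooled_sd,
    sam_statistic,
    samgs_statistic,
    significant_sets,
)

from conftest import make_dataset, random_dataset


# ---------------------------------------------------------------------------
# independent oracle: naive loops over the printed formulas


def naive_pooled_sd(x_d, x_c):
    n_d, n_c = len(x_d), len(x_c)
    ss_d = sum((v - np.mean(x_d)) ** 2 for v in x_d)
    ss_c = sum((v - np.mean(x_c)) ** 2 for v in x_c)
    return math.sqrt((1 / n_d + 1 / n_c) * (ss_d + ss_c) / (n_d + n_c - 2))


def naive_sam_all(X, diseased_mask, s0_q=0.05):
    """Per-gene d_i and pooled SDs, one gene at a time."""
    sds = [naive_pooled_sd(row[diseased_mask], row[~diseased_mask]) for row in X]
    s0 = np.quantile(sds, s0_q)
    d = [
        (row[diseased_mask].mean() - row[~diseased_mask].mean()) / (sd + s0)
        for row, sd in zip(X, sds)
    ]
    return np.array(d), np.array(sds), s0


class TestPooledSd:
    def test_zero_within_group_scatter(self):
        assert pooled_sd([1, 1], [0, 0]) == 0.0

    def test_hand_computed_value(self):
        # sqrt((1/2 + 1/2) * (2 + 0) / 2) = 1
        assert pooled_sd([0, 2], [0, 0]) == pytest.approx(1.0)

    def test_group_too_small(self):
        with pytest.raises(ValueError):
            pooled_sd([1.0], [0.0, 0.0])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=6),
        st.lists(st.floats(-50, 50), min_size=2, max_size=6),
        st.floats(0.1, 10),
    )
    def test_absolute_homogeneity(self, x_d, x_c, c):
        base = pooled_sd(x_d, x_c)
        scaled = pooled_sd([c * v for v in x_d], [c * v for v in x_c])
        assert scaled == pytest.approx(c * base, rel=1e-9, abs=1e-9)


class TestSamStatistic:
    def test_zero_numerator(self):
        assert sam_statistic([1, 3], [2, 2], s0=0.5) == 0.0

    def test_hand_computed_value(self):
        assert sam_statistic([2, 2], [0, 0], s0=1.0) == pytest.approx(2.0)

    def test_antisymmetric_under_group_swap(self):
        x_d, x_c = [1.0, 2.5, 3.0], [0.5, 0.1, 0.2]
        assert sam_statistic(x_d, x_c, 0.3) == pytest.approx(
            -sam_statistic(x_c, x_d, 0.3)
        )

    def test_degenerate_gene_rejected(self):
        with pytest.raises(ValueError):
            sam_statistic([1, 1], [0, 0], s0=0.0)


class TestChooseS0:
    def test_constant_sds(self):
        assert choose_s0([1, 1, 1, 1], q=0.3) == 1.0

    def test_fixed_mode(self):
        assert choose_s0([1, 2, 3], method="fixed", fixed_value=0.3) == 0.3

    def test_empirical_quantile_convention(self):
        # numpy linear-interpolation quantile of 0..100 at q=0.05
        assert choose_s0(list(range(101)), q=0.05) == pytest.approx(5.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            choose_s0([])


class TestSamGsStatistic:
    def test_sum_of_squares(self):
        d = pd.Series({"a": 1.0, "b": 2.0, "c": 2.0})
        assert samgs_statistic(d, ["a", "b", "c"]) == pytest.approx(9.0)

    def test_additive_over_disjoint_sets(self):
        d = pd.Series({"a": 1.0, "b": -2.0, "c": 0.5, "e": 3.0})
        whole = samgs_statistic(d, ["a", "b", "c", "e"])
        assert whole == pytest.approx(
            samgs_statistic(d, ["a", "b"]) + samgs_statistic(d, ["c", "e"])
        )

    def test_gene_order_invariant(self):
        d = pd.Series({"a": 1.0, "b": -2.0, "c": 0.5})
        assert samgs_statistic(d, ["c", "a", "b"]) == samgs_statistic(
            d, ["a", "b", "c"]
        )

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            samgs_statistic(pd.Series({"a": 1.0}), ["a", "zz"])


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_statistics_match_naive_loops(self, seed):
        """Vectorized d_i, pooled SDs and SAMGS_j agree with an independent
        per-gene re-implementation of the formulas to 1e-12."""
        rng = np.random.default_rng(seed)
        G = int(rng.integers(3, 21))
        n_d = int(rng.integers(2, 7))
        n_c = int(rng.integers(2, 7))
        X = rng.standard_normal((G, n_d + n_c)) * rng.uniform(0.5, 3)
        ds = make_dataset(X, n_d)
        mask = np.array([True] * n_d + [False] * n_c)
        d_naive, sds_naive, s0_naive = naive_sam_all(X, mask)

        members = list(ds.gene_ids[: max(2, G // 2)])
        coll = GeneSetCollection(sets={"S": members})
        res = permutation_null(ds, coll, B=5, seed=0, exhaustive="never")
        np.testing.assert_allclose(res.sam.d.to_numpy(), d_naive, atol=1e-12)
        np.testing.assert_allclose(res.sam.s.to_numpy(), sds_naive, atol=1e-12)
        assert res.sam.s0 == pytest.approx(s0_naive, abs=1e-12)
        idx = [ds.gene_ids.index(g) for g in members]
        assert res.samgs["S"] == pytest.approx(
            float((d_naive[idx] ** 2).sum()), abs=1e-12
        )


class TestPermutationNull:
    def test_exhaustive_matches_enumeration(self):
        """n = 3 vs 3: p-values equal brute-force enumeration over all 20
        label splits."""
        ds = random_dataset(seed=5, G=6, n_d=3, n_c=3, shift_first=2.5)
        coll = GeneSetCollection(sets={"S": ds.gene_ids[:3]})
        res = permutation_null(ds, coll, B=999, seed=0)
        assert res.exhaustive and res.B == 20

        X = ds.values.to_numpy()
        stats = []
        for picks in itertools.combinations(range(6), 3):
            mask = np.zeros(6, dtype=bool)
            mask[list(picks)] = True
            d, _, _ = naive_sam_all(X, mask)
            stats.append(d)
        stats = np.array(stats)
        obs_d, _, _ = naive_sam_all(X, np.array([True] * 3 + [False] * 3))
        samgs_null = (stats[:, :3] ** 2).sum(axis=1)
        obs_set = (obs_d[:3] ** 2).sum()
        assert res.set_p["S"] == pytest.approx(
            (samgs_null >= obs_set - 1e-12).sum() / 20
        )
        for i, g in enumerate(ds.gene_ids):
            expected = (np.abs(stats[:, i]) >= abs(obs_d[i]) - 1e-12).sum() / 20
            assert res.sam.gene_p[g] == pytest.approx(expected)

    def test_add_one_convention_floor(self):
        """A set statistic dominating every random shuffle gets p = 1/(B+1)."""
        ds = random_dataset(seed=0, G=8, n_d=10, n_c=10, shift_first=6.0)
        coll = GeneSetCollection(sets={"S": [ds.gene_ids[0], ds.gene_ids[1]]})
        res = permutation_null(ds, coll, B=199, seed=3, exhaustive="never")
        assert res.set_p["S"] == pytest.approx(1 / 200)
        assert res.set_p.min() >= 1 / 200 and res.set_p.max() <= 1.0

    def test_bit_reproducible_for_fixed_seed(self):
        ds = random_dataset(seed=2, G=12, n_d=6, n_c=6)
        coll = GeneSetCollection(sets={"S": ds.gene_ids[:4]})
        a = permutation_null(ds, coll, B=50, seed=9, exhaustive="never")
        b = permutation_null(ds, coll, B=50, seed=9, exhaustive="never")
        assert (a.d_perm == b.d_perm).all()
        assert a.set_p.equals(b.set_p) and a.sam.gene_p.equals(b.sam.gene_p)

    def test_shift_does_not_lower_median_samgs(self):
        """Raising the mean shift of a set's members raises (or preserves)
        the median observed set statistic across replicates."""
        medians = []
        for shift in (0.0, 1.0, 3.0):
            vals = []
            for rep in range(15):
                ds = random_dataset(seed=100 + rep, G=10, n_d=6, n_c=6,
                                    shift_first=shift)
                coll = GeneSetCollection(sets={"S": ds.gene_ids[:3]})
                res = permutation_null(ds, coll, B=1, seed=0,
                                       exhaustive="never")
                vals.append(res.samgs["S"])
            medians.append(np.median(vals))
        assert medians[0] <= medians[1] <= medians[2]

    def test_invalid_B_rejected(self):
        ds = random_dataset(seed=0)
        coll = GeneSetCollection(sets={"S": ds.gene_ids[:2]})
        with pytest.raises(ValueError):
            permutation_null(ds, coll, B=0)

    def test_s0_observed_mode(self):
        ds = random_dataset(seed=1, G=8, n_d=4, n_c=4)
        coll = GeneSetCollection(sets={"S": ds.gene_ids[:3]})
        res = permutation_null(ds, coll, B=20, seed=0, s0_recompute=False,
                               exhaustive="never")
        assert res.s0_mode == "observed"


class TestSignificance:
    def test_threshold_and_fdr(self):
        class R:
            set_p = pd.Series({"a": 0.01, "b": 0.04, "c": 0.2})

        assert significant_sets(R(), threshold=0.05) == ["a", "b"]
        # BH adjusted: 0.03, 0.06, 0.2 -> only "a" survives at 0.05
        assert significant_sets(R(), threshold=0.05, fdr=True) == ["a"]

    def test_bh_monotone_and_capped(self):
        p = pd.Series({"x": 0.001, "y": 0.5, "z": 0.9, "w": 1.0})
        adj = benjamini_hochberg(p)
        assert (adj <= 1).all()
        assert adj["x"] <= adj["y"] <= adj["z"] <= adj["w"]
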