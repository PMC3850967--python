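import numpy as np
import pandas as pd
import pytest

from episig.genomic_correlates import (cnv_subgroup_filter,
                                       define_extreme_groups,
                                       permutation_false_positive_rate,
                                       sliding_window_meth_test)
from episig.matrix import GenomicMatrix
from oracles import welch_by_hand


def _coords(ids, chrom="chr1"):
    return pd.DataFrame({"chrom": [chrom] * len(ids),
                         "pos": np.arange(1, len(ids) + 1) * 100}, index=ids)


def _meth(values, samples, split_chrom=False):
    values = np.asarray(values, dtype=float)
    ids = [f"cg{i}" for i in range(values.shape[0])]
    coords = _coords(ids)
    if split_chrom:
        half = len(ids) // 2
        coords.loc[ids[half:], "chrom"] = "chr2"
        coords.loc[ids[half:], "pos"] = np.arange(1, len(ids) - half + 1) * 100
    return GenomicMatrix(pd.DataFrame(values, index=ids, columns=samples),
                         kind="methylation", coords=coords)


class TestExtremeGroups:
    def _scores(self, a, b):
        return pd.DataFrame({"A": a, "B": b},
                            index=[f"s{j}" for j in range(len(a))])

    def test_corner_assignment_at_half(self):
        sc = self._scores([0.9, 0.1, 0.6], [0.1, 0.9, 0.6])
        g1, g2 = define_extreme_groups(sc, "A", "B", cutoff=0.5)
        assert g1 == ["s0"] and g2 == ["s1"]  # s2 fails the low condition

    def test_symmetric_rule_matches_enumeration(self):
        a = [0.9, 0.1, 0.85, 0.15, 0.5, 0.9, 0.1, 0.81]
        b = [0.1, 0.9, 0.15, 0.85, 0.5, 0.5, 0.5, 0.19]
        sc = self._scores(a, b)
        hi, lo = 0.8, 0.2
        want1 = [f"s{j}" for j in range(8) if a[j] > hi and b[j] < lo]
        want2 = [f"s{j}" for j in range(8) if a[j] < lo and b[j] > hi]
        g1, g2 = define_extreme_groups(sc, "A", "B", cutoff=0.2)
        assert g1 == want1 and g2 == want2
        # a cutoff above one half selects the same corners
        g1b, g2b = define_extreme_groups(sc, "A", "B", cutoff=0.8)
        assert g1b == g1 and g2b == g2

    def test_empty_group_rejected(self):
        sc = self._scores([0.9, 0.9], [0.1, 0.1])
        with pytest.raises(ValueError, match="empty extreme group"):
            define_extreme_groups(sc, "A", "B", cutoff=0.5)


class TestCnvFilter:
    def _cnv(self, rows, samples):
        ids = [f"g{i}" for i in range(len(rows))]
        return GenomicMatrix(pd.DataFrame(rows, index=ids, columns=samples),
                             kind="copy_number", coords=_coords(ids))

    def test_planted_statuses_exact(self):
        g1 = [f"a{j}" for j in range(5)]
        g2 = [f"b{j}" for j in range(5)]
        rows = [
            [0.6, 0.6, 0, 0, 0] + [0] * 5,          # 40% gain in group1 only
            [0.6, 0.6, 0, 0, 0] + [0.7, 0.7, 0, 0, 0],  # gained in both
            [0.1, -0.2, 0.3, 0, 0.4] + [0.2, 0.1, 0, -0.3, 0.4],  # quiet
        ]
        res = cnv_subgroup_filter(self._cnv(rows, g1 + g2), g1, g2)
        assert list(res["status"]) == ["group1_specific_gain", "removed",
                                       "none"]

    def test_gain_one_group_loss_other_removed(self):
        g1, g2 = ["a0", "a1"], ["b0", "b1"]
        rows = [[0.8, 0.8, -0.8, -0.8]]
        res = cnv_subgroup_filter(self._cnv(rows, g1 + g2), g1, g2)
        assert res["status"].iloc[0] == "removed"

    def test_every_gene_gets_exactly_one_status(self):
        rng = np.random.default_rng(4)
        g1 = [f"a{j}" for j in range(6)]
        g2 = [f"b{j}" for j in range(6)]
        rows = rng.normal(0, 0.5, size=(50, 12))
        res = cnv_subgroup_filter(self._cnv(rows, g1 + g2), g1, g2)
        valid = {"group1_specific_gain", "group1_specific_loss",
                 "group2_specific_gain", "group2_specific_loss",
                 "removed", "none"}
        assert set(res["status"]).issubset(valid)
        assert len(res) == 50

    def test_overlapping_groups_rejected(self):
        g = self._cnv([[0.0, 0.0]], ["a", "b"])
        with pytest.raises(ValueError, match="disjoint"):
            cnv_subgroup_filter(g, ["a"], ["a", "b"])


class TestSlidingWindow:
    def test_window_one_equals_welch_oracle(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(0.2, 0.8, size=(40, 10))
        g = _meth(vals, [f"s{j}" for j in range(10)], split_chrom=True)
        res = sliding_window_meth_test(g, [f"s{j}" for j in range(5)],
                                       [f"s{j}" for j in range(5, 10)],
                                       window_size=1)
        for i, fid in enumerate(g.feature_ids):
            row = g.data.loc[fid].to_numpy()
            t, p = welch_by_hand(row[:5], row[5:])
            assert res.loc[fid, "t"] == pytest.approx(t, abs=1e-12)
            assert res.loc[fid, "p"] == pytest.approx(p, abs=1e-12)

    def test_identical_groups_not_kept(self):
        base = np.tile(np.array([[0.3], [0.5], [0.7]]), (1, 8))
        g = _meth(base, [f"s{j}" for j in range(8)])
        res = sliding_window_meth_test(g, [f"s{j}" for j in range(4)],
                                       [f"s{j}" for j in range(4, 8)],
                                       window_size=3)
        assert (res["t"] == 0).all()
        assert (res["p"] == 1).all()
        assert not res["kept"].any()

    def test_planted_window_shift_detected(self):
        detected = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            vals = rng.normal(0.5, 0.05, size=(60, 20))
            vals[10:15, :10] += 0.15  # 3-SD shift over 5 probes in group 1
            g = _meth(vals, [f"s{j}" for j in range(20)])
            res = sliding_window_meth_test(
                g, [f"s{j}" for j in range(10)],
                [f"s{j}" for j in range(10, 20)], window_size=5)
            detected += res.loc["cg12", "p"] < 0.01
        assert detected >= round(0.95 * n_seeds)

    def test_larger_shift_smaller_p(self):
        rng = np.random.default_rng(8)
        noise = rng.normal(0.5, 0.05, size=(20, 12))
        pvals = []
        for shift in (0.02, 0.05, 0.1, 0.2):
            vals = noise.copy()
            vals[8:11, :6] += shift
            g = _meth(vals, [f"s{j}" for j in range(12)])
            res = sliding_window_meth_test(
                g, [f"s{j}" for j in range(6)],
                [f"s{j}" for j in range(6, 12)], window_size=3)
            pvals.append(res.loc["cg9", "p"])
        assert all(np.diff(pvals) < 0)

    def test_even_window_rejected(self):
        g = _meth(np.full((4, 4), 0.5), list("abcd"))
        with pytest.raises(ValueError, match="odd"):
            sliding_window_meth_test(g, ["a", "b"], ["c", "d"], window_size=2)

    def test_oversized_window_truncated_with_warning(self):
        rng = np.random.default_rng(9)
        g = _meth(rng.uniform(0.2, 0.8, (3, 6)), [f"s{j}" for j in range(6)])
        with pytest.warns(UserWarning, match="truncating"):
            res = sliding_window_meth_test(g, [f"s{j}" for j in range(3)],
                                           [f"s{j}" for j in range(3, 6)],
                                           window_size=5)
        assert len(res) == 3


class TestPermutationFPR:
    def _null(self, n_features=120, n_per_group=8, seed=3):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0.5, 0.05, size=(n_features, 2 * n_per_group))
        samples = [f"s{j}" for j in range(2 * n_per_group)]
        g = _meth(vals, samples, split_chrom=True)
        return g, samples[:n_per_group], samples[n_per_group:]

    def test_alpha_one_keeps_everything(self):
        g, g1, g2 = self._null()
        res = permutation_false_positive_rate(g, g1, g2, alpha=1.0,
                                              n_perm=3, seed=1)
        assert res.mean_fraction == 1.0

    def test_same_seed_reproducible(self):
        g, g1, g2 = self._null()
        r1 = permutation_false_positive_rate(g, g1, g2, n_perm=5, seed=7)
        r2 = permutation_false_positive_rate(g, g1, g2, n_perm=5, seed=7)
        np.testing.assert_array_equal(r1.fractions, r2.fractions)

    def test_invariant_to_group_relabeling(self):
        g, g1, g2 = self._null()
        r1 = permutation_false_positive_rate(g, g1, g2, n_perm=5, seed=7)
        r2 = permutation_false_positive_rate(g, g2, g1, n_perm=5, seed=7)
        # equal group sizes + canonical pooling -> identical shuffles
        np.testing.assert_array_equal(r1.fractions, r2.fractions)

    def test_zero_permutations_rejected(self):
        g, g1, g2 = self._null()
        with pytest.raises(ValueError):
            permutation_false_positive_rate(g, g1, g2, n_perm=0, seed=1)
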