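import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from episig.exclusivity import (QuadrantSummary, classify_quadrants,
                                coactivation_deficit_test,
                                pairwise_correlations, subtype_association)
from episig.projection import ActivityTable
from oracles import anova_f_by_hand, binomial_lower_tail, spearman_by_hand


def _table(scores: dict, raw: dict | None = None) -> ActivityTable:
    rescaled = pd.DataFrame(scores)
    if raw is None:
        raw = {k: np.clip(v, 0.01, 0.99) for k, v in scores.items()}
    return ActivityTable(raw=pd.DataFrame(raw, index=rescaled.index),
                         rescaled=rescaled)


class TestPairwiseCorrelations:
    def test_self_and_reversal(self):
        x = np.array([0.1, 0.4, 0.2, 0.8, 0.6, 0.3])
        t = _table({"A": x, "B": 1 - x})
        r, p = pairwise_correlations(t)
        assert r.loc["A", "A"] == 1.0
        assert r.loc["A", "B"] == pytest.approx(-1.0)

    def test_matches_hand_ranked_oracle(self, rng):
        x = rng.uniform(0.05, 0.95, 6)
        y = rng.uniform(0.05, 0.95, 6)
        y[3] = y[1]  # force a tie
        t = _table({"A": x, "B": y})
        r, _ = pairwise_correlations(t)
        assert r.loc["A", "B"] == pytest.approx(spearman_by_hand(x, y),
                                                abs=1e-12)

    def test_constant_column_reported_missing(self):
        t = _table({"A": [0.1, 0.2, 0.3], "B": [0.4, 0.4, 0.4]})
        with pytest.warns(UserWarning, match="constant"):
            r, _ = pairwise_correlations(t)
        assert np.isnan(r.loc["A", "B"])


class TestClassifyQuadrants:
    def test_examples_with_explicit_threshold(self):
        t = _table({"A": [0.9, 0.5, 0.2], "B": [0.9, 0.9, 0.1]})
        labels, summary = classify_quadrants(t, "A", "B", threshold=0.5)
        assert list(labels) == ["both", "B_only", "neither"]
        assert summary.n == 3

    def test_boundary_score_is_not_active(self):
        t = _table({"A": [0.5], "B": [0.7]})
        labels, _ = classify_quadrants(t, "A", "B", threshold=0.5)
        assert list(labels) == ["B_only"]

    def test_decision_boundary_rule_uses_raw_probabilities(self):
        t = _table({"A": [0.9, 0.1], "B": [0.9, 0.1]},
                   raw={"A": [0.7, 0.2], "B": [0.6, 0.4]})
        labels, summary = classify_quadrants(t, "A", "B")
        assert list(labels) == ["both", "neither"]
        assert summary.threshold["rule"] == "raw_probability>0.5"

    def test_monotone_rescaling_invariance(self, rng):
        x = rng.uniform(0.05, 0.95, 40)
        y = rng.uniform(0.05, 0.95, 40)
        t1 = _table({"A": x, "B": y})
        # strictly monotone map fixing the 0.5 crossing set
        warp = lambda v: np.clip(0.5 + np.sign(v - 0.5) * (abs(v - 0.5)) ** 1.7, 0, 1)
        t2 = _table({"A": warp(x), "B": warp(y)})
        l1, _ = classify_quadrants(t1, "A", "B", threshold=0.5)
        l2, _ = classify_quadrants(t2, "A", "B", threshold=0.5)
        assert (l1 == l2).all()

    def test_printed_fraction_example(self):
        summary = QuadrantSummary(threshold=0.5, both_active=300,
                                  a_only=3000, b_only=2500, neither=4200)
        assert summary.marginal_a == pytest.approx(0.33)
        assert summary.marginal_b == pytest.approx(0.28)
        assert summary.expected_coactivation == pytest.approx(0.0924)

    def test_missing_pathway_rejected(self):
        t = _table({"A": [0.5, 0.6]})
        with pytest.raises(KeyError):
            classify_quadrants(t, "A", "Z", threshold=0.5)


class TestDeficitTest:
    def test_matches_enumeration_oracle(self):
        # the oracle itself reproduces the closed form 0.5^10 for no
        # successes in 10 trials at rate one half
        assert binomial_lower_tail(0, 10, 0.5) == pytest.approx(0.5 ** 10)
        q = QuadrantSummary(threshold=0.5, both_active=0, a_only=5,
                            b_only=5, neither=0)
        assert coactivation_deficit_test(q) == pytest.approx(
            binomial_lower_tail(0, q.n, q.expected_coactivation))
        q2 = QuadrantSummary(threshold=0.5, both_active=5, a_only=2,
                             b_only=2, neither=1)
        assert coactivation_deficit_test(q2) == pytest.approx(
            binomial_lower_tail(5, 10, q2.expected_coactivation))

    def test_observed_at_expectation_not_significant(self):
        q = QuadrantSummary(threshold=0.5, both_active=25, a_only=25,
                            b_only=25, neither=25)
        assert coactivation_deficit_test(q) >= 0.5

    def test_monotone_in_both_active(self):
        pvals = []
        for both in (30, 20, 10, 0):
            q = QuadrantSummary(threshold=0.5, both_active=both,
                                a_only=100 - both, b_only=100 - both,
                                neither=300 + both)
            pvals.append(coactivation_deficit_test(q))
        assert all(np.diff(pvals) <= 0)

    def test_zero_expected_edge(self):
        q = QuadrantSummary(threshold=0.5, both_active=0, a_only=0,
                            b_only=0, neither=10)
        assert coactivation_deficit_test(q) == 1.0

    def test_identity_expected_is_product_of_marginals(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 50, 4)
            if counts.sum() == 0:
                continue
            q = QuadrantSummary(threshold=0.5, both_active=int(counts[0]),
                                a_only=int(counts[1]), b_only=int(counts[2]),
                                neither=int(counts[3]))
            assert q.expected_coactivation == q.marginal_a * q.marginal_b


class TestSubtypeAssociation:
    def _subtyped_table(self, rng, means, n=20, sd=0.1):
        scores, labels = [], []
        for name, mu in means.items():
            scores.append(np.clip(rng.normal(mu, sd, n), 0.01, 0.99))
            labels += [name] * n
        vals = np.concatenate(scores)
        idx = [f"s{j}" for j in range(len(vals))]
        t = ActivityTable(raw=pd.DataFrame({"P": vals}, index=idx),
                          rescaled=pd.DataFrame({"P": vals}, index=idx))
        return t, pd.Series(labels, index=idx)

    def test_f_matches_textbook_oracle(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0],
                  "c": [4.0, 5.0, 6.0]}
        vals = np.concatenate([np.array(v) / 10 for v in groups.values()])
        idx = [f"s{j}" for j in range(9)]
        t = ActivityTable(raw=pd.DataFrame({"P": vals}, index=idx),
                          rescaled=pd.DataFrame({"P": vals}, index=idx))
        labels = pd.Series(sum([[k] * 3 for k in groups], []), index=idx)
        res = subtype_association(t, labels, "P", threshold=0.5)
        expected_f = anova_f_by_hand([np.array(v) / 10
                                      for v in groups.values()])
        assert res.f_statistic["P"] == pytest.approx(expected_f, abs=1e-10)

    def test_strong_separation_is_significant(self, rng):
        t, labels = self._subtyped_table(rng, {"lo": 0.2, "hi": 0.8})
        res = subtype_association(t, labels, "P", threshold=0.5)
        assert res.p_value["P"] < 1e-6
        assert res.enrichment["hi"] > 0.9

    def test_null_p_values_roughly_uniform(self, rng):
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            t, labels = self._subtyped_table(
                rng, {"a": 0.5, "b": 0.5, "c": 0.5}, n=10)
            res = subtype_association(t, labels, "P", threshold=0.5)
            rejections += res.p_value["P"] < 0.05
        assert 0.01 <= rejections / n_sims <= 0.11

    def test_joint_high_low_conditions(self, rng):
        idx = [f"s{j}" for j in range(4)]
        sc = pd.DataFrame({"A": [0.9, 0.9, 0.1, 0.9],
                           "B": [0.1, 0.9, 0.1, 0.2]}, index=idx)
        t = ActivityTable(raw=sc.clip(0.01, 0.99), rescaled=sc)
        labels = pd.Series(["x", "x", "y", "y"], index=idx)
        res = subtype_association(t, labels, {"A": "high", "B": "low"},
                                  threshold=0.5)
        # samples 0 and 3 satisfy A-high & B-low; one from each subtype
        assert res.n_activated == 2
        assert res.enrichment["x"] == pytest.approx(0.5)

    def test_tiny_subtype_dropped_with_warning(self, rng):
        t, labels = self._subtyped_table(rng, {"a": 0.3, "b": 0.7}, n=5)
        labels.iloc[0] = "singleton"
        with pytest.warns(UserWarning, match="singleton"):
            subtype_association(t, labels, "P", threshold=0.5)
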