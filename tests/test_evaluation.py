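"""Benchmark construction, ROC/AUC against a counting oracle, rank-sum test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetlncsim import (
    LNC_MRNA,
    InteractionTable,
    LabeledPairSet,
    SimilarityNetwork,
    balanced_subset,
    build_positive_pairs,
    network_weights,
    restrict_labels,
    roc_auc,
    sample_negative_pairs,
    score_distribution_test,
)
from hetlncsim.errors import SamplingError


def table(*pairs):
    return InteractionTable(kind=LNC_MRNA, pairs=frozenset(pairs))


def labels_from(pos_scores, neg_scores):
    """Build labels + score map from two score lists."""
    scores = {}
    pos, neg = set(), set()
    for i, s in enumerate(pos_scores):
        pair = (f"P{i}a", f"P{i}b")
        scores[pair] = s
        pos.add(pair)
    for i, s in enumerate(neg_scores):
        pair = (f"N{i}a", f"N{i}b")
        scores[pair] = s
        neg.add(pair)
    return scores, LabeledPairSet(positives=frozenset(pos),
                                  negatives=frozenset(neg))


def counting_auc(pos, neg):
    """Oracle: exhaustive concordant-pair counting with ties worth 1/2."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestPositivePairs:
    def test_shared_target_yields_pair(self):
        assert build_positive_pairs(table(("L1", "G1"), ("L2", "G1"))) == {
            ("L1", "L2")}

    def test_disjoint_targets_yield_nothing(self):
        assert build_positive_pairs(table(("L1", "G1"), ("L2", "G2"))) == set()

    def test_three_sharing_lncrnas_give_all_pairs(self):
        pos = build_positive_pairs(
            table(("L1", "G1"), ("L2", "G1"), ("L3", "G1")))
        assert pos == {("L1", "L2"), ("L1", "L3"), ("L2", "L3")}


class TestNegativeSampling:
    def test_forced_sample_when_count_equals_available(self):
        got = sample_negative_pairs(
            {"a", "b", "c"}, {("a", "b")}, count=2, seed=0)
        assert got == {("a", "c"), ("b", "c")}

    def test_same_seed_reproduces_sample(self):
        universe = {f"L{i}" for i in range(12)}
        s1 = sample_negative_pairs(universe, frozenset(), 10, seed=5)
        s2 = sample_negative_pairs(universe, frozenset(), 10, seed=5)
        assert s1 == s2

    def test_overdraw_is_an_error(self):
        with pytest.raises(SamplingError):
            sample_negative_pairs({"a", "b", "c"}, {("a", "b")}, 4, seed=0)


def full_net(name, ids, value=0.5, rng=None):
    scores = {}
    ids = sorted(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            scores[(a, b)] = value if rng is None else float(rng.random())
    return SimilarityNetwork(name=name, coverage=frozenset(ids), scores=scores)


class TestBalancedSubset:
    def test_identical_networks_merge_to_cap(self):
        ids = [f"L{i}" for i in range(8)]
        positives = frozenset({("L0", "L1"), ("L2", "L3"), ("L4", "L5")})
        nets = [full_net("a", ids), full_net("b", ids)]
        labels = balanced_subset(nets, positives, ids, seed=1)
        assert labels.n_pos == 3  # cap=3, full duplicate overlap
        assert labels.positives == positives

    def test_disjoint_coverage_merges_additively(self):
        a = full_net("a", ["A1", "A2", "A3", "A4"])
        b = full_net("b", ["B1", "B2", "B3", "B4"])
        positives = frozenset({("A1", "A2"), ("A2", "A3"),
                               ("B1", "B2"), ("B2", "B3")})
        labels = balanced_subset(
            [a, b], positives,
            ["A1", "A2", "A3", "A4", "B1", "B2", "B3", "B4"], seed=2)
        assert labels.n_pos == 4  # cap=2 per network, no overlap

    def test_priority_prefers_widely_scored_pairs(self):
        ids = ["L0", "L1", "L2", "L3", "L4"]
        wide = full_net("wide", ids)
        narrow = SimilarityNetwork(
            name="narrow", coverage=frozenset(ids),
            scores={("L0", "L1"): 0.9, ("L2", "L3"): 0.8,
                    ("L0", "L4"): 0.1, ("L1", "L4"): 0.2})
        # cap = 2 (narrow scores two positives); "wide" must prefer the two
        # pairs also scored by "narrow" over its other positives
        positives = frozenset({("L0", "L1"), ("L2", "L3"), ("L0", "L2"),
                               ("L1", "L3")})
        labels = balanced_subset([wide, narrow], positives, ids, seed=3)
        assert {("L0", "L1"), ("L2", "L3")} <= labels.positives

    def test_network_without_positives_is_an_error(self):
        a = full_net("a", ["L0", "L1"])
        with pytest.raises(SamplingError, match="no positive"):
            balanced_subset([a], frozenset({("X1", "X2")}),
                            ["L0", "L1", "X1", "X2"], seed=0)

    def test_no_overlap_between_classes(self, small_networks, small_bundle):
        positives = build_positive_pairs(small_bundle.lnc_mrna)
        labels = balanced_subset(small_networks, positives,
                                 small_bundle.lnc_mrna.lncrnas, seed=11)
        assert not (labels.positives & labels.negatives)
        assert labels.positives <= positives


class TestRocAuc:
    @pytest.mark.parametrize(
        "pos,neg,expected",
        [
            ([0.9, 0.8], [0.7, 0.1], 1.0),
            ([0.9, 0.4], [0.6, 0.1], 0.75),
            ([0.5], [0.5], 0.5),
        ],
    )
    def test_known_auc_values(self, pos, neg, expected):
        scores, labels = labels_from(pos, neg)
        assert roc_auc(scores, labels).auc == pytest.approx(expected, abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self):
        scores, labels = labels_from([0.9, 0.5, 0.5], [0.5, 0.2])
        r = roc_auc(scores, labels)
        assert r.curve[0] == (0.0, 0.0) and r.curve[-1] == (1.0, 1.0)
        fpr = [p[0] for p in r.curve]
        tpr = [p[1] for p in r.curve]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)

    def test_sweep_matches_counting_oracle_with_ties(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            pos = rng.integers(0, 6, size=rng.integers(1, 10)) / 5.0
            neg = rng.integers(0, 6, size=rng.integers(1, 10)) / 5.0
            scores, labels = labels_from(list(pos), list(neg))
            assert roc_auc(scores, labels).auc == pytest.approx(
                counting_auc(pos, neg), abs=1e-12)

    def test_label_flip_antisymmetry(self):
        rng = np.random.default_rng(23)
        pos = list(rng.random(7))
        neg = list(rng.random(9))
        scores, labels = labels_from(pos, neg)
        flipped = LabeledPairSet(positives=labels.negatives,
                                 negatives=labels.positives)
        assert roc_auc(scores, labels).auc == pytest.approx(
            1.0 - roc_auc(scores, flipped).auc, abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10),
           st.lists(st.floats(0, 1), min_size=1, max_size=10),
           st.floats(0.5, 5.0))
    def test_monotone_transform_invariance(self, pos, neg, scale):
        # scores on a coarse grid so the transform cannot collapse distinct
        # values to the same float (which would introduce new ties)
        pos = [round(v, 3) for v in pos]
        neg = [round(v, 3) for v in neg]
        scores, labels = labels_from(pos, neg)
        base = roc_auc(scores, labels).auc
        transformed = {k: np.expm1(scale * v) for k, v in scores.items()}
        assert roc_auc(transformed, labels).auc == pytest.approx(base, abs=1e-12)

    def test_missing_score_is_an_error(self):
        scores, labels = labels_from([0.9], [0.1])
        del scores[next(iter(labels.negatives))]
        with pytest.raises(ValueError, match="no score"):
            roc_auc(scores, labels)


class TestNetworkWeights:
    def test_perfect_and_anti_separating_weights(self):
        scores, labels = labels_from([0.9, 0.8], [0.2, 0.1])
        cov = frozenset(x for p in scores for x in p)
        net = SimilarityNetwork(name="n", coverage=cov, scores=scores)
        w = network_weights([net], {"n": labels})
        assert w["n"] == 1.0
        flipped = LabeledPairSet(positives=labels.negatives,
                                 negatives=labels.positives)
        assert network_weights([net], {"n": flipped})["n"] == 0.0

    def test_random_scores_give_weight_near_half(self):
        rng = np.random.default_rng(31)
        pos = list(rng.random(300))
        neg = list(rng.random(300))
        scores, labels = labels_from(pos, neg)
        cov = frozenset(x for p in scores for x in p)
        net = SimilarityNetwork(name="n", coverage=cov, scores=scores)
        assert network_weights([net], {"n": labels})["n"] == pytest.approx(
            0.5, abs=0.08)


class TestDistributionTest:
    def test_identical_distributions_give_p_near_one(self):
        vals = list(np.linspace(0, 1, 15))
        scores, labels = labels_from(vals, vals)
        res = score_distribution_test(scores, labels)
        assert res.p_value > 0.9

    def test_fully_separated_classes_give_tiny_p(self):
        scores, labels = labels_from(
            list(np.linspace(0.6, 1.0, 20)), list(np.linspace(0.0, 0.4, 20)))
        res = score_distribution_test(scores, labels)
        assert res.method == "exact"
        assert res.p_value < 1e-3
        assert res.pos_quartiles[1] > res.neg_quartiles[1]

    def test_single_observation_per_class_is_valid(self):
        scores, labels = labels_from([0.9], [0.1])
        res = score_distribution_test(scores, labels)
        assert res.p_value >= 0.33


def test_evaluation_reproducible_under_fixed_seed(small_networks, small_bundle):
    positives = build_positive_pairs(small_bundle.lnc_mrna)
    runs = [
        balanced_subset(small_networks, positives,
                        small_bundle.lnc_mrna.lncrnas, seed=9)
        for _ in range(2)
    ]
    assert runs[0] == runs[1]
    w = [network_weights(small_networks,
                         {n.name: restrict_labels(runs[i], n)
                          for n in small_networks})
         for i in range(2)]
    assert w[0].weights == w[1].weights
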