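"""Validation protocol: shared-target benchmark, balanced subsets, ROC/AUC.

Two lncRNAs sharing at least one target mRNA form a positive pair; negative
pairs are drawn uniformly from lncRNA pairs with no shared target.  Because
layer coverage differs wildly, evaluation uses per-layer balanced subsets:
every layer contributes the same number of positives and negatives (the
minimum any layer can score), positives chosen with priority for pairs
scored by more layers, and the per-layer selections are merged with
duplicates removed.  Each layer's AUC on its own subset doubles as its
fusion weight.

AUC is computed by a threshold sweep over distinct scores; the trapezoidal
area of that curve equals the Mann–Whitney probability with ties counted
one half.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import (
    LNC_MRNA,
    InteractionTable,
    IntegrationWeights,
    LabeledPairSet,
    RocResult,
    SimilarityNetwork,
    canonical_pair,
)
from .errors import SamplingError

Pair = tuple[str, str]

__all__ = [
    "build_positive_pairs",
    "sample_negative_pairs",
    "restrict_labels",
    "balanced_subset",
    "roc_auc",
    "network_weights",
    "score_distribution_test",
    "DistributionTest",
]


def build_positive_pairs(lnc_mrna: InteractionTable) -> frozenset[Pair]:
    """All unordered lncRNA pairs sharing at least one target mRNA."""
    if lnc_mrna.kind != LNC_MRNA:
        raise ValueError(f"expected {LNC_MRNA} interactions, got {lnc_mrna.kind}")
    by_target: dict[str, set[str]] = {}
    for lnc, mrna in lnc_mrna.pairs:
        by_target.setdefault(mrna, set()).add(lnc)
    positives: set[Pair] = set()
    for lncs in by_target.values():
        ordered = sorted(lncs)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1:]:
                positives.add((a, b))
    return frozenset(positives)


def _all_pairs(universe: Iterable[str]) -> list[Pair]:
    ids = sorted(set(universe))
    return [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]


def sample_negative_pairs(
    universe: Iterable[str],
    positives: frozenset[Pair] | set[Pair],
    count: int,
    seed: int,
) -> frozenset[Pair]:
    """Draw ``count`` non-positive pairs uniformly without replacement."""
    if count <= 0:
        raise ValueError("count must be positive")
    candidates = [p for p in _all_pairs(universe) if p not in positives]
    if count > len(candidates):
        raise SamplingError(
            f"requested {count} negative pairs but only {len(candidates)} exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=count, replace=False)
    return frozenset(candidates[i] for i in chosen)


def restrict_labels(labels: LabeledPairSet, net: SimilarityNetwork) -> LabeledPairSet:
    """Keep only the labeled pairs the network actually scores."""
    return LabeledPairSet(
        positives=frozenset(p for p in labels.positives if p in net.scores),
        negatives=frozenset(p for p in labels.negatives if p in net.scores),
        seed=labels.seed,
    )


def balanced_subset(
    networks: Sequence[SimilarityNetwork],
    positives: frozenset[Pair] | set[Pair],
    negatives_universe: Iterable[str],
    seed: int,
) -> LabeledPairSet:
    """Per-layer balanced positive/negative selection, merged.

    cap = the minimum number of positives any layer scores.  From each
    layer take its top ``cap`` scored positives ranked by (number of layers
    scoring the pair, descending; canonical pair id, ascending), and
    ``cap`` seeded negatives drawn from non-positive pairs over
    ``negatives_universe`` that the layer scores.  Selections are merged
    with duplicates removed.
    """
    if not networks:
        raise ValueError("at least one network is required")
    positives = frozenset(positives)
    ordered = sorted(networks, key=lambda n: n.name)
    scored_pos = {net.name: sorted(p for p in positives if p in net.scores)
                  for net in ordered}
    for name, pos in scored_pos.items():
        if not pos:
            raise SamplingError(f"network {name!r} scores no positive pair")
    cap = min(len(pos) for pos in scored_pos.values())

    support = {p: sum(p in net.scores for net in ordered) for p in positives}
    neg_candidates = [p for p in _all_pairs(negatives_universe)
                      if p not in positives]

    merged_pos: set[Pair] = set()
    merged_neg: set[Pair] = set()
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(ordered))
    for child, net in zip(children, ordered):
        ranked = sorted(scored_pos[net.name], key=lambda p: (-support[p], p))
        merged_pos.update(ranked[:cap])
        scored_neg = [p for p in neg_candidates if p in net.scores]
        if len(scored_neg) < cap:
            raise SamplingError(
                f"network {net.name!r} scores only {len(scored_neg)} "
                f"negative candidates, need {cap}"
            )
        rng = np.random.default_rng(child)
        chosen = rng.choice(len(scored_neg), size=cap, replace=False)
        merged_neg.update(scored_neg[i] for i in chosen)
    return LabeledPairSet(
        positives=frozenset(merged_pos),
        negatives=frozenset(merged_neg),
        seed=seed,
    )


def roc_auc(scores: Mapping[Pair, float], labels: LabeledPairSet) -> RocResult:
    """ROC curve by threshold sweep; AUC = trapezoidal area (ties count ½)."""
    if labels.n_pos == 0 or labels.n_neg == 0:
        raise ValueError("both classes must be non-empty")
    try:
        pos = np.array([scores[p] for p in sorted(labels.positives)])
        neg = np.array([scores[p] for p in sorted(labels.negatives)])
    except KeyError as exc:
        raise ValueError(f"labeled pair has no score: {exc}") from None
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    s = np.concatenate([pos, neg])
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    # group by distinct threshold: record cumulative (FP, TP) after each group
    distinct = np.nonzero(np.diff(s))[0]
    boundaries = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(y)[boundaries]
    fp = np.cumsum(1 - y)[boundaries]
    tpr = np.concatenate([[0.0], tp / len(pos)])
    fpr = np.concatenate([[0.0], fp / len(neg)])
    auc = float(np.trapezoid(tpr, fpr))
    curve = tuple((float(x), float(t)) for x, t in zip(fpr, tpr))
    return RocResult(auc=auc, curve=curve, n_pos=len(pos), n_neg=len(neg))


def network_weights(
    networks: Sequence[SimilarityNetwork],
    labels_per_network: Mapping[str, LabeledPairSet],
) -> IntegrationWeights:
    """Per-layer AUC on the layer's own labeled pairs, used as fusion weight."""
    weights = {}
    for net in networks:
        labels = labels_per_network[net.name]
        weights[net.name] = roc_auc(net.scores, labels).auc
    return IntegrationWeights(weights=weights)


@dataclass(frozen=True)
class DistributionTest:
    """Two-sided rank-sum comparison of positive vs negative scores."""

    statistic: float
    p_value: float
    method: str
    pos_quartiles: tuple[float, float, float]
    neg_quartiles: tuple[float, float, float]
    n_pos: int
    n_neg: int


def score_distribution_test(
    scores: Mapping[Pair, float], labels: LabeledPairSet
) -> DistributionTest:
    """Wilcoxon rank-sum (Mann–Whitney) test of class score distributions.

    Exact enumeration for small tie-free samples (both classes ≤ 20),
    normal approximation with tie correction otherwise.
    """
    if labels.n_pos == 0 or labels.n_neg == 0:
        raise ValueError("both classes must be non-empty")
    pos = np.array([scores[p] for p in sorted(labels.positives)])
    neg = np.array([scores[p] for p in sorted(labels.negatives)])
    has_ties = len(np.unique(np.concatenate([pos, neg]))) < len(pos) + len(neg)
    method = "exact" if (len(pos) <= 20 and len(neg) <= 20 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method=method)
    q = (25.0, 50.0, 75.0)
    return DistributionTest(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=method,
        pos_quartiles=tuple(float(v) for v in np.percentile(pos, q)),
        neg_quartiles=tuple(float(v) for v in np.percentile(neg, q)),
        n_pos=len(pos),
        n_neg=len(neg),
    )
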