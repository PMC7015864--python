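"""Core domain types shared across the package.

Everything downstream operates on the in-memory containers defined here;
file parsing lives in :mod:`hetlncsim.io` and never leaks raw rows into the
rest of the code.  All lncRNA pairs are unordered and canonicalised with the
two ids in lexicographic order, because every similarity this package
computes is symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LNC_MIRNA",
    "LNC_DISEASE",
    "LNC_MRNA",
    "INTERACTION_KINDS",
    "canonical_pair",
    "InteractionTable",
    "SquareSimilarityMatrix",
    "ExpressionMatrix",
    "DagEdgeList",
    "FeatureVector",
    "SimilarityNetwork",
    "IntegrationWeights",
    "IntegratedNetwork",
    "LabeledPairSet",
    "RocResult",
]

# Interaction kinds (partner entity class differs per kind).
LNC_MIRNA = "lncRNA-miRNA"
LNC_DISEASE = "lncRNA-disease"
LNC_MRNA = "lncRNA-mRNA"
INTERACTION_KINDS = (LNC_MIRNA, LNC_DISEASE, LNC_MRNA)

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Return the unordered pair (a, b) with ids in lexicographic order.

    Raises ``ValueError`` for a self-pair: self-similarity is 1 by
    definition and never stored.
    """
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class InteractionTable:
    """Deduplicated bipartite interaction set (lncRNA id, partner id)."""

    kind: str
    pairs: frozenset[Pair]

    def __post_init__(self) -> None:
        if self.kind not in INTERACTION_KINDS:
            raise ValueError(f"unknown interaction kind: {self.kind!r}")
        for lnc, partner in self.pairs:
            if not lnc or not partner or lnc != lnc.strip() or partner != partner.strip():
                raise ValueError(f"invalid ids in pair {(lnc, partner)!r}")

    @property
    def lncrnas(self) -> frozenset[str]:
        return frozenset(l for l, _ in self.pairs)

    @property
    def partners(self) -> frozenset[str]:
        return frozenset(p for _, p in self.pairs)

    def partners_of(self, lnc: str) -> frozenset[str]:
        return frozenset(p for l, p in self.pairs if l == lnc)

    def partner_map(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for l, p in self.pairs:
            out.setdefault(l, set()).add(p)
        return out

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class SquareSimilarityMatrix:
    """Symmetric entity-by-entity similarity matrix with unit diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in similarity matrix")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("diagonal entries must equal 1")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("matrix not symmetric within 1e-9")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "_index", {e: i for i, e in enumerate(self.ids)})

    def __contains__(self, entity: str) -> bool:
        return entity in self._index  # type: ignore[attr-defined]

    def value(self, a: str, b: str) -> float:
        idx: dict[str, int] = self._index  # type: ignore[attr-defined]
        return float(self.values[idx[a], idx[b]])

    def indices(self, entities: Iterable[str]) -> np.ndarray:
        idx: dict[str, int] = self._index  # type: ignore[attr-defined]
        return np.array([idx[e] for e in entities], dtype=int)


@dataclass(frozen=True)
class ExpressionMatrix:
    """lncRNA-by-condition expression matrix; NaN marks a missing value.

    ``unit`` records the normalisation (TPM or FPKM) declared for the file;
    matrices with different units are never merged.
    """

    data: pd.DataFrame  # rows = lncRNA ids, columns = condition ids
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in ("TPM", "FPKM"):
            raise ValueError(f"unit must be TPM or FPKM, got {self.unit!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate lncRNA ids in expression matrix")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def lncrna_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def condition_ids(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def profile(self, lnc: str) -> np.ndarray:
        return self.data.loc[lnc].to_numpy(dtype=float)


@dataclass(frozen=True)
class DagEdgeList:
    """Parent→child edges of a disease hierarchy, unique, no self-loops."""

    edges: tuple[Pair, ...]

    def __post_init__(self) -> None:
        seen = set()
        for parent, child in self.edges:
            if parent == child:
                raise ValueError(f"self-loop edge {parent!r}")
            if (parent, child) in seen:
                raise ValueError(f"duplicate edge {(parent, child)!r}")
            seen.add((parent, child))

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(n for e in self.edges for n in e)


@dataclass(frozen=True)
class FeatureVector:
    """Named numeric vector over a union of partner entities."""

    keys: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) != len(self.keys):
            raise ValueError("values length must match keys")
        object.__setattr__(self, "values", v)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))


@dataclass(frozen=True)
class SimilarityNetwork:
    """One evidence layer: scored unordered lncRNA pairs plus coverage.

    ``coverage`` is the set of lncRNAs the layer is able to score (e.g. the
    lncRNAs with at least one miRNA partner); pairs whose score is undefined
    (zero-norm vector, constant profile) are simply absent from ``scores``.
    Self-similarity is 1 by convention and never stored.
    """

    name: str
    coverage: frozenset[str]
    scores: Mapping[Pair, float]

    def __post_init__(self) -> None:
        for (a, b) in self.scores:
            if a >= b:
                raise ValueError(f"pair {(a, b)!r} not canonical")
            if a not in self.coverage or b not in self.coverage:
                raise ValueError(f"pair {(a, b)!r} outside coverage")
        object.__setattr__(self, "scores", dict(self.scores))

    def score(self, a: str, b: str) -> float:
        return self.scores[canonical_pair(a, b)]

    def has_pair(self, a: str, b: str) -> bool:
        return canonical_pair(a, b) in self.scores

    def pairs(self) -> Iterator[Pair]:
        return iter(self.scores)

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class IntegrationWeights:
    """Per-layer fusion weights: the layer's AUC on the shared-target task."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, w in self.weights.items():
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"weight for {name!r} outside [0, 1]: {w}")
        object.__setattr__(self, "weights", dict(self.weights))

    def __getitem__(self, name: str) -> float:
        return self.weights[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.weights)


@dataclass(frozen=True)
class IntegratedNetwork:
    """Fused network: per-pair weighted-average score plus supporting layers."""

    scores: Mapping[Pair, float]
    support: Mapping[Pair, tuple[str, ...]]

    def __post_init__(self) -> None:
        if set(self.scores) != set(self.support):
            raise ValueError("scores and support must cover identical pairs")
        for pair, layers in self.support.items():
            if not layers:
                raise ValueError(f"pair {pair!r} has empty support")
        object.__setattr__(self, "scores", dict(self.scores))
        object.__setattr__(self, "support", dict(self.support))

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class LabeledPairSet:
    """Positive (shared-target) and negative lncRNA pairs for ROC evaluation."""

    positives: frozenset[Pair]
    negatives: frozenset[Pair]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("positives and negatives overlap")

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)


@dataclass(frozen=True)
class RocResult:
    """ROC curve and its trapezoidal area."""

    auc: float
    curve: tuple[tuple[float, float], ...]  # (FPR, TPR) points
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        fpr = np.array([p[0] for p in self.curve])
        tpr = np.array([p[1] for p in self.curve])
        if self.curve[0] != (0.0, 0.0) or self.curve[-1] != (1.0, 1.0):
            raise ValueError("ROC curve must run from (0,0) to (1,1)")
        if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
            raise ValueError("ROC curve coordinates must be non-decreasing")
        area = float(np.trapezoid(tpr, fpr))
        if abs(area - self.auc) > 1e-12:
            raise ValueError("auc inconsistent with trapezoidal curve area")
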