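"""Wang-style disease semantic similarity over a MeSH-like hierarchy.

A disease term ``i`` is characterised by the sub-DAG ``DAG_i`` induced by
its ancestor set ``T_i`` (all terms reachable via parent edges, plus ``i``
itself).  Each ancestor ``s`` receives a semantic contribution

    D_i(i) = 1
    D_i(s) = max{ delta * D_i(s') : s' a child of s within T_i }

with a decay factor ``delta`` in (0, 1), so a term ``h`` edges above the
anchor contributes ``delta**h`` (the max picks the shortest ancestor path).
The semantic value ``DV(i)`` sums the contributions over ``T_i``, and the
similarity of two terms is the contribution mass on their shared ancestors
relative to their combined semantic values:

    DS(i1, i2) = sum_{s in T_i1 ∩ T_i2} (D_i1(s) + D_i2(s)) / (DV(i1) + DV(i2))

DS is symmetric, lies in [0, 1], equals 1 on the diagonal, and is 0 for
terms that share no ancestor (multiple hierarchy roots are allowed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .core import DagEdgeList
from .errors import CycleError

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseDAG",
    "SemanticContributionTable",
    "DiseaseSimilarityMatrix",
    "semantic_contributions",
    "semantic_value",
    "disease_similarity",
    "disease_similarity_matrix",
]

DEFAULT_DELTA = 0.5  # the conventional decay value for MeSH semantics


class DiseaseDAG:
    """Rooted directed acyclic hierarchy of disease terms (parent→child).

    Acyclicity is verified at construction; a cycle is a hard error because
    the contribution recursion diverges on cycles.
    """

    def __init__(self, edges: DagEdgeList | Iterable[tuple[str, str]],
                 extra_nodes: Iterable[str] = ()) -> None:
        edge_list = edges.edges if isinstance(edges, DagEdgeList) else tuple(edges)
        g = nx.DiGraph()
        g.add_nodes_from(extra_nodes)
        g.add_edges_from(edge_list)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
            raise CycleError(f"disease hierarchy contains a cycle: {path}")
        self._g = g

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    def children(self, node: str) -> frozenset[str]:
        return frozenset(self._g.successors(node))

    def parents(self, node: str) -> frozenset[str]:
        return frozenset(self._g.predecessors(node))

    def ancestors(self, node: str) -> frozenset[str]:
        """All terms reachable from ``node`` via parent edges (excluding it)."""
        if node not in self._g:
            raise KeyError(f"unknown disease id {node!r}")
        return frozenset(nx.ancestors(self._g, node))

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()


@dataclass(frozen=True)
class SemanticContributionTable:
    """Contributions D_i(s) of every term s in T_i to the anchor term i."""

    anchor: str
    delta: float
    contributions: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.contributions.get(self.anchor) != 1.0:
            raise ValueError("anchor contribution must be exactly 1")
        if any(not (0.0 < v <= 1.0) for v in self.contributions.values()):
            raise ValueError("contributions must lie in (0, 1]")
        object.__setattr__(self, "contributions", dict(self.contributions))


def semantic_contributions(
    dag: DiseaseDAG, i: str, delta: float = DEFAULT_DELTA
) -> SemanticContributionTable:
    """Compute D_i(s) for every s in T_i by memoized traversal."""
    if i not in dag:
        raise KeyError(f"unknown disease id {i!r}")
    if not (0.0 < delta < 1.0):
        raise ValueError(f"delta must lie in (0, 1), got {delta}")
    t_i = dag.ancestors(i) | {i}
    memo: dict[str, float] = {i: 1.0}

    def contrib(s: str) -> float:
        if s in memo:
            return memo[s]
        # children restricted to the sub-DAG induced by T_i
        kids = [c for c in dag.children(s) if c in t_i]
        memo[s] = max(delta * contrib(c) for c in kids)
        return memo[s]

    for s in t_i:
        contrib(s)
    return SemanticContributionTable(anchor=i, delta=delta, contributions=memo)


def semantic_value(table: SemanticContributionTable) -> float:
    """DV(i): the summed contributions over T_i; always >= 1."""
    return float(sum(table.contributions.values()))


def disease_similarity(
    dag: DiseaseDAG, i1: str, i2: str, delta: float = DEFAULT_DELTA
) -> float:
    """DS(i1, i2): shared-ancestor contribution mass over combined DV."""
    t1 = semantic_contributions(dag, i1, delta)
    t2 = semantic_contributions(dag, i2, delta)
    return _ds_from_tables(t1, t2)


def _ds_from_tables(
    t1: SemanticContributionTable, t2: SemanticContributionTable
) -> float:
    if t1.anchor == t2.anchor:
        return 1.0
    shared = t1.contributions.keys() & t2.contributions.keys()
    if not shared:
        return 0.0
    num = sum(t1.contributions[s] + t2.contributions[s] for s in shared)
    dv1 = semantic_value(t1)
    dv2 = semantic_value(t2)
    return float(num / (dv1 + dv2))


@dataclass(frozen=True)
class DiseaseSimilarityMatrix:
    """All-pairs DS over a term list, with cached semantic values."""

    ids: tuple[str, ...]
    values: np.ndarray
    semantic_values: Mapping[str, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "semantic_values", dict(self.semantic_values))
        object.__setattr__(self, "_index", {d: k for k, d in enumerate(self.ids)})

    def __contains__(self, disease: str) -> bool:
        return disease in self._index  # type: ignore[attr-defined]

    def ds(self, d1: str, d2: str) -> float:
        idx: dict[str, int] = self._index  # type: ignore[attr-defined]
        return float(self.values[idx[d1], idx[d2]])

    def dv(self, d: str) -> float:
        return self.semantic_values[d]


def disease_similarity_matrix(
    dag: DiseaseDAG, ids: Sequence[str], delta: float = DEFAULT_DELTA
) -> DiseaseSimilarityMatrix:
    """All-pairs DS matrix; contribution tables are computed once per term."""
    ids = tuple(ids)
    tables = {d: semantic_contributions(dag, d, delta) for d in ids}
    dvs = {d: semantic_value(tables[d]) for d in ids}
    n = len(ids)
    values = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            ds = _ds_from_tables(tables[ids[a]], tables[ids[b]])
            values[a, b] = values[b, a] = ds
    return DiseaseSimilarityMatrix(ids=ids, values=values, semantic_values=dvs)
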