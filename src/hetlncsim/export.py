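"""Graph export of similarity layers for visualization tools.

Each retained pair becomes one edge per layer that scores it at or above
the threshold, carrying ``network`` (the evidence-layer label) and
``score`` attributes — two layers scoring the same pair yield two parallel
edges, mirroring colored multi-layer network views.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import networkx as nx

from .core import SimilarityNetwork

logger = logging.getLogger(__name__)

__all__ = ["export_graph", "build_multigraph"]


def build_multigraph(
    networks: Sequence[SimilarityNetwork], threshold: float
) -> nx.MultiGraph:
    """Multigraph over lncRNAs incident to a retained edge."""
    if not networks:
        raise ValueError("at least one network is required")
    g = nx.MultiGraph()
    for net in sorted(networks, key=lambda n: n.name):
        for (a, b), score in sorted(net.scores.items()):
            if score >= threshold:
                g.add_edge(a, b, network=net.name, score=float(score))
    return g


def export_graph(
    networks: Sequence[SimilarityNetwork],
    threshold: float,
    path: str | Path,
    fmt: str = "graphml",
) -> nx.MultiGraph:
    """Write retained edges as GraphML or a plain edge list."""
    if fmt not in ("graphml", "edgelist"):
        raise ValueError(f"unknown export format {fmt!r}")
    g = build_multigraph(networks, threshold)
    if g.number_of_edges() == 0:
        logger.warning("threshold %g excludes all edges; writing empty graph",
                       threshold)
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        rows = [
            f"{a}\t{b}\t{data['network']}\t{data['score']!r}"
            for a, b, data in sorted(
                g.edges(data=True),
                key=lambda e: (e[0], e[1], e[2]["network"]),
            )
        ]
        path.write_text("\n".join(rows) + ("\n" if rows else ""),
                        encoding="utf-8")
    return g
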