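"""AUC-weighted fusion of evidence layers into one integrated network.

The integrated score of a pair is the weighted average

    S_bar = sum_i AUC_i * S_i / n

where ``AUC_i`` is the layer's discrimination weight and ``S_i`` its score
for the pair.  Two policy axes are exposed:

* ``missing`` — "available" (default): ``n`` counts only the layers that
  actually score the pair, so partially-covered pairs are kept; "strict":
  only pairs scored by every layer are emitted, with ``n`` the layer count.
* ``denominator`` — "n" (default, the literal weighted-average form above;
  note it deflates scores below the per-layer scale because weights are
  below 1) or "sum-weights", the normalised convex combination dividing by
  the sum of contributing weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import IntegratedNetwork, IntegrationWeights, SimilarityNetwork

__all__ = ["integrate", "coverage_report", "CoverageReport"]


def integrate(
    networks: Sequence[SimilarityNetwork],
    weights: IntegrationWeights,
    missing: str = "available",
    denominator: str = "n",
) -> IntegratedNetwork:
    """Fuse layers by the AUC-weighted average."""
    if not networks:
        raise ValueError("at least one network is required")
    if missing not in ("available", "strict"):
        raise ValueError(f"unknown missing policy {missing!r}")
    if denominator not in ("n", "sum-weights"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    names = [net.name for net in networks]
    if len(set(names)) != len(names):
        raise ValueError("duplicate network names")
    unknown = set(weights) - set(names)
    if unknown:
        raise ValueError(f"weights name unknown networks: {sorted(unknown)}")
    missing_w = set(names) - set(weights)
    if missing_w:
        raise ValueError(f"no weight supplied for networks: {sorted(missing_w)}")

    all_pairs = set()
    for net in networks:
        all_pairs.update(net.pairs())

    # iterate layers in name order so input order never changes the result
    ordered = sorted(networks, key=lambda n: n.name)
    scores: dict[tuple[str, str], float] = {}
    support: dict[tuple[str, str], tuple[str, ...]] = {}
    for pair in all_pairs:
        contributing = [net for net in ordered if pair in net.scores]
        if missing == "strict" and len(contributing) < len(networks):
            continue
        numer = sum(weights[net.name] * net.scores[pair] for net in contributing)
        if denominator == "n":
            denom = float(len(contributing))
        else:
            denom = sum(weights[net.name] for net in contributing)
            if denom == 0.0:
                continue  # all contributing weights zero: score undefined
        scores[pair] = numer / denom
        support[pair] = tuple(net.name for net in contributing)
    return IntegratedNetwork(scores=scores, support=support)


@dataclass(frozen=True)
class CoverageReport:
    """lncRNA coverage overlap between layers (Venn-style regions)."""

    per_layer: dict[str, int]
    union: int
    # exclusive region counts keyed by the sorted tuple of member layers
    regions: dict[tuple[str, ...], int]

    def intersection(self, *names: str) -> int:
        """Count of lncRNAs covered by at least all of ``names``."""
        want = set(names)
        return sum(c for members, c in self.regions.items()
                   if want <= set(members))


def coverage_report(networks: Sequence[SimilarityNetwork]) -> CoverageReport:
    """Per-layer coverage counts and all overlap-region counts."""
    if not networks:
        raise ValueError("at least one network is required")
    membership: dict[str, set[str]] = {}
    for net in networks:
        for lnc in net.coverage:
            membership.setdefault(lnc, set()).add(net.name)
    regions: dict[tuple[str, ...], int] = {}
    for layers in membership.values():
        key = tuple(sorted(layers))
        regions[key] = regions.get(key, 0) + 1
    return CoverageReport(
        per_layer={net.name: len(net.coverage) for net in networks},
        union=len(membership),
        regions=regions,
    )
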