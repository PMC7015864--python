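"""Synthetic dataset generator with planted co-function clusters.

Emulates the five kinds of input the pipeline needs — a disease hierarchy,
a miRNA functional-similarity matrix, lncRNA–miRNA / –disease / –mRNA
interaction tables, and two expression atlases — with a planted cluster
structure: lncRNAs are assigned to clusters round-robin, each cluster owns
a pool of miRNAs, diseases (sibling leaves under a cluster-specific branch
of the hierarchy), mRNAs, and a mean expression profile per atlas.  Each
lncRNA keeps each own-pool partner with probability ``overlap`` and picks
up each foreign partner with probability ``leak``; a cluster "anchor" mRNA
is always included so every same-cluster pair is guaranteed a shared
target (the positive class of the benchmark), and no cross-cluster pair
shares a target when ``leak`` is 0.

All randomness flows from a single seed through named spawned sub-streams,
so adding a new sub-generator never perturbs the draws of existing ones.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    LNC_DISEASE,
    LNC_MIRNA,
    LNC_MRNA,
    DagEdgeList,
    ExpressionMatrix,
    InteractionTable,
    SquareSimilarityMatrix,
)

__all__ = ["FixtureParams", "FixtureBundle", "generate_fixture", "write_fixture"]

# fixed order of named random sub-streams; append-only
_STREAMS = ("misim", "mirna", "disease", "mrna", "expr_a", "expr_b")


@dataclass(frozen=True)
class FixtureParams:
    """Generation parameters; defaults define the standard study conditions."""

    n_lncrnas: int = 60
    n_clusters: int = 3
    n_mirnas: int = 30
    n_diseases: int = 30
    n_mrnas: int = 30
    n_tissues_a: int = 53  # GTEx-like atlas (TPM)
    n_tissues_b: int = 23  # NONCODE-like atlas (FPKM)
    within_cluster_partner_overlap: float = 0.9
    cross_cluster_leak: float = 0.05
    expression_noise_sd: float = 0.25
    dag_depth: int = 3
    dag_branching: int = 2
    seed: int = 7

    def __post_init__(self) -> None:
        if not (0.0 < self.within_cluster_partner_overlap <= 1.0):
            raise ValueError("overlap must lie in (0, 1]")
        if not (0.0 <= self.cross_cluster_leak < 1.0):
            raise ValueError("leak must lie in [0, 1)")
        if self.cross_cluster_leak >= self.within_cluster_partner_overlap:
            raise ValueError("overlap must exceed leak (no planted signal)")
        if self.expression_noise_sd < 0:
            raise ValueError("expression_noise_sd must be non-negative")
        if self.n_clusters < 2 or self.n_lncrnas < 2 * self.n_clusters:
            raise ValueError("need >= 2 clusters and >= 2 lncRNAs per cluster")
        for name in ("n_mirnas", "n_diseases", "n_mrnas"):
            if getattr(self, name) < self.n_clusters:
                raise ValueError(f"{name} must be >= n_clusters (empty pool)")
        if min(self.n_tissues_a, self.n_tissues_b) < 3:
            raise ValueError("each atlas needs >= 3 tissues")
        if self.dag_depth < 1 or self.dag_branching < 1:
            raise ValueError("dag_depth and dag_branching must be >= 1")


@dataclass(frozen=True)
class FixtureBundle:
    """One internally consistent synthetic dataset."""

    params: FixtureParams
    dag: DagEdgeList
    misim: SquareSimilarityMatrix
    lnc_mirna: InteractionTable
    lnc_disease: InteractionTable
    lnc_mrna: InteractionTable
    expr_a: ExpressionMatrix
    expr_b: ExpressionMatrix
    truth: dict[str, int]  # lncRNA id -> cluster index


def _pools(ids: list[str], n_clusters: int) -> list[list[str]]:
    """Round-robin split of ids into per-cluster pools."""
    pools: list[list[str]] = [[] for _ in range(n_clusters)]
    for i, ident in enumerate(ids):
        pools[i % n_clusters].append(ident)
    return pools


def _sample_partners(
    rng: np.random.Generator,
    own_pool: list[str],
    other_pools: list[list[str]],
    overlap: float,
    leak: float,
    anchor: bool,
) -> list[str]:
    chosen = []
    start = 1 if anchor else 0
    if anchor:
        chosen.append(own_pool[0])  # guarantees within-cluster sharing
    for item in own_pool[start:]:
        if rng.random() < overlap:
            chosen.append(item)
    if not chosen:
        chosen.append(own_pool[int(rng.integers(len(own_pool)))])
    # leak: per foreign pool, one uniformly drawn partner with probability
    # `leak` — scales with the number of clusters, not with pool size, so
    # cross-cluster contamination stays a minority signal
    for pool in other_pools:
        if rng.random() < leak:
            chosen.append(pool[int(rng.integers(len(pool)))])
    return chosen


def _cluster_dag(params: FixtureParams, disease_pools: list[list[str]]
                 ) -> DagEdgeList:
    """Root + per-cluster complete internal tree; diseases as leaf siblings."""
    edges: list[tuple[str, str]] = []
    for c, pool in enumerate(disease_pools):
        levels: list[list[str]] = [["ROOT"]]
        counter = 0
        for depth in range(1, params.dag_depth + 1):
            level = []
            for parent in levels[-1]:
                for _ in range(params.dag_branching):
                    node = f"C{c}N{counter:03d}"
                    counter += 1
                    edges.append((parent, node))
                    level.append(node)
            levels.append(level)
        deepest = levels[-1]
        for i, disease in enumerate(pool):
            edges.append((deepest[i % len(deepest)], disease))
    return DagEdgeList(edges=tuple(edges))


def _misim(rng: np.random.Generator, mirnas: list[str],
           cluster_of: dict[str, int]) -> SquareSimilarityMatrix:
    n = len(mirnas)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if cluster_of[mirnas[i]] == cluster_of[mirnas[j]]:
                v = rng.uniform(0.6, 1.0)
            else:
                v = rng.uniform(0.0, 0.3)
            values[i, j] = values[j, i] = v
    return SquareSimilarityMatrix(ids=tuple(mirnas), values=values)


def _expression(
    rng: np.random.Generator,
    lncrnas: list[str],
    truth: dict[str, int],
    n_clusters: int,
    n_tissues: int,
    prefix: str,
    noise_sd: float,
    unit: str,
) -> ExpressionMatrix:
    tissues = [f"{prefix}{t:02d}" for t in range(1, n_tissues + 1)]
    # cluster mean profiles on a unit-ish scale so noise_sd is relative to it
    means = rng.uniform(0.5, 2.5, size=(n_clusters, n_tissues))
    rows = []
    for lnc in lncrnas:
        noise = rng.normal(0.0, noise_sd, size=n_tissues) if noise_sd > 0 \
            else np.zeros(n_tissues)
        rows.append(np.clip(means[truth[lnc]] + noise, 0.0, None))
    df = pd.DataFrame(np.array(rows), index=lncrnas, columns=tissues)
    return ExpressionMatrix(data=df, unit=unit)


def generate_fixture(params: FixtureParams | None = None, **kwargs) -> FixtureBundle:
    """Generate a complete bundle; ``kwargs`` override FixtureParams fields."""
    if params is None:
        params = FixtureParams(**kwargs)
    elif kwargs:
        params = FixtureParams(**{**asdict(params), **kwargs})
    streams = dict(zip(_STREAMS, np.random.SeedSequence(params.seed).spawn(
        len(_STREAMS))))

    lncrnas = [f"LNC{i:03d}" for i in range(1, params.n_lncrnas + 1)]
    mirnas = [f"MIR{i:03d}" for i in range(1, params.n_mirnas + 1)]
    diseases = [f"DIS{i:03d}" for i in range(1, params.n_diseases + 1)]
    mrnas = [f"GENE{i:03d}" for i in range(1, params.n_mrnas + 1)]
    truth = {lnc: i % params.n_clusters for i, lnc in enumerate(lncrnas)}

    mirna_pools = _pools(mirnas, params.n_clusters)
    disease_pools = _pools(diseases, params.n_clusters)
    mrna_pools = _pools(mrnas, params.n_clusters)
    mirna_cluster = {m: c for c, pool in enumerate(mirna_pools) for m in pool}

    misim = _misim(np.random.default_rng(streams["misim"]), mirnas, mirna_cluster)
    dag = _cluster_dag(params, disease_pools)

    tables = {}
    for key, pools, kind, anchor in (
        ("mirna", mirna_pools, LNC_MIRNA, False),
        ("disease", disease_pools, LNC_DISEASE, False),
        ("mrna", mrna_pools, LNC_MRNA, True),
    ):
        rng = np.random.default_rng(streams[key])
        pairs = set()
        for lnc in lncrnas:
            c = truth[lnc]
            others = [p for k, p in enumerate(pools) if k != c]
            for partner in _sample_partners(
                rng, pools[c], others,
                params.within_cluster_partner_overlap,
                params.cross_cluster_leak, anchor,
            ):
                pairs.add((lnc, partner))
        tables[key] = InteractionTable(kind=kind, pairs=frozenset(pairs))

    expr_a = _expression(np.random.default_rng(streams["expr_a"]), lncrnas,
                         truth, params.n_clusters, params.n_tissues_a, "TA",
                         params.expression_noise_sd, "TPM")
    expr_b = _expression(np.random.default_rng(streams["expr_b"]), lncrnas,
                         truth, params.n_clusters, params.n_tissues_b, "TB",
                         params.expression_noise_sd, "FPKM")
    return FixtureBundle(
        params=params, dag=dag, misim=misim,
        lnc_mirna=tables["mirna"], lnc_disease=tables["disease"],
        lnc_mrna=tables["mrna"], expr_a=expr_a, expr_b=expr_b, truth=truth,
    )


def write_fixture(bundle: FixtureBundle, directory: str | Path) -> None:
    """Write every file in the TSV dialects the readers expect, plus a
    manifest recording the parameters and seed."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    d.joinpath("dag.tsv").write_text(
        "".join(f"{p}\t{c}\n" for p, c in bundle.dag.edges), encoding="utf-8")

    ids = bundle.misim.ids
    lines = ["\t".join(("miRNA",) + ids)]
    for i, row_id in enumerate(ids):
        lines.append("\t".join(
            [row_id] + [repr(float(v)) for v in bundle.misim.values[i]]))
    d.joinpath("misim.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    for fname, table in (("lnc_mirna.tsv", bundle.lnc_mirna),
                         ("lnc_disease.tsv", bundle.lnc_disease),
                         ("lnc_mrna.tsv", bundle.lnc_mrna)):
        d.joinpath(fname).write_text(
            "".join(f"{a}\t{b}\n" for a, b in sorted(table.pairs)),
            encoding="utf-8")

    for fname, expr in (("expr_a.tsv", bundle.expr_a),
                        ("expr_b.tsv", bundle.expr_b)):
        lines = ["\t".join(("lncRNA",) + expr.condition_ids)]
        for lnc in expr.lncrna_ids:
            vals = expr.profile(lnc)
            cells = ["" if np.isnan(v) else repr(float(v)) for v in vals]
            lines.append("\t".join([lnc] + cells))
        d.joinpath(fname).write_text("\n".join(lines) + "\n", encoding="utf-8")

    d.joinpath("truth.tsv").write_text(
        "".join(f"{lnc}\t{c}\n" for lnc, c in sorted(bundle.truth.items())),
        encoding="utf-8")

    manifest = {"generator": "hetlncsim.fixtures", "params": asdict(bundle.params)}
    d.joinpath("manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
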