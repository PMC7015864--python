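"""Readers and writers for every file format the tool touches.

All formats are plain TSV (tab-delimited, UTF-8, "." decimal point):

* interaction tables — ``lncRNA<TAB>partner``, optional header
* square similarity matrices — header row and header column of ids
* expression matrices — first column lncRNA id, one column per tissue,
  header required; blank cells are *missing*, not zero
* DAG edges — ``parent<TAB>child``
* similarity networks — long form ``lncA<TAB>lncB<TAB>score`` with
  ``lncA < lncB`` lexicographically, or a full square matrix

Scores are serialised with ``repr`` so a write/read round trip is exact.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import (
    DagEdgeList,
    ExpressionMatrix,
    InteractionTable,
    SimilarityNetwork,
    SquareSimilarityMatrix,
    canonical_pair,
)
from .errors import FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "read_interaction_table",
    "read_square_matrix",
    "read_expression_matrix",
    "read_dag_edges",
    "read_similarity_network",
    "write_similarity_network",
    "read_weights",
    "write_weights",
]


def _lines(path: str | Path) -> list[str]:
    p = Path(path)
    if not p.is_file():
        raise FormatError(f"no such file: {p}")
    return p.read_text(encoding="utf-8").splitlines()


def read_interaction_table(
    path: str | Path, kind: str, header: bool = False
) -> InteractionTable:
    """Load a two-column TSV of (lncRNA id, partner id) interactions.

    Duplicate rows are dropped (counted in the log); rows with fewer than
    two fields are an error naming the offending line.
    """
    lines = _lines(path)
    if header and lines:
        lines = lines[1:]
    pairs: set[tuple[str, str]] = set()
    n_rows = 0
    offset = 2 if header else 1
    for lineno, line in enumerate(lines, start=offset):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise FormatError(f"{path}: line {lineno}: expected 2 columns")
        n_rows += 1
        pairs.add((fields[0].strip(), fields[1].strip()))
    if not pairs:
        raise FormatError(f"{path}: empty interaction table")
    dupes = n_rows - len(pairs)
    logger.info(
        "read %d rows from %s (%d unique %s pairs, %d duplicates dropped)",
        n_rows, path, len(pairs), kind, dupes,
    )
    return InteractionTable(kind=kind, pairs=frozenset(pairs))


def read_square_matrix(
    path: str | Path, symmetrize: str = "average"
) -> SquareSimilarityMatrix:
    """Load a square similarity matrix TSV with id headers on both axes.

    The diagonal is forced to 1.  Off-diagonal asymmetries — e.g. a source
    that reports Sim(A,B) and Sim(B,A) separately — are reconciled per
    ``symmetrize``: "average" (default), "max", or "error" (reject any
    asymmetry beyond 1e-9).  Out-of-range values are clamped to [0, 1]
    with a logged warning count.
    """
    if symmetrize not in ("average", "max", "error"):
        raise ValueError(f"unknown symmetrize mode {symmetrize!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except FileNotFoundError:
        raise FormatError(f"no such file: {path}") from None
    rows = [str(i).strip() for i in df.index]
    cols = [str(c).strip() for c in df.columns]
    if len(rows) != len(cols):
        raise FormatError(f"{path}: matrix not square ({len(rows)}x{len(cols)})")
    if len(set(rows)) != len(rows):
        raise FormatError(f"{path}: duplicate row ids")
    if set(rows) != set(cols):
        raise FormatError(f"{path}: row and column ids differ")
    df.index, df.columns = rows, cols
    df = df[rows]  # align column order to row order
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from None
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise FormatError(f"{path}: non-numeric cell at ({rows[r]}, {rows[c]})")

    asym = np.max(np.abs(values - values.T), initial=0.0)
    if symmetrize == "error":
        if asym > 1e-9:
            raise FormatError(f"{path}: matrix asymmetric (max deviation {asym:g})")
    elif symmetrize == "average":
        values = (values + values.T) / 2.0
    else:
        values = np.maximum(values, values.T)

    n_clamped = int(np.sum((values < 0) | (values > 1)))
    if n_clamped:
        logger.warning("%s: clamped %d values to [0, 1]", path, n_clamped)
        values = np.clip(values, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SquareSimilarityMatrix(ids=tuple(rows), values=values)


def read_expression_matrix(path: str | Path, unit: str) -> ExpressionMatrix:
    """Load an expression TSV (rows = lncRNAs, columns = tissues).

    Blank cells become NaN missing sentinels — never zeros, since "not
    measured" and "not expressed" must stay distinct for rank correlation.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except FileNotFoundError:
        raise FormatError(f"no such file: {path}") from None
    df.index = [str(i).strip() for i in df.index]
    if pd.Index(df.index).has_duplicates:
        dupe = pd.Index(df.index)[pd.Index(df.index).duplicated()][0]
        raise FormatError(f"{path}: duplicate lncRNA id {dupe!r}")
    raw = df.to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    for (r, c), cell in np.ndenumerate(raw):
        text = "" if cell is None or cell != cell else str(cell).strip()
        if not text:
            values[r, c] = np.nan  # blank = missing, never zero
            continue
        try:
            v = float(text)  # exact strtod: repr round-trips bit-for-bit
        except ValueError:
            raise FormatError(
                f"{path}: non-numeric cell at ({df.index[r]}, {df.columns[c]})"
            ) from None
        if v < 0:
            raise FormatError(
                f"{path}: negative value at ({df.index[r]}, {df.columns[c]})"
            )
        values[r, c] = v
    num = pd.DataFrame(values, index=df.index, columns=df.columns)
    return ExpressionMatrix(data=num, unit=unit)


def read_dag_edges(path: str | Path) -> DagEdgeList:
    """Load parent→child DAG edges from a two-column TSV."""
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dupes = 0
    for lineno, line in enumerate(_lines(path), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise FormatError(f"{path}: line {lineno}: expected 2 columns")
        parent, child = fields[0].strip(), fields[1].strip()
        if parent == child:
            raise FormatError(f"{path}: line {lineno}: self-loop on {parent!r}")
        if (parent, child) in seen:
            n_dupes += 1
            continue
        seen.add((parent, child))
        edges.append((parent, child))
    if n_dupes:
        logger.info("%s: dropped %d duplicate DAG edges", path, n_dupes)
    return DagEdgeList(edges=tuple(edges))


def write_similarity_network(
    net: SimilarityNetwork, path: str | Path, shape: str = "long"
) -> None:
    """Write a similarity layer as long-form pairs or a square matrix.

    Long shape: one ``lncA<TAB>lncB<TAB>score`` row per stored pair, lncA
    before lncB lexicographically, rows sorted.  Square shape: a full
    symmetric matrix over the layer's coverage with diagonal 1 and blanks
    for unscored pairs.
    """
    if len(net) == 0:
        raise ValueError("refusing to write an empty similarity network")
    path = Path(path)
    if shape == "long":
        rows = [f"{a}\t{b}\t{float(score)!r}"
                for (a, b), score in sorted(net.scores.items())]
        path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    elif shape == "square":
        ids = sorted(net.coverage)
        lines = ["\t".join(["lncRNA"] + ids)]
        for a in ids:
            cells = [a]
            for b in ids:
                if a == b:
                    cells.append("1.0")
                elif net.has_pair(a, b):
                    cells.append(repr(net.score(a, b)))
                else:
                    cells.append("")
            lines.append("\t".join(cells))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown shape {shape!r}")


def read_similarity_network(path: str | Path, name: str) -> SimilarityNetwork:
    """Load a long-form similarity network written by write_similarity_network."""
    scores: dict[tuple[str, str], float] = {}
    for lineno, line in enumerate(_lines(path), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: line {lineno}: expected 3 columns")
        try:
            score = float(fields[2])
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: non-numeric score") from None
        scores[canonical_pair(fields[0].strip(), fields[1].strip())] = score
    if not scores:
        raise FormatError(f"{path}: empty similarity network")
    coverage = frozenset(x for pair in scores for x in pair)
    return SimilarityNetwork(name=name, coverage=coverage, scores=scores)


def read_weights(path: str | Path) -> dict[str, float]:
    """Load a ``name<TAB>auc`` weights TSV."""
    out: dict[str, float] = {}
    for lineno, line in enumerate(_lines(path), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 columns")
        try:
            out[fields[0].strip()] = float(fields[1])
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: non-numeric weight") from None
    if not out:
        raise FormatError(f"{path}: empty weights file")
    return out


def write_weights(weights: dict[str, float], path: str | Path) -> None:
    rows = [f"{name}\t{float(w)!r}" for name, w in sorted(weights.items())]
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")
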