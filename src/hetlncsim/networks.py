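"""Builders for the four single-evidence lncRNA similarity layers.

Two layers are interaction-profile layers scored by cosine similarity:

* miRNA-based — each lncRNA's miRNA partner set is lifted to a vector over
  the union of the pair's partner miRNAs; the entry for miRNA ``m`` is the
  maximum functional similarity between ``m`` and the lncRNA's own partner
  set (so partners themselves score 1, and near-partners score close to 1).
  With an identity similarity matrix this reduces to plain 0/1 membership
  indicators.
* disease-based — the same construction over associated disease terms,
  using DAG semantic similarity (default mode "ds-max"); mode "dv-literal"
  instead fills the vector with the disease's semantic value DV on the
  lncRNA's own diseases and 0 elsewhere.

Two layers are expression layers scored by Spearman rank correlation of
tissue profiles (computed on pairwise-complete conditions), one per atlas;
atlases with different normalisation units are never merged.

Pairs whose score is undefined — a zero-norm vector or a constant profile —
are omitted from the layer rather than set to 0, because 0 is a meaningful
"dissimilar" score.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import (
    LNC_DISEASE,
    LNC_MIRNA,
    ExpressionMatrix,
    FeatureVector,
    InteractionTable,
    SimilarityNetwork,
    SquareSimilarityMatrix,
    canonical_pair,
)
from .disease import DiseaseSimilarityMatrix
from .errors import CoverageError, UndefinedSimilarityError

logger = logging.getLogger(__name__)

__all__ = [
    "cosine_similarity",
    "mirna_feature_vectors",
    "mirna_network",
    "disease_feature_vector",
    "disease_network",
    "spearman_similarity",
    "expression_network",
]


def cosine_similarity(v1: FeatureVector, v2: FeatureVector) -> float:
    """Cosine of two feature vectors over identical key lists."""
    if v1.keys != v2.keys:
        raise ValueError("feature vectors have different key lists")
    n1, n2 = v1.norm, v2.norm
    if n1 == 0.0 or n2 == 0.0:
        raise UndefinedSimilarityError("zero-norm feature vector")
    return float(np.dot(v1.values, v2.values) / (n1 * n2))


def _max_sim_profile(
    own: Sequence[str], keys: Sequence[str], misim: SquareSimilarityMatrix
) -> np.ndarray:
    """Entry for key m = max over own partners m' of misim(m, m')."""
    own_idx = misim.indices(own)
    key_idx = misim.indices(keys)
    return misim.values[np.ix_(key_idx, own_idx)].max(axis=1)


def mirna_feature_vectors(
    lnc1: str,
    lnc2: str,
    interactions: InteractionTable,
    misim: SquareSimilarityMatrix,
) -> tuple[FeatureVector, FeatureVector]:
    """Build the pair's two miRNA vectors over their partner union.

    Partner miRNAs absent from the similarity matrix would contribute 0 to
    both vectors on every key, so they are dropped from the key space (and
    logged).  An lncRNA left with no usable partners cannot be scored.
    """
    lists = {}
    for lnc in (lnc1, lnc2):
        partners = interactions.partners_of(lnc)
        if not partners:
            raise CoverageError(f"{lnc!r} has no miRNA partners")
        usable = sorted(p for p in partners if p in misim)
        if absent := partners.difference(usable):
            logger.info("%s: %d partner miRNAs absent from the similarity "
                        "matrix ignored", lnc, len(absent))
        if not usable:
            raise CoverageError(f"{lnc!r} has no partners in the similarity matrix")
        lists[lnc] = usable
    keys = tuple(sorted(set(lists[lnc1]) | set(lists[lnc2])))
    v1 = FeatureVector(keys=keys, values=_max_sim_profile(lists[lnc1], keys, misim))
    v2 = FeatureVector(keys=keys, values=_max_sim_profile(lists[lnc2], keys, misim))
    return v1, v2


def _pair_scores_from_profiles(
    coverage: Sequence[str],
    partner_sets: dict[str, Sequence[str]],
    full_profiles: dict[str, np.ndarray],
    key_positions: dict[str, int],
    name: str,
) -> SimilarityNetwork:
    """Score all pairs using per-lncRNA profiles over the full key space.

    Each pair is scored over the union of the two lncRNAs' partner sets.
    A profile entry depends only on the lncRNA's own partner set, never on
    the pair, so restricting the precomputed full profile to the union
    indices reproduces the per-pair union-key vectors exactly.
    """
    scores: dict[tuple[str, str], float] = {}
    n_skipped = 0
    for a, b in itertools.combinations(sorted(coverage), 2):
        union_idx = sorted(
            {key_positions[k] for k in partner_sets[a]}
            | {key_positions[k] for k in partner_sets[b]}
        )
        va = full_profiles[a][union_idx]
        vb = full_profiles[b][union_idx]
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0.0 or nb == 0.0:
            n_skipped += 1
            continue
        scores[canonical_pair(a, b)] = float(np.dot(va, vb) / (na * nb))
    if n_skipped:
        logger.info("%s: skipped %d pairs with undefined similarity", name, n_skipped)
    return SimilarityNetwork(name=name, coverage=frozenset(coverage), scores=scores)


def mirna_network(
    interactions: InteractionTable,
    misim: SquareSimilarityMatrix,
    name: str = "mirna",
    subset: Iterable[str] | None = None,
) -> SimilarityNetwork:
    """Score every unordered pair of lncRNAs with usable miRNA partners."""
    if interactions.kind != LNC_MIRNA:
        raise ValueError(f"expected {LNC_MIRNA} interactions, got {interactions.kind}")
    partner_map = interactions.partner_map()
    coverage = sorted(
        lnc for lnc, partners in partner_map.items()
        if any(p in misim for p in partners)
        and (subset is None or lnc in set(subset))
    )
    if not coverage:
        raise CoverageError("no lncRNA has a usable miRNA partner")
    all_keys = sorted({p for lnc in coverage for p in partner_map[lnc] if p in misim})
    key_positions = {k: i for i, k in enumerate(all_keys)}
    partner_sets = {
        lnc: sorted(p for p in partner_map[lnc] if p in misim) for lnc in coverage
    }
    profiles = {
        lnc: _max_sim_profile(partner_sets[lnc], all_keys, misim) for lnc in coverage
    }
    return _pair_scores_from_profiles(coverage, partner_sets, profiles,
                                      key_positions, name)


def disease_feature_vector(
    lnc: str,
    associations: InteractionTable,
    union_keys: Sequence[str],
    ds: DiseaseSimilarityMatrix,
    mode: str = "ds-max",
) -> FeatureVector:
    """Semantic feature vector of one lncRNA over a disease key list.

    mode "ds-max": entry for disease d = max over the lncRNA's own diseases
    d' of DS(d, d').  mode "dv-literal": entry = DV(d) for the lncRNA's own
    diseases, 0 elsewhere.
    """
    if mode not in ("ds-max", "dv-literal"):
        raise ValueError(f"unknown disease vector mode {mode!r}")
    own = sorted(d for d in associations.partners_of(lnc) if d in ds)
    if not own:
        raise CoverageError(f"{lnc!r} has no associated diseases in the hierarchy")
    keys = tuple(union_keys)
    if mode == "ds-max":
        values = np.array([max(ds.ds(d, o) for o in own) for d in keys])
    else:
        own_set = set(own)
        values = np.array([ds.dv(d) if d in own_set else 0.0 for d in keys])
    return FeatureVector(keys=keys, values=values)


def disease_network(
    associations: InteractionTable,
    ds: DiseaseSimilarityMatrix,
    mode: str = "ds-max",
    name: str = "disease",
    subset: Iterable[str] | None = None,
) -> SimilarityNetwork:
    """Cosine similarity of per-pair disease feature vectors."""
    if associations.kind != LNC_DISEASE:
        raise ValueError(
            f"expected {LNC_DISEASE} associations, got {associations.kind}"
        )
    if mode not in ("ds-max", "dv-literal"):
        raise ValueError(f"unknown disease vector mode {mode!r}")
    partner_map = associations.partner_map()
    disease_sets = {
        lnc: sorted(d for d in partners if d in ds)
        for lnc, partners in partner_map.items()
    }
    n_dropped = sum(len(p) - len(disease_sets[l]) for l, p in partner_map.items())
    if n_dropped:
        logger.warning("dropped %d lncRNA-disease associations whose disease "
                       "is absent from the hierarchy", n_dropped)
    coverage = sorted(
        lnc for lnc, dset in disease_sets.items()
        if dset and (subset is None or lnc in set(subset))
    )
    if not coverage:
        raise CoverageError("no lncRNA has an associated disease in the hierarchy")
    all_keys = sorted({d for lnc in coverage for d in disease_sets[lnc]})
    key_positions = {k: i for i, k in enumerate(all_keys)}
    profiles = {
        lnc: disease_feature_vector(lnc, associations, all_keys, ds, mode).values
        for lnc in coverage
    }
    return _pair_scores_from_profiles(coverage, disease_sets, profiles,
                                      key_positions, name)


def spearman_similarity(
    p1: np.ndarray, p2: np.ndarray, min_conditions: int = 3
) -> float:
    """Spearman rank correlation over pairwise-complete conditions.

    Missing values (NaN) are excluded pairwise; at least ``min_conditions``
    shared observations are required, and a constant profile makes the
    correlation undefined.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("profiles have different lengths")
    mask = ~(np.isnan(p1) | np.isnan(p2))
    if int(mask.sum()) < min_conditions:
        raise UndefinedSimilarityError(
            f"fewer than {min_conditions} pairwise-complete conditions"
        )
    with warnings.catch_warnings():
        # a constant input is reported as an undefined-similarity error below
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(p1[mask], p2[mask]).statistic
    if np.isnan(rho):
        raise UndefinedSimilarityError("constant profile over complete conditions")
    return float(rho)


def expression_network(
    expr: ExpressionMatrix,
    name: str,
    negatives: str = "keep",
    subset: Iterable[str] | None = None,
    min_conditions: int = 3,
) -> SimilarityNetwork:
    """All-pairs Spearman correlation of expression profiles.

    ``negatives`` is "keep" (default; scores stay in [-1, 1]) or
    "clamp-zero" (anti-correlation floored at 0).
    """
    if negatives not in ("keep", "clamp-zero"):
        raise ValueError(f"unknown negatives policy {negatives!r}")
    ids = sorted(expr.lncrna_ids)
    if subset is not None:
        keep = set(subset)
        ids = [i for i in ids if i in keep]
    if len(ids) < 2:
        raise CoverageError("expression network needs at least 2 lncRNAs")
    mat = expr.data.loc[ids].to_numpy(dtype=float)
    scores: dict[tuple[str, str], float] = {}
    n_skipped = 0
    for ia, ib in itertools.combinations(range(len(ids)), 2):
        try:
            rho = spearman_similarity(mat[ia], mat[ib], min_conditions)
        except UndefinedSimilarityError:
            n_skipped += 1
            continue
        if negatives == "clamp-zero":
            rho = max(rho, 0.0)
        scores[canonical_pair(ids[ia], ids[ib])] = rho
    if n_skipped:
        logger.info("%s: skipped %d pairs with undefined correlation",
                    name, n_skipped)
    return SimilarityNetwork(name=name, coverage=frozenset(ids), scores=scores)
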