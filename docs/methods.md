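# Methods

## Problem and approach

Given heterogeneous evidence about lncRNAs — miRNA interactions, disease
associations, and tissue expression — the package scores the functional
similarity of every unordered lncRNA pair in each evidence layer, then
fuses the layers into one integrated network. The fusion weight of a layer
is its measured ability (ROC AUC) to discriminate lncRNA pairs that share a
target mRNA from pairs that do not: layers that carry more functional
signal contribute more. All similarities are symmetric; pairs are stored
once with ids in lexicographic order, and self-similarity is 1 by
convention and never stored.

## Disease semantic similarity

Disease terms form a directed acyclic hierarchy (parent → child, MeSH
Category-C style). For an anchor term *i*, the ancestor set T(i) contains
*i* and everything reachable via parent edges. Contributions decay per
level: D_i(i) = 1 and D_i(s) = max{Δ · D_i(s′) : s′ child of s within
T(i)}, evaluated by memoized recursion on the sub-DAG induced by T(i); the
max over children makes D_i(s) = Δ^(shortest ancestor-path length), which
the test suite verifies against an explicit all-paths enumeration oracle.
The semantic value is DV(i) = Σ_{s∈T(i)} D_i(s) ≥ 1, and

DS(i₁, i₂) = Σ_{s ∈ T(i₁)∩T(i₂)} (D_{i₁}(s) + D_{i₂}(s)) / (DV(i₁) + DV(i₂)).

Properties relied on: DS ∈ [0, 1], DS(i, i) = 1 exactly, DS = 0 for terms
sharing no ancestor (multiple roots are allowed), and strict monotonicity
of each contribution in Δ. Δ defaults to 0.5, the conventional decay for
this construction; it is exposed as `--delta`/`delta=` everywhere. Cycles
are rejected at construction (the recursion diverges on them), with one
offending cycle reported. Each disease id is one node; a term with several
hierarchy positions is represented as one node with several parents.
Diseases referenced by association tables but absent from the hierarchy are
dropped with a logged count.

## Interaction-profile layers

Both the miRNA and the disease layer lift an lncRNA's partner set to a
numeric profile and score pairs by cosine similarity over the union of the
two partner sets. The profile entry of lncRNA *L* for partner key *k* is
max over L's own partners *k′* of the partner–partner similarity (the MISIM
matrix for miRNAs, the DS matrix for diseases). Because an entry depends
only on L's own partner set, full profiles are precomputed once per lncRNA
and restricted to the pair's union key list, which reproduces the per-pair
construction exactly at O(n·m + n²·|union|) cost instead of recomputing
vectors per pair.

Design choices here, made where the construction was genuinely open:

* The "replace the 0/1 indicator with similarity values" step is
  implemented as the max similarity of each union key to the lncRNA's own
  partner set. This keeps entries in [0, 1], gives entry 1 for the lncRNA's
  own partners, and degrades gracefully to plain 0/1 indicator vectors
  (binary cosine = |A∩B|/√(|A||B|)) when the partner-similarity matrix is
  the identity. The literal alternative for the disease layer — a vector of
  semantic values DV over the lncRNA's own diseases, zero elsewhere — is
  kept as mode `dv-literal`; the default `ds-max` actually uses the
  precomputed DS matrix and lets related-but-not-identical disease sets
  score above zero.
* Partner miRNAs absent from the similarity matrix would contribute zero to
  every vector entry, so they are pruned from the key space and logged; an
  lncRNA with no usable partner is excluded from the layer's coverage.
* Pairs with an undefined score (zero-norm vector) are omitted from the
  layer, not set to 0: zero is a meaningful "dissimilar" value and must not
  be conflated with "not computable".

## Expression layers

Each atlas (rows = lncRNAs, columns = tissues; TPM or FPKM, declared per
file and never mixed) yields one layer scored by Spearman rank correlation
over pairwise-complete tissues, requiring at least 3 shared non-missing
conditions. Blank cells are missing values, distinct from zero expression.
Constant profiles make the correlation undefined and the pair is skipped.
Negative correlations are kept by default (`negatives=keep`); a
`clamp-zero` policy floors them at 0 for workflows that want non-negative
scores before fusion. Rank computation is delegated to scipy (fractional
average-tie ranks).

## Benchmark and fusion

Positive pairs are lncRNA pairs sharing ≥ 1 target mRNA; negatives are
sampled uniformly without replacement from pairs of lncRNAs that both
appear in the lncRNA–mRNA table but share no target (this universe makes
"no shared target" verifiable; the choice is the package's own, as the
negative universe is otherwise unconstrained). Layer coverage differs, so
evaluation uses per-layer balanced subsets: cap = the minimum number of
positives any layer scores; each layer contributes its top-cap scored
positives ranked by (number of layers scoring the pair, descending;
canonical pair id, ascending — ids are unique, so the rank is
deterministic) and cap seeded negatives drawn from the scored non-positive
pairs; the per-layer selections are merged with duplicates removed.
Layers are processed in name order and each draws from its own spawned
child seed, so input order cannot change the result.

ROC curves are computed by a threshold sweep over distinct scores; the AUC
is the trapezoidal area of that curve, which equals Mann–Whitney
concordant-pair counting with ties worth ½ (property-tested against the
brute-force count). Each layer's AUC on its own subset is its fusion
weight. The integrated score is S̄ = Σᵢ AUCᵢ·Sᵢ / n with, by default,
n = the number of layers scoring the pair (`missing=available`): a strict
intersection would discard most pairs when coverage overlap is poor. The
literal /n denominator deflates scores below the per-layer scale (weights
are < 1); the normalised variant (`denominator=sum-weights`), a convex
combination of the layer scores, is available behind a flag, and the mode
used is recorded in the run manifest. Class separation is additionally
reported as a two-sided rank-sum test (exact enumeration when both classes
are ≤ 20 and tie-free, normal approximation with tie correction otherwise)
plus per-class quartiles.

## Synthetic data generator

The generator emulates the input ensemble with planted co-function
clusters. lncRNAs are assigned to clusters round-robin; each cluster owns
round-robin pools of miRNAs, diseases, mRNAs, and one mean expression
profile per atlas. Each lncRNA keeps each own-pool partner with probability
`overlap` (default 0.9) and, per foreign cluster, gains one uniformly
drawn partner with probability `leak` (default 0.05). The per-cluster leak
(rather than per-foreign-item) keeps cross-cluster contamination a minority
signal regardless of pool size, so the shared-target benchmark stays
well-posed: with per-item leakage most cross-cluster pairs would share a
leaked mRNA and the positive class would swamp the negatives. A cluster
anchor mRNA is always included, guaranteeing every same-cluster pair is a
benchmark positive; with `leak=0` no cross-cluster pair shares any partner.

Cluster structure in the other sources: the disease hierarchy has one
internal branch per cluster (a complete `dag_branching`-ary tree of depth
`dag_depth` under a common root) with the cluster's diseases as sibling
leaves, so within-cluster DS is high and cross-cluster DS decays to the
root contribution; the miRNA similarity matrix is block-structured
(within-cluster entries uniform on [0.6, 1.0], cross-cluster on [0, 0.3],
unit diagonal); expression is the cluster mean profile (uniform on
[0.5, 2.5] per tissue, scale ≈ 1) plus Gaussian noise (sd 0.25 by default,
i.e. a quarter of the signal scale), clipped at zero. Default sizes — 60
lncRNAs, 3 clusters, 30 miRNAs/diseases/mRNAs, 53 + 23 tissues — keep the
all-pairs computation around 1,770 pairs per layer, and the whole pipeline
runs in seconds; they are the standard conditions the acceptance script
re-runs.

What the fixture does **not** emulate: realistic heavy-tailed TPM/FPKM
distributions, partial and biased coverage per source (every synthetic
lncRNA appears in every table), realistic hierarchy topology, or dependence
between sources beyond shared cluster identity. Passing the planted-signal
tests therefore shows the pipeline recovers structure each source encodes;
it does not certify performance on real, sparse, inconsistently covered
data.

All randomness descends from one seed through named spawned sub-streams in
a fixed, append-only order, so adding a sub-generator never changes
existing draws and two runs with the same seed are byte-identical after
serialisation.

## Numerical and I/O choices

* Scores are serialised with `repr`, so write/read round trips are exact;
  expression cells are parsed with exact `float()` for the same reason.
* Square similarity matrices force the diagonal to 1, reconcile asymmetric
  sources by arithmetic average (configurable: max, or reject), and clamp
  out-of-range values into [0, 1] with a logged count rather than rejecting
  real-world exports.
* The CLI writes a manifest per run (inputs with SHA-256 hashes, effective
  configuration after flag > YAML config > default resolution, seed, tool
  version) containing no timestamps, so manifests of identical runs are
  identical.
* Undefined similarity, insufficient coverage, format violations, cycles
  and over-drawn negative sampling are distinct exception types; the CLI
  maps usage errors to exit 2 and computation failures to exit 1.

## Known limitations

* All-pairs layers are O(n²) in lncRNAs by design; builders accept an
  optional subset to bound cost on large inputs.
* Identifier harmonisation across lncRNA naming schemes is out of scope;
  inputs must already use consistent ids.
* The integrated score scale depends on the denominator mode; scores from
  different modes are not comparable with each other.
* The rank-sum p-value for large samples uses the normal approximation;
  extremely small p-values are order-of-magnitude statements, not exact
  tail probabilities.
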