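"""AUC-weighted fusion and the shared-target benchmark, end to end.

Labels lncRNA pairs positive when they share a target mRNA, draws balanced
per-layer subsets, uses each layer's AUC as its fusion weight, and
evaluates the integrated network against the single layers.
"""

from hetlncsim import (
    DiseaseDAG,
    LabeledPairSet,
    balanced_subset,
    build_positive_pairs,
    disease_network,
    disease_similarity_matrix,
    expression_network,
    generate_fixture,
    integrate,
    mirna_network,
    network_weights,
    restrict_labels,
    roc_auc,
    score_distribution_test,
)

bundle = generate_fixture(seed=7)
dag = DiseaseDAG(bundle.dag)
diseases = sorted(d for d in bundle.lnc_disease.partners if d in dag)
ds = disease_similarity_matrix(dag, diseases)
nets = [
    mirna_network(bundle.lnc_mirna, bundle.misim, name="mirna"),
    disease_network(bundle.lnc_disease, ds, name="disease"),
    expression_network(bundle.expr_a, name="expression_a"),
    expression_network(bundle.expr_b, name="expression_b"),
]

positives = build_positive_pairs(bundle.lnc_mrna)
labels = balanced_subset(nets, positives, bundle.lnc_mrna.lncrnas, seed=7)
print(f"Benchmark: {labels.n_pos} positive (shared-target) and "
      f"{labels.n_neg} negative lncRNA pairs\n")

per_net = {n.name: restrict_labels(labels, n) for n in nets}
weights = network_weights(nets, per_net)
print("Per-layer AUC (doubles as the fusion weight):")
for name, auc in sorted(weights.weights.items()):
    print(f"  {name:14s} {auc:.3f}")

fused = integrate(nets, weights)  # weighted average over scoring layers
fused_labels = LabeledPairSet(
    positives=frozenset(p for p in labels.positives if p in fused.scores),
    negatives=frozenset(p for p in labels.negatives if p in fused.scores),
)
roc = roc_auc(fused.scores, fused_labels)
dist = score_distribution_test(fused.scores, fused_labels)
print(f"\nIntegrated network: {len(fused)} pairs, AUC {roc.auc:.3f}")
print(f"Rank-sum test positive vs negative scores: p = {dist.p_value:.3g}")
print("\nThe integrated AUC sits at the level of the best single layer "
      "while covering every pair any layer can score.")
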