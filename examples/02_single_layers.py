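"""The four single-evidence similarity layers on a synthetic dataset.

Generates a planted-cluster dataset and builds the miRNA-profile,
disease-semantic, and two expression (Spearman) layers, then compares the
mean score of same-cluster versus cross-cluster lncRNA pairs in each layer.
"""

import numpy as np

from hetlncsim import (
    DiseaseDAG,
    disease_network,
    disease_similarity_matrix,
    expression_network,
    generate_fixture,
    mirna_network,
)

bundle = generate_fixture(seed=7)
dag = DiseaseDAG(bundle.dag)
diseases = sorted(d for d in bundle.lnc_disease.partners if d in dag)
ds = disease_similarity_matrix(dag, diseases)

layers = [
    mirna_network(bundle.lnc_mirna, bundle.misim, name="mirna"),
    disease_network(bundle.lnc_disease, ds, name="disease"),
    expression_network(bundle.expr_a, name="expression_a"),
    expression_network(bundle.expr_b, name="expression_b"),
]

print(f"{len(bundle.truth)} lncRNAs in {bundle.params.n_clusters} planted "
      "clusters; per-layer mean pair score:\n")
print(f"{'layer':14s}{'pairs':>8s}{'same-cluster':>14s}{'cross-cluster':>15s}")
for net in layers:
    same = [s for (a, b), s in net.scores.items()
            if bundle.truth[a] == bundle.truth[b]]
    cross = [s for (a, b), s in net.scores.items()
             if bundle.truth[a] != bundle.truth[b]]
    print(f"{net.name:14s}{len(net):>8d}{np.mean(same):>14.3f}"
          f"{np.mean(cross):>15.3f}")
print("\nEvery layer scores same-cluster pairs higher on average — the "
      "planted co-function signal each evidence source carries.")
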