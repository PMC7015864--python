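#!/usr/bin/env bash
# Full pipeline through the command-line interface: synthetic data,
# four similarity layers, evaluation-derived weights, integration,
# graph export, and a one-vs-all query.
set -euo pipefail

out=$(mktemp -d)
cd "$out"
echo "working in $out"

hetlncsim fixtures --out fx --seed 7

hetlncsim sim-mirna --interactions fx/lnc_mirna.tsv --misim fx/misim.tsv \
    --out net_mirna.tsv
hetlncsim sim-disease --associations fx/lnc_disease.tsv --dag fx/dag.tsv \
    --out net_disease.tsv
hetlncsim sim-expression --expr fx/expr_a.tsv --unit TPM --name gtex \
    --out net_gtex.tsv
hetlncsim sim-expression --expr fx/expr_b.tsv --unit FPKM --name noncode \
    --out net_noncode.tsv

hetlncsim evaluate \
    --net mirna=net_mirna.tsv --net disease=net_disease.tsv \
    --net gtex=net_gtex.tsv --net noncode=net_noncode.tsv \
    --lnc-mrna fx/lnc_mrna.tsv --seed 7 \
    --out report.json --weights-out weights.tsv --curves-out curves

hetlncsim integrate \
    --net mirna=net_mirna.tsv --net disease=net_disease.tsv \
    --net gtex=net_gtex.tsv --net noncode=net_noncode.tsv \
    --weights weights.tsv --out integrated.tsv

hetlncsim export-graph --net mirna=net_mirna.tsv --net disease=net_disease.tsv \
    --threshold 0.9 --out strong_edges.graphml

echo "--- per-layer weights (AUC) ---"
cat weights.tsv
echo "--- five most similar partners of LNC001 ---"
hetlncsim query --net integrated.tsv --one LNC001 | sort -t$'\t' -k3,3gr | head -5
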