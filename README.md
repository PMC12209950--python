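# moimech

Graph-of-graphs prediction of **mode of inheritance** and **dominant-disease
mechanism** for human proteins.

Two questions sit at the start of most Mendelian-disease analyses. First,
does a candidate gene cause disease through one damaged copy (autosomal
dominant, AD), two (autosomal recessive, AR), or either (ADAR)? Second, when
inheritance is dominant, which molecular mechanism is at work — a
dominant-negative protein (DN), haploinsufficiency (HI), or gain of function
(GOF)? `moimech` frames the first as multi-label **node classification on
the protein–protein interaction network** and the second as multi-label
**graph classification on residue-level protein-structure graphs**: every
protein is a node in one graph and, for the mechanism task, is itself a
graph of amino-acid residues.

The package provides, as importable modules and a CLI:

- **netgraph** — merge interaction edge lists from multiple resources
  (optionally score-thresholded), annotate nodes with feature tables, and
  filter features by training-set variance (< 0.1) and pairwise correlation
  (> 0.8).
- **structgraph** — parse PDB structures and build typed residue graphs:
  peptide, disulfide, hydrogen-bond, ionic, aromatic, aromatic-sulfur,
  cation-π, and long-range edges (heavy-atom distance < 5 Å, sequence
  separation > 5).
- **splitter** — cluster sequences at 20% identity / 20% coverage (MMseqs2,
  or a builtin k-mer clusterer) and assign whole clusters to
  train/validation/test (80/10/10), eliminating homology leakage.
- **gnn** — GCN, GIN and single-head GAT layers written directly from their
  update rules on a small in-house autodiff engine, composed into the
  two-unit node model (AD, AR) and the three-unit mean-pooled graph model
  (DN, HI, GOF):

  `h_i^{(l+1)} = Σ_{j∈N(i)} (deg i · deg j)^{-1/2} W^{(l)} h_j^{(l)}`  (GCN)

  `h_i^{(l+1)} = MLP((1+ε) h_i^{(l)} + Σ_{j∈N(i)} h_j^{(l)})`  (GIN)

  `α_ij = softmax_j LeakyReLU(aᵀ[W h_i ‖ W h_j])`,
  `h_i^{(l+1)} = σ(Σ_j α_ij W h_j^{(l)})`  (GAT)

- **trainer** — multi-label BCE, Adam with weight decay 5×10⁻⁴, dropout 0.3,
  ReduceLROnPlateau, early stopping on validation loss, the 5×5 hidden-size ×
  learning-rate grid, macro precision/recall/F1, and the AD/AR/ADAR
  class-assignment rules.
- **attribution** — integrated gradients (exact for linear scores;
  completeness-checked) restricted to correctly predicted single-label test
  samples, averaged and scaled to a maximum absolute importance of 1.
- **enrichstats** — hypergeometric over-representation with the 10–500 set
  size filter and Benjamini–Hochberg correction at 0.05, plus 2×2 odds
  ratio / Fisher exact analysis.
- **synthdata** — synthetic fixtures with planted, recoverable signal: toy
  PDB structures (helix / extended / compact fold), planted-signal networks
  with a recorded Bayes rule, labelled residue-graph datasets, and gene-set
  collections with one enriched set.

## Worked example

Train the inheritance model on a planted-signal network, score the held-out
nodes, and ask which feature drives AD calls:

```python
import numpy as np
from moimech.synthdata import make_planted_network, PlantedNetworkSpec
from moimech.gnn import GNNModel
from moimech.trainer import (NodeTaskData, TrainConfig, PredictionSet,
                             train_model, evaluate, assign_moi_class)
from moimech.attribution import (AttributionConfig, aggregate_attributions,
                                 node_model_attributions, select_explanation_samples)

planted = make_planted_network(PlantedNetworkSpec(n_nodes=200, seed=1))
g = planted.graph
idx = np.random.default_rng(1).permutation(g.n_nodes)
data = NodeTaskData(g, g.y, idx[:160], idx[160:180], idx[180:])

model = GNNModel("gcn", input_dim=10, hidden_dim=64, n_out=2, task="node", seed=1)
train_model(model, data, TrainConfig(hidden_size=64, learning_rate=1e-2, seed=1))

probs = model.predict_proba(g.X, g.adjacency())[data.test_idx]
preds = PredictionSet([g.node_ids[i] for i in data.test_idx], probs,
                      ["AD", "AR"], g.y[data.test_idx])
print("held-out metrics:", evaluate(preds))
print("first test protein:", preds.ids[0], "->",
      assign_moi_class(*probs[0], rule="inference"))

kept = select_explanation_samples(preds)
nodes = [data.test_idx[i] for i in kept if preds.y_true[i, 0] == 1]
per_sample = node_model_attributions(model, g, nodes, "AD", AttributionConfig(steps=64))
report = aggregate_attributions(per_sample, g.feature_names, target_label="AD")
print("top features for AD:", report.ranking()[:3])
```

Output:

```
held-out metrics: {'precision': 0.8535353535353536, 'recall': 0.8136363636363637, 'F1': 0.8285714285714285}
first test protein: P0058 -> AD
top features for AD: [('feat0', 1.0), ('feat9', 0.09843148653236367), ('feat4', -0.0793237111536396)]
```

The model recovers the planted signal on the 20 held-out nodes (macro-F1
0.83 for this seed; the median over seeds 1–3 is 0.92), the inference rule
turns the two per-label probabilities into an AD call, and the attribution
report correctly identifies `feat0` — the generator's informative feature —
with relative importance 1.0, an order of magnitude above every noise
feature.

The same workflow is available from the shell:

```sh
moimech synth network --n 200 --seed 1 --outdir fixtures/
moimech split --fasta proteins.fasta --outdir splits/
moimech grid-search --network-dir fixtures/ --labels fixtures/labels.tsv \
        --splits splits/splits.tsv --arch gcn --outdir runs/
moimech enrich --query ad_proteins.txt --gmt go_bp.gmt --outdir enrichment/
```

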