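# Methods

`moimech` implements a graph-of-graphs approach to two linked questions in
medical genetics: for every autosomal protein, is disease inheritance
dominant (AD), recessive (AR) or both (ADAR)? And for dominant-disease
proteins, does the pathogenic mechanism act by dominant negative (DN),
haploinsufficiency (HI) or gain of function (GOF)? The first question is a
multi-label node-classification problem on the protein–protein interaction
(PPI) network; the second is a multi-label graph-classification problem on
residue-level protein-structure graphs.

## Data model

**Interaction network.** Edge lists from several resources are merged as an
undirected union; duplicate pairs in either orientation collapse to one edge
that remembers every contributing source, and self-pairs are dropped (the
message-passing layers insert their own self-loops). A per-source minimum
interaction score supports score-thresholded resources. Nodes carry numeric
feature vectors from a TSV table; missing rows and cells receive per-feature
median imputation when enabled.

**Feature filter.** Features are removed if their unbiased sample variance is
below a threshold (0.1 for protein-level features, 0.01 for residue-level
features) or if their absolute Pearson correlation with an already-kept
feature exceeds 0.8. Both statistics are computed on training rows only, so
validation/test proteins cannot leak into feature selection. The scan runs in
table order and the earlier feature wins, which makes selection deterministic
and stable; constant columns fall to the variance step, so correlations are
always defined.

**Residue graphs.** A structure (PDB, single model, one chain; HETATM ignored,
insertion codes rejected, alternate locations resolved to highest occupancy)
becomes a graph with one node per residue. Typed edges:

| type | predicate | default |
|---|---|---|
| peptide | consecutive residue numbers | — |
| disulfide | Cys SG–SG | ≤ 2.2 Å |
| hbond | any N/O to any N/O | ≤ 3.5 Å |
| ionic | Arg/Lys/His side-chain N vs Asp/Glu side-chain O | ≤ 6.0 Å |
| aromatic | ring-centroid to ring-centroid (Phe/Tyr/Trp/His) | ≤ 7.0 Å |
| aromatic-sulfur | Cys/Met S to ring centroid | ≤ 5.3 Å |
| cation-π | Lys NZ / Arg CZ to ring centroid | ≤ 6.0 Å |
| long-range | min heavy-atom distance < 5 Å **and** sequence separation > 5 | strict |

All thresholds live in `ContactRules` and are configurable. Chemical
predicates additionally require a sequence separation of at least two
residues: a distance-only hydrogen-bond rule would otherwise re-detect every
peptide bond, since backbone N(i+1)–O(i) sits around 2.2 Å. Pairs missing a
required atom are skipped with a debug log rather than an error. The
hydrogen-bond rule is distance-only (no angle term) — a deliberate
simplification; the threshold is exposed for stricter use. Edge types are
recorded individually, but the classifiers consume the flattened untyped
union, since the layer update rules carry no edge features.

## Homology-aware splitting

Sequences are clustered at 20% identity and 20% mutual coverage and whole
clusters are assigned to train/validation/test (0.8/0.1/0.1), so near-duplicate
sequences never straddle a split. The production path shells out to MMseqs2
(`easy-cluster --min-seq-id 0.2 -c 0.2 --cov-mode 0`); a builtin clusterer
covers environments without it, estimating pairwise identity as the best
single-diagonal (ungapped) chain of shared 5-mers, scored against the shorter
sequence, with greedy single-linkage merging. The builtin estimator is a
deliberately conservative stand-in: it underestimates gapped homology, which
for split hygiene errs on the permissive side of *separating* sequences —
acceptable for fixtures, not a substitute for the external tool on real
proteomes. Cluster-to-split assignment shuffles clusters by seed and greedily
gives each cluster to the split with the largest protein-count deficit
relative to its target fraction; realized fractions are within
(largest cluster)/(total) of the targets, and an explicit leakage check
verifies atomicity.

## Models

Three message-passing layers are implemented exactly from their update rules
on dense adjacency (graphs here have at most a few hundred nodes):

- **GCN** — `h_i' = Σ_{j∈N(i)} (deg i · deg j)^{-1/2} W h_j`, self-loop
  included, degrees computed after self-loop insertion; equivalently
  `D̃^{-1/2}(A+I)D̃^{-1/2} H W`.
- **GIN** — `h_i' = MLP((1+ε) h_i + Σ_{j∈N(i)} h_j)` with learnable ε and a
  two-layer ReLU MLP; the `(1+ε)h_i` term plays the self-loop role.
- **GAT** — `α_ij = softmax_{j∈N(i)} LeakyReLU(aᵀ[W h_i ‖ W h_j])`,
  `h_i' = σ(Σ_j α_ij W h_j)`; one head, LeakyReLU slope 0.2, self-loops added
  so `α_ii` is defined. Attention rows sum to 1 by construction.

Layers carry additive biases (as the standard graph-learning implementations
do; the printed equations omit them as usual). Both task models have a single
hidden layer. The node model stacks two message-passing layers
(input → hidden, ReLU; hidden → 2) and applies a per-unit sigmoid. The graph
model applies one message-passing layer (input → hidden, ReLU), mean-pools
over nodes — the minimal permutation-invariant readout; sum and max are
available — and maps the pooled embedding through an affine head to 3 sigmoid
units. Dropout 0.3 acts on input features and hidden activations during
training only.

Everything runs on a small in-house reverse-mode automatic-differentiation
engine over dense numpy arrays (`moimech._autodiff`), which also supplies the
input gradients that integrated gradients needs. Gradient correctness is
tested against central finite differences for every primitive and for full
models.

## Training

Multi-label binary cross-entropy (each label an independent Bernoulli,
computed from logits for stability), Adam (β₁ 0.9, β₂ 0.999) with weight
decay 5×10⁻⁴ added to the gradient, at most 100 epochs of full-batch steps.
A plateau scheduler halves the learning rate after 10 epochs without
validation-loss improvement; early stopping fires after 30 such epochs and
the parameters from the best-validation-loss epoch are restored. The patience
values are larger than habit because full-batch Adam at the grid's largest
learning rate spends its first tens of epochs on a loss plateau; stopping or
decaying inside that plateau freezes the model at chance.

The hyperparameter grid crosses hidden sizes {128, 64, 32, 16, 8} with
learning rates {1e-2, 5e-3, 2e-3, 1e-3, 5e-4} — the grid's endpoints are
fixed, the middle learning rates are a choice — for 25 configurations; the
winner has the highest validation macro-F1, ties broken by lower validation
loss then smaller hidden size. Metrics are per-label precision/recall/F1,
macro-averaged, with probabilities binarized at 0.5; a label with neither
positive truth nor positive prediction scores 1.0 (there was nothing to get
wrong — this keeps degenerate validation splits finite).

Class calls from probabilities: the benchmark rule maps a single
dominant-probability to AD (> 0.6), AR (< 0.4) or ADAR (otherwise); the
inference rule uses both labels at 0.5 (both high → ADAR, one high → that
class, neither → argmax).

## Attribution

Integrated gradients with a right-Riemann approximation:
`IG_i = (x_i − b_i) · (1/m) Σ_{s=1..m} ∂F/∂x_i |_{b+(s/m)(x−b)}` — exact for
linear scores at any m, with a completeness gap `|Σ IG − (F(x) − F(b))|`
shrinking as 1/m (verified empirically by doubling m). Default baseline is
all-zeros in feature space (feature-means by flag), 128 steps. Samples are
restricted to test items with exactly one true label whose thresholded
prediction is correct on every label. For the node task the attribution of a
sample is the sample node's own feature row; for the graph task per-node
attributions are reduced over nodes (mean by default, sum-of-absolutes by
flag) before averaging across samples. The averaged vector is divided by its
maximum absolute entry, so the leading feature reads ±1; signs and order are
preserved. Residue-level attributions summarized at the protein level are
associations, not residue-resolved explanations.

## Enrichment

Over-representation of a gene set in a query list uses the upper-tail
hypergeometric probability `p = 1 − Σ_{i<k} C(M,i)C(N−M,n−i)/C(N,n)`,
evaluated as a direct log-space sum of the upper tail (lgamma-based binomial
coefficients; no 1-minus-lower-tail cancellation), so p-values stay accurate
at N ≈ 20,000 and below 1e-20. Sets are restricted to 10–500 members after
intersection with the background — by default the union of all gene-set
members, overridable with an explicit list — and Benjamini–Hochberg adjusted
across surviving sets with significance at adjusted p < 0.05. The 2×2
contingency analysis reports the odds ratio (a/b)/(c/d), a two-sided Fisher
exact p by enumeration over all tables with the observed margins (probability
no greater than observed, with the customary 1+1e-7 tolerance), and a
Woolf/log-normal 95% CI with Haldane 0.5 correction when a cell is zero.

## Synthetic fixtures

The generators produce every input format the pipeline reads (PDB, FASTA,
TSV, GMT) with planted, recoverable ground truth:

- **Toy structures.** Ideal helix (CA rise 1.5 Å, 100°/residue, radius
  2.3 Å — consecutive CA ≈ 3.8 Å), extended chain (CA every 3.8 Å on an
  axis), and a confined self-avoiding random walk (3.8 Å steps, clash
  distance 3.6 Å, confinement radius ∝ n^⅓) that reliably develops long-range
  contacts under the < 5 Å / > 5 separation rule. Backbone N, C, O and CB are
  placed from the CA trace by simple internal coordinates — adequate for
  every contact predicate, not stereochemically exact.
- **Planted network.** Erdős–Rényi graph (p = 0.05, n = 200 by default),
  standard-normal features, and per-label logistic labels in a latent z that
  mixes one informative feature with its network smoothing — two
  applications of the symmetric-normalized self-looped adjacency, the same
  propagation operator the models use — standardized so labels are balanced.
  Defaults: mixing 1.0, effect size 20. The smoothing matters: a
  two-message-passing-round model cannot represent an unsmoothed
  single-feature signal (its output is itself twice-smoothed), so keying the
  labels to raw features would cap held-out macro-F1 well below what the
  Bayes rule allows regardless of training. The generator returns the true
  Bernoulli means so tests can compare against the Bayes ceiling.
- **Residue dataset.** Each protein is a helix/extended chimera with a random
  helix fraction and a random sequence (so homology clustering yields
  singletons); residue features are a helix flag, a protein-level latent
  echoed per residue, and pure noise. Labels: GOF = helix fraction > 0.5,
  DN = its complement, HI = latent > 0, each flipped independently with
  probability 0.05. The geometry-linked GOF label gives the graph classifier
  and the attribution pipeline a recoverable structural signal.
- **Gene sets.** Random sets over a synthetic background plus one planted set
  with a controlled query overlap (defaults: background 1000, set 40, query
  50, overlap 25 — far into the hypergeometric tail).

What passing these fixtures does **not** show: performance on real curated
labels, robustness to the class imbalance and annotation noise of real MOI
data, or AlphaFold-scale structures; the fixtures are designed for signal
recovery, not realism.

## Problem sizes and determinism

The recovery studies use n = 200 nodes / 200 proteins with three seeds and a
majority criterion — sizes at which the planted signal is comfortably above
the noise floor of 20-sample test splits while the full suite stays quick on
a single CPU. All generators, splits and training runs are pure functions of
their seeds; two runs with the same seed produce byte-identical fixtures and
identical training histories.

## Known limitations

- GIN trains poorly at these tiny scales (sum aggregation inflates activation
  scale and the loss surface is harder for few full-batch steps); its layer
  semantics are oracle-verified, but the recovery studies use GCN.
- The builtin clustering estimator is ungapped; real-world use should prefer
  the external tool.
- Fisher CI uses the normal approximation rather than an exact conditional
  interval.
- The training loop is full-batch only, appropriate for the desk-scale
  graphs this package targets.
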