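# dualddi

Structure-based prediction of drug–drug interactions (DDIs) with a
dual-attention graph neural network, for computational chemists and
method developers who need an inductive DDI classifier that works from
SMILES alone — no interaction-network features, no curated descriptors.

## The model

Each drug is a heavy-atom molecular graph G = (X, A) with atom features
X ∈ R^{N×d0} and binary adjacency A. A pair of drugs (d1, d2) is mapped to
an interaction probability f(d1, d2) ∈ [0, 1] as follows:

1. **GIN encoder.** L layers of Graph Isomorphism Network updates,
   h_i ← h_i + MLP(Σ_{j∈N(i)} h_j), produce node embeddings x1 = GIN(G1),
   x2 = GIN(G2) of width d.
2. **Pattern self-attention (similarity branch).** M learnable pattern
   queries Q0 attend over each drug's nodes:
   A = softmax(Q Kᵀ/√d), O = ReLU((Q + A V) W0), giving M *representative
   vectors* per drug — substructure-pattern summaries. The M×M cosine
   matrix S between the two drugs' representative vectors is an
   interpretable map of substructure-interaction strength; its row-major
   flattening s feeds the classifier.
3. **Cross-attention (interaction branch).** Shared tiled pattern queries
   attend over the *other* drug's keys/values (per-drug projections
   W1K/W1V, W2K/W2V); a hard threshold λ zeroes attention weights below λ
   (no renormalization), and O_k = ReLU(WO(Q + (A_k ⊙ Mask_k) V)) is
   average-pooled over patterns and standardized per vector into
   interaction vectors inter1, inter2.
4. **Head.** y = MLP(inter1 ∥ inter2 ∥ s), trained with binary
   cross-entropy on observed interactions (positives) versus uniformly
   sampled non-edges (negatives), under repeated stratified 6:2:2 or
   8:1:1 splits.

The network is implemented on a small numpy reverse-mode autodiff engine
(`dualddi.autodiff`) with Adam and Xavier initialization; RDKit parses
SMILES, scikit-learn computes metrics.

## Worked example

The package ships a synthetic benchmark generator whose pair labels come
from a *planted substructure rule*: molecules are scaffolds decorated with
functional-group motifs, and a pair interacts exactly when it carries an
interacting motif pair (carboxylic acid × pyridyl, amine × thienyl, …),
with 5% label noise at the default desk scale. Ground truth is known, so
learnability is measurable.

```python
from dualddi import standard_benchmark, scaled_synthetic_config, run_cv

records, pairs, manifest = standard_benchmark("desk", seed=0)   # 400 drugs, 4000 pairs
config = scaled_synthetic_config(seed=0)                        # d=32, M=16, L=3, 60 epochs
report, _ = run_cv(records, pairs, "three_fold_622", config, repeats=1)
print(report.repeats[0])
```

Output (about one minute on one CPU core):

```
{'n_pairs': 800, 'f1': 0.8546, 'acc': 0.8575, 'auroc': 0.9327, 'ap': 0.9288, ...}
```

Test AUROC 0.93 / AP 0.93 against a Bayes ceiling just under 1.0 (5% of
labels are flipped) shows the model recovering the planted
substructure-interaction rule from structure alone; permuting the labels
drops AUROC to ≈ 0.5.

The same machinery runs on real data: CSV/TSV tables with columns
`drug_id,smiles` and `drug_a,drug_b,label` (e.g. the public ZhangDDI /
ChCh-Miner / DeepDDI pair tables, with full-size defaults `TrainConfig()`:
d=128, M=60, L=5, 300 epochs, batch 512).

A CLI wraps the library:

```
dualddi synth --scale desk --seed 0 --out bench/
dualddi train --drugs bench/drugs.csv --pairs bench/pairs.csv --config cfg.yaml --out run/
dualddi cv | eval | predict | ablate | sweep ...
```

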