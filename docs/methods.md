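# Methods

## Problem and approach

`cognigraph` classifies elderly subjects into three diagnostic classes —
cognitively healthy Controls, amnesic mild cognitive impairment (MCI), and
probable mild Alzheimer's disease (AD) — from eleven tabular features:
six numerics (Age, Education, MMSE, MoCA, FAB, HDRS) and four categoricals
(Sex, Comorbidity, Treatment, Rehabilitation). Besides a per-subject MLP
baseline, two models exploit a *population graph* in which nodes are subjects
and edges connect subjects with similar clinical profiles; classification is
transductive semi-supervised node labelling on that graph.

The clinical data this design targets are private, so the package ships a
synthetic-cohort generator that reproduces the documented structure of the
sample and makes the entire pipeline executable and testable end to end.

## Synthetic cohort

The default cohort has 214 subjects: 107 Controls (78 F / 29 M, age
Normal(74.06, 6.8²)), 77 MCI (54 F / 23 M, Normal(75.53, 7.3²)), 30 AD
(19 F / 11 M, Normal(76.33, 6.4²)), ages truncated to [55, 95] years by
rejection (the truncation sits ≈2.7–3 SD from each mean, shifting group
means by well under 0.1 y). Sex is assigned by exact counts and shuffled,
because the composition is documented as exact tallies, not rates.

Screening scores are discretized truncated normals restricted to the
inclusion windows: patients (MCI/AD) need MMSE in [18, 28]; Controls need
MMSE ≥ 28 and MoCA > 26. Both rules deliberately admit MMSE = 28 — the stated
criteria overlap at that value and we implement them as stated. Every
generated record therefore passes `apply_inclusion_criteria` by
construction; the screen exists as a separate operation so that externally
loaded tables can be filtered with the same rules.

Everything the sample description does not pin down is a package default,
chosen once to give overlapping but learnable classes with a monotone
severity ordering, and configurable per group:

| feature | Control | MCI | AD | note |
|---|---|---|---|---|
| MMSE mean (SD) | 29 (1.0) | 25 (2.0) | 21 (2.5) | within windows above |
| MoCA mean (SD), window | 28 (1.2), [27,30] | 22 (3.0), [10,26] | 15 (4.0), [4,22] | |
| FAB mean (SD) | 16.5 (1.2) | 13.5 (2.0) | 10.5 (2.5) | clipped [0, 18] |
| HDRS Poisson mean | 3 | 8 | 6 | clipped [0, 52]; MCI highest |
| Education | Normal(9, 4²) y, clipped [3, 20] | same | same | |
| P(comorbidity) | 0.30 | 0.55 | 0.70 | |
| P(treatment) | 0.02 | 0.40 | 0.80 | |
| P(rehabilitation) | 0.00 | 0.30 | 0.50 | |

These are **not** literature values. The generator emulates marginal group
structure only: no correlations between features within a subject, no
longitudinal decline, no informant reports, no missing data. Consequently a
passing pipeline demonstrates that the machinery (graph construction,
propagation, training, metrics) behaves correctly on data with this group
structure — it does not certify accuracy on real clinical cohorts, where
feature correlations and label noise are harsher.

## Preprocessing

Numerics are standardized to zero mean and unit variance using the sample SD
(`ddof=1`; documented so the tests are unambiguous — a constant column raises
rather than dividing by zero). Sex is one-hot encoded into two indicator
columns; the three binary flags pass through as single 0/1 indicators —
6 + 2 + 3 = 11 features, the only encoding that totals the declared feature
count.

Scaling is fitted on the **full cohort** (transductive) by default, because
the population graph itself is built over all subjects before any split;
with graph models the test nodes participate in propagation regardless, so
the usual train-only-fit hygiene buys little here. A train-only fit is
available (`build_feature_matrix(..., fit_ids=train_ids)`) for users who
want inductive discipline on the MLP path.

Splitting is stratified jointly by diagnosis × sex (both balances are
reported for the original subsets). Within each stratum, members are
shuffled and allocated by largest-remainder rounding, so every stratum's
partition count is within one subject of `fraction × stratum size`; ties in
the remainders resolve in partition order (train, val, test). Default
fractions are 119/214, 30/214, 65/214 ≈ 0.556/0.140/0.304 — the subset sizes
recoverable from the documented subset sex percentages (85/119, 23/30,
43/65).

## Population graph

1. Pairwise Euclidean distances on the 11 processed features.
2. Gaussian RBF similarity `s_ij = exp(−d_ij²/(2σ²))`. σ defaults to the
   median heuristic (median off-diagonal distance) — scale-free and, because
   the kernel is strictly order-reversing, *irrelevant to the edge set*; it
   matters only if similarities are exported.
3. Threshold at the 80th percentile (linear interpolation between order
   statistics) of the strict-upper-triangle scores. The diagonal's n unit
   self-similarities are excluded from the percentile population — including
   them would bias the cut upward; candidate pairs are what the rule ranks.
   A pair is kept only if its score is **strictly** above the threshold
   ("top 20 %" semantics; ties at the threshold drop, so an all-tied matrix
   yields an empty edge set with a warning rather than a clique).
4. The edge index lists every retained pair in both directions; the graph is
   undirected with no self-loops. Edge counts are reported as *directed
   entries* and average degree as entries/nodes — the only reading under
   which a 214-node, 4,472-entry graph has the quoted mean degree of 20.9.

Isolated nodes are counted and reported but always retained in the dataset;
only visualizations omit them.

## Models

All parameters initialize Glorot-uniform (zero biases) from a seeded
generator; forward passes run on a small in-package reverse-mode autodiff
core over numpy (verified against central finite differences at 1e-4
relative tolerance). Propagation and attention are computed densely: at a
few hundred nodes dense n×n linear algebra is simpler and faster than sparse
scatter kernels.

* **MLP** 11→16→8→3, ReLU, dropout 0.1 on hidden activations.
* **GCN** 11→16→3 with `Â = D̃^{-1/2}(A+I)D̃^{-1/2}` (symmetric-normalized
  adjacency with self-loops — the standard spectral rule; self-loops also
  guarantee positive degree, hence finite outputs, for isolated nodes),
  ReLU and dropout 0.1 after the first layer, biases in both layers.
* **GAT** layer 1: 8 heads × 16 units; per head
  `e_ij = LeakyReLU₀.₂(a_src·Wx_i + a_dst·Wx_j)` on each edge plus
  self-loop, row-softmax to attention coefficients, aggregation
  `z_i = Σ_j α_ij W x_j`. Heads are **concatenated** (width 128), then ELU.
  Layer 2 is a single attention head mapping 128→3 — the conventional design
  when the last layer emits class scores. Dropout 0.2 is applied to layer
  inputs and attention coefficients. The attention form is the
  single-linear-layer LeakyReLU variant; head aggregation and second-layer
  head count were genuinely open design points and are fixed as above.

No softmax at the output: the loss consumes raw logits.

## Training and evaluation

Full-batch Adam (β₁=0.9, β₂=0.999, ε=1e-8; L2 weight decay added to the
gradient) on unweighted cross-entropy for exactly 100 epochs — no early
stopping. Class weights are deliberately off by default despite the 107/77/30
imbalance (an option exists). Training is transductive: the loss covers
training-partition nodes only while graph models propagate over all nodes.
Dropout noise is driven by a generator seeded from the training config, so
trajectories are bit-reproducible.

Grid search covers lr ∈ {0.1, 0.01, 0.001} × wd ∈ {5e-4, 1e-4, 1e-5} (nine
points, containing both winning configurations of the original analysis),
every combination retrained from the same seeded initialization. Selection
is by final-epoch validation accuracy, with ties broken by weighted PPV,
then smaller weight decay, then smaller learning rate. Final-epoch (rather
than best-epoch) selection was an open point; final-epoch is chosen because
epochs are fixed in the protocol and selection happens afterwards.

Evaluation reports a 3×3 confusion matrix (rows = true), per-class PPV
(precision) and recall, and support-weighted aggregates. A class never
predicted gets PPV 0 with a warning. Support-weighted recall equals overall
accuracy algebraically; the evaluator asserts the identity on every call.

## Pipeline, seeds, artifacts

`run_pipeline` executes cohort → features → graph → split → grid-search ×3 →
test evaluation, writing every artifact as CSV/TSV/JSON. A single master
seed fans out by fixed offsets (cohort +0, split +1, MLP/GCN/GAT +2/+3/+4)
so stages re-run in isolation reproduce the pipeline's behaviour. A
non-empty output directory is never overwritten; a versioned sibling is
created instead.

The default run (214 subjects, 3 models, 9-point grid, 100 epochs) takes
about 40 s on one CPU core; the dominant cost is the GAT's eight dense
attention heads.

## Numerical and degenerate-input choices

* Percentile: numpy's linear interpolation, the dominant convention.
* Constant feature column → explicit error, never silent division.
* Zero median distance (all-identical rows) → explicit error.
* n < 2 subjects → distance matrix refuses.
* Empty train partition or non-finite loss → immediate error with context.
* Strata smaller than the partition count → warning, largest-remainder
  allocation proceeds.
* `-1e9` additive mask implements the attention neighbourhood restriction;
  with self-loops every softmax row has at least one unmasked entry.

## Validation experiments shipped with the tests

* **Class recovery**: on the default cohort, seeds 0–4, all three models
  trained at lr 0.01 (wd 1e-4 MLP / 5e-4 graph models) reach ≥ 85 % test
  accuracy and ≥ 95 % Control recall, mirroring the qualitative pattern of
  near-perfect Control separation (measured: 0.92–0.99 accuracy, Control
  recall ≥ 0.97).
* **Permutation null**: shuffling labels before splitting drops mean test
  accuracy over 10 seeds to within 10 points of the 50 % majority rate
  (measured mean ≈ 0.43).
* **Graph advantage**: adding Normal(0, 2²) noise to the model inputs while
  building the graph from the noiseless features degrades the MLP
  (mean ≈ 0.60) but not the graph models (GCN ≈ 0.93, GAT ≈ 0.88 over 10
  seeds at 50 epochs) — the relational signal is recoverable by construction.

These experiments use a single training run per (model, seed) at the fixed
hyperparameters above rather than the full grid, keeping the suite's runtime
proportionate; the pipeline's grid search is exercised separately.

## Known limitations

* The synthetic cohort's class separation is stronger than real
  neuropsychological data (independent features, clean labels), so absolute
  accuracies here exceed what the architecture achieves on clinical cohorts;
  only the qualitative ordering and the machinery are validated.
* Dense n×n propagation scales to thousands of nodes, not millions.
* The percentile population (diagonal excluded) and the directed-entry edge
  accounting are documented conventions; alternative readings change the
  reported edge counts but not the methodology.
* No cross-validation, calibration, ROC/AUC, or uncertainty quantification.
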