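# Methods

## Model

The predictor is a feedforward network in two branches. The multiomics
branch mirrors a Gene Ontology-style hierarchy restricted to `is_a`
edges: each retained term is a module of `k` nonlinear units (default
`k = 6`; 16 in the synergy variant) receiving (i) the binary
mutation/amplification/deletion indicators of the genes annotated to the
term, (ii) the term's own expression enrichment score (NES), and
(iii) for each retained child, the child's `k`-unit embedding together
with the child's NES as a separate scalar input. Leaves receive only
their gene blocks and own NES. The module nonlinearity is hyperbolic
tangent followed by batch normalization; the order is configurable
(`bn_after_tanh`) since either convention is defensible, and the
tanh-first form is the default. The drug branch is a dense
100–50–6 stack with the same per-layer nonlinearity. The head
concatenates the root embedding (width `k`) with the drug embedding and
maps through a 6-unit hidden layer to a single linear output (the AUC).
A toggle (`root_nes_to_head`, default off) appends the root term's NES
to the head input.

Connectivity is structural, not learned: a weight exists only where the
layout places one, which the tests verify by bit-exact output invariance
to unwired gene perturbations.

Because no deep-learning framework is part of the runtime environment,
the network runs on a compact in-package reverse-mode autodiff engine
(`_autodiff.py`) providing broadcast-aware arithmetic, matrix products,
tanh/sigmoid/log/power, reductions, concatenation, batch normalization
with running statistics, and Adam. Its gradients are validated against
central finite differences in the test suite.

## Ontology processing

Terms are pruned with the rule: keep a term iff the union of its
mutation/amplification/deletion genes has at least `min_genes` members
(default 1) or it has at least one retained descendant; children of
pruned terms re-attach to their nearest retained ancestors. This
guarantees every module has input. Gene annotation is direct by
default; the `propagate` flag applies the true-path rule (each term
unions its descendants' genes). Multi-parent terms are wired to all
retained parents. Only `is_a` edges are read; other relationship types
are ignored to keep the DAG minimal. Term depth is the longest path to
a leaf, so the root always has maximal depth and a sort by depth is a
valid children-first evaluation order.

## Enrichment score

NES uses the standard Mann–Whitney identity `U = mn + m(m+1)/2 − T`
with midranks on ties, giving `NES = 1 − U/(mn) ∈ [0, 1]` — exactly the
probability that an in-set gene outranks an out-of-set gene when there
are no ties (verified exhaustively for all placements with `m, n ≤ 5`).
Terms with an empty annotated set or empty complement get the
uninformative midpoint 0.5, logged. Only within-cell ranks are used, so
any strictly monotone per-cell normalization of expression is
irrelevant.

## Imbalance machinery

AUC is binned into 12 lower-closed bins over [0, 1.2] (the last bin
closed; out-of-range values clamp to the end bins and are logged — real
screens occasionally exceed 1.2 and discarding them would bias the
majority class). Weights are smoothed inverse frequencies
`v_i = 1/(f_i + ε)`, normalized to sum to 1. The smoothing penalty
defaults to ε = 80 for sensitivity training and ε = 5 for the synergy
variant; ε = 0 is allowed only when every bin is occupied. Each record's
sampling weight is its truth bin's weight; one resampled epoch draws
(with replacement) as many records as the training set holds. The
double-weighted loss multiplies each squared error by
`max(w_bin(p), w_bin(t))`; the weight factor is piecewise-constant in
the prediction and is treated as a constant in the gradient. The focal
loss for synergy is the standard binary form with α = 0.4, γ = 2,
probabilities clamped away from {0, 1} by 1e-12.

## Evaluation

Macroaverage MSE averages per-bin MSEs over *non-empty* bins (including
empty bins would be undefined). Balanced correlations draw
`n_per_class = 100` records from every occupied bin (with replacement
when a bin is smaller) for 1000 runs by default and report mean ± sd of
Pearson and Spearman. Cross-validation supports random triplet
partition and grouped leave-cell-lines-out / leave-drugs-out schemes in
which no group id spans two folds.

## Interpretability (RIS)

Silencing a term zeroes its embedding *and* its NES pass-up before
parents consume them — equivalent to zeroing the module's weights,
biases and batch-norm scale/shift plus the parents' weight columns for
that child, which a dual-implementation test confirms to 1e-10. The
children-ablation silences every child the same way; for leaves it
zeroes the gene-block inputs (the term's own NES stays, so the score
contrasts gene-level evidence with the module's integration).
`RIS = (s_cf − s_f)/(s_cf + s_f)` is defined as 0 when both deviations
vanish. Combination candidates take the top-5 terms by RIS among leaf
terms by default (internal terms via a flag), union their genes over
all channels, and return target-table drugs hitting any such gene,
excluding the query drug. The enrichment test is a one-sided binomial
tail `P(X ≥ TP | n = TP+FP, p = S/(S+NS))`.

## Synthetic study design

The generator emulates the *shapes* of real screening data, not its
pharmacology:

- **Ontology**: a complete tree (default depth 4, branching 3 → 40
  terms), optionally with extra cross-edges for DAG tests; each leaf
  annotated with 5 genes from a 120-gene universe, identical across the
  four channels.
- **Planted truth**: 6 causal leaf terms; each drug "hits" 1–2 of them
  (20% of drugs are inert controls); each cell activates each causal
  term independently with probability 0.3.
- **Omics**: background Bernoulli(0.05) binary matrices; mutation bits
  of a causal term's genes are switched on with probability 0.6 in
  active cells; expression of active terms' genes is shifted by +2 SD so
  the term NES is informative.
- **AUC**: `clip(base − 0.35·(#hit active terms) + N(0, 0.03), 0, 1.2)`
  with `base ~ 1.2·Beta(25, 7.3)`. These defaults were calibrated once
  so the histogram matches the skew of real screens: modal bin 9
  ([0.9, 1.0)), with the most sensitive bin roughly 50–100 times rarer —
  the regime the weighting machinery exists for.
- **Drug features**: one fingerprint bit per causal term encodes the
  mechanism, the rest are Bernoulli(0.1) noise; descriptors are noise
  except one mild signal column (the mechanism size).
- **Synergy labels**: a pair is positive when the two drugs hit
  disjoint non-empty causal-term sets all active in the cell; pairs are
  sampled to ~10% positives (mirroring published synergy screens) with
  2% label flips.

What passing tests on this cohort do **not** show: robustness to
measurement noise structure, batch effects, correlated omics channels,
non-additive dose interactions, or the scale of real screens
(hundreds of cells × hundreds of drugs × thousands of terms). The
generator's effect is additive and low-dimensional by design so that
recovery is checkable.

## Problem sizes and training settings used in the checks

The reference configuration (learning rate 1e-5, 300 epochs, ε = 80,
batch 512) matches full-scale training of a ~12k-neuron model on
hundreds of thousands of triplets. The package's own verification runs
use the default synthetic preset (200 cells × 40 drugs = 8000 triplets,
40-term ontology, ~20k parameters) with learning rate 1e-3 and ≤25
epochs: on a model and dataset this small the reference rate would
barely move the weights, and the planted signal is recoverable well
within that budget. The synergy checks train 12 epochs on 4000 pairs
(doubled by order augmentation) at batch 256. Chosen once as the
package's desk-scale study conditions; all stochastic components run
from explicit seeded generators, and two runs with the same seed are
bit-identical (checkpoint-hash test).

## Numerical choices

- Bin assignment adds 1e-9 before flooring to keep exact bin-edge
  values (0.1·i) in their lower-closed bin despite float division.
- Batch normalization uses momentum 0.1, eps 1e-5, unbiased running
  variance; a training batch of one falls back to running statistics.
- Best-validation snapshotting selects on the configured loss; training
  aborts with the epoch index on a non-finite loss.
- Ties in RIS-based rankings break by term id; aggregation tables sort
  deterministically, so permuting input records never changes output.
- Descriptor z-scoring maps zero-variance columns to 0 and imputes
  missing values with training-column medians.

## Known limitations

- The autodiff engine is minimal by design (no GPU, no fused ops); the
  package targets desk-scale studies and method development, not
  full-scale screen reproduction.
- Per-term auxiliary losses (used by some ontology-structured models)
  are not implemented; the hierarchy is trained end-to-end only.
- Drug-feature attribution is exposed only as a drug-branch embedding
  export hook for external attribution tools.
- The OBO reader handles `is_a` only; ontologies relying on `part_of`
  or regulates relations must be pre-flattened.
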