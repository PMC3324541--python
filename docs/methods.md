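# Methods

## Problem and model

Single-cell multiplex RT-PCR on neocortical neurons yields, per neuron, a
binary presence/absence call for each gene of an ion-channel panel plus
three phenotype labels: cortical layer (L2/3–L6), morphological type (LBC,
MC, NBC, PC) and electrical firing type (cAD, cFS, dFS, cST) — the LME
triple. The question the pipeline answers is combinatorial: within a
neuronal type, is the expression of one channel gene predictable from the
expression of others, and if so by what Boolean rule? With 26 genes there
are 2²⁶ − 1 ≈ 6.7 × 10⁷ non-empty gene subsets, so the search is
model-based rather than exhaustive.

The pipeline stages are:

1. **Pre-processing.** Neurons missing any LME label are excluded. The rest
   are grouped by LME triple; groups with ≥ `min_count` (default 4) neurons
   form the *model* set, smaller groups whose layer, morphology and
   electrical type each appear somewhere in the model set (but whose triple
   does not) form the *generalization* set, and the remainder is discarded
   but reported. Because L, M, E are categorical, only new *combinations*
   of already-seen values are predictable, hence the generalization
   filter.
2. **Base classifiers.** For each target gene, a soft-margin SVM on the
   one-hot LME encoding (12 features), tuned over a power-of-two (C, γ)
   grid — 31 × 31 = 961 points with integer exponents −15..15 by default —
   with both RBF and linear kernels, scored by 10-fold cross-validated
   accuracy. An unregularized logistic-regression baseline thresholds the
   fitted probability at the panel's mean expression frequency (sparse
   panels make 0.5 a poor operating point).
3. **Incremental selection (iSVM).** Greedy forward selection: at each
   iteration every not-yet-selected gene is appended to the feature set and
   scored; the best candidate is retained only on a *strict* increase in CV
   accuracy, otherwise the loop stops. The selection order (IG1, IG2, …)
   ranks the inputs' predictive value.
4. **Null models.** riiSVM replaces each model's inputs and (C, γ) by
   random draws; rdiSVM refits the whole incremental pipeline on data where
   every gene is an independent Bernoulli draw at its observed marginal
   frequency (neuron types and counts preserved). Accuracy distributions
   are compared by one-way ANOVA and pairwise Student t-tests.
5. **Rule extraction.** In LME types where the augmented model beat the
   base model on held-out per-type accuracy, the target's observed bits are
   tabulated against the selected inputs' on/off combinations. Majority
   vote per observed combination defines the on-set; ties and unobserved
   combinations are don't-cares; Quine–McCluskey minimization (sympy
   `SOPform`) produces a minimal AND/OR/NOT rule in disjunctive normal
   form. A rule's *occurrence* is the fraction of neurons of that type
   whose target bit matches the rule's output; rules under the occurrence
   threshold (default 0.8) are reported separately, not dropped.
6. **Network.** Each selection contributes a directed edge (input gene →
   target gene) with the iteration rank as attribute (colors
   red/blue/green/orange/black for ranks 1–5, cycling beyond); indegree =
   model size, outdegree = number of models a gene serves.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `min_count` | 4 | minimum neurons per LME group for the model set |
| grid | 2^k, k = −15..15, 31 points/axis | SVM (C, γ) search space |
| `k` | 10 | cross-validation folds (seeded, unstratified) |
| `tune` | `"full"` | re-run the grid per candidate; `"once"` tunes only the base model and reuses its (C, γ) — the cheap screening mode for large panels |
| `min_occurrence` | 0.8 | rule retention threshold |
| `fn_rate` | 0 (generator) | probability of a 1→0 dropout flip |

## Numerical and tie-break conventions

- Accuracies within 1e−12 are ties. Grid-search ties resolve to smaller C,
  then smaller γ, then RBF before linear; candidate-gene ties resolve to
  the lowest panel index. The argmax is therefore evaluation-order
  invariant and bit-reproducible.
- Fold assignment is a seeded random partition (sizes differ by ≤ 1),
  fixed per target model so every candidate is scored on identical folds.
  Stratification is deliberately off: with marginal frequencies under 10%
  some folds lack positives either way.
- A training fold with a single class short-circuits to constant
  prediction; a non-convergent logistic fit (e.g. complete separation)
  falls back to majority-class prediction and flags the result.
- ROC scores are the SVM's signed decision values, not calibrated
  probabilities; AUC is the rank statistic with ties counted ½ and is
  undefined (None) for single-class targets.
- In `minimize_boolean`, an observed input combination with an exact 1/0
  tie contributes no constraint (don't-care); if every row ties, no rule is
  emitted. Minimization non-uniqueness is resolved by sympy's
  deterministic cover plus canonical literal/clause ordering by panel
  index. Canonicalization re-derives the full truth table and re-minimizes,
  so logically equivalent formulas map to the identical object and
  non-influential literals drop out.
- Inputs constant within a neuronal type carry no within-type information
  and are dropped before table construction; they are recorded on the rule
  (`dropped_inputs`) rather than silently lost.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *structure* of the motivating study: the ten
model LME groups with counts 7, 7, 4, 9, 12, 4, 6, 5, 5, 6 (65 neurons)
plus fourteen one-or-two-neuron generalization groups (18 neurons); sparse
marginal frequencies drawn from [0.05, 0.5] (matching panels whose mean
frequency is ≈ 23% and maximum ≈ 50%); planted Boolean rules applied
within designated types; and asymmetric measurement noise — RT-PCR dropout
produces false negatives, so noise flips only 1→0 at `fn_rate`, applied to
inputs and targets alike (a symmetric flag exists for robustness studies).
The default panel carries the 24 channel-subunit symbols of the
neocortical assay; 26-gene runs append two synthetic placeholder symbols
(ICG25/ICG26), and a user panel file replaces them for fidelity to a
specific assay.

It does **not** emulate between-gene correlation beyond the planted rules,
within-type expression gradients, batch effects, or any quantitative
(non-binary) signal. Passing tests therefore demonstrate that the
implementation recovers structure it was designed to detect under the
assay's noise model — not that real neurons obey such rules.

## Calibration studies (`ionrules.validation`)

- **Greedy vs exhaustive** (`oracle_agreement`): 5-gene panels, 40 neurons
  in two LME types, one planted rule per dataset rotating through identity,
  sparse OR (input frequency 0.3) and common AND (0.7), noise-free; both
  search routes share folds and a fixed (C=32, γ=0.5) RBF configuration so
  disagreement isolates the search. The rule mix deliberately stays in the
  forward-selectable regime: a balanced AND/OR rule whose single inputs
  cannot shift the majority prediction defeats *any* greedy forward
  selector under 0/1 loss — that is a property of greedy search, not an
  implementation defect, and testing it would measure the wrong thing.
- **Rule recovery** (`rule_recovery`): Kv1.4 = HCN3 planted in two
  50-neuron types at 10% dropout; recovery = the planted canonical formula
  extracted with occurrence ≥ 0.8. Uses full per-candidate re-tuning on a
  coarse 4 × 4 power-of-two grid (exponents −15, −5, 5, 15) — the grid
  resolution chosen for these simulation-scale studies; the full 961-point
  grid remains the analysis default.
- **Null calibration** (`null_calibration`): independent-Bernoulli data at
  the full 65-neuron/26-gene scale, tune-once mode. The mean number of
  selected inputs per target is small (≈ 0.4 over 20 seeds) but not zero:
  with 25 candidates, strict-improvement stopping and an accuracy
  granularity of 1/65, chance selections are intrinsic to greedy wrapper
  selection at this sample size, and a chance-selected input in a
  4–12-neuron type usually admits a majority-vote rule above the
  occurrence threshold. Hallucinated structure on random data therefore
  vanishes only in expectation (the mean improvement over the base model
  tends to zero), not run by run — a known property of wrapper feature
  selection that users should keep in mind when interpreting single-run
  rule lists.

## Known limitations

- Greedy selection cannot discover rules invisible to single-input steps
  (balanced XOR/AND-type dependencies).
- Per-type accuracies rest on very few held-out neurons (4–12), so the
  candidate-type gate is noisy; occurrence counts on such types have wide
  binomial uncertainty.
- The rdiSVM null refits the entire pipeline per iteration and is the
  computational bottleneck; at full scale use tune-once mode and modest
  iteration counts, or parallelize across targets.
- Exact Quine–McCluskey is used instead of heuristic two-level
  minimization; it is exponential in the input count but the pipeline
  never feeds it more than the handful of selected genes.
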