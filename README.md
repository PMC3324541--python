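# ionrules

Combinatorial Boolean expression-rule extraction for binary single-cell
ion-channel gene panels.

Single-cell multiplex RT-PCR screens give each neuron a 0/1 expression call
for a panel of ion-channel genes (Kv, HCN, SK, Caα/Caβ subunits) plus a
phenotype triple — cortical **L**ayer, **M**orphological type, **E**lectrical
firing type (LME). Even a 26-gene panel spans 2²⁶ − 1 ≈ 67 million possible
gene combinations, far beyond exhaustive screening. `ionrules` is for
researchers who want to ask, from such data: *within a neuronal type, is
the expression of one channel gene predictable from the others — and by
what Boolean rule?*

The pipeline:

- **Split.** Drop neurons with incomplete LME labels; groups with ≥ 4
  neurons form the model set, smaller groups made of already-seen L/M/E
  values form the generalization set.
- **iSVM.** Per target gene *g*: start from an SVM on the one-hot LME
  features (hyperparameters tuned over a 31 × 31 power-of-two (C, γ) grid,
  10-fold cross-validation), then greedily add the input gene that most
  improves CV accuracy, stopping when no strict improvement remains. The
  retained genes IG1, IG2, … rank the predictors of *g*.
- **Null models.** Random-input models (riiSVM) and full refits on
  Bernoulli-resampled data (rdiSVM) calibrate how much accuracy arises by
  chance; distributions are compared by ANOVA and t-tests.
- **Rules.** In types where the augmented model beats the base model,
  tabulate the target against its selected inputs and minimize
  (Quine–McCluskey with don't-cares) into an AND/OR/NOT rule such as
  `Kv1.4 = HCN3` or `Kv1.2 = Kv3.1 AND Kv3.2`, each scored by its
  *occurrence* (fraction of neurons obeying it).
- **Network.** Selections become directed edges (input → target) with the
  selection iteration as rank; export to SIF/GraphML/DOT for Cytoscape.

See `docs/methods.md` for the model details, conventions and limitations.

## Worked example

Generate a synthetic study with a planted rule and run the pipeline:

```sh
ionrules simulate --mode planted --rule "Kv1.4 = HCN3" --fn-rate 0.05 \
    --seed 11 --panel-file panel4.txt --out synth.csv
ionrules all synth.csv --panel-file panel4.txt --outdir out \
    --grid-n 3 --grid-lo -5 --grid-hi 5 --tune full --k 10 --seed 5 --n-iter 2
```

where `panel4.txt` lists one gene symbol per line (`Kv1.4`, `HCN3`,
`Kv3.1`, `Kv3.2`). The run prints, among others:

```
model: 10 groups / 65 neurons; generalization: 14 groups / 18 neurons; discarded: 0
fitted 4 targets; mean base accuracy 0.726, mean incremental accuracy 0.849
17 rules retained, 0 below threshold
4 genes, 2 edges
```

Reading: the simulated study reproduces the standard group layout (65
model neurons in 10 LME types); greedy selection lifts mean CV accuracy
from 0.726 to 0.849 by discovering informative input genes; rule
extraction recovers the planted dependency — `out/rules.tsv` lists
`Kv1.4 = HCN3` per neuron type (e.g. holding 12/12 in L2/3 NBC-cFS and 6/7
in L2/3 LBC-cAD under the 5% dropout noise), together with its mirror-image
`HCN3 = Kv1.4`, since an identity rule predicts in both directions — and
the network contains the matching HCN3 → Kv1.4 and Kv1.4 → HCN3 edges
(rank 1, red in `out/network.dot`).

The same pipeline is available as a library:

```python
from ionrules import (default_panel, read_expression_table, filter_complete,
                      group_by_lme, split_model_generalization,
                      fit_all_targets, extract_rules, build_network)

panel = default_panel()
records, _ = filter_complete(read_expression_table("expression.csv", panel))
split = split_model_generalization(group_by_lme(records))
models = fit_all_targets(split.model_records, panel, seed=1)
rules = extract_rules(split.model_records, models, panel)
```

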