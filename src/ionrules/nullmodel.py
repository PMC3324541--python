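"""Significance assessment of the incremental models against two nulls.

* **Random-input models (riiSVM):** keep the real data, but replace each
  target's selected input genes and tuned (C, γ) by uniformly random draws.
  Measures how much of the accuracy is attributable to choosing the *right*
  inputs and hyperparameters.
* **Random-data models (rdiSVM):** refit the full incremental pipeline on
  data where every gene is resampled as an independent Bernoulli at its
  observed marginal frequency, preserving neuron types and counts. Measures
  what accuracies arise when no combinatorial structure exists at all.

Accuracy distributions of the real models (over re-randomized CV folds) and
the two nulls are compared with one-way ANOVA plus pairwise Student
t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .classify import FeatureSpec, HyperParams, cv_accuracy, make_hyper_grid
from .data import FrequencyProfile, NeuronRecord
from .isvm import ISVMModel, fit_all_targets
from .panel import GenePanel

__all__ = ["NullRunResult", "DistributionComparison", "bernoulli_resample",
           "riisvm_run", "compare_accuracy_distributions", "null_experiment"]


@dataclass(frozen=True)
class NullRunResult:
    model_kind: str  # "isvm" | "riisvm" | "rdisvm"
    iteration: int
    per_target_accuracy: dict[str, float]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(list(self.per_target_accuracy.values())))


@dataclass(frozen=True)
class DistributionComparison:
    anova_F: float
    anova_p: float
    pairwise: dict[tuple[int, int], float]
    degenerate: bool = False


def bernoulli_resample(
    records: Sequence[NeuronRecord],
    frequencies: FrequencyProfile,
    panel: GenePanel,
    seed: int = 0,
) -> list[NeuronRecord]:
    """Redraw every expression bit ~ Bernoulli(per-gene frequency).

    Neuron ids, LME labels and group counts are preserved exactly; only the
    expression matrix is randomized (gene-wise independent).
    """
    probs = np.array([frequencies[g] for g in panel], dtype=float)
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("frequencies must be in [0, 1]")
    rng = np.random.default_rng(seed)
    draws = (rng.random((len(records), len(panel))) < probs).astype(int)
    return [
        NeuronRecord(
            neuron_id=r.neuron_id, layer=r.layer, morphology=r.morphology,
            etype=r.etype, expression=tuple(int(b) for b in draws[i]))
        for i, r in enumerate(records)
    ]


def riisvm_run(
    records: Sequence[NeuronRecord],
    target: str,
    panel: GenePanel,
    n_inputs: int,
    seed: int = 0,
    grid: list[tuple[float, float]] | None = None,
    k: int = 10,
) -> float:
    """CV accuracy of a model with random inputs and random (C, γ).

    ``n_inputs`` genes are drawn uniformly without replacement (excluding
    the target) and one RBF (C, γ) pair uniformly from the grid.
    """
    if n_inputs > len(panel) - 1:
        raise ValueError("n_inputs exceeds available genes")
    if grid is None:
        grid = make_hyper_grid()
    rng = np.random.default_rng(seed)
    others = [g for g in panel if g != panel.resolve(target)]
    chosen = tuple(rng.choice(len(others), size=n_inputs, replace=False))
    inputs = tuple(others[i] for i in sorted(chosen))
    c, gamma = grid[int(rng.integers(len(grid)))]
    params = HyperParams(C=c, gamma=gamma, kernel="rbf")
    fold_seed = int(rng.integers(2**31))
    res = cv_accuracy(records, target, FeatureSpec(True, inputs), params,
                      panel, k=k, seed=fold_seed)
    return res.cv_accuracy


def compare_accuracy_distributions(
    a: Sequence[float], b: Sequence[float], c: Sequence[float]
) -> DistributionComparison:
    """One-way ANOVA across three accuracy samples plus pairwise t-tests.

    Three identical samples give F = 0, p = 1. When every group has zero
    within-group variance but the means differ, the F statistic is
    undefined and the result is flagged degenerate (F = inf, p = 0).
    """
    groups = [np.asarray(g, dtype=float) for g in (a, b, c)]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each sample needs length >= 2")
    within_var = sum(float(np.var(g, ddof=1)) for g in groups)
    means = [float(g.mean()) for g in groups]
    between_spread = max(means) - min(means)
    if within_var == 0.0:
        if between_spread == 0.0:
            F, p, degenerate = 0.0, 1.0, False
        else:
            F, p, degenerate = float("inf"), 0.0, True
    else:
        F, p = stats.f_oneway(*groups)
        F, p, degenerate = float(F), float(p), False
    pairwise: dict[tuple[int, int], float] = {}
    for i, j in ((0, 1), (0, 2), (1, 2)):
        gi, gj = groups[i], groups[j]
        if np.var(gi) == 0 and np.var(gj) == 0:
            t_p = 1.0 if gi.mean() == gj.mean() else 0.0
        else:
            t_p = float(stats.ttest_ind(gi, gj, equal_var=True).pvalue)
        pairwise[(i, j)] = t_p
    return DistributionComparison(anova_F=F, anova_p=p, pairwise=pairwise,
                                  degenerate=degenerate)


def null_experiment(
    records: Sequence[NeuronRecord],
    panel: GenePanel,
    frequencies: FrequencyProfile,
    n_iter: int = 1000,
    seed: int = 0,
    k: int = 10,
    grid: list[tuple[float, float]] | None = None,
    tune: str = "full",
    max_random_inputs: int = 5,
    models: dict[str, ISVMModel] | None = None,
) -> list[NullRunResult]:
    """Accuracy distributions of real vs null models over ``n_iter`` rounds.

    Per iteration three results are produced: (1) the fitted incremental
    models re-scored on freshly randomized CV folds (the models themselves
    are deterministic given the data, so fold noise is the only stochastic
    source); (2) one riiSVM accuracy per target with the input count drawn
    uniformly from 1..``max_random_inputs``; (3) a full incremental refit
    per target on freshly Bernoulli-resampled data. All streams are
    independently seeded from ``seed`` and reproducible.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    max_random_inputs = min(max_random_inputs, len(panel) - 1)
    if models is None:
        models = fit_all_targets(records, panel, k=k, seed=seed,
                                 grid=grid, tune=tune)

    def stream_seed(kind: int, iteration: int, extra: int = 0) -> int:
        ss = np.random.SeedSequence(entropy=seed,
                                    spawn_key=(kind, iteration, extra))
        return int(ss.generate_state(1)[0] & 0x7FFFFFFF)

    results: list[NullRunResult] = []
    for it in range(1, n_iter + 1):
        # (1) real models, re-randomized folds
        acc_isvm: dict[str, float] = {}
        for ti, g in enumerate(panel):
            m = models[g]
            spec = FeatureSpec(True, m.selected)
            res = cv_accuracy(records, g, spec, m.params, panel, k=k,
                              seed=stream_seed(1, it, ti))
            acc_isvm[g] = res.cv_accuracy
        results.append(NullRunResult("isvm", it, acc_isvm))

        # (2) random-input models
        acc_rii: dict[str, float] = {}
        for ti, g in enumerate(panel):
            rng = np.random.default_rng(stream_seed(2, it, ti))
            n_inputs = int(rng.integers(1, max_random_inputs + 1))
            acc_rii[g] = riisvm_run(records, g, panel, n_inputs,
                                    seed=stream_seed(2, it, ti + 10_000),
                                    grid=grid, k=k)
        results.append(NullRunResult("riisvm", it, acc_rii))

        # (3) random-data incremental refit
        resampled = bernoulli_resample(records, frequencies, panel,
                                       seed=stream_seed(3, it))
        rd_models = fit_all_targets(resampled, panel, k=k,
                                    seed=stream_seed(3, it, 1),
                                    grid=grid, tune=tune)
        acc_rd = {g: m.final_accuracy for g, m in rd_models.items()}
        results.append(NullRunResult("rdisvm", it, acc_rd))
    return results
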