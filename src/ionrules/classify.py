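"""Per-gene base classifiers on LME labels and optional input genes.

The prediction task is binary: is gene *g* expressed in a neuron, given the
neuron's one-hot-encoded layer/morphology/electrical-type labels and the 0/1
expression of a chosen set of other genes. Two families are provided:

* a soft-margin SVM (linear or RBF kernel) tuned over a power-of-two
  (C, γ) grid — 31×31 integer exponents spanning 2⁻¹⁵..2¹⁵ by default —
  scored by k-fold cross-validated accuracy, and
* an unregularized logistic-regression baseline thresholded at a configurable
  probability cutoff (the panel-wide mean expression frequency by default,
  sensible when positives are rare).

All fold assignment is seeded and reproducible; ties in the grid search are
broken toward smaller C, then smaller γ, then RBF before linear, so the
argmax is independent of evaluation order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .data import ETYPES, LAYERS, MORPHOLOGIES, NeuronRecord, expression_frequencies
from .panel import GenePanel

__all__ = [
    "FeatureSpec",
    "HyperParams",
    "EvalResult",
    "encode_features",
    "encode_matrix",
    "make_hyper_grid",
    "make_folds",
    "cv_accuracy",
    "grid_search",
    "lr_baseline",
    "roc_auc",
]

#: Accuracies closer than this are considered tied in argmax comparisons.
TIE_TOL = 1e-12


@dataclass(frozen=True)
class FeatureSpec:
    """Which features feed the classifier for one target gene."""

    use_lme: bool = True
    input_genes: tuple[str, ...] = ()

    def validate(self, panel: GenePanel, target: str) -> None:
        canon = [panel.resolve(g) for g in self.input_genes]
        if len(set(canon)) != len(canon):
            raise ValueError("duplicate input genes")
        if panel.resolve(target) in canon:
            raise ValueError("target gene cannot be its own input")


@dataclass(frozen=True)
class HyperParams:
    C: float
    gamma: float | None = None
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.kernel == "rbf" and (self.gamma is None or self.gamma <= 0):
            raise ValueError("rbf kernel needs gamma > 0")

    def sort_key(self) -> tuple:
        # smaller C, then smaller gamma, then rbf before linear
        gamma_key = self.gamma if self.gamma is not None else float("inf")
        return (self.C, gamma_key, 0 if self.kernel == "rbf" else 1)


@dataclass
class EvalResult:
    """Cross-validated performance of one classifier configuration."""

    cv_accuracy: float
    fold_accuracies: list[float]
    auc: float | None
    per_type_accuracy: dict[tuple[str, str, str], float]
    fallback: bool = False
    params: HyperParams | None = None
    predictions: np.ndarray | None = field(default=None, repr=False)


def encode_features(
    record: NeuronRecord, spec: FeatureSpec, panel: GenePanel
) -> np.ndarray:
    """One-hot L (4) + M (4) + E (4) blocks, then raw 0/1 input-gene bits."""
    parts: list[float] = []
    if spec.use_lme:
        for value, cats in ((record.layer, LAYERS),
                            (record.morphology, MORPHOLOGIES),
                            (record.etype, ETYPES)):
            parts.extend(1.0 if value == c else 0.0 for c in cats)
    for g in spec.input_genes:
        parts.append(float(record.expression[panel.index(g)]))
    return np.array(parts, dtype=np.float64)


def encode_matrix(
    records: Sequence[NeuronRecord], spec: FeatureSpec, panel: GenePanel
) -> np.ndarray:
    return np.vstack([encode_features(r, spec, panel) for r in records])


def make_hyper_grid(
    lo_exp: float = -15, hi_exp: float = 15, n: int = 31
) -> list[tuple[float, float]]:
    """All (C, γ) pairs with both values 2**k, k evenly spanning [lo, hi].

    Defaults give the canonical 31×31 = 961-point grid over integer
    exponents −15..15, i.e. values from 2⁻¹⁵ ≈ 3.05e−5 up to 2¹⁵.
    """
    if n < 2 or lo_exp >= hi_exp:
        raise ValueError("need n >= 2 and lo_exp < hi_exp")
    exps = np.linspace(lo_exp, hi_exp, n)
    values = [float(2.0 ** e) for e in exps]
    return [(c, g) for c in values for g in values]


def make_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded unstratified partition into k folds with sizes differing <= 1."""
    if k > n:
        raise ValueError(f"k={k} exceeds record count {n}")
    if k < 2:
        raise ValueError("need k >= 2 folds")
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def _fit_predict_svm(Xtr, ytr, Xte, params: HyperParams):
    """Fit an SVC on one training fold; constant labels short-circuit."""
    classes = np.unique(ytr)
    if classes.size == 1:
        const = int(classes[0])
        preds = np.full(len(Xte), const)
        # degenerate margin: sign carries the constant class
        scores = np.full(len(Xte), 1.0 if const == 1 else -1.0)
        return preds, scores
    if params.kernel == "rbf":
        clf = SVC(C=params.C, gamma=params.gamma, kernel="rbf")
    else:
        clf = SVC(C=params.C, kernel="linear")
    clf.fit(Xtr, ytr)
    return clf.predict(Xte), clf.decision_function(Xte)


def _pooled_eval(
    records: Sequence[NeuronRecord],
    y: np.ndarray,
    folds: list[np.ndarray],
    preds: np.ndarray,
    scores: np.ndarray,
) -> EvalResult:
    fold_accs = [float(np.mean(preds[f] == y[f])) for f in folds]
    per_type: dict[tuple[str, str, str], list[int]] = {}
    for i, r in enumerate(records):
        per_type.setdefault(r.lme, []).append(int(preds[i] == y[i]))
    per_type_acc = {k: float(np.mean(v)) for k, v in per_type.items()}
    auc = roc_auc(scores.tolist(), y.tolist())
    return EvalResult(
        cv_accuracy=float(np.mean(fold_accs)),
        fold_accuracies=fold_accs,
        auc=auc,
        per_type_accuracy=per_type_acc,
        predictions=preds,
    )


def _cv_eval_svm(records, X, y, folds, params: HyperParams) -> EvalResult:
    preds = np.empty(len(y), dtype=int)
    scores = np.empty(len(y), dtype=float)
    mask = np.ones(len(y), dtype=bool)
    for f in folds:
        mask[:] = True
        mask[f] = False
        p, s = _fit_predict_svm(X[mask], y[mask], X[f], params)
        preds[f], scores[f] = p, s
    res = _pooled_eval(records, y, folds, preds, scores)
    res.params = params
    return res


def _target_vector(records, panel: GenePanel, target: str) -> np.ndarray:
    j = panel.index(target)
    return np.array([r.expression[j] for r in records], dtype=int)


def cv_accuracy(
    records: Sequence[NeuronRecord],
    target: str,
    spec: FeatureSpec,
    params: HyperParams,
    panel: GenePanel,
    k: int = 10,
    seed: int = 0,
) -> EvalResult:
    """k-fold cross-validated accuracy of one SVM configuration.

    Folds are a seeded random partition; per-LME-type accuracies are
    aggregated from the pooled held-out predictions, and the AUC from the
    pooled signed decision values (None when the target is single-class).
    """
    spec.validate(panel, target)
    y = _target_vector(records, panel, target)
    X = encode_matrix(records, spec, panel)
    folds = make_folds(len(records), k, seed)
    return _cv_eval_svm(records, X, y, folds, params)


def grid_search(
    records: Sequence[NeuronRecord],
    target: str,
    spec: FeatureSpec,
    panel: GenePanel,
    grid: list[tuple[float, float]] | None = None,
    kernels: Sequence[str] = ("rbf", "linear"),
    k: int = 10,
    seed: int = 0,
    trace: list | None = None,
) -> tuple[HyperParams, EvalResult]:
    """Exhaustive (C, γ) grid search by CV accuracy.

    The linear kernel is searched over the grid's distinct C values only.
    Ties (within 1e-12) resolve to smaller C, then smaller γ, then RBF
    before linear, making the result order-invariant. Pass ``trace`` to
    collect (HyperParams, accuracy) tuples for every evaluation.
    """
    spec.validate(panel, target)
    if grid is None:
        grid = make_hyper_grid()
    y = _target_vector(records, panel, target)
    X = encode_matrix(records, spec, panel)
    folds = make_folds(len(records), k, seed)

    candidates: list[HyperParams] = []
    if "rbf" in kernels:
        candidates.extend(HyperParams(C=c, gamma=g) for c, g in grid)
    if "linear" in kernels:
        for c in sorted({c for c, _ in grid}):
            candidates.append(HyperParams(C=c, kernel="linear"))

    best: tuple[HyperParams, EvalResult] | None = None
    for params in candidates:
        res = _cv_eval_svm(records, X, y, folds, params)
        if trace is not None:
            trace.append((params, res.cv_accuracy))
        if best is None:
            best = (params, res)
            continue
        diff = res.cv_accuracy - best[1].cv_accuracy
        if diff > TIE_TOL or (abs(diff) <= TIE_TOL
                              and params.sort_key() < best[0].sort_key()):
            best = (params, res)
    assert best is not None
    return best


def lr_baseline(
    records: Sequence[NeuronRecord],
    target: str,
    spec: FeatureSpec,
    panel: GenePanel,
    cutoff: float | None = None,
    k: int = 10,
    seed: int = 0,
) -> EvalResult:
    """Logistic-regression baseline with a probability cutoff.

    Unregularized maximum likelihood per training fold; the predicted class
    is 1 iff the fitted probability exceeds ``cutoff``. The default cutoff
    is the mean expression frequency of the training fold (low-prevalence
    panels make 0.5 a poor operating point). Non-convergent fits (e.g.
    complete separation) fall back to majority-class prediction and flag
    the result.
    """
    spec.validate(panel, target)
    if cutoff is not None and not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must be in (0, 1)")
    y = _target_vector(records, panel, target)
    X = encode_matrix(records, spec, panel)
    folds = make_folds(len(records), k, seed)

    preds = np.empty(len(y), dtype=int)
    scores = np.empty(len(y), dtype=float)
    fallback = False
    for f in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[f] = False
        tr = [records[i] for i in np.flatnonzero(mask)]
        cut = cutoff if cutoff is not None else max(
            min(expression_frequencies(tr, panel).overall_mean, 1 - 1e-9), 1e-9)
        ytr = y[mask]
        if np.unique(ytr).size == 1:
            const = int(ytr[0])
            preds[f] = const
            scores[f] = float(const)
            continue
        clf = LogisticRegression(penalty=None, max_iter=2000, solver="lbfgs")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            clf.fit(X[mask], ytr)
            converged = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught)
        if not converged:
            fallback = True
            majority = int(np.mean(ytr) > 0.5)
            preds[f] = majority
            scores[f] = float(majority)
            continue
        prob = clf.predict_proba(X[f])[:, 1]
        preds[f] = (prob > cut).astype(int)
        scores[f] = prob
    res = _pooled_eval(records, y, folds, preds, scores)
    res.fallback = fallback
    return res


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float | None:
    """Rank-based AUC: P(random positive outscores random negative), ties ½.

    Returns None when the labels are single-class (AUC undefined).
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s)
    rank_sum = float(np.sum(ranks[y == 1]))
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
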