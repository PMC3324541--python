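"""Feature encoding, hyperparameter grid, CV, grid search, LR and AUC."""

import numpy as np
import pytest

from ionrules import (FeatureSpec, HyperParams, cv_accuracy, grid_search,
                      lr_baseline, make_hyper_grid, roc_auc)
from ionrules.classify import encode_features, encode_matrix

from conftest import make_record


class TestEncoding:
    def test_lme_one_hot_block(self, panel4):
        rec = make_record(1, bits=(0, 0, 0, 0))
        vec = encode_features(rec, FeatureSpec(use_lme=True), panel4)
        assert len(vec) == 12 and vec.sum() == 3.0

    def test_input_genes_appended(self, panel4):
        rec = make_record(1, bits=(1, 0, 1, 0))
        spec = FeatureSpec(use_lme=True, input_genes=("Kv1.1", "HCN1"))
        vec = encode_features(rec, spec, panel4)
        assert len(vec) == 14 and vec.sum() == 5.0

    def test_encoding_is_permutation_equivariant(self, panel4):
        rng = np.random.default_rng(0)
        records = [make_record(i, bits=tuple(rng.integers(0, 2, 4)))
                   for i in range(10)]
        spec = FeatureSpec(use_lme=True, input_genes=("HCN3",))
        X = encode_matrix(records, spec, panel4)
        perm = rng.permutation(10)
        Xp = encode_matrix([records[i] for i in perm], spec, panel4)
        assert np.array_equal(X[perm], Xp)

    def test_unknown_gene_rejected(self, panel4):
        spec = FeatureSpec(use_lme=True, input_genes=("Kv9.9",))
        with pytest.raises(KeyError):
            encode_features(make_record(1), spec, panel4)


class TestHyperGrid:
    def test_default_grid_is_961_points(self):
        grid = make_hyper_grid()
        assert len(grid) == 961
        values = sorted({c for c, _ in grid})
        assert len(values) == 31
        assert values[0] == pytest.approx(2.0 ** -15)  # ~3.0518e-5
        assert values[-1] == pytest.approx(2.0 ** 15)

    def test_small_grid(self):
        grid = make_hyper_grid(-1, 1, 2)
        assert sorted(set(grid)) == [(0.5, 0.5), (0.5, 2.0), (2.0, 0.5),
                                     (2.0, 2.0)]

    def test_bad_args(self):
        with pytest.raises(ValueError):
            make_hyper_grid(1, -1, 31)
        with pytest.raises(ValueError):
            make_hyper_grid(-1, 1, 1)


def _toy_records(n=30, seed=0, link=True):
    """Target gene Kv1.1 equals input HCN3 (if link), others random."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        h3 = int(rng.random() < 0.5)
        bits = (h3 if link else int(rng.random() < 0.5),
                int(rng.random() < 0.3), int(rng.random() < 0.3), h3)
        layer = "L2/3" if i % 2 else "L4"
        out.append(make_record(i, layer=layer, bits=bits))
    return out


class TestCrossValidation:
    def test_constant_target_scores_perfectly(self, panel4):
        records = [make_record(i, bits=(0, int(i % 2), 0, 0))
                   for i in range(20)]
        res = cv_accuracy(records, "Kv1.1", FeatureSpec(True),
                          HyperParams(C=1.0, gamma=0.5), panel4, k=5, seed=1)
        assert res.cv_accuracy == 1.0
        assert res.auc is None  # single-class target

    def test_separable_target_reaches_one(self, panel4):
        records = _toy_records(n=30, seed=2)
        spec = FeatureSpec(True, input_genes=("HCN3",))
        res = cv_accuracy(records, "Kv1.1", spec,
                          HyperParams(C=100.0, kernel="linear"),
                          panel4, k=5, seed=1)
        assert res.cv_accuracy == 1.0

    def test_determinism_and_fold_shapes(self, panel4):
        records = _toy_records(n=23, seed=3, link=False)
        spec = FeatureSpec(True, input_genes=("HCN3",))
        p = HyperParams(C=1.0, gamma=0.5)
        a = cv_accuracy(records, "Kv1.1", spec, p, panel4, k=10, seed=42)
        b = cv_accuracy(records, "Kv1.1", spec, p, panel4, k=10, seed=42)
        assert a.fold_accuracies == b.fold_accuracies
        assert np.array_equal(a.predictions, b.predictions)
        assert len(a.fold_accuracies) == 10
        assert a.cv_accuracy == pytest.approx(np.mean(a.fold_accuracies))
        # per-type accuracies cover both LME types present
        assert set(a.per_type_accuracy) == {("L2/3", "LBC", "cAD"),
                                            ("L4", "LBC", "cAD")}

    def test_k_larger_than_n_rejected(self, panel4):
        with pytest.raises(ValueError):
            cv_accuracy(_toy_records(5), "Kv1.1", FeatureSpec(True),
                        HyperParams(C=1.0, gamma=1.0), panel4, k=10, seed=0)


class TestGridSearch:
    def test_degenerate_target_tie_breaks_to_smallest(self, panel4):
        records = [make_record(i, bits=(0, int(i % 2), 0, 0))
                   for i in range(20)]
        grid = make_hyper_grid(-2, 2, 3)
        best, res = grid_search(records, "Kv1.1", FeatureSpec(True), panel4,
                                grid=grid, k=5, seed=0)
        assert res.cv_accuracy == 1.0
        assert best.kernel == "rbf"
        assert best.C == 0.25 and best.gamma == 0.25

    def test_separable_toy_reaches_one(self, panel4):
        records = _toy_records(n=30, seed=5)
        best, res = grid_search(records, "Kv1.1",
                                FeatureSpec(True, ("HCN3",)), panel4,
                                grid=make_hyper_grid(-5, 5, 3), k=5, seed=1)
        assert res.cv_accuracy == 1.0

    def test_evaluation_count_and_order_invariance(self, panel4):
        records = _toy_records(n=24, seed=6, link=False)
        grid = make_hyper_grid(-1, 1, 2)
        trace = []
        best, _ = grid_search(records, "Kv1.1", FeatureSpec(True), panel4,
                              grid=grid, k=4, seed=2, trace=trace)
        # 4 rbf pairs + 2 linear C values
        assert len(trace) == 6
        reversed_best, _ = grid_search(records, "Kv1.1", FeatureSpec(True),
                                       panel4, grid=grid[::-1], k=4, seed=2)
        assert best == reversed_best


class TestLogisticBaseline:
    def test_constant_target(self, panel4):
        records = [make_record(i, bits=(0, int(i % 2), 0, 0))
                   for i in range(20)]
        res = lr_baseline(records, "Kv1.1", FeatureSpec(True), panel4,
                          k=5, seed=0)
        assert res.cv_accuracy == 1.0
        assert not np.any(res.predictions)

    def test_lower_cutoff_never_predicts_fewer_positives(self, panel4):
        records = _toy_records(n=40, seed=8, link=False)
        spec = FeatureSpec(True, input_genes=("HCN3",))
        n_pos = []
        for cutoff in (0.6, 0.3, 0.1):
            res = lr_baseline(records, "Kv1.1", spec, panel4,
                              cutoff=cutoff, k=5, seed=4)
            n_pos.append(int(res.predictions.sum()))
        assert n_pos[0] <= n_pos[1] <= n_pos[2]

    def test_cutoff_bounds(self, panel4):
        with pytest.raises(ValueError):
            lr_baseline(_toy_records(20), "Kv1.1", FeatureSpec(True),
                        panel4, cutoff=1.5, k=5, seed=0)


class TestRocAuc:
    def test_constant_scores_give_half(self):
        assert roc_auc([0.3] * 10, [0, 1] * 5) == 0.5

    def test_perfect_ranking(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_single_class_undefined(self):
        assert roc_auc([0.1, 0.2], [1, 1]) is None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40).round(1)  # rounding forces ties
        labels = rng.integers(0, 2, size=40)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        expected = wins / (len(pos) * len(neg))
        assert roc_auc(scores.tolist(), labels.tolist()) == \
            pytest.approx(expected)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        a = roc_auc(scores.tolist(), labels.tolist())
        b = roc_auc(np.exp(2 * scores).tolist(), labels.tolist())
        assert a == pytest.approx(b)
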