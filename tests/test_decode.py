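"""Scaling, grid search, one-vs-one voting, cross-validation, t-tests."""

import numpy as np
import pytest

from motorspec.decode import (CvResult, FeatureBank, GridSpec, Task,
                              apply_scaler, assemble_features, build_tasks,
                              compare_accuracies, cross_validate, fit_scaler,
                              ovo_predict, train_binary, train_ovo)
from motorspec.discrim import ChannelSelection

TINY_GRID = GridSpec(c_exponents=(0, 4), gamma_exponents=(-3, 0))


class TestScaler:
    def test_training_extremes_map_to_unit_interval_ends(self):
        params = fit_scaler(np.array([[0.0], [10.0]]))
        np.testing.assert_allclose(apply_scaler(np.array([[0.0], [10.0]]), params),
                                   [[-1.0], [1.0]])

    def test_constant_feature_maps_to_zero(self):
        params = fit_scaler(np.array([[2.0], [2.0]]))
        np.testing.assert_allclose(apply_scaler(np.array([[2.0], [7.0]]), params), 0.0)

    def test_test_values_extrapolate_beyond_the_interval(self):
        params = fit_scaler(np.array([[0.0], [10.0]]))
        assert apply_scaler(np.array([[20.0]]), params)[0, 0] == pytest.approx(3.0)


class TestGrid:
    def test_default_grid_has_806_candidates(self):
        assert GridSpec().size == 31 * 26

    def test_coarsened_grid_keeps_the_ranges(self):
        g = GridSpec.with_step(4)
        assert g.c_exponents[0] == -10 and g.gamma_exponents[0] == -15
        assert max(g.c_exponents) <= 20 and max(g.gamma_exponents) <= 10


class TestAssembleFeatures:
    def bank(self, m=6, n=4):
        rng = np.random.default_rng(0)
        values = {k: rng.normal(size=(m, n)) for k in ("PC1", "PC2", "alpha")}
        labels = np.asarray(["rest", "thumb"] * (m // 2), dtype=object)
        return FeatureBank(values=values, labels=labels,
                           channel_labels=tuple(f"E{i}" for i in range(n)))

    def test_column_counts_sum_per_kind_selections(self):
        bank = self.bank()
        sel = {"PC1": ("E0", "E1", "E2"), "PC2": ("E1",), "alpha": ("E0", "E3")}
        fm = assemble_features(bank, sel, ("PC1", "PC2", "alpha"))
        assert fm.x.shape == (6, 6)
        assert fm.provenance[:3] == (("PC1", "E0"), ("PC1", "E1"), ("PC1", "E2"))

    def test_single_kind_ten_channels_gives_ten_columns(self):
        bank = self.bank(n=12)
        sel = {"PC1": ChannelSelection(tuple(f"E{i}" for i in range(10)))}
        fm = assemble_features(bank, sel, ("PC1",))
        assert fm.x.shape[1] == 10

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assemble_features(self.bank(), {"PC1": ()}, ("PC1",))


def gaussian_clouds(n=60, d=2.0, seed=0, n_features=4):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(2 * n, n_features))
    x[:n, 0] += d
    y = np.asarray(["a"] * n + ["b"] * n, dtype=object)
    return x, y


class TestTrainBinary:
    def test_separated_clouds_reach_high_inner_accuracy(self):
        x, y = gaussian_clouds(n=50, d=6.0)
        _, info = train_binary(x, y, grid=GridSpec.with_step(4), seed=0)
        assert info["inner_accuracy"] >= 0.99

    def test_shuffled_labels_sit_near_chance(self):
        rng = np.random.default_rng(1)
        x, y = gaussian_clouds(n=50, d=6.0)
        _, info = train_binary(x, rng.permutation(y), grid=TINY_GRID, seed=0)
        assert 0.35 <= info["inner_accuracy"] <= 0.7

    def test_single_class_rejected(self):
        x = np.zeros((10, 2))
        with pytest.raises(ValueError, match="class"):
            train_binary(x, np.asarray(["a"] * 10), grid=TINY_GRID)


class _StubClassifier:
    """Duck-typed pairwise classifier with fixed decision values."""

    def __init__(self, classes, value):
        self.classes_ = np.asarray(classes)
        self._value = value

    def decision_function(self, x):
        return np.full(x.shape[0], self._value)


class TestOvo:
    def test_five_classes_train_ten_pairwise_classifiers(self):
        rng = np.random.default_rng(2)
        classes = tuple("abcde")
        x = np.concatenate([rng.normal(loc=3 * i, scale=0.1, size=(8, 2))
                            for i in range(5)])
        y = np.asarray(sum(([c] * 8 for c in classes), []), dtype=object)
        clfs = train_ovo(x, y, classes, grid=TINY_GRID, seed=0, inner_folds=2)
        assert len(clfs) == 10
        pred = ovo_predict(clfs, x, classes)
        assert np.mean(pred == y) == 1.0

    def test_unanimous_vote_wins(self):
        classes = ("a", "b", "c")
        clfs = {("a", "b"): _StubClassifier(["a", "b"], -1.0),   # -> a
                ("a", "c"): _StubClassifier(["a", "c"], -2.0),   # -> a
                ("b", "c"): _StubClassifier(["b", "c"], 1.0)}    # -> c
        pred = ovo_predict(clfs, np.zeros((3, 2)), classes)
        assert list(pred) == ["a"] * 3

    def test_cyclic_tie_resolves_by_summed_margins_then_index(self):
        classes = ("a", "b", "c")
        # a beats b, b beats c, c beats a: one vote each
        clfs = {("a", "b"): _StubClassifier(["a", "b"], -0.5),
                ("b", "c"): _StubClassifier(["b", "c"], -2.0),
                ("a", "c"): _StubClassifier(["a", "c"], 3.0)}
        # brute-force margins: a: +0.5 - 3.0 = -2.5; b: -0.5 + 2.0 = 1.5; c: -3.0 + 3.0...
        # recompute: b gets +2.0 from (b,c); c gets -2.0 from (b,c) and +3.0 from (a,c)
        pred = ovo_predict(clfs, np.zeros((1, 2)), classes)
        votes_margin = {"a": 0.5 - 3.0, "b": -0.5 + 2.0, "c": -2.0 + 3.0}
        expect = max(sorted(votes_margin), key=lambda k: votes_margin[k])
        assert pred[0] == expect == "b"

    def test_missing_pair_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            ovo_predict({}, np.zeros((1, 2)), ("a", "b"))


class TestBuildTasks:
    def labels(self, per=6):
        fingers = ("thumb", "index", "middle", "ring", "little")
        lab = ["rest"] * (5 * per) + sum(([f] * per for f in fingers), [])
        return np.asarray(lab, dtype=object), fingers

    def test_detection_pools_fingers_and_fingers_excludes_rest(self):
        labels, fingers = self.labels()
        det, fin = build_tasks(labels, fingers)
        assert (det.y == "movement").sum() == 30
        assert (det.y == "rest").sum() == 30
        assert set(fin.y) == set(fingers)
        assert fin.indices.size == 30

    def test_missing_condition_rejected(self):
        labels, fingers = self.labels()
        with pytest.raises(ValueError, match="ring"):
            build_tasks(labels[labels != "ring"], fingers)


class TestCrossValidate:
    def separable_bank(self, per_class=15, n_ch=6):
        rng = np.random.default_rng(3)
        fingers = ("thumb", "index")
        labels = np.asarray(["rest"] * 2 * per_class
                            + ["thumb"] * per_class + ["index"] * per_class,
                            dtype=object)
        base = rng.normal(size=(labels.size, n_ch))
        base[labels != "rest", 0] += 8.0
        values = {"PC1": base, "PC2": rng.normal(size=base.shape)}
        return FeatureBank(values=values, labels=labels,
                           channel_labels=tuple(f"E{i}" for i in range(n_ch))), fingers

    def test_perfectly_separable_features_reach_full_accuracy(self):
        bank, fingers = self.separable_bank()
        det = Task(name="detection", indices=np.arange(bank.n_segments),
                   y=np.where(bank.labels == "rest", "rest", "movement").astype(object),
                   classes=("movement", "rest"))
        res = cross_validate(bank, det, kinds=("PC1",), folds=5, repeats=2,
                             seed=0, grid=TINY_GRID, top_n=3)
        assert res.mean_accuracy == 1.0

    def test_confusion_columns_sum_to_class_counts_and_trace_is_accuracy(self):
        bank, fingers = self.separable_bank()
        det = Task(name="detection", indices=np.arange(bank.n_segments),
                   y=np.where(bank.labels == "rest", "rest", "movement").astype(object),
                   classes=("movement", "rest"))
        res = cross_validate(bank, det, kinds=("PC1", "PC2"), folds=5, repeats=3,
                             seed=1, grid=TINY_GRID, top_n=2)
        n = bank.n_segments
        assert res.confusion.sum() == 3 * n
        np.testing.assert_array_equal(res.confusion.sum(axis=0),
                                      [3 * (n // 2), 3 * (n // 2)])
        assert res.pooled_accuracy == pytest.approx(
            np.trace(res.confusion) / res.confusion.sum())

    def test_rerun_with_same_seed_is_identical(self):
        bank, _ = self.separable_bank()
        det = Task(name="detection", indices=np.arange(bank.n_segments),
                   y=np.where(bank.labels == "rest", "rest", "movement").astype(object),
                   classes=("movement", "rest"))
        kw = dict(kinds=("PC1",), folds=5, repeats=2, seed=5, grid=TINY_GRID, top_n=2)
        a = cross_validate(bank, det, **kw)
        b = cross_validate(bank, det, **kw)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_class_smaller_than_fold_count_rejected(self):
        bank, fingers = self.separable_bank(per_class=3)
        fin = Task(name="fingers", indices=np.nonzero(bank.labels != "rest")[0],
                   y=bank.labels[bank.labels != "rest"], classes=fingers)
        with pytest.raises(ValueError, match="fold"):
            cross_validate(bank, fin, kinds=("PC1",), folds=5, repeats=1,
                           grid=TINY_GRID)


class TestCompareAccuracies:
    def cv(self, accs):
        accs = np.asarray(accs, dtype=float)[:, None]
        return CvResult(task="detection", accuracies=accs,
                        confusion=np.eye(2, dtype=int), classes=("movement", "rest"),
                        seed=0)

    def test_identical_paired_samples_give_t0_p1(self):
        res = compare_accuracies(self.cv([0.6, 0.7]), self.cv([0.6, 0.7]))
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_hand_computed_one_sample_t(self):
        res = compare_accuracies(self.cv([0.6, 0.7, 0.8]), 0.5)
        assert res.statistic == pytest.approx(2 * np.sqrt(3))
        assert res.df == 2

    def test_one_sample_equals_paired_against_constant(self):
        a = self.cv([0.55, 0.62, 0.71, 0.66])
        one = compare_accuracies(a, 0.5)
        paired = compare_accuracies(a, self.cv([0.5] * 4))
        assert one.statistic == pytest.approx(paired.statistic)
        assert one.pvalue == pytest.approx(paired.pvalue)

    def test_mismatched_repeat_counts_rejected(self):
        with pytest.raises(ValueError, match="repeat"):
            compare_accuracies(self.cv([0.6, 0.7]), self.cv([0.6, 0.7, 0.8]))
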