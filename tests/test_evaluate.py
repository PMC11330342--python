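"""Multi-label metrics, ranking areas, cross-validation and group analysis."""

import numpy as np
import pytest

from miloc.config import ClassifierParams, PipelineConfig
from miloc.datatypes import EntityIndex, FeatureBundle, MIRNA_LOCALIZATIONS
from miloc.evaluate import (
    ablation,
    ablation_size_groups,
    auc_aupr,
    cross_validate,
    feature_subsets,
    group_analysis,
    set_metrics,
    set_metrics_from_matrices,
    split_strength_groups,
)

L = MIRNA_LOCALIZATIONS


def metrics_oracle(true_sets, pred_sets, M=7):
    """Independent per-sample set computation."""
    n = len(true_sets)
    aim = sum(len(y & p) / len(p) for y, p in zip(true_sets, pred_sets) if p) / n
    cov = sum(len(y & p) / len(y) for y, p in zip(true_sets, pred_sets)) / n
    acc = sum(len(y & p) / len(y | p) for y, p in zip(true_sets, pred_sets)) / n
    at = sum(y == p for y, p in zip(true_sets, pred_sets)) / n
    af = sum((len(y | p) - len(y & p)) / M for y, p in zip(true_sets, pred_sets)) / n
    return aim, cov, acc, at, af


def auc_pair_oracle(scores, y):
    """Exhaustive concordant-pair statistic with half credit for ties."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestSetMetrics:
    def test_perfect_prediction(self):
        sets = [{L[0], L[1]}, {L[3]}]
        m = set_metrics(sets, [set(s) for s in sets])
        assert (m.aiming, m.coverage, m.accuracy, m.absolute_true,
                m.absolute_false) == (1, 1, 1, 1, 0)

    def test_worked_example(self):
        true = [{L[0], L[1]}, {L[3]}]
        pred = [{L[1], L[2]}, {L[3]}]
        m = set_metrics(true, pred)
        assert m.aiming == pytest.approx(0.75)
        assert m.coverage == pytest.approx(0.75)
        assert m.accuracy == pytest.approx(2 / 3, abs=1e-4)
        assert m.absolute_true == pytest.approx(0.5)
        assert m.absolute_false == pytest.approx(1 / 7, abs=1e-4)

    def test_all_empty_predictions(self):
        true = [{L[0]}, {L[1], L[2]}]
        m = set_metrics(true, [set(), set()])
        assert m.aiming == 0 and m.coverage == 0 and m.accuracy == 0
        assert m.absolute_true == 0
        assert m.absolute_false == pytest.approx((1 / 7 + 2 / 7) / 2)

    def test_label_outside_vocabulary_rejected(self):
        with pytest.raises(Exception, match="vocabulary"):
            set_metrics([{L[0]}], [{"golgi"}])

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_per_sample_oracle(self, trial):
        rng = np.random.default_rng(800 + trial)
        n = int(rng.integers(2, 12))
        true, pred = [], []
        for _ in range(n):
            y = {l for l in L if rng.random() < 0.4} or {L[0]}
            p = {l for l in L if rng.random() < 0.4}
            true.append(y)
            pred.append(p)
        m = set_metrics(true, pred)
        aim, cov, acc, at, af = metrics_oracle(true, pred)
        assert m.aiming == pytest.approx(aim)
        assert m.coverage == pytest.approx(cov)
        assert m.accuracy == pytest.approx(acc)
        assert m.absolute_true == pytest.approx(at)
        assert m.absolute_false == pytest.approx(af)


class TestAucAupr:
    def test_perfect_ranking(self):
        auc, _ = auc_aupr(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert auc == 1.0

    def test_reversed_ranking(self):
        auc, _ = auc_aupr(np.array([0.1, 0.2, 0.8, 0.9]), np.array([1, 1, 0, 0]))
        assert auc == 0.0

    def test_tie_gets_half_credit(self):
        auc, _ = auc_aupr(np.array([0.9, 0.6, 0.6, 0.1]), np.array([1, 0, 1, 0]))
        assert auc == pytest.approx(0.875)

    def test_single_class_undefined_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="miloc"):
            auc, aupr = auc_aupr(np.array([0.2, 0.4]), np.array([1, 1]))
        assert auc is None and aupr is None

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_pair_counting_oracle(self, trial):
        rng = np.random.default_rng(900 + trial)
        n = int(rng.integers(4, 50))
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # forces ties
        y = rng.integers(0, 2, size=n)
        if len(set(y.tolist())) < 2:
            y[0], y[1] = 0, 1
        auc, _ = auc_aupr(scores, y)
        assert auc == pytest.approx(auc_pair_oracle(scores, y), abs=1e-12)


def _signal_data(rng, n=60, d=10):
    Y = (rng.random((n, 7)) < 0.4).astype(int)
    Y[Y.sum(axis=1) == 0, 0] = 1
    X = Y @ rng.normal(size=(7, d)) + 0.3 * rng.normal(size=(n, d))
    return X, Y


class TestCrossValidate:
    def _config(self):
        cfg = PipelineConfig(seed=3)
        cfg.classifier = ClassifierParams(epochs=40, use_attention=False)
        return cfg

    def test_folds_partition_index(self, rng):
        X, Y = _signal_data(rng, n=50)
        report = cross_validate(X, Y, self._config(), k=10)
        counts = np.bincount(report.fold_assignment, minlength=10)
        assert (counts == 5).all()

    def test_same_seed_identical_report(self, rng):
        X, Y = _signal_data(rng, n=30)
        a = cross_validate(X, Y, self._config(), k=3)
        b = cross_validate(X, Y, self._config(), k=3)
        np.testing.assert_array_equal(a.scores, b.scores)
        assert a.fold_assignment.tolist() == b.fold_assignment.tolist()

    def test_average_auc_is_mean_of_defined_labels(self, rng):
        X, Y = _signal_data(rng)
        report = cross_validate(X, Y, self._config(), k=5)
        defined = [v for v in report.auc.values() if v is not None]
        assert report.average_auc == pytest.approx(np.mean(defined), abs=1e-12)

    def test_label_shuffled_control_gives_chance_auc(self, rng):
        """Label-shuffled negative control sits at AUC ~ 0.5."""
        X, Y = _signal_data(rng, n=80)
        Y = Y[rng.permutation(len(Y))]
        report = cross_validate(X, Y, self._config(), k=5)
        assert abs(report.average_auc - 0.5) < 0.1


class TestAblation:
    def test_subset_enumeration(self):
        subsets = feature_subsets()
        assert len(subsets) == 31
        assert sum(len(s) < 5 for s in subsets) == 30
        assert ("sequence", "disease", "drug", "mrna_network", "coloc") in subsets

    def test_widths_and_size_groups(self, rng):
        n = 30
        index = EntityIndex(tuple(f"m{i}" for i in range(n)), "mirna")
        bundle = FeatureBundle(index, {
            "sequence": rng.normal(size=(n, 6)),
            "disease": rng.normal(size=(n, 5)),
            "drug": rng.normal(size=(n, 5)),
            "mrna_network": rng.normal(size=(n, 5)),
            "coloc": rng.random((n, 4)),
        })
        Y = (rng.random((n, 7)) < 0.4).astype(int)
        Y[Y.sum(axis=1) == 0, 0] = 1
        cfg = PipelineConfig(seed=1)
        cfg.classifier = ClassifierParams(epochs=5, use_attention=False)
        rows = ablation(bundle, Y, cfg)
        assert len(rows) == 31
        for row in rows:
            expected = sum(bundle.blocks[b].shape[1] for b in row["subset"])
            assert row["width"] == expected
        groups = ablation_size_groups(rows)
        assert set(groups) == {1, 2, 3, 4, 5}


class TestGroupAnalysis:
    def test_median_split_on_distinct_counts(self):
        strongly, weakly, thr = split_strength_groups(
            np.array([9, 7, 5, 3]), ("a", "b", "c", "d")
        )
        assert strongly.tolist() == [0, 1]
        assert weakly.tolist() == [2, 3]
        assert thr == 7.0

    def test_tied_counts_split_by_id_order(self):
        strongly, weakly, _ = split_strength_groups(
            np.array([4, 4, 4, 4, 4]), tuple("abcde")
        )
        assert strongly.tolist() == [0, 1]       # floor(n/2) strongly
        assert weakly.tolist() == [2, 3, 4]      # extra member goes weakly

    def test_group_metrics_computed_separately(self, rng):
        n = 20
        Y = (rng.random((n, 7)) < 0.5).astype(int)
        Y[Y.sum(axis=1) == 0, 0] = 1
        scores = rng.random((n, 7))
        counts = {"disease": rng.integers(1, 20, size=n)}
        out = group_analysis(Y, scores, counts, tuple(f"m{i}" for i in range(n)))
        assert set(out["disease"]) == {"count_threshold", "strongly", "weakly"}
        for grp in ("strongly", "weakly"):
            for v in out["disease"][grp].values():
                assert 0 <= v <= 1
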