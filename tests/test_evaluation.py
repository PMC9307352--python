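"""Metric derivations, stratified CV mechanics, and the table audit."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ovaclass as ov
from ovaclass.errors import ConfigurationError, DataError
from ovaclass.evaluation import ConfusionMatrix, metrics_from_confusion, stratified_folds
from ovaclass.reference_tables import reference_rows

counts = st.integers(min_value=0, max_value=400)


class TestMetrics:
    def test_published_row_sda_nlr(self):
        r = metrics_from_confusion(ConfusionMatrix(48, 44, 6, 2)).rounded()
        assert r["accuracy"] == 92
        assert r["precision"] == 88.889
        assert r["f1"] == 92.308
        assert r["mcc"] == 0.843
        assert r["fm"] == 0.924
        assert r["error_rate"] == 8
        assert r["jaccard"] == 85.714
        assert r["csi"] == 84.889

    def test_published_row_dct_gmm_selected(self):
        r = metrics_from_confusion(ConfusionMatrix(46, 42, 8, 4)).rounded()
        assert r["accuracy"] == 88
        assert r["precision"] == 85.185
        assert r["f1"] == 88.462
        assert r["mcc"] == 0.762
        assert r["csi"] == 77.185

    def test_perfect_classifier(self):
        r = metrics_from_confusion(ConfusionMatrix(50, 50, 0, 0))
        assert r.accuracy == 100 and r.mcc == 1.0 and r.jaccard == 100

    def test_chance_classifier(self):
        r = metrics_from_confusion(ConfusionMatrix(25, 25, 25, 25))
        assert r.accuracy == 50 and r.mcc == 0.0

    def test_zero_denominator_flagged(self):
        r = metrics_from_confusion(ConfusionMatrix(0, 10, 0, 0))
        assert r.precision == 0.0
        assert "precision" in r.flags

    @given(tp=counts, tn=counts, fp=counts, fn=counts)
    def test_metric_identities(self, tp, tn, fp, fn):
        """accuracy + error = 100; Jaccard <-> F1; FM = sqrt(PPV*TPR);
        CSI = PPV + SEN - 100; MCC within [-1, 1]."""
        if tp + tn + fp + fn == 0:
            return
        r = metrics_from_confusion(ConfusionMatrix(tp, tn, fp, fn))
        assert r.accuracy + r.error_rate == pytest.approx(100, abs=1e-9)
        assert r.jaccard / 100 == pytest.approx(
            (r.f1 / 100) / (2 - r.f1 / 100), abs=1e-9
        )
        sen = tp / (tp + fn) if tp + fn else 0.0
        assert r.fm == pytest.approx(np.sqrt((r.precision / 100) * sen), abs=1e-9)
        assert r.csi == pytest.approx(r.precision + 100 * sen - 100, abs=1e-9)
        assert -1.0 - 1e-12 <= r.mcc <= 1.0 + 1e-12

    @given(tp=counts, tn=counts, fp=counts, fn=counts)
    def test_prediction_flip_negates_mcc(self, tp, tn, fp, fn):
        """Flipping every predicted label (tp<->fn, fp<->tn) negates MCC."""
        if tp + tn + fp + fn == 0:
            return
        a = metrics_from_confusion(ConfusionMatrix(tp, tn, fp, fn))
        b = metrics_from_confusion(ConfusionMatrix(fn, fp, tn, tp))
        assert b.mcc == pytest.approx(-a.mcc, abs=1e-12)

    def test_mse_examples(self):
        t = np.array([0.9, 0.1, 0.9, 0.1, 0.9])
        assert ov.mse_scores(t, t) == 0.0
        assert ov.mse_scores(t + 0.1, t) == pytest.approx(0.01)
        rng = np.random.default_rng(50)
        s, tt = rng.uniform(size=5), rng.uniform(size=5)
        assert ov.mse_scores(s, tt) == pytest.approx(
            sum((a - b) ** 2 for a, b in zip(s, tt)) / 5
        )


class TestStratifiedCV:
    def test_balanced_folds_100_samples(self):
        labels = np.array([0] * 50 + [1] * 50)
        folds = stratified_folds(labels, 10, seed=1)
        assert len(folds) == 10
        for train, test in folds:
            assert test.size == 10
            assert np.bincount(labels[test]).tolist() == [5, 5]
            assert np.intersect1d(train, test).size == 0

    def test_each_sample_tested_exactly_once(self):
        labels = np.array([0, 0, 1, 1])
        folds = stratified_folds(labels, 2, seed=0)
        tested = np.concatenate([test for _, test in folds])
        assert sorted(tested.tolist()) == [0, 1, 2, 3]

    def test_small_class_suggests_smaller_k(self):
        with pytest.raises(DataError, match="smaller k"):
            stratified_folds(np.array([0] * 3 + [1] * 50), 10, seed=0)

    def test_two_seeds_same_coverage(self):
        labels = np.array([0] * 20 + [1] * 20)
        a = stratified_folds(labels, 5, seed=1)
        b = stratified_folds(labels, 5, seed=2)
        union = lambda f: sorted(np.concatenate([t for _, t in f]).tolist())
        assert union(a) == union(b) == list(range(40))
        assert any(
            not np.array_equal(x[1], y[1]) for x, y in zip(a, b)
        )

    def test_pooled_equals_fold_sum(self, small_data):
        config = ov.PipelineConfig(
            method="DCT", classifier="LR", cv_k=5, seed=2, n_features=20
        )
        result = ov.stratified_kfold_cv(config, small_data, k=5, seed=2)
        tp = sum(c.tp for c in result.fold_confusions)
        tn = sum(c.tn for c in result.fold_confusions)
        fp = sum(c.fp for c in result.fold_confusions)
        fn = sum(c.fn for c in result.fold_confusions)
        assert (result.pooled_confusion.tp, result.pooled_confusion.tn,
                result.pooled_confusion.fp, result.pooled_confusion.fn) == (tp, tn, fp, fn)
        assert result.pooled_confusion.total == small_data.n_samples


class TestAudit:
    def test_reference_tables_fully_consistent(self):
        rows = reference_rows()
        assert len(rows) == 60
        d = ov.audit_metric_table(
            [r.confusion for r in rows], [r.printed_metrics for r in rows]
        )
        assert d == []

    def test_corrupted_row_is_flagged(self):
        rows = reference_rows()[:5]
        printed = [r.printed_metrics for r in rows]
        printed[2] = dict(printed[2], precision=printed[2]["precision"] + 0.5)
        d = ov.audit_metric_table([r.confusion for r in rows], printed)
        assert len(d) == 1 and d[0].row == 2 and d[0].column == "precision"

    def test_empty_input_empty_report(self):
        assert ov.audit_metric_table([], []) == []
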