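"""Segmentation and classification metrics against explicit set arithmetic,
printed-formula hand arithmetic, and rank-statistic cross-checks."""

import numpy as np
import pytest
from scipy import stats

from ctgnet.metrics import (METRIC_COLUMNS, aggregate, cls_metrics,
                            seg_metrics, summarize)


def seg_reference(pred, true):
    """Explicit coordinate-set evaluation of all five metrics."""
    ap = {tuple(ix) for ix in np.argwhere(pred)}
    ag = {tuple(ix) for ix in np.argwhere(true)}
    inter, union = ap & ag, ap | ag
    fp = union - ag
    return {
        "dsc": 2 * len(inter) / (len(ag) + len(ap)),
        "ji": len(inter) / len(union),
        "tpr": len(inter) / len(ag),
        "fpr": len(fp) / len(union),
        "tfpr": len(fp) / len(ag),
    }


class TestSegMetrics:
    def test_perfect_prediction(self):
        m = np.zeros((10, 10), bool)
        m[2:6, 2:6] = True
        got = seg_metrics(m, m)
        assert (got.dsc, got.ji, got.tpr) == (1.0, 1.0, 1.0)
        assert (got.fpr, got.tfpr) == (0.0, 0.0)

    def test_printed_overlap_example(self):
        # |A_g| = 100, |A_p| = 80, overlap 60 on a 20x20 grid
        true = np.zeros((20, 20), bool)
        pred = np.zeros((20, 20), bool)
        true.flat[0:100] = True
        pred.flat[40:120] = True
        got = seg_metrics(pred, true)
        assert got.dsc == pytest.approx(120 / 180)
        assert got.ji == pytest.approx(60 / 120)
        assert got.tpr == pytest.approx(0.6)
        assert got.fpr == pytest.approx(20 / 120)
        assert got.tfpr == pytest.approx(0.2)

    def test_tumor_based_false_positive_rate_can_exceed_one(self):
        true = np.zeros((12, 12), bool)
        true.flat[:12] = True
        pred = np.zeros((12, 12), bool)
        pred.flat[:36] = True  # superset, |A_p| = 3 |A_g|
        got = seg_metrics(pred, true)
        assert got.tfpr == pytest.approx(2.0)
        assert got.tfpr > 1.0

    def test_matches_set_arithmetic_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            pred = rng.uniform(size=(16, 16)) < rng.uniform(0.05, 0.6)
            true = rng.uniform(size=(16, 16)) < rng.uniform(0.05, 0.6)
            if not true.any():
                continue
            got = seg_metrics(pred, true)
            want = seg_reference(pred, true)
            for name, value in want.items():
                assert getattr(got, name) == value, name

    def test_dice_jaccard_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            pred = rng.uniform(size=(16, 16)) < 0.3
            true = rng.uniform(size=(16, 16)) < 0.3
            if not (pred | true).any():
                continue
            got = seg_metrics(pred, true)
            assert got.dsc == pytest.approx(2 * got.ji / (1 + got.ji),
                                            abs=1e-9)
            assert got.ji <= got.dsc + 1e-12

    def test_empty_mask_conventions(self):
        empty = np.zeros((8, 8), bool)
        some = empty.copy()
        some[0, 0] = True
        both = seg_metrics(empty, empty)
        assert (both.dsc, both.ji, both.tpr, both.fpr, both.tfpr) == \
            (1.0, 1.0, 1.0, 0.0, 0.0)
        fp_only = seg_metrics(some, empty)
        assert (fp_only.dsc, fp_only.ji, fp_only.tpr, fp_only.fpr) == \
            (0.0, 0.0, 0.0, 1.0)
        assert np.isnan(fp_only.tfpr)
        miss = seg_metrics(empty, some)
        assert (miss.dsc, miss.ji, miss.tpr, miss.fpr, miss.tfpr) == \
            (0.0, 0.0, 0.0, 0.0, 0.0)

    def test_shape_mismatch_is_rejected(self):
        with pytest.raises(ValueError):
            seg_metrics(np.zeros((4, 4)), np.zeros((5, 5)))


class TestClsMetrics:
    def test_printed_confusion_arithmetic(self):
        # TP=8, FN=2, TN=9, FP=1
        labels = np.array([1] * 10 + [0] * 10)
        scores = np.array([0.9] * 8 + [0.1] * 2 + [0.1] * 9 + [0.9] * 1)
        got = cls_metrics(scores, labels)
        assert (got.tp, got.fn, got.tn, got.fp) == (8, 2, 9, 1)
        assert got.sen == pytest.approx(0.8)
        assert got.spc == pytest.approx(0.9)
        assert got.acc == pytest.approx(0.85)
        assert got.pre == pytest.approx(8 / 9)
        assert got.f1 == pytest.approx(2 * (8 / 9) * 0.8 / (8 / 9 + 0.8),
                                       abs=1e-9)
        assert got.f1 == pytest.approx(0.8421, abs=5e-5)

    def test_perfect_separation(self):
        labels = np.array([0] * 5 + [1] * 5)
        scores = np.array([0.1] * 5 + [0.9] * 5)
        got = cls_metrics(scores, labels)
        assert got.auc == 1.0 and got.acc == 1.0

    def test_random_scores_have_chance_level_auc(self):
        rng = np.random.default_rng(0)
        n = 2000
        labels = rng.integers(0, 2, size=n)
        scores = rng.uniform(size=n)
        got = cls_metrics(scores, labels)
        assert abs(got.auc - 0.5) < 3 / np.sqrt(n)

    def test_auc_equals_mann_whitney_statistic(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, size=100)
        scores = np.round(rng.uniform(size=100), 2)  # force ties
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                               alternative="two-sided").statistic
        want = u / ((labels == 1).sum() * (labels == 0).sum())
        assert cls_metrics(scores, labels).auc == pytest.approx(want, abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, size=60)
        scores = rng.normal(size=60)
        base = cls_metrics(scores, labels).auc
        for f in (np.exp, np.tanh, lambda s: 3 * s - 7):
            # threshold is irrelevant to AUC
            assert cls_metrics(f(scores), labels, threshold=0.0).auc == \
                pytest.approx(base, abs=1e-12)

    def test_degenerate_labels_yield_nan_auc_with_other_metrics(self):
        with pytest.warns(UserWarning, match="degenerate"):
            got = cls_metrics(np.array([0.9, 0.2]), np.array([1, 1]))
        assert np.isnan(got.auc)
        assert got.sen == pytest.approx(0.5)


class TestAggregation:
    def test_single_image_summary_is_identity(self):
        m = seg_metrics(np.ones((4, 4), bool), np.ones((4, 4), bool))
        agg = aggregate([m])
        assert agg["dsc"] == m.dsc and agg["tfpr"] == m.tfpr

    def test_mean_of_two_images(self):
        a = np.zeros((10, 10), bool)
        a[:5] = True
        b = np.zeros((10, 10), bool)
        b[:, :2] = True
        m1 = seg_metrics(a, a)                      # dsc 1
        pred = a.copy()
        pred[5:] = True                             # half-overlap variants
        m2 = seg_metrics(b, a)
        agg = aggregate([m1, m2])
        assert agg["dsc"] == pytest.approx((m1.dsc + m2.dsc) / 2)

    def test_undefined_tfpr_is_excluded_and_counted(self):
        empty = np.zeros((4, 4), bool)
        fp = empty.copy()
        fp[0, 0] = True
        good = seg_metrics(fp, fp)
        bad = seg_metrics(fp, empty)
        agg = aggregate([good, bad])
        assert agg["tfpr"] == good.tfpr
        assert agg["tfpr_excluded"] == 1

    def test_empty_list_is_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])

    def test_summary_table_schema_and_pooled_classification(self):
        masks = [np.zeros((6, 6), bool) for _ in range(4)]
        for m in masks:
            m[2:4, 2:4] = True
        seg = [seg_metrics(m, m) for m in masks]
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        df = summarize(seg, scores, labels)
        assert list(df.columns) == METRIC_COLUMNS
        # classification metrics are pooled over images, not averaged
        assert df.loc[0, "auc"] == cls_metrics(scores, np.array(labels)).auc
        assert df.loc[0, "dsc"] == 1.0
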