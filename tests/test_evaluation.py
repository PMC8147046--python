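import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippofuse.densecnn import TrainConfig
from hippofuse.evaluation import (compute_metrics, run_cv_experiment,
                                  stratified_kfold_plan)
from hippofuse.fusion import FusionConfig

from conftest import small_arch


def pairwise_auc(labels, scores):
    """Independent AUC oracle: pairwise concordance with ties counted 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestFoldPlan:
    def test_imbalanced_cohort_fold_sizes(self):
        """326 AD + 607 CN split 5 ways: AD folds {66,65,65,65,65} and CN
        folds {122,122,121,121,121}."""
        labels = ["AD"] * 326 + ["CN"] * 607
        plan = stratified_kfold_plan(labels, k=5, repeats=2, seed=0)
        for folds in plan.repeats:
            ad_sizes, cn_sizes = [], []
            lab = dict(zip(plan.subject_ids, labels))
            for fold in folds:
                test_labs = [lab[s] for s in fold["test"]]
                ad_sizes.append(test_labs.count("AD"))
                cn_sizes.append(test_labs.count("CN"))
            assert sorted(ad_sizes) == [65, 65, 65, 65, 66]
            assert sorted(cn_sizes) == [121, 121, 121, 122, 122]

    def test_each_subject_tested_once_per_repeat(self):
        labels = ["AD"] * 13 + ["CN"] * 17
        plan = stratified_kfold_plan(labels, k=5, repeats=3, seed=4)
        plan.check_partition()
        for folds in plan.repeats:
            tested = sorted(s for f in folds for s in f["test"])
            assert tested == sorted(plan.subject_ids)

    def test_validation_is_tenth_of_training(self):
        labels = ["AD"] * 50 + ["CN"] * 50
        plan = stratified_kfold_plan(labels, k=5, repeats=1, seed=1)
        fold = plan.repeats[0][0]
        n_train_portion = len(fold["train"]) + len(fold["val"])
        assert len(fold["val"]) == round(0.1 * n_train_portion)

    def test_seed_determinism(self):
        labels = ["AD"] * 20 + ["CN"] * 30
        p1 = stratified_kfold_plan(labels, k=4, repeats=2, seed=5)
        p2 = stratified_kfold_plan(labels, k=4, repeats=2, seed=5)
        p3 = stratified_kfold_plan(labels, k=4, repeats=2, seed=6)
        assert p1.repeats == p2.repeats
        assert p1.repeats != p3.repeats

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="fewer than k"):
            stratified_kfold_plan(["AD"] * 3 + ["CN"] * 10, k=5, repeats=1, seed=0)


class TestMetrics:
    def test_confusion_arithmetic(self):
        """TP=5 FN=1 TN=8 FP=2: sens 5/6, spec 8/10, acc 13/16."""
        y = [1] * 6 + [0] * 10
        scores = [0.9] * 5 + [0.1] + [0.8] * 2 + [0.2] * 8
        m = compute_metrics(y, scores)
        assert (m.tp, m.fn, m.tn, m.fp) == (5, 1, 8, 2)
        assert np.isclose(m.sensitivity, 0.8333, atol=1e-4)
        assert np.isclose(m.specificity, 0.8)
        assert np.isclose(m.accuracy, 0.8125)

    def test_worked_auc_example(self):
        m = compute_metrics([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
        assert np.isclose(m.auc, 0.75)

    def test_auc_antisymmetry(self):
        y = [0, 0, 0, 1, 1]
        s = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        assert compute_metrics(y, s).auc == 1.0
        assert compute_metrics(y, 1 - s).auc == 0.0

    def test_roc_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        y = rng.permutation([0] * 25 + [1] * 25)
        m = compute_metrics(y, rng.random(50))
        pts = m.roc_points
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            compute_metrics([1, 1, 1], [0.2, 0.5, 0.9])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_trapezoid_auc_equals_pairwise_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        y = np.zeros(n, int)
        y[: int(rng.integers(1, n - 1))] = 1
        rng.shuffle(y)
        scores = np.round(rng.random(n), 2)  # coarse grid provokes ties
        assert abs(compute_metrics(y, scores).auc - pairwise_auc(y, scores)) < 1e-10

    def test_youden_threshold_maximizes_j(self):
        from hippofuse.evaluation import youden_threshold
        y = [0, 0, 0, 0, 1, 1, 1]
        s = [0.1, 0.2, 0.3, 0.6, 0.55, 0.7, 0.9]
        thr = youden_threshold(y, s)
        m = compute_metrics(y, s, threshold=thr)
        best_j = m.sensitivity + m.specificity - 1
        for other in np.linspace(0.01, 0.99, 99):
            mo = compute_metrics(y, s, threshold=other)
            assert mo.sensitivity + mo.specificity - 1 <= best_j + 1e-12

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        y = np.array([0, 1] * 15)
        s = rng.random(30)
        a1 = compute_metrics(y, s).auc
        a2 = compute_metrics(y, np.exp(5 * s)).auc
        assert np.isclose(a1, a2, atol=1e-12)


@pytest.fixture(scope="module")
def small_report(small_dataset):
    plan = stratified_kfold_plan([p.label for p in small_dataset], k=2,
                                 repeats=1, seed=2,
                                 subject_ids=[p.subject_id
                                              for p in small_dataset])
    fusion = FusionConfig(train=TrainConfig(epochs=80, batch_size=8, seed=0))
    return run_cv_experiment(small_dataset, small_arch(), fusion, plan,
                             cnn_train=TrainConfig(epochs=3, batch_size=6),
                             shape_k=6)


class TestRunCV:
    def test_all_models_all_folds_reported(self, small_report):
        for name in ("shape", "visual", "fused"):
            assert len(small_report.records[name]) == 2

    def test_summary_mean_matches_folds(self, small_report):
        summ = small_report.summary()
        for name, recs in small_report.records.items():
            aucs = [r["metrics"].auc for r in recs]
            assert np.isclose(summ[name]["auc"], np.mean(aucs))

    def test_pooled_features_cover_every_subject(self, small_report,
                                                 small_dataset):
        for name in ("visual", "fused"):
            store = small_report.features[name]
            assert sorted(store["ids"]) == sorted(p.subject_id
                                                  for p in small_dataset)
            assert store["rows"].shape[0] == len(small_dataset)

    def test_fused_features_include_shape_block(self, small_report):
        vis = small_report.features["visual"]["rows"].shape[1]
        fus = small_report.features["fused"]["rows"].shape[1]
        assert fus == vis + 2 * 6

    def test_report_serialization(self, small_report, tmp_path):
        small_report.save(tmp_path)
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "roc_fused.csv").read_text().startswith("fpr,tpr")
        folds = (tmp_path / "folds.csv").read_text().strip().splitlines()
        assert len(folds) == 1 + 3 * 2  # header + 3 models x 2 folds
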