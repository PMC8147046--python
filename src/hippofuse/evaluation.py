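"""Repeated stratified cross-validation of the three model variants.

The harness mirrors the evaluation protocol: stratified k-fold with each
fold tested once, the training portion further split into training and
validation (validation = 10% of the training portion, also stratified),
the whole procedure repeated with re-randomized folds, and mean metrics
reported.  Three variants are compared on identical folds: a shape-only
fully connected head, the visual CNN alone, and the late-fusion model.
AD is the positive class for sensitivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .densecnn import (ArchConfig, TrainConfig, VisualModel, build_visual_model,
                       encode_labels, pairs_to_arrays)
from .fusion import FusionConfig, fit_apply_zscore, predict_scores, train_fusion
from .spectrum import subject_shape_features
from . import nn

MODEL_NAMES = ("shape", "visual", "fused")


@dataclass
class FoldPlan:
    """Per-repeat, per-fold train/validation/test subject-id lists."""

    subject_ids: list[str]
    labels: list[str]
    repeats: list[list[dict[str, list[str]]]]
    seed: int

    def check_partition(self) -> None:
        all_ids = set(self.subject_ids)
        for folds in self.repeats:
            tested = [sid for fold in folds for sid in fold["test"]]
            if sorted(tested) != sorted(all_ids):
                raise AssertionError("test folds do not partition the subjects")
            for fold in folds:
                overlap = set(fold["test"]) & (set(fold["train"]) | set(fold["val"]))
                if overlap:
                    raise AssertionError(f"train/test leakage: {sorted(overlap)[:3]}")


def stratified_kfold_plan(labels, k: int = 5, repeats: int = 10, seed: int = 0,
                          subject_ids=None, val_fraction: float = 0.1) -> FoldPlan:
    """Seeded repeated stratified k-fold plan with stratified validation split."""
    labels = [str(l) for l in labels]
    if subject_ids is None:
        subject_ids = [f"sub-{i:04d}" for i in range(len(labels))]
    subject_ids = list(subject_ids)
    y = np.asarray(labels)
    counts = {c: int((y == c).sum()) for c in np.unique(y)}
    small = [c for c, n in counts.items() if n < k]
    if small:
        raise ValueError(f"class(es) {small} have fewer than k={k} members")
    rng = np.random.default_rng(seed)
    repeat_seeds = rng.integers(2 ** 31, size=repeats)
    ids = np.asarray(subject_ids)
    plan_repeats = []
    for rs in repeat_seeds:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rs))
        folds = []
        for fi, (train_idx, test_idx) in enumerate(skf.split(ids, y)):
            # validation = val_fraction of the training portion, stratified;
            # never below one subject per class
            n_val = max(len(counts), int(round(val_fraction * len(train_idx))))
            tr, va = train_test_split(train_idx, test_size=n_val,
                                      stratify=y[train_idx],
                                      random_state=int(rs) % (2 ** 31 - k) + fi)
            folds.append({"train": ids[tr].tolist(), "val": ids[va].tolist(),
                          "test": ids[test_idx].tolist()})
        plan_repeats.append(folds)
    plan = FoldPlan(subject_ids=subject_ids, labels=labels,
                    repeats=plan_repeats, seed=seed)
    plan.check_partition()
    return plan


@dataclass
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    tp: int
    fp: int
    tn: int
    fn: int
    roc_points: np.ndarray  # (n, 2) columns FPR, TPR

    def as_dict(self):
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "auc": self.auc,
                "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


def compute_metrics(labels, scores, threshold: float = 0.5) -> Metrics:
    """Confusion-matrix metrics at a threshold plus the full ROC and AUC.

    Labels may be 'AD'/'CN' strings or 0/1 codes (AD = 1 = positive).  The
    ROC sweeps every distinct score (ties grouped at one threshold) and the
    AUC is the trapezoid-rule area, which equals pairwise concordance with
    ties counted as one half.
    """
    y = np.asarray(labels)
    if y.dtype.kind in "US":
        y = encode_labels(y)
    y = y.astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; sensitivity and "
                         "specificity are undefined")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return Metrics(accuracy=(tp + tn) / len(y), sensitivity=tp / (tp + fn),
                   specificity=tn / (tn + fp), auc=auc,
                   tp=tp, fp=fp, tn=tn, fn=fn,
                   roc_points=np.column_stack([fpr, tpr]))


def youden_threshold(labels, scores) -> float:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1.

    An alternative to the default 0.5 threshold for the confusion-matrix
    metrics; ties broken toward the lowest threshold.
    """
    y = np.asarray(labels)
    if y.dtype.kind in "US":
        y = encode_labels(y)
    fpr, tpr, thr = roc_curve(y, np.asarray(scores, float),
                              drop_intermediate=False)
    j = tpr - fpr
    return float(thr[np.argmax(j)])


@dataclass
class EvalReport:
    """Per-model, per-repeat, per-fold metrics plus pooled test features."""

    records: dict[str, list[dict]] = field(default_factory=dict)
    features: dict[str, dict] = field(default_factory=dict)

    def add(self, model: str, repeat: int, fold: int, metrics: Metrics) -> None:
        self.records.setdefault(model, []).append(
            {"repeat": repeat, "fold": fold, "metrics": metrics})

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for model, recs in self.records.items():
            out[model] = {}
            for key in ("accuracy", "sensitivity", "specificity", "auc"):
                vals = np.asarray([getattr(r["metrics"], key) for r in recs])
                out[model][key] = float(vals.mean())
                out[model][f"{key}_sd"] = float(vals.std())
        return out

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        payload = {"summary": self.summary(), "folds": {
            model: [{"repeat": r["repeat"], "fold": r["fold"],
                     **r["metrics"].as_dict()} for r in recs]
            for model, recs in self.records.items()}}
        (out_dir / "report.json").write_text(json.dumps(payload, indent=2))
        lines = ["model,repeat,fold,accuracy,sensitivity,specificity,auc"]
        for model, recs in self.records.items():
            for r in recs:
                m = r["metrics"]
                lines.append(f"{model},{r['repeat']},{r['fold']},"
                             f"{m.accuracy:.6f},{m.sensitivity:.6f},"
                             f"{m.specificity:.6f},{m.auc:.6f}")
        (out_dir / "folds.csv").write_text("\n".join(lines) + "\n")
        for model, recs in self.records.items():
            lines = ["fpr,tpr"]
            lines += [f"{p[0]:.6f},{p[1]:.6f}"
                      for p in recs[0]["metrics"].roc_points]
            (out_dir / f"roc_{model}.csv").write_text("\n".join(lines) + "\n")


def compute_all_shape_features(dataset, k: int = 30) -> dict[str, np.ndarray]:
    """Spectral features per subject (fold-independent, computed once)."""
    return {p.subject_id: subject_shape_features(p, k=k).values for p in dataset}


def run_cv_experiment(dataset, arch_cfg: ArchConfig, fusion_cfg: FusionConfig,
                      plan: FoldPlan, cnn_train: TrainConfig | None = None,
                      shape_k: int = 30,
                      shape_features: dict[str, np.ndarray] | None = None,
                      collect_features: bool = True,
                      verbose: bool = False) -> EvalReport:
    """Run the full three-model comparison over a fold plan.

    Per repeat and fold: the CNN is trained on the training split with
    early selection on the validation split; deep features are extracted in
    inference mode; z-score normalizers and both fully connected heads
    (shape-only and fused) are fit on the non-test rows only; all three
    variants are scored on the untouched test fold.  With
    ``collect_features`` the z-scored deep-only and fused test-fold feature
    rows of the first repeat are pooled (each subject out-of-fold exactly
    once) for downstream separability analysis.
    """
    cnn_train = cnn_train or TrainConfig()
    by_id = {p.subject_id: p for p in dataset}
    if set(plan.subject_ids) - set(by_id):
        raise ValueError("plan references subjects missing from the dataset")
    if shape_features is None:
        shape_features = compute_all_shape_features(dataset, k=shape_k)
    x_all, y_all = pairs_to_arrays([by_id[s] for s in plan.subject_ids])
    pos = {sid: i for i, sid in enumerate(plan.subject_ids)}
    shape_all = np.vstack([shape_features[s] for s in plan.subject_ids])
    report = EvalReport()
    master = np.random.default_rng(plan.seed + 1)
    for ri, folds in enumerate(plan.repeats):
        for fi, fold in enumerate(folds):
            tr = np.asarray([pos[s] for s in fold["train"]])
            va = np.asarray([pos[s] for s in fold["val"]])
            te = np.asarray([pos[s] for s in fold["test"]])
            head_tr = np.concatenate([tr, va])
            seed_cnn = int(master.integers(2 ** 31))
            seed_head = int(master.integers(2 ** 31))
            model = build_visual_model(arch_cfg, rng_seed=seed_cnn)
            nn.fit_classifier(
                model, (x_all[0][tr], x_all[1][tr]), y_all[tr],
                epochs=cnn_train.epochs, batch_size=cnn_train.batch_size,
                lr=cnn_train.learning_rate, momentum=cnn_train.momentum,
                l2=arch_cfg.l2_weight, seed=seed_cnn + 1,
                val=((x_all[0][va], x_all[1][va]), y_all[va]))
            deep_all = _batched_features(model, x_all)
            # visual-only: the CNN's own softmax output
            visual_scores = model.predict_proba((x_all[0][te], x_all[1][te]))
            # shape-only head
            shape_cfg = _head_cfg(fusion_cfg, seed_head)
            _, ztr_s, zte_s = fit_apply_zscore(shape_all[head_tr], shape_all[te])
            shape_model, _ = train_fusion(ztr_s, y_all[head_tr], shape_cfg)
            shape_scores = predict_scores(shape_model, zte_s)
            # fused head: deep features first, shape features second
            fused_all = np.hstack([deep_all, shape_all])
            fused_cfg = _head_cfg(fusion_cfg, seed_head + 1)
            _, ztr_f, zte_f = fit_apply_zscore(fused_all[head_tr], fused_all[te])
            fused_model, _ = train_fusion(ztr_f, y_all[head_tr], fused_cfg)
            fused_scores = predict_scores(fused_model, zte_f)
            y_te = y_all[te]
            for name, scores in (("shape", shape_scores),
                                 ("visual", visual_scores),
                                 ("fused", fused_scores)):
                report.add(name, ri, fi, compute_metrics(y_te, scores))
            if collect_features and ri == 0:
                _, _, zdeep_te = fit_apply_zscore(deep_all[head_tr], deep_all[te])
                for name, rows in (("visual", zdeep_te), ("fused", zte_f)):
                    store = report.features.setdefault(
                        name, {"ids": [], "rows": [], "labels": []})
                    store["ids"] += [plan.subject_ids[i] for i in te]
                    store["rows"].append(rows)
                    store["labels"].append(y_te)
            if verbose:
                m = report.records["fused"][-1]["metrics"]
                print(f"repeat {ri} fold {fi}: fused auc={m.auc:.3f} "
                      f"acc={m.accuracy:.3f}")
    for store in report.features.values():
        store["rows"] = np.vstack(store["rows"])
        store["labels"] = np.concatenate(store["labels"])
    return report


def _head_cfg(fusion_cfg: FusionConfig, seed: int) -> FusionConfig:
    train = TrainConfig(learning_rate=fusion_cfg.train.learning_rate,
                        momentum=fusion_cfg.train.momentum,
                        epochs=fusion_cfg.train.epochs,
                        batch_size=fusion_cfg.train.batch_size, seed=seed)
    return FusionConfig(hidden_layers=fusion_cfg.hidden_layers,
                        dropout_rate=fusion_cfg.dropout_rate,
                        l2_weight=fusion_cfg.l2_weight, train=train)


def _batched_features(model: VisualModel, x, batch_size: int = 32) -> np.ndarray:
    n = x[0].shape[0]
    out = []
    for s in range(0, n, batch_size):
        sl = slice(s, min(s + batch_size, n))
        out.append(model.features((x[0][sl], x[1][sl])))
    return np.vstack(out)
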