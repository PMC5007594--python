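"""Stratified K-fold cross-validation and classification metrics.

Metrics follow the standard confusion-matrix definitions:

    Se  = TP / (TP + FN)                    (sensitivity, recall)
    Sp  = TN / (TN + FP)                    (specificity)
    ACC = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP·TN − FP·FN) /
          sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC is defined as 0 when any denominator factor is 0. Confusion counts are
real-valued so that matrices built from printed rates (Se, Sp under a
balanced design) can be evaluated directly; on balanced classes
ACC = (Se + Sp)/2 exactly.

AUC is the rank (Mann–Whitney) statistic with average ranks for ties,
equivalent to the trapezoidal area under the tie-aware ROC curve.

Cross-validation is stratified: within each class, ids are shuffled with
the given seed and dealt round-robin into K folds, so per-class fold sizes
differ by at most one. Held-out scores are pooled across folds for the
headline metrics; per-fold metrics are also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .genomic_io import FeatureMatrix
from .rf_selection import EnhancerForest, RFConfig

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "stratified_folds",
    "confusion_metrics",
    "roc_auc",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Real-valued confusion counts (supports rate-derived matrices)."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn <= 0:
            raise ValueError("empty confusion matrix")


@dataclass
class EvalReport:
    """Headline metrics plus the ROC polyline and optional per-fold reports."""

    se: float
    sp: float
    acc: float
    mcc: float
    auc: float
    roc: list = field(default_factory=list)  # (fpr, tpr) points
    per_fold: list | None = None

    def to_dict(self) -> dict:
        d = {
            "se": self.se,
            "sp": self.sp,
            "acc": self.acc,
            "mcc": self.mcc,
            "auc": self.auc,
            "roc": [[float(f), float(t)] for f, t in self.roc],
        }
        if self.per_fold is not None:
            d["per_fold"] = [r.to_dict() for r in self.per_fold]
        return d


def stratified_folds(labels: dict, K: int, seed: int | None = 0) -> dict:
    """Assign ids to folds 1..K, stratified by class.

    Within each class the ids are shuffled (seeded; insertion order is
    first made deterministic by sorting) and dealt round-robin, so fold
    sizes within a class differ by at most 1.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    by_class: dict[str, list] = {}
    for rid, lab in labels.items():
        by_class.setdefault(lab, []).append(rid)
    rng = np.random.default_rng(seed)
    assignment: dict = {}
    for lab in sorted(by_class):
        ids = sorted(by_class[lab])
        if len(ids) < K:
            raise ValueError(f"class {lab!r} has fewer than K={K} members")
        perm = rng.permutation(len(ids))
        for pos, idx in enumerate(perm):
            assignment[ids[idx]] = pos % K + 1
    return assignment


def confusion_metrics(cm: ConfusionMatrix) -> tuple[float, float, float, float]:
    """(Se, Sp, ACC, MCC) from a confusion matrix; MCC = 0 on a 0 factor."""
    if cm.tp + cm.fn <= 0 or cm.tn + cm.fp <= 0:
        raise ValueError("both classes must be represented")
    se = cm.tp / (cm.tp + cm.fn)
    sp = cm.tn / (cm.tn + cm.fp)
    acc = (cm.tp + cm.tn) / (cm.tp + cm.tn + cm.fp + cm.fn)
    denom2 = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom2 <= 0:
        mcc = 0.0
    else:
        mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / np.sqrt(denom2)
    return se, sp, acc, float(mcc)


def roc_auc(scores: dict, labels: dict) -> tuple[float, list]:
    """AUC (tie-aware rank statistic) and ROC points sorted by FPR."""
    ids = sorted(scores)
    y = np.array([1 if labels[i] == "positive" else 0 for i in ids])
    s = np.array([float(scores[i]) for i in ids])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    points = sorted(zip(fpr.tolist(), tpr.tolist()))
    return auc, points


def _report_from_scores(
    y: np.ndarray, s: np.ndarray, threshold: float
) -> EvalReport:
    pred = (s >= threshold).astype(int)
    cm = ConfusionMatrix(
        tp=float(((pred == 1) & (y == 1)).sum()),
        fp=float(((pred == 1) & (y == 0)).sum()),
        tn=float(((pred == 0) & (y == 0)).sum()),
        fn=float(((pred == 0) & (y == 1)).sum()),
    )
    se, sp, acc, mcc = confusion_metrics(cm)
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    return EvalReport(se, sp, acc, mcc, auc, sorted(zip(fpr.tolist(), tpr.tolist())))


def cross_validate(
    m: FeatureMatrix,
    cfg: RFConfig | None = None,
    K: int = 10,
    seed: int | None = 0,
    threshold: float = 0.5,
) -> EvalReport:
    """Stratified K-fold cross-validation of the forest on a feature matrix.

    Every region is scored exactly once, by the forest trained on the
    other K−1 folds. Scores >= ``threshold`` predict the positive class.
    Pooled (all held-out scores together) metrics are the headline report;
    per-fold reports are attached as ``per_fold``.
    """
    cfg = cfg or RFConfig()
    ss = np.random.SeedSequence(seed)
    fold_ss, *fit_seeds = ss.spawn(K + 1)
    folds = stratified_folds(
        m.labels, K, seed=int(fold_ss.generate_state(1)[0] % (2**31))
    )
    y = m.y()
    idx_of = {rid: i for i, rid in enumerate(m.region_ids)}
    pooled_scores = np.empty(m.n_regions)
    scored = np.zeros(m.n_regions, dtype=bool)
    per_fold = []
    for k in range(1, K + 1):
        test_ids = [rid for rid in m.region_ids if folds[rid] == k]
        train_idx = np.array(
            [idx_of[rid] for rid in m.region_ids if folds[rid] != k]
        )
        test_idx = np.array([idx_of[rid] for rid in test_ids])
        forest = EnhancerForest(
            ntree=cfg.ntree,
            mtry=cfg.mtry,
            seed=int(fit_seeds[k - 1].generate_state(1)[0] % (2**31)),
            compute_importance=False,
            n_jobs=cfg.n_jobs,
        ).fit(m.values[train_idx], y[train_idx])
        s = forest.predict_score(m.values[test_idx])
        pooled_scores[test_idx] = s
        scored[test_idx] = True
        per_fold.append(_report_from_scores(y[test_idx], s, threshold))
    assert scored.all(), "every sample must be scored exactly once"
    report = _report_from_scores(y, pooled_scores, threshold)
    report.per_fold = per_fold
    return report
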