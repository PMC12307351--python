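"""Stratified cross-validation, classification metrics, fold aggregation.

Metrics follow the standard confusion-matrix definitions

    ACC = (TP+TN)/(TP+TN+FP+FN),  Precision = TP/(TP+FP),
    Recall = TP/(TP+FN),          F1 = 2·P·R/(P+R),

with the convention that precision/recall/F1 are 0 when their denominator is
0.  AUC is the Mann–Whitney concordance statistic (ties counted 1/2).  Fold
results are aggregated as the mean M and the *population-form* dispersion
σ_M = sqrt((1/K) Σ (M_k − M)²) — divisor K, not K−1.

``run_cv`` trains the given estimator from scratch inside every fold
(including contrastive pretraining and vocabulary construction on the fold's
training subjects only) and asserts, via the provenance tags carried by every
derived object, that no held-out subject leaked into any training artefact.
A ``global_pretrain`` escape hatch reproduces the riskier
pretrain-once-on-everything alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .exceptions import StratificationError, UndefinedAUCError, ValidationError

__all__ = [
    "CVReport",
    "stratified_folds",
    "confusion_metrics",
    "auc_score",
    "aggregate_folds",
    "run_cv",
]

METRICS = ("ACC", "AUC", "F1", "precision", "recall")


@dataclass
class CVReport:
    """Per-fold metrics with mean and population dispersion per metric."""

    per_fold: dict[str, list[float]]
    K: int
    seed: int
    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.mean:
            for name, values in self.per_fold.items():
                m, s = aggregate_folds(values)
                self.mean[name] = m
                self.std[name] = s

    def format(self, digits: int = 3) -> dict[str, str]:
        """Metric → "mean ± std" strings, the usual results-table shape."""
        return {
            name: f"{self.mean[name]:.{digits}f} ± {self.std[name]:.{digits}f}"
            for name in self.per_fold
        }

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "seed": self.seed,
            "per_fold": {k: list(map(float, v)) for k, v in self.per_fold.items()},
            "mean": dict(self.mean),
            "std": dict(self.std),
            "formatted": self.format(),
        }


def stratified_folds(labels, K: int = 5, seed: int = 0) -> np.ndarray:
    """Fold assignment (0..K-1 per subject) preserving class proportions.

    Deterministic given ``seed``; per-class counts per fold differ by at most
    one, as do total fold sizes.
    """
    y = np.asarray(labels)
    if K < 2:
        raise StratificationError("need at least 2 folds")
    classes, counts = np.unique(y, return_counts=True)
    small = counts < K
    if small.any():
        raise StratificationError(
            f"class {classes[small][0]} has {counts[small][0]} members, "
            f"fewer than K={K} folds"
        )
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold
    return assignment


def confusion_metrics(y_true, y_pred) -> dict[str, float]:
    """ACC / precision / recall / F1 from the binary confusion counts."""
    yt = np.asarray(y_true).ravel()
    yp = np.asarray(y_pred).ravel()
    if yt.shape != yp.shape:
        raise ValidationError(f"length mismatch: {yt.size} vs {yp.size}")
    if yt.size == 0:
        raise ValidationError("empty prediction vectors")
    tp = int(((yt == 1) & (yp == 1)).sum())
    tn = int(((yt == 0) & (yp == 0)).sum())
    fp = int(((yt == 0) & (yp == 1)).sum())
    fn = int(((yt == 1) & (yp == 0)).sum())
    acc = (tp + tn) / (tp + tn + fp + fn)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return {
        "ACC": float(acc),
        "precision": float(precision),
        "recall": float(recall),
        "F1": float(f1),
    }


def auc_score(y_true, scores) -> float:
    """Mann–Whitney AUC: fraction of concordant (positive, negative) pairs.

    Tied scores receive half credit; invariant to strictly monotone
    transforms of ``scores``.
    """
    yt = np.asarray(y_true).ravel()
    s = np.asarray(scores, dtype=np.float64).ravel()
    if yt.shape != s.shape:
        raise ValidationError(f"length mismatch: {yt.size} vs {s.size}")
    n_pos = int((yt == 1).sum())
    n_neg = int((yt == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC undefined with a single class in y_true")
    ranks = rankdata(s)  # average ranks handle ties with 1/2 credit
    return float((ranks[yt == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def aggregate_folds(values) -> tuple[float, float]:
    """Mean and population-style dispersion (divisor K) across folds."""
    v = np.asarray(list(values), dtype=np.float64)
    if v.size == 0:
        raise ValidationError("cannot aggregate an empty metric list")
    m = float(v.mean())
    return m, float(np.sqrt(np.mean((v - m) ** 2)))


def _assert_no_leakage(estimator, test_ids: set[str]) -> None:
    prov = getattr(estimator, "provenance_", None)
    if prov is None:
        raise ValidationError("estimator carries no provenance tags")
    leaked = prov & test_ids
    if leaked:
        raise ValidationError(
            f"leakage: test subjects {sorted(leaked)[:3]} influenced training artefacts"
        )
    vocab = getattr(estimator, "vocab_", None)
    if vocab is not None and vocab.provenance & test_ids:
        raise ValidationError("leakage: vocabulary built from held-out subjects")


def run_cv(dataset, estimator, K: int = 5, seed: int = 0,
           global_pretrain: bool = False) -> CVReport:
    """Stratified K-fold cross-validation of a multimodal estimator.

    Every fold clones ``estimator`` and fits it on the training subjects only;
    metrics are computed on the held-out fold and aggregated.  With
    ``global_pretrain`` the contrastive stage runs once on the full cohort and
    its weights initialise every fold (leakage checks are then skipped for the
    pretrained artefacts, which is the point of the flag).
    """
    labels = np.asarray(dataset.labels, dtype=int)
    assignment = stratified_folds(labels, K=K, seed=seed)
    pretrained_state = None
    if global_pretrain:
        from .model import MultimodalFusionClassifier

        proto: MultimodalFusionClassifier = clone(estimator)
        proto.set_params(epochs=0)
        proto.fit(dataset)
        pretrained_state = {
            "image": proto.image_encoder_.state_dict(),
            "text": proto.text_encoder_.state_dict(),
            "vocab": proto.vocab_.token_to_id,
            "provenance": sorted(proto.vocab_.provenance),
            "trace": proto.pretrain_trace_,
        }
    per_fold: dict[str, list[float]] = {m: [] for m in METRICS}
    for fold in range(K):
        test_idx = np.where(assignment == fold)[0]
        train_idx = np.where(assignment != fold)[0]
        train_ds = dataset.subset(train_idx)
        test_ds = dataset.subset(test_idx)
        est = clone(estimator)
        est.set_params(random_state=int(seed) + fold)
        if pretrained_state is not None:
            est.set_params(pretrained_state=pretrained_state)
        est.fit(train_ds)
        if not global_pretrain:
            _assert_no_leakage(est, set(test_ds.subject_ids))
        y_pred = est.predict(test_ds)
        scores = est.decision_scores(test_ds)
        cm = confusion_metrics(test_ds.labels, y_pred)
        for name, value in cm.items():
            per_fold[name].append(value)
        per_fold["AUC"].append(auc_score(test_ds.labels, scores))
    return CVReport(per_fold=per_fold, K=K, seed=seed)
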