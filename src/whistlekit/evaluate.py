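"""Evaluation protocol: cross-validation, classification metrics, ROC/AUC,
event-level detection scoring, and contour quality checks.

Two scoring paths are kept distinct: segment-level classification
metrics (confusion counts over spectrogram images) and event-level
matching (detected time intervals vs ground-truth whistle intervals
under a minimum-overlap criterion, 5% of the truth interval by
default).  Metrics with a zero denominator are reported as NaN, never
coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from whistlekit.annotations import WhistleAnnotation, overlap_seconds
from whistlekit.spectrogram import SpectrogramImage


@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN over a set of evaluated items."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class DetectionMetrics:
    """Derived fractions: accuracy, precision, recall, TPR, FPR.

    Precision = TP/(TP+FP), Recall = TPR = TP/(TP+FN),
    FPR = FP/(FP+TN), accuracy = (TP+TN)/total.  Undefined ratios are
    NaN.
    """

    accuracy: float
    precision: float
    recall: float
    tpr: float
    fpr: float

    def as_percent_strings(self) -> dict:
        """Format each defined metric as a percentage to one decimal."""
        out = {}
        for name in ("accuracy", "precision", "recall", "tpr", "fpr"):
            v = getattr(self, name)
            out[name] = "n/a" if math.isnan(v) else f"{100.0 * v:.1f}%"
        return out


@dataclass
class ROCCurve:
    """Threshold sweep: descending thresholds with cumulative FPR/TPR
    and the trapezoidal AUC."""

    thresholds: np.ndarray
    fpr_points: np.ndarray
    tpr_points: np.ndarray
    auc: float


@dataclass
class FoldPlan:
    """Stratified assignment of items to k folds."""

    k: int
    assignments: np.ndarray  # fold index per item
    seed: int

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, test_idx) for one fold."""
        test = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, test


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Confusion counts for binary labels (1 = whistle, 0 = noise)."""
    t = np.asarray(y_true, dtype=np.int64)
    p = np.asarray(y_pred, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if not (np.isin(t, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be 0 or 1")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def metrics_from_counts(c: ConfusionCounts) -> DetectionMetrics:
    if c.total == 0:
        raise ValueError("no evaluated items")
    recall = _ratio(c.tp, c.tp + c.fn)
    return DetectionMetrics(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=_ratio(c.tp, c.tp + c.fp),
        recall=recall,
        tpr=recall,
        fpr=_ratio(c.fp, c.fp + c.tn),
    )


def roc_auc(y_true, scores) -> ROCCurve:
    """ROC curve and AUC from a threshold sweep over unique scores.

    Equal scores are grouped into one threshold step, so the AUC
    (trapezoidal) equals the concordance probability with half credit
    for ties.  Requires both classes present.
    """
    t = np.asarray(y_true, dtype=np.int64)
    s = np.asarray(scores, dtype=np.float64)
    if t.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos, n_neg = int((t == 1).sum()), int((t == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted, t_sorted = s[order], t[order]
    # cumulative counts at each distinct-score boundary
    distinct = np.flatnonzero(np.diff(s_sorted)) if len(s_sorted) > 1 else np.array([], int)
    boundaries = np.concatenate((distinct, [len(s_sorted) - 1]))
    cum_tp = np.cumsum(t_sorted == 1)[boundaries]
    cum_fp = np.cumsum(t_sorted == 0)[boundaries]
    tpr = np.concatenate(([0.0], cum_tp / n_pos))
    fpr = np.concatenate(([0.0], cum_fp / n_neg))
    thresholds = np.concatenate(([np.inf], s_sorted[boundaries]))
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr_points=fpr, tpr_points=tpr, auc=auc)


def match_detections(
    detected: list[tuple[float, float]],
    truth: list[WhistleAnnotation],
    min_overlap_frac: float = 0.05,
) -> ConfusionCounts:
    """Score detected intervals against ground-truth whistles.

    A truth whistle is a TP if any detection overlaps at least
    ``min_overlap_frac`` of the truth interval's duration, else an FN.
    A detection that validates no whistle at that threshold is an FP.
    One detection may validate several overlapping truths.  TN is not
    defined at event level and stays 0.
    """
    for d0, d1 in detected:
        if not d1 > d0:
            raise ValueError(f"malformed detection interval [{d0}, {d1})")
    whistles = [a for a in truth if a.is_whistle]
    tp = fn = 0
    used = [False] * len(detected)
    for w in whistles:
        hit = False
        for i, (d0, d1) in enumerate(detected):
            if overlap_seconds(d0, d1, w.t_start, w.t_end) / w.duration >= min_overlap_frac:
                used[i] = True
                hit = True
        if hit:
            tp += 1
        else:
            fn += 1
    fp = sum(1 for u in used if not u)
    return ConfusionCounts(tp=tp, tn=0, fp=fp, fn=fn)


def contour_qa(
    ann: WhistleAnnotation,
    spec: SpectrogramImage,
    band: tuple[float, float] = (3000.0, 20000.0),
    var_limit_db2: float = 25.0,
) -> dict:
    """Quality checks on a hand-drawn whistle contour.

    Check 1 (bandwidth): every contour frequency lies inside ``band`` —
    a dolphin whistle should stay within 3-20 kHz.  Check 2 (intensity
    stability): the variance of the spectrogram dB values sampled at the
    nearest time/frequency bin along the contour must not exceed
    ``var_limit_db2`` — a valid whistle has stable intensity along its
    contour.
    """
    if ann.contour is None:
        raise ValueError("annotation carries no contour")
    c = ann.contour
    in_band = bool(np.all((c[:, 1] >= band[0]) & (c[:, 1] <= band[1])))
    ti = np.clip(np.searchsorted(spec.times, c[:, 0]), 0, len(spec.times) - 1)
    # snap to nearest frame/bin
    ti = np.where(
        (ti > 0)
        & (np.abs(spec.times[np.maximum(ti - 1, 0)] - c[:, 0]) < np.abs(spec.times[ti] - c[:, 0])),
        ti - 1,
        ti,
    )
    fi = np.clip(np.searchsorted(spec.freqs, c[:, 1]), 0, len(spec.freqs) - 1)
    fi = np.where(
        (fi > 0)
        & (np.abs(spec.freqs[np.maximum(fi - 1, 0)] - c[:, 1]) < np.abs(spec.freqs[fi] - c[:, 1])),
        fi - 1,
        fi,
    )
    values = spec.power_db[fi, ti]
    variance = float(np.var(values))
    return {
        "bandwidth_ok": in_band,
        "intensity_variance_db2": variance,
        "intensity_ok": variance <= var_limit_db2,
    }


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> FoldPlan:
    """Shuffled stratified k-fold assignment.

    Items of each class are shuffled and dealt round-robin across
    folds, so per-fold class counts differ from the ideal proportion by
    at most one item.  Deterministic per seed.
    """
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes to stratify")
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(f"class {small!r} has fewer members ({counts.min()}) than k={k}")
    assignments = np.empty(len(y), dtype=np.int64)
    # rotate the starting fold per class so remainders spread evenly
    start = 0
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assignments[idx] = (np.arange(len(idx)) + start) % k
        start += len(idx)
    return FoldPlan(k=k, assignments=assignments, seed=seed)


def run_cv(
    x: np.ndarray,
    y: np.ndarray,
    model_builder,
    training_cfg,
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Stratified k-fold cross-validation of a detector.

    ``model_builder(seed)`` must return a fresh built model.  One model
    is trained per fold (with the fold held out for evaluation) and
    per-fold accuracy/loss histories are aggregated into mean and
    standard deviation.
    """
    y = np.asarray(y, dtype=np.int64)
    plan = stratified_kfold(y, k=k, seed=seed)
    fold_metrics, histories = [], []
    for fold in range(k):
        tr, te = plan.fold_indices(fold)
        model = model_builder(seed + fold)
        hist = model.fit(x[tr], y[tr], training_cfg)
        pred = model.predict_proba(x[te]).argmax(axis=1)
        acc = float((pred == y[te]).mean())
        fold_metrics.append(acc)
        histories.append(hist)
    return {
        "fold_accuracy": fold_metrics,
        "mean_accuracy": float(np.mean(fold_metrics)),
        "sd_accuracy": float(np.std(fold_metrics, ddof=1)) if k > 1 else 0.0,
        "histories": histories,
        "fold_plan": plan,
    }


def train_final(x: np.ndarray, y: np.ndarray, model_builder, training_cfg,
                checkpoint_path=None):
    """Train the deployment model on all training items.

    An internal validation split (``training_cfg.validation_fraction``)
    serves early stopping only.  Returns ``(model, history)``;
    optionally checkpoints the weights.
    """
    if len(x) == 0:
        raise ValueError("empty dataset")
    model = model_builder(training_cfg.seed)
    history = model.fit(x, np.asarray(y, dtype=np.int64), training_cfg)
    if checkpoint_path is not None:
        model.save(checkpoint_path)
    return model, history
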