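"""Diagnostic metrics and the patient-grouped cross-validation protocol.

The evaluation design mirrors a clinical-imaging study: a fixed test set
of patients is carved out first and never enters cross-validation; the
remaining patients are split into ``k`` folds *by patient*, so the two
radiographs of one person can never straddle a train/validation boundary
(that would leak near-duplicate images). Each fold trains the classifier
head from scratch on the other ``k - 1`` folds, early-stops on its own
fold, and is scored on the fixed test set; fold metrics are aggregated as
mean +/- population standard deviation (divisor ``k``).

All metrics derive from the binary confusion matrix with ``pes_planus``
as the positive class and are reported as percentages:

    accuracy    = (TP + TN) / (TP + FP + FN + TN)
    sensitivity = recall = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    F1          = 2 * precision * recall / (precision + recall)

Zero denominators yield 0 with a warning rather than an error.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigError, InvalidInputError
from .samples import CLASSES, PES_PLANUS, one_hot
from . import elm

__all__ = [
    "ConfusionMatrix", "MetricsReport", "FoldPlan", "CVSummary", "CurveSet",
    "confusion_matrix", "metrics_from_cm", "make_fold_plan", "run_crossval",
    "aggregate", "roc_pr_curves",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "recall",
                "precision", "f1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positive class = pes_planus."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass(frozen=True)
class MetricsReport:
    """Percentage metrics in [0, 100]; ``recall`` is an alias of sensitivity."""

    accuracy: float
    sensitivity: float
    specificity: float
    recall: float
    precision: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def confusion_matrix(y_true, y_pred, positive: str = PES_PLANUS) -> ConfusionMatrix:
    """Count TP/FP/FN/TN over two equal-length label sequences.

    Labels must come from the two known classes; swapping ``positive``
    swaps TP with TN and FP with FN.
    """
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise InvalidInputError("label sequences differ in length")
    known = set(CLASSES)
    bad = (set(y_true) | set(y_pred)) - known
    if bad:
        raise InvalidInputError(f"unknown label values: {sorted(bad)}")
    if positive not in known:
        raise InvalidInputError(f"unknown positive label {positive!r}")
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive:
            tp += p == positive
            fn += p != positive
        else:
            fp += p == positive
            tn += p != positive
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, reporting 0", stacklevel=3)
        return 0.0
    return num / den


def metrics_from_cm(cm: ConfusionMatrix) -> MetricsReport:
    """Percentage metrics from a confusion matrix (see module docstring)."""
    if cm.n == 0:
        raise InvalidInputError("confusion matrix has no samples")
    acc = (cm.tp + cm.tn) / cm.n
    sens = _safe_div(cm.tp, cm.tp + cm.fn, "sensitivity")
    spec = _safe_div(cm.tn, cm.tn + cm.fp, "specificity")
    prec = _safe_div(cm.tp, cm.tp + cm.fp, "precision")
    f1 = _safe_div(2 * prec * sens, prec + sens, "f1")
    return MetricsReport(accuracy=100 * acc, sensitivity=100 * sens,
                         specificity=100 * spec, recall=100 * sens,
                         precision=100 * prec, f1=100 * f1)


# ---------------------------------------------------------------------------
# fold planning


@dataclass(frozen=True)
class FoldPlan:
    """Patient-disjoint partition: ``k`` CV folds plus a fixed test set.

    ``image_patients`` is the per-image patient-id sequence the plan was
    built from; image index lists are derived from it on demand.
    """

    k: int
    cv_patient_groups: tuple[frozenset, ...]
    test_patients: frozenset
    image_patients: tuple = ()

    def _indices(self, patients: frozenset) -> np.ndarray:
        return np.array([i for i, p in enumerate(self.image_patients)
                         if p in patients], dtype=int)

    def fold_indices(self, fold: int) -> np.ndarray:
        """Image indices of one validation fold."""
        return self._indices(self.cv_patient_groups[fold])

    def train_indices(self, fold: int) -> np.ndarray:
        """Image indices of the other ``k - 1`` folds."""
        rest = frozenset().union(*(g for i, g in
                                   enumerate(self.cv_patient_groups) if i != fold))
        return self._indices(rest)

    @property
    def test_indices(self) -> np.ndarray:
        return self._indices(self.test_patients)


def make_fold_plan(image_patients, k: int, test_fraction: float = 0.1,
                   test_patients=None, seed: int = 0) -> FoldPlan:
    """Build a patient-grouped ``k``-fold plan with a fixed held-out test set.

    Parameters
    ----------
    image_patients
        Patient id of every image, in dataset order.
    k
        Number of CV folds.
    test_fraction
        Fraction of patients reserved for the fixed test set; ignored when
        ``test_patients`` is given explicitly.
    test_patients
        Explicit test-set patient ids (must exist in the dataset).
    seed
        Shuffling seed; plans are deterministic under it.

    Folds are balanced in patient count to within one patient; no patient
    appears in more than one partition.
    """
    image_patients = tuple(image_patients)
    unique = list(dict.fromkeys(image_patients))   # stable first-appearance order
    rng = np.random.default_rng(seed)
    order = [unique[i] for i in rng.permutation(len(unique))]
    if test_patients is None:
        n_test = int(round(test_fraction * len(unique)))
        test = frozenset(order[:n_test])
        pool = [p for p in order if p not in test]
    else:
        test = frozenset(test_patients)
        missing = test - set(unique)
        if missing:
            raise InvalidConfigError(f"unknown test patients: {sorted(missing)}")
        pool = [p for p in order if p not in test]
    if k < 1 or k > len(pool):
        raise InvalidConfigError(
            f"k={k} infeasible with {len(pool)} cross-validation patients")
    groups = [set() for _ in range(k)]
    for i, p in enumerate(pool):        # round-robin => sizes within 1
        groups[i % k].add(p)
    return FoldPlan(k=k, cv_patient_groups=tuple(frozenset(g) for g in groups),
                    test_patients=test, image_patients=image_patients)


# ---------------------------------------------------------------------------
# cross-validation harness


@dataclass
class CVSummary:
    """Per-fold metric reports plus mean/population-std aggregates."""

    per_fold: list[MetricsReport]
    matrices: list[ConfusionMatrix]
    mean: MetricsReport = None
    std: MetricsReport = None
    pooled: ConfusionMatrix = None
    logs: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: one row per fold plus mean and std rows."""
        rows = [{"fold": f"fold-{i + 1}", **r.as_dict()}
                for i, r in enumerate(self.per_fold)]
        rows.append({"fold": "mean", **self.mean.as_dict()})
        rows.append({"fold": "std", **self.std.as_dict()})
        return pd.DataFrame(rows)


def aggregate(reports) -> tuple[MetricsReport, MetricsReport]:
    """Per-metric arithmetic mean and population std (divisor ``k``)."""
    reports = list(reports)
    if not reports:
        raise InvalidInputError("no reports to aggregate")
    vals = {m: np.array([getattr(r, m) for r in reports]) for m in METRIC_NAMES}
    mean = MetricsReport(**{m: float(v.mean()) for m, v in vals.items()})
    std = MetricsReport(**{m: float(v.std(ddof=0)) for m, v in vals.items()})
    return mean, std


def _standardize(train: np.ndarray, *others):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return tuple((x - mu) / sd for x in (train, *others))


def run_crossval(features: np.ndarray, labels, patients, plan: FoldPlan,
                 config: elm.OELMConfig) -> CVSummary:
    """Train-from-scratch-per-fold cross-validation on a fixed test set.

    For fold ``i``: the head (fresh hidden layer, seeded per fold) trains
    on the other ``k - 1`` folds, early-stops on fold ``i``'s images, and
    is evaluated on the fixed test set. Features are standardized with the
    training fold's mean/std before entering the hidden layer.
    """
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    labels = list(labels)
    if plan.image_patients and len(plan.image_patients) != len(labels):
        raise InvalidInputError("plan does not cover the dataset")
    test_idx = plan.test_indices
    if test_idx.size == 0:
        raise InvalidConfigError("empty test set")
    T = one_hot(labels)
    per_fold, matrices, logs = [], [], []
    for fold in range(plan.k):
        tr, va = plan.train_indices(fold), plan.fold_indices(fold)
        if tr.size == 0:        # degenerate k=1 plan: no folds to rotate
            tr = va
        X_tr, X_va, X_te = _standardize(features[tr], features[va],
                                        features[test_idx])
        layer = elm.init_hidden(features.shape[1], config.L, config.activation,
                                seed=config.seed + fold)
        beta, log = elm.fit(X_tr, T[tr], layer, config, X_va, T[va])
        logs.append(log)
        pred, _ = elm.predict(X_te, layer, beta)
        cm = confusion_matrix([labels[i] for i in test_idx], pred)
        matrices.append(cm)
        per_fold.append(metrics_from_cm(cm))
    mean, std = aggregate(per_fold)
    pooled = matrices[0]
    for cm in matrices[1:]:
        pooled = pooled + cm
    return CVSummary(per_fold=per_fold, matrices=matrices, mean=mean,
                     std=std, pooled=pooled, logs=logs)


# ---------------------------------------------------------------------------
# threshold curves


@dataclass(frozen=True)
class CurveSet:
    """ROC and precision-recall curves with trapezoidal areas."""

    roc: np.ndarray          # (n, 2) columns fpr, tpr; (0,0) .. (1,1)
    pr: np.ndarray           # (n, 2) columns recall, precision
    roc_auc: float
    pr_auc: float


def roc_pr_curves(scores, y_true, positive: str = PES_PLANUS) -> CurveSet:
    """Threshold sweep over the distinct positive-class scores.

    Produces the ROC curve from (0, 0) to (1, 1), the precision-recall
    curve, and their trapezoidal areas. Both classes must be present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.array([t == positive for t in y_true])
    if scores.shape[0] != y.shape[0]:
        raise InvalidInputError("scores and labels differ in length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise InvalidInputError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    # cumulative counts after each sample; keep only the last index of each
    # distinct score (ties move together through the threshold sweep)
    tp_cum = np.cumsum(y_sorted)
    fp_cum = np.cumsum(~y_sorted)
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp = tp_cum[distinct]
    fp = fp_cum[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    roc = np.column_stack([fpr, tpr])
    roc_auc = float(np.trapezoid(tpr, fpr))
    with np.errstate(invalid="ignore"):
        precision = tp / (tp + fp)
    recall = tp / n_pos
    pr = np.column_stack([np.r_[0.0, recall], np.r_[precision[0], precision]])
    pr_auc = float(np.trapezoid(pr[:, 1], pr[:, 0]))
    return CurveSet(roc=roc, pr=pr, roc_auc=roc_auc, pr_auc=pr_auc)


def save_curves(curves: CurveSet, out_dir, plot: bool = True) -> None:
    """Export ROC/PR point lists as CSV and (optionally) a PNG figure."""
    from pathlib import Path
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(curves.roc, columns=["fpr", "tpr"]).to_csv(
        out_dir / "roc_curve.csv", index=False)
    pd.DataFrame(curves.pr, columns=["recall", "precision"]).to_csv(
        out_dir / "pr_curve.csv", index=False)
    if plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        ax1.plot(curves.roc[:, 0], curves.roc[:, 1])
        ax1.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
        ax1.set(xlabel="false positive rate", ylabel="true positive rate",
                title=f"ROC (AUC = {curves.roc_auc:.3f})")
        ax2.plot(curves.pr[:, 0], curves.pr[:, 1])
        ax2.set(xlabel="recall", ylabel="precision",
                title=f"Precision-Recall (AUC = {curves.pr_auc:.3f})")
        fig.tight_layout()
        fig.savefig(out_dir / "curves.png", dpi=120)
        plt.close(fig)
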