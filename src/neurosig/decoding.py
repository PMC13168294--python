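"""Linear whole-brain signatures: training, cross-validation, evaluation.

A signature is a linear support-vector decision rule over in-mask voxels,
trained on paired condition images (+1 target, -1 control; C-SVM with linear
kernel, no feature scaling).  Evaluation follows two paradigms: thresholded
classification of cross-validated decision values, and two-alternative
forced choice on pattern expressions (dot products) of within-subject image
pairs.  Binomial p-values use the exact one-sided tail at chance 0.5 as the
primary statistic, with the doubled tail reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from neurosig.volume_core import ValidationError

__all__ = [
    "SignatureModel",
    "ClassificationReport",
    "CVResult",
    "train_signature",
    "loso_cv",
    "threshold_report",
    "forced_choice",
    "exclude_voxels",
    "roc",
]


@dataclass
class SignatureModel:
    """Trained linear decoder: per-voxel weights, intercept, metadata."""

    weights: np.ndarray
    intercept: float
    trained_pair: str
    regularization: float = 1.0
    mask_fingerprint: str | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.intercept):
            raise ValidationError("signature weights/intercept must be finite")

    def decision(self, values: np.ndarray) -> float:
        return float(self.weights @ np.asarray(values, dtype=float) + self.intercept)

    def expression(self, values: np.ndarray) -> float:
        """Pattern expression: dot product without the intercept."""
        return float(self.weights @ np.asarray(values, dtype=float))

    def _check_mask(self, fingerprint: str | None) -> None:
        if (
            self.mask_fingerprint is not None
            and fingerprint is not None
            and fingerprint != self.mask_fingerprint
        ):
            raise ValidationError("mask fingerprint mismatch between model and data")


@dataclass
class ClassificationReport:
    """Accuracy/sensitivity/specificity bundle for one evaluation."""

    n_comparisons: int
    accuracy: float
    sensitivity: float
    specificity: float
    accuracy_sd: float
    ci_low: float
    ci_high: float
    effect_size: float
    p_value: float          # exact one-sided binomial tail, chance 0.5
    p_value_doubled: float  # doubled tail (capped at 1)

    def as_dict(self) -> dict:
        return {
            "n": self.n_comparisons,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "sd": self.accuracy_sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "effect_size": self.effect_size,
            "p": self.p_value,
            "p_doubled": self.p_value_doubled,
        }


@dataclass
class CVResult:
    """Held-out decision values per subject from leave-one-subject-out CV."""

    subject_ids: list[str]
    #: subject -> (decision value for target image, for control image)
    decisions: dict[str, tuple[float, float]]
    trained_pair: str
    #: subject -> (expression of target, expression of control)
    expressions: dict[str, tuple[float, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# training


def _stack_paired(paired: dict[str, tuple[np.ndarray, np.ndarray]]):
    sids = list(paired)
    X, y, groups = [], [], []
    for sid in sids:
        tgt, ctl = paired[sid]
        X.append(np.asarray(tgt, dtype=float))
        y.append(1)
        X.append(np.asarray(ctl, dtype=float))
        y.append(-1)
        groups.extend([sid, sid])
    return np.asarray(X), np.asarray(y), groups, sids


def train_signature(
    paired: dict[str, tuple[np.ndarray, np.ndarray]],
    pair: str,
    regularization: float = 1.0,
    mask_fingerprint: str | None = None,
) -> SignatureModel:
    """Fit the linear C-SVM on paired condition images (+1 target, -1 control).

    Minimizes ``0.5 ||w||^2 + C sum_i hinge(y_i (w.x_i + b))``; images enter
    unscaled.  Requires at least two subjects, each with both conditions.
    """
    if len(paired) < 2:
        raise ValidationError("training needs >= 2 subjects with both conditions")
    X, y, _, _ = _stack_paired(paired)
    if len(np.unique(y)) < 2:
        raise ValidationError("training data contain a single class")
    clf = SVC(kernel="linear", C=regularization, tol=1e-6)
    clf.fit(X, y)
    return SignatureModel(
        weights=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
        trained_pair=pair,
        regularization=regularization,
        mask_fingerprint=mask_fingerprint,
    )


def loso_cv(
    paired: dict[str, tuple[np.ndarray, np.ndarray]],
    pair: str,
    regularization: float = 1.0,
) -> CVResult:
    """Leave-one-subject-out CV: train on all other subjects, score both
    held-out images.  Training never sees the test subject's data."""
    sids = list(paired)
    if len(sids) < 3:
        raise ValidationError("LOSO requires >= 3 subjects")
    decisions: dict[str, tuple[float, float]] = {}
    expressions: dict[str, tuple[float, float]] = {}
    for sid in sids:
        train = {s: paired[s] for s in sids if s != sid}
        model = train_signature(train, pair, regularization)
        tgt, ctl = paired[sid]
        decisions[sid] = (model.decision(tgt), model.decision(ctl))
        expressions[sid] = (model.expression(tgt), model.expression(ctl))
    return CVResult(sids, decisions, pair, expressions)


# ---------------------------------------------------------------------------
# evaluation


def binomial_p(correct: int, n: int) -> tuple[float, float]:
    """Exact one-sided tail P(X >= correct | n, 0.5) and its doubled form."""
    p_one = float(stats.binom.sf(correct - 1, n, 0.5))
    return p_one, min(1.0, 2.0 * p_one)


def _bootstrap_accuracy_sd_ci(
    per_subject_correct: np.ndarray,
    per_subject_total: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Subject-level bootstrap of accuracy: SD and percentile 95% CI."""
    rng = np.random.default_rng(seed)
    n_sub = per_subject_correct.size
    idx = rng.integers(0, n_sub, size=(n_boot, n_sub))
    accs = per_subject_correct[idx].sum(axis=1) / per_subject_total[idx].sum(axis=1)
    return float(accs.std(ddof=1)), float(np.percentile(accs, 2.5)), float(
        np.percentile(accs, 97.5)
    )


def _effect_size_from_expressions(
    expressions: dict[str, tuple[float, float]]
) -> float:
    """Cohen's d of within-subject expression differences against zero."""
    if not expressions:
        return float("nan")
    deltas = np.array([t - c for t, c in expressions.values()])
    sd = deltas.std(ddof=1) if deltas.size > 1 else 0.0
    if sd == 0:
        return float("nan")
    return float(deltas.mean() / sd)


def threshold_report(
    cv: CVResult, threshold: float = 0.0, n_boot: int = 1000, seed: int = 0
) -> ClassificationReport:
    """Thresholded classification of held-out decision values.

    An image is classified +1 iff its decision value strictly exceeds the
    threshold (ties count as incorrect).  n = number of held-out images
    (two per subject); binomial p at chance 0.5; SD/CI by subject bootstrap.
    """
    if not cv.decisions:
        raise ValidationError("empty cross-validation result")
    sub_correct, sub_total = [], []
    tp = fn = tn = fp = 0
    for sid in cv.subject_ids:
        d_tgt, d_ctl = cv.decisions[sid]
        c_t = d_tgt > threshold
        c_c = d_ctl <= threshold
        tp += c_t
        fn += not c_t
        tn += c_c
        fp += not c_c
        sub_correct.append(int(c_t) + int(c_c))
        sub_total.append(2)
    n = 2 * len(cv.subject_ids)
    correct = tp + tn
    p_one, p_two = binomial_p(correct, n)
    sd, lo, hi = _bootstrap_accuracy_sd_ci(
        np.array(sub_correct, dtype=float), np.array(sub_total, dtype=float),
        n_boot=n_boot, seed=seed,
    )
    return ClassificationReport(
        n_comparisons=n,
        accuracy=correct / n,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy_sd=sd,
        ci_low=lo,
        ci_high=hi,
        effect_size=_effect_size_from_expressions(cv.expressions),
        p_value=p_one,
        p_value_doubled=p_two,
    )


def forced_choice(
    model: SignatureModel,
    paired: dict[str, tuple[np.ndarray, np.ndarray]],
    mask_fingerprint: str | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> ClassificationReport:
    """Two-alternative forced choice on pattern expressions.

    A subject is counted correct iff expression(target) strictly exceeds
    expression(control); the intercept cancels, so any constant added to both
    images of a pair leaves the choice unchanged.  n = number of subjects.
    """
    model._check_mask(mask_fingerprint)
    if not paired:
        raise ValidationError("no subjects to evaluate")
    expressions: dict[str, tuple[float, float]] = {}
    correct_flags = []
    for sid, (tgt, ctl) in paired.items():
        e_t, e_c = model.expression(tgt), model.expression(ctl)
        expressions[sid] = (e_t, e_c)
        correct_flags.append(e_t > e_c)
    flags = np.array(correct_flags, dtype=float)
    n = flags.size
    correct = int(flags.sum())
    p_one, p_two = binomial_p(correct, n)
    if n > 1:
        sd, lo, hi = _bootstrap_accuracy_sd_ci(
            flags, np.ones(n), n_boot=n_boot, seed=seed
        )
    else:
        sd, lo, hi = 0.0, flags.mean(), flags.mean()
    acc = correct / n
    return ClassificationReport(
        n_comparisons=n,
        accuracy=acc,
        sensitivity=acc,  # one forced choice per subject: single class
        specificity=acc,
        accuracy_sd=sd,
        ci_low=lo,
        ci_high=hi,
        effect_size=_effect_size_from_expressions(expressions),
        p_value=p_one,
        p_value_doubled=p_two,
    )


def forced_choice_from_cv(
    cv: CVResult, n_boot: int = 1000, seed: int = 0
) -> ClassificationReport:
    """Forced choice on the held-out LOSO expressions (no refitting).

    Uses each fold's cross-validated pattern expressions, so the report is
    out-of-sample — unlike applying a single model to its own training pairs,
    whose margins are optimistic.
    """
    if not cv.expressions:
        raise ValidationError("CV result carries no expressions")
    flags = np.array(
        [float(cv.expressions[s][0] > cv.expressions[s][1]) for s in cv.subject_ids]
    )
    n = flags.size
    correct = int(flags.sum())
    p_one, p_two = binomial_p(correct, n)
    sd, lo, hi = _bootstrap_accuracy_sd_ci(flags, np.ones(n), n_boot=n_boot, seed=seed)
    acc = correct / n
    return ClassificationReport(
        n_comparisons=n,
        accuracy=acc,
        sensitivity=acc,
        specificity=acc,
        accuracy_sd=sd,
        ci_low=lo,
        ci_high=hi,
        effect_size=_effect_size_from_expressions(cv.expressions),
        p_value=p_one,
        p_value_doubled=p_two,
    )


def exclude_voxels(model: SignatureModel, drop: np.ndarray) -> SignatureModel:
    """Zero the weights on dropped voxels (boolean vector over the mask).

    Pattern expressions become independent of the dropped voxels' values;
    used, e.g., to remove visual-network voxels before cross-modal transfer.
    """
    drop = np.asarray(drop, dtype=bool)
    if drop.shape != model.weights.shape:
        raise ValidationError("drop mask length must equal weight length")
    new_w = model.weights.copy()
    new_w[drop] = 0.0
    if not np.any(new_w):
        raise ValidationError("all weights dropped: degenerate model")
    return SignatureModel(
        weights=new_w,
        intercept=model.intercept,
        trained_pair=model.trained_pair,
        regularization=model.regularization,
        mask_fingerprint=model.mask_fingerprint,
    )


def roc(cv: CVResult) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR arrays) and AUC from held-out decision values."""
    scores, labels = [], []
    for sid in cv.subject_ids:
        d_tgt, d_ctl = cv.decisions[sid]
        scores.extend([d_tgt, d_ctl])
        labels.extend([1, 0])
    labels_arr = np.array(labels)
    if len(np.unique(labels_arr)) < 2:
        raise ValidationError("ROC needs both classes present")
    from sklearn.metrics import roc_curve, roc_auc_score

    fpr, tpr, _ = roc_curve(labels_arr, np.array(scores))
    auc = float(roc_auc_score(labels_arr, np.array(scores)))
    return fpr, tpr, auc
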