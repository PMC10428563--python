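"""Model evaluation and group statistics.

Covers the evaluation surface of the monitoring study: test accuracy per
feature combination, confusion matrix and specificity (VE is the positive
class, so specificity is the rate at which CE windows are not called VE),
ROC curve and AUC from the decision scores, learning curves with an
over/underfitting diagnosis, and the small-sample group comparisons (t-based
confidence intervals, Welch independent-samples t-test at the transition
hour, paired t-test between the transition hour and 24 h).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix, roc_curve

from .features import LabeledDataset
from .svm import ProtocolResult, SoftMarginLinearSVM

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "VE"  # ROC/specificity convention
NEGATIVE_LABEL = "CE"


def accuracy_percent(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Accuracy as a percentage (raw value; reports round to two decimals)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty test set")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred have different lengths")
    return 100.0 * float(np.mean(y_true == y_pred))


def model_accuracy(model: SoftMarginLinearSVM, X, y) -> float:
    return accuracy_percent(np.asarray(y), model.predict(X))


def confusion_and_specificity(
    model: SoftMarginLinearSVM, X, y
) -> tuple[np.ndarray, float]:
    """2x2 confusion matrix (rows: true CE, VE) and specificity TN/(TN+FP)."""
    y = np.asarray(y)
    pred = model.predict(X)
    cm = confusion_matrix(y, pred, labels=[NEGATIVE_LABEL, POSITIVE_LABEL])
    tn, fp = int(cm[0, 0]), int(cm[0, 1])
    if tn + fp == 0:
        raise ValueError("no CE rows in the test set; specificity is undefined")
    return cm, tn / (tn + fp)


def roc_auc(model: SoftMarginLinearSVM, X, y) -> tuple[list[tuple[float, float]], float]:
    """ROC by threshold sweep over decision scores and trapezoid-rule AUC."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("ROC requires both classes in the test set")
    scores = model.decision_function(X)
    fpr, tpr, _ = roc_curve(y, scores, pos_label=POSITIVE_LABEL)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_trapezoid_auc(fpr, tpr))


@dataclass(frozen=True)
class LearningCurvePoint:
    n_train: int
    train_error: float
    test_error: float


def learning_curve(
    dataset: LabeledDataset,
    c: float,
    sizes: list[int] | None = None,
    standardize: bool = False,
) -> list[LearningCurvePoint]:
    """Error rates vs training-set size.

    Refits at each size on the first ``n`` rows of the (already shuffled)
    training split and scores on the held-out test split.  Sizes that leave a
    single class in the subsample are skipped with a warning.
    """
    X_tr, y_tr = dataset.rows("train")
    X_te, y_te = dataset.rows("test")
    n_train = len(y_tr)
    if sizes is None:
        sizes = sorted(set(np.linspace(10, n_train, 8).astype(int).tolist()))
    points: list[LearningCurvePoint] = []
    for n in sizes:
        if n < 2 or n > n_train:
            warnings.warn(f"skipping learning-curve size {n} (train split has {n_train})")
            continue
        Xs, ys = X_tr[:n], y_tr[:n]
        if np.unique(ys).size < 2:
            warnings.warn(f"skipping learning-curve size {n}: single-class subsample")
            continue
        model = SoftMarginLinearSVM(C=c, standardize=standardize).fit(Xs, ys)
        points.append(LearningCurvePoint(
            n_train=int(n),
            train_error=1.0 - float(model.score(Xs, ys)),
            test_error=1.0 - float(model.score(X_te, y_te)),
        ))
    return points


def diagnose(
    curve: list[LearningCurvePoint],
    gap_threshold: float = 0.1,
    high_threshold: float = 0.2,
) -> str:
    """'overfit' | 'underfit' | 'ok' from the full-size end of the curve.

    Overfitting: the training error is much lower than the test error
    (gap > ``gap_threshold``).  Underfitting: both errors are high
    (> ``high_threshold``) and approximately equal.
    """
    if not curve:
        raise ValueError("empty learning curve")
    last = curve[-1]
    gap = last.test_error - last.train_error
    if gap > gap_threshold:
        return "overfit"
    if (last.train_error > high_threshold and last.test_error > high_threshold
            and abs(gap) <= gap_threshold):
        return "underfit"
    return "ok"


@dataclass
class EvalReport:
    """Serializable evaluation record for one feature combination."""

    combination: str
    c: float
    random_state: int
    test_accuracy_percent: float
    confusion: list[list[int]]
    specificity: float
    roc: list[tuple[float, float]]
    auc: float
    learning_curve: list[LearningCurvePoint]
    diagnosis: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"AUC {self.auc} outside [0, 1]")
        for p in self.learning_curve:
            if not (0.0 <= p.train_error <= 1.0 and 0.0 <= p.test_error <= 1.0):
                raise ValueError("error rates must lie in [0, 1]")

    @property
    def test_accuracy_rounded(self) -> float:
        return round(self.test_accuracy_percent, 2)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["test_accuracy_rounded"] = self.test_accuracy_rounded
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        d = dict(d)
        d.pop("test_accuracy_rounded", None)
        d["roc"] = [tuple(p) for p in d["roc"]]
        d["learning_curve"] = [LearningCurvePoint(**p) for p in d["learning_curve"]]
        d["confusion"] = [[int(v) for v in row] for row in d["confusion"]]
        return cls(**d)

    @classmethod
    def from_json(cls, source: str | Path) -> "EvalReport":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


def evaluate_model(result: ProtocolResult, sizes: list[int] | None = None,
                   standardize: bool = False) -> EvalReport:
    """Score the finalized model on the untouched test split."""
    X_te, y_te = result.dataset.rows("test")
    acc = model_accuracy(result.model, X_te, y_te)
    cm, spec = confusion_and_specificity(result.model, X_te, y_te)
    roc, auc_value = roc_auc(result.model, X_te, y_te)
    curve = learning_curve(result.dataset, result.c_star, sizes=sizes,
                           standardize=standardize)
    return EvalReport(
        combination=result.combination,
        c=result.c_star,
        random_state=result.state_star,
        test_accuracy_percent=acc,
        confusion=cm.tolist(),
        specificity=float(spec),
        roc=roc,
        auc=auc_value,
        learning_curve=curve,
        diagnosis=diagnose(curve),
    )


@dataclass(frozen=True)
class GroupStats:
    """One hypothesis test with its associated confidence interval."""

    comparison: str  # 'independent_6h' or 'paired_6h_vs_24h'
    ci_low: float
    ci_high: float
    t_stat: float
    p_value: float

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class GroupStatsReport:
    independent: GroupStats
    paired: GroupStats
    ci_control_eta: tuple[float, float]
    ci_experimental_eta: tuple[float, float]
    ci_experimental_24h: tuple[float, float]
    ci_paired_diff: tuple[float, float]
    confidence: float


def t_interval(x: np.ndarray, confidence: float = 0.95) -> tuple[float, float]:
    """Two-sided t confidence interval of the mean."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations for a confidence interval")
    lo, hi = stats.t.interval(confidence, df=x.size - 1, loc=x.mean(),
                              scale=stats.sem(x))
    return float(lo), float(hi)


def group_stats(
    experimental_mpfb_at_eta,
    control_mpfb_at_eta,
    experimental_mpfb_at_24h,
    confidence: float = 0.95,
    welch: bool = True,
) -> GroupStatsReport:
    """Group comparisons at the transition hour and at 24 h.

    Welch's independent-samples t-test (unequal group sizes and variances) is
    the default; set ``welch=False`` for the pooled-variance test.  The
    paired test compares the experimental group's MPFB at the transition hour
    against 24 h; a zero-variance nonzero-mean difference vector is rejected
    explicitly rather than yielding a degenerate p-value.
    """
    exp_eta = np.asarray(experimental_mpfb_at_eta, dtype=float)
    ctrl_eta = np.asarray(control_mpfb_at_eta, dtype=float)
    exp_24 = np.asarray(experimental_mpfb_at_24h, dtype=float)
    for name, arr in (("experimental", exp_eta), ("control", ctrl_eta),
                      ("experimental 24 h", exp_24)):
        if arr.size < 2:
            raise ValueError(f"{name} group needs at least 2 subjects")
    if exp_eta.size != exp_24.size:
        raise ValueError("paired comparison requires equal lengths")

    t_ind, p_ind = stats.ttest_ind(exp_eta, ctrl_eta, equal_var=not welch)

    diff = exp_eta - exp_24
    if np.std(diff, ddof=1) == 0.0:
        if np.all(diff == 0.0):
            t_rel, p_rel = 0.0, 1.0
        else:
            raise ValueError(
                "paired differences have zero variance with a nonzero mean; "
                "the paired t statistic is undefined for these data"
            )
    else:
        t_rel, p_rel = stats.ttest_rel(exp_eta, exp_24)

    ci_exp = t_interval(exp_eta, confidence)
    ci_diff = (t_interval(diff, confidence) if np.std(diff, ddof=1) > 0
               else (float(diff.mean()), float(diff.mean())))
    return GroupStatsReport(
        independent=GroupStats("independent_6h", ci_exp[0], ci_exp[1],
                               float(t_ind), float(p_ind)),
        paired=GroupStats("paired_6h_vs_24h", ci_diff[0], ci_diff[1],
                          float(t_rel), float(p_rel)),
        ci_control_eta=t_interval(ctrl_eta, confidence),
        ci_experimental_eta=ci_exp,
        ci_experimental_24h=t_interval(exp_24, confidence),
        ci_paired_diff=ci_diff,
        confidence=confidence,
    )
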