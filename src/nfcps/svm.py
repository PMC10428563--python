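"""Soft-margin linear SVM and the full edema-type training protocol.

The classifier solves the standard soft-margin primal

    min_{w, b, xi}  1/2 ||w||^2 + C sum_i xi_i
    s.t.  y_i (w^T x_i + b) >= 1 - xi_i,  xi_i >= 0

with a linear kernel, labels encoded CE = -1, VE = +1.  The fitted model
exposes the dual multipliers lambda_i (one per training row), which satisfy
the KKT/dual-feasibility invariants 0 <= lambda_i <= C, sum_i lambda_i y_i = 0
and w = sum_i lambda_i y_i x_i to tight tolerance.

The training protocol is: pick the penalty C from the grid 0.1, 0.2, ..., 10.0
(100 values) by the highest mean tenfold cross-validated accuracy on the
training split, ties resolved toward the smallest C; evaluate random states
1..5 (seeds of the 6:2:2 shuffle) on their validation splits and keep the
state whose validation accuracy is the median of the five; refit on the
union of training and validation rows.  The test split is never touched
before final scoring.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import LabeledDataset, build_dataset, normalize_combination

logger = logging.getLogger(__name__)

#: Penalty grid: 0.1 increments, 100 values.
DEFAULT_C_GRID = tuple(np.round(np.arange(1, 101) * 0.1, 10))
DEFAULT_STATES = (1, 2, 3, 4, 5)

_KKT_TOL = 1e-6


class SoftMarginLinearSVM(ClassifierMixin, BaseEstimator):
    """Binary soft-margin linear SVM with exposed dual multipliers.

    Parameters
    ----------
    C : float
        Penalty factor of the soft margin (> 0).
    standardize : bool
        If True, features are centred/scaled using training-set statistics
        only.  Off by default: the window features are all degrees on
        comparable scales.
    tol : float
        Solver stopping tolerance (kept tight so the KKT residual checks at
        1e-6 hold).

    Attributes (after fit)
    ----------------------
    classes_ : ndarray, the two class labels (negative class first).
    coef_ : ndarray (n_features,), primal weights w.
    intercept_ : float, bias b.
    dual_multipliers_ : ndarray (n_samples,), lambda_i for every training row.
    """

    def __init__(self, C: float = 1.0, standardize: bool = False,
                 tol: float = 1e-8, max_iter: int = -1):
        self.C = C
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y) -> "SoftMarginLinearSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D array of shape (n_samples, n_features)")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent numbers of rows")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if not self.C > 0:
            raise ValueError(f"C must be > 0, got {self.C}")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(
                f"exactly two classes are required, got {classes.tolist()}"
            )
        self.classes_ = classes  # sorted; 'CE' < 'VE' maps CE -> -1, VE -> +1
        y_signed = np.where(y == classes[1], 1.0, -1.0)

        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0] = 1.0
            self.scale_ = scale
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Xs = (X - self.mean_) / self.scale_

        svc = SVC(C=self.C, kernel="linear", tol=self.tol, max_iter=self.max_iter)
        svc.fit(Xs, y_signed)
        if self.max_iter != -1 and svc.fit_status_ != 0:
            raise RuntimeError(
                f"SVM solver did not converge within {self.max_iter} iterations"
            )
        self.coef_ = svc.coef_[0].astype(float).copy()
        self.intercept_ = float(svc.intercept_[0])
        lam = np.zeros(X.shape[0])
        lam[svc.support_] = svc.dual_coef_[0] * y_signed[svc.support_]
        self.dual_multipliers_ = lam
        self.support_ = svc.support_.copy()
        self.n_features_in_ = X.shape[1]
        self._y_signed = y_signed
        self._X_scaled = Xs
        self._check_kkt(Xs, y_signed)
        return self

    def _check_kkt(self, Xs: np.ndarray, y_signed: np.ndarray) -> None:
        lam = self.dual_multipliers_
        if np.any(lam < -_KKT_TOL) or np.any(lam > self.C + _KKT_TOL):
            raise RuntimeError("dual multipliers violate the box constraint [0, C]")
        balance = float(np.dot(lam, y_signed))
        if abs(balance) > _KKT_TOL * max(1.0, self.C):
            raise RuntimeError(
                f"dual equality constraint violated: sum(lambda*y) = {balance:.3e}"
            )
        w = (lam * y_signed) @ Xs
        if not np.allclose(w, self.coef_, atol=_KKT_TOL):
            raise RuntimeError("primal weights do not match sum(lambda*y*x)")

    # -- inference ---------------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} feature(s), got shape {X.shape}"
            )
        Xs = (X - self.mean_) / self.scale_
        return Xs @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        n_ties = int(np.sum(scores == 0.0))
        if n_ties:
            logger.debug("%d sample(s) exactly on the boundary; assigned to %s",
                         n_ties, self.classes_[1])
        # score >= 0 -> positive class (VE); exact ties go to VE by convention
        return np.where(scores >= 0, self.classes_[1], self.classes_[0])

    # -- bookkeeping -------------------------------------------------------
    def primal_objective(self) -> float:
        """1/2 ||w||^2 + C sum(xi) at the fitted solution."""
        margins = self._y_signed * (self._X_scaled @ self.coef_ + self.intercept_)
        xi = np.maximum(0.0, 1.0 - margins)
        return 0.5 * float(self.coef_ @ self.coef_) + self.C * float(xi.sum())

    def dual_objective(self) -> float:
        """sum(lambda) - 1/2 sum_ij lambda_i lambda_j y_i y_j x_i.x_j."""
        lam_y = self.dual_multipliers_ * self._y_signed
        w = lam_y @ self._X_scaled
        return float(self.dual_multipliers_.sum()) - 0.5 * float(w @ w)

    def to_dict(self) -> dict:
        return {
            "format": "nfcps-linear-svm/1",
            "C": self.C,
            "standardize": self.standardize,
            "classes": [str(c) for c in self.classes_],
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
            "dual_multipliers": self.dual_multipliers_.tolist(),
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "meta": getattr(self, "meta_", {}),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "SoftMarginLinearSVM":
        if d.get("format") != "nfcps-linear-svm/1":
            raise ValueError(f"unrecognised model format {d.get('format')!r}")
        model = cls(C=d["C"], standardize=d["standardize"])
        model.classes_ = np.asarray(d["classes"])
        model.coef_ = np.asarray(d["coef"], dtype=float)
        model.intercept_ = float(d["intercept"])
        model.dual_multipliers_ = np.asarray(d["dual_multipliers"], dtype=float)
        model.mean_ = np.asarray(d["mean"], dtype=float)
        model.scale_ = np.asarray(d["scale"], dtype=float)
        model.n_features_in_ = model.coef_.size
        model.meta_ = d.get("meta", {})
        return model

    @classmethod
    def load(cls, path: str | Path) -> "SoftMarginLinearSVM":
        return cls.from_dict(json.loads(Path(path).read_text()))


def tune_c(
    X: np.ndarray,
    y: np.ndarray,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    folds: int = 10,
    fold_seed: int = 0,
    standardize: bool = False,
) -> float:
    """Smallest C from the grid attaining the highest mean CV accuracy.

    Folds are stratified by class and fixed by ``fold_seed``; if a class has
    fewer members than ``folds``, the fold count is reduced with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.size != 2:
        raise ValueError("tune_c requires both classes in the training rows")
    folds_eff = int(min(folds, counts.min()))
    if folds_eff < folds:
        logger.warning("reducing CV folds from %d to %d (smallest class has %d rows)",
                       folds, folds_eff, counts.min())
    if folds_eff < 2:
        raise ValueError("need at least 2 rows per class for cross-validation")

    skf = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=fold_seed)
    splits = list(skf.split(X, y))
    best_c, best_acc = None, -np.inf
    for c in c_grid:
        accs = []
        for tr, va in splits:
            model = SoftMarginLinearSVM(C=float(c), standardize=standardize)
            model.fit(X[tr], y[tr])
            accs.append(model.score(X[va], y[va]))
        mean_acc = float(np.mean(accs))
        if mean_acc > best_acc + 1e-12:  # strict improvement; ties keep lowest C
            best_acc, best_c = mean_acc, float(c)
    return best_c


def pick_median_state(accuracies: dict[int, float]) -> int:
    """State whose accuracy equals the median; ties go to the lowest index."""
    values = np.asarray(list(accuracies.values()), dtype=float)
    med = float(np.median(values))
    attaining = [s for s in sorted(accuracies) if np.isclose(accuracies[s], med)]
    if attaining:
        return attaining[0]
    # even counts can put the median between values; take the closest, lowest index
    return min(sorted(accuracies), key=lambda s: (abs(accuracies[s] - med), s))


def select_random_state(
    features,
    combination: str,
    c: float,
    states: Sequence[int] = DEFAULT_STATES,
    split_ratio: tuple[int, int, int] = (6, 2, 2),
    standardize: bool = False,
) -> tuple[int, dict[int, float]]:
    """Median-validation-accuracy selection of the shuffle seed.

    For each candidate state the 6:2:2 split is drawn, the model fitted on
    the training rows with the tuned C and scored on the validation rows;
    the state with the median of the accuracies wins (ties -> lowest state).
    """
    accuracies: dict[int, float] = {}
    for state in states:
        ds = build_dataset(features, combination, random_state=state,
                           split_ratio=split_ratio)
        model = SoftMarginLinearSVM(C=c, standardize=standardize)
        model.fit(*ds.rows("train"))
        accuracies[state] = float(model.score(*ds.rows("validation")))
    return pick_median_state(accuracies), accuracies


def finalize(dataset: LabeledDataset, c: float,
             standardize: bool = False) -> SoftMarginLinearSVM:
    """Final fit on the union of training and validation rows."""
    model = SoftMarginLinearSVM(C=c, standardize=standardize)
    model.fit(*dataset.rows("train", "validation"))
    model.meta_ = {
        "combination": dataset.combination,
        "random_state": dataset.random_state,
        "split_ratio": list(dataset.split_ratio),
        "C": c,
    }
    return model


@dataclass
class ProtocolResult:
    """Everything the training protocol produced for one feature combination."""

    combination: str
    model: SoftMarginLinearSVM
    c_star: float
    state_star: int
    validation_accuracies: dict[int, float]
    dataset: LabeledDataset
    folds: int = 10


def run_protocol(
    features,
    combination: str,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    folds: int = 10,
    states: Sequence[int] = DEFAULT_STATES,
    split_ratio: tuple[int, int, int] = (6, 2, 2),
    fold_seed: int = 0,
    standardize: bool = False,
) -> ProtocolResult:
    """Full training protocol for one feature combination.

    C is tuned by tenfold CV on the training split of the first candidate
    state; the shuffle state is then chosen by median validation accuracy and
    the model refit on train + validation of the chosen split.
    """
    combination = normalize_combination(combination)
    ds0 = build_dataset(features, combination, random_state=states[0],
                        split_ratio=split_ratio)
    X_tr, y_tr = ds0.rows("train")
    c_star = tune_c(X_tr, y_tr, c_grid=c_grid, folds=folds, fold_seed=fold_seed,
                    standardize=standardize)
    state_star, val_accs = select_random_state(
        features, combination, c_star, states=states, split_ratio=split_ratio,
        standardize=standardize,
    )
    dataset = build_dataset(features, combination, random_state=state_star,
                            split_ratio=split_ratio)
    model = finalize(dataset, c_star, standardize=standardize)
    logger.info("protocol[%s]: C* = %.1f, state* = %d (val acc %s)",
                combination, c_star, state_star,
                {k: round(v, 4) for k, v in val_accs.items()})
    return ProtocolResult(
        combination=combination, model=model, c_star=c_star,
        state_star=state_star, validation_accuracies=val_accs,
        dataset=dataset, folds=folds,
    )
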