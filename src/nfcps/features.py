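"""Sliding-window features over MPFB series and labeled dataset assembly.

For a window starting at hour t0 (with t1 = t0 + 1, t2 = t0 + 2):

    alpha = MPFB(t0)                       current level
    beta  = MPFB(t1) - MPFB(t0)            1-h change
    gamma = MPFB(t2) - MPFB(t1)            second-hour change
    delta = (MPFB(t2) - MPFB(t0)) / 2      2-h change rate (degrees/hour)

gamma at t0 is identically beta at t0 + 1 (the distribution of gamma is that
of beta shifted by one hour).  Windows from experimental subjects are labeled
CE before the subject's transition time and VE from it onward; control
subjects have no transition and are excluded from classification datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .processing import MpfbSeries

LABELS = ("CE", "VE")

#: Feature columns per named combination.
COMBINATIONS: dict[str, tuple[str, ...]] = {
    "a": ("alpha",),
    "b": ("beta",),
    "ab": ("alpha", "beta"),
    "ad": ("alpha", "delta"),
    "abg": ("alpha", "beta", "gamma"),
}

_COMBINATION_ALIASES = {
    "a": "a", "alpha": "a", "α": "a",
    "b": "b", "beta": "b", "β": "b",
    "ab": "ab", "alphabeta": "ab", "αβ": "ab", "alpha-beta": "ab",
    "ad": "ad", "alphadelta": "ad", "αδ": "ad", "alpha-delta": "ad",
    "abg": "abg", "alphabetagamma": "abg", "αβγ": "abg", "alpha-beta-gamma": "abg",
}

#: Window starts pooled into datasets: t0 = 0..22 so that all four features
#: (needing up to t0 + 2) are defined at every row; 8 experimental subjects
#: then contribute 8 x 23 = 184 rows.
DATASET_WINDOW_STARTS = tuple(range(0, 23))


def normalize_combination(name: str) -> str:
    key = str(name).strip().lower().replace("_", "").replace(" ", "")
    try:
        return _COMBINATION_ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unknown feature combination {name!r}; expected one of "
            f"{sorted(COMBINATIONS)} (or alpha/beta/... aliases)"
        ) from None


def features_1h(series: MpfbSeries, t0_h: float) -> tuple[float, float]:
    """(alpha, beta) for the 1-h window starting at ``t0_h``."""
    alpha = series.value_at(t0_h)
    beta = series.value_at(t0_h + 1) - alpha
    return alpha, beta


def features_2h(series: MpfbSeries, t0_h: float) -> tuple[float, float, float]:
    """(alpha, gamma, delta) for the 2-h window starting at ``t0_h``."""
    alpha = series.value_at(t0_h)
    a1 = series.value_at(t0_h + 1)
    a2 = series.value_at(t0_h + 2)
    return alpha, a2 - a1, (a2 - alpha) / 2.0


def label_window(eta_h: float | None, t0_h: float) -> str:
    """CE if the window starts before the transition time, VE from it onward."""
    if eta_h is None or (isinstance(eta_h, float) and np.isnan(eta_h)):
        raise ValueError(
            "control subjects have no CE/VE transition and are excluded from "
            "classification datasets"
        )
    return "CE" if t0_h < eta_h else "VE"


def window_features(
    series: Iterable[MpfbSeries],
    transition_hours: Mapping[str, float],
    window_starts: Iterable[int] = DATASET_WINDOW_STARTS,
) -> pd.DataFrame:
    """Pooled window-feature table for experimental subjects.

    ``transition_hours`` maps subject_id to the transition time used for
    labeling (the hour of the subject's MPFB nadir at the 1-h sampling
    resolution).  Columns: subject_id, t0_h, alpha..delta, label.
    """
    rows = []
    for s in series:
        if s.group != "experimental":
            continue
        if s.subject_id not in transition_hours:
            raise ValueError(f"no transition hour given for subject {s.subject_id}")
        eta = float(transition_hours[s.subject_id])
        for t0 in window_starts:
            alpha, beta = features_1h(s, t0)
            _, gamma, delta = features_2h(s, t0)
            rows.append({
                "subject_id": s.subject_id,
                "t0_h": int(t0),
                "alpha": alpha,
                "beta": beta,
                "gamma": gamma,
                "delta": delta,
                "label": label_window(eta, t0),
            })
    if not rows:
        raise ValueError("no experimental subjects found")
    return pd.DataFrame(rows)


SPLITS = ("train", "validation", "test")


@dataclass
class LabeledDataset:
    """Feature matrix of one combination with labels and split assignments.

    ``frame`` holds rows in shuffle order (deterministic in ``random_state``)
    with the selected feature columns plus 'label' and 'split'.
    """

    combination: str
    frame: pd.DataFrame
    random_state: int
    split_ratio: tuple[int, int, int]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return COMBINATIONS[self.combination]

    def rows(self, *splits: str) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) for the union of the requested splits, in shuffle order."""
        for s in splits:
            if s not in SPLITS:
                raise ValueError(f"unknown split {s!r}; expected one of {SPLITS}")
        sel = self.frame[self.frame["split"].isin(splits)]
        X = sel[list(self.feature_names)].to_numpy(dtype=float)
        y = sel["label"].to_numpy()
        return X, y

    def n_rows(self, split: str) -> int:
        return int((self.frame["split"] == split).sum())


def build_dataset(
    features: pd.DataFrame,
    combination: str,
    random_state: int,
    split_ratio: tuple[int, int, int] = (6, 2, 2),
) -> LabeledDataset:
    """Shuffle rows and assign train/validation/test splits (default 6:2:2).

    Validation and test sizes are the floor of their proportions; the
    remainder goes to the training split.  The shuffle is deterministic in
    ``random_state`` (this seed realises the protocol's "random state").
    """
    comb = normalize_combination(combination)
    cols = COMBINATIONS[comb]
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks column(s) {missing}")
    if "label" not in features.columns:
        raise ValueError("feature table lacks a 'label' column")
    bad = set(features["label"].unique()) - set(LABELS)
    if bad:
        raise ValueError(f"unknown label value(s) {sorted(bad)}; expected {LABELS}")

    n = len(features)
    total = sum(split_ratio)
    n_val = int(np.floor(n * split_ratio[1] / total))
    n_test = int(np.floor(n * split_ratio[2] / total))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) <= 0:
        raise ValueError(f"dataset of {n} rows is too small for a {split_ratio} split")

    perm = np.random.default_rng(random_state).permutation(n)
    frame = features.iloc[perm].reset_index(drop=True)
    split = np.empty(n, dtype=object)
    split[:n_train] = "train"
    split[n_train:n_train + n_val] = "validation"
    split[n_train + n_val:] = "test"
    keep = [c for c in ("subject_id", "t0_h") if c in frame.columns]
    frame = frame[keep + list(cols) + ["label"]].copy()
    frame["split"] = split
    return LabeledDataset(
        combination=comb, frame=frame, random_state=int(random_state),
        split_ratio=tuple(split_ratio),
    )
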