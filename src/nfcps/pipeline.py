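"""End-to-end conveniences tying the pipeline stages together."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import EvalReport, evaluate_model
from .features import window_features
from .processing import MpfbSeries, group_mean_curve, process_cohort
from .simulate import Cohort, CohortConfig, generate_cohort, transition_hour
from .svm import DEFAULT_C_GRID, DEFAULT_STATES, ProtocolResult, run_protocol


def cohort_mpfb(config: CohortConfig | None, master_seed: int) -> tuple[Cohort, list[MpfbSeries]]:
    """Generate a cohort and run cancellation -> offset -> MPFB."""
    cohort = generate_cohort(config, master_seed)
    series = process_cohort(cohort.sweeps, cohort.config.grid, cohort.config.band_mhz)
    return cohort, series


def transition_hours(cohort: Cohort) -> dict[str, int]:
    """Labeling transition hour per experimental subject (hourly nadir)."""
    return {
        p.subject_id: transition_hour(
            p,
            recovery_fast_hours=cohort.config.recovery_fast_hours,
            recovery_fast_weight=cohort.config.recovery_fast_weight,
        )
        for p in cohort.subject_params
        if p.group == "experimental"
    }


def cohort_features(config: CohortConfig | None, master_seed: int) -> pd.DataFrame:
    """Pooled labeled window-feature table for one synthetic cohort."""
    cohort, series = cohort_mpfb(config, master_seed)
    return window_features(series, transition_hours(cohort))


def experimental_mean_curve(
    config: CohortConfig | None, master_seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Group-mean experimental MPFB trajectory of one cohort."""
    _, series = cohort_mpfb(config, master_seed)
    return group_mean_curve(series, "experimental")


@dataclass
class ReplicateOutcome:
    """Protocol result + evaluation for one cohort replicate and combination."""

    seed: int
    combination: str
    result: ProtocolResult
    report: EvalReport


def run_replicate(
    config: CohortConfig | None,
    master_seed: int,
    combination: str,
    fold_seed: int | None = None,
    folds: int = 10,
    states=DEFAULT_STATES,
    c_grid=DEFAULT_C_GRID,
) -> ReplicateOutcome:
    """Cohort generation through evaluated model for one seed/combination."""
    features = cohort_features(config, master_seed)
    result = run_protocol(
        features, combination, c_grid=c_grid, folds=folds, states=states,
        fold_seed=master_seed if fold_seed is None else fold_seed,
    )
    report = evaluate_model(result)
    return ReplicateOutcome(seed=master_seed, combination=result.combination,
                            result=result, report=report)
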