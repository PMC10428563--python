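"""Raw sweep processing: symmetric cancellation, time-difference offset, MPFB.

The processing chain per subject and hour is

    cancelled(t) = lesion(t) - healthy(t)            (symmetric cancellation)
    offset(t)    = cancelled(t) - cancelled(-1 h)    (time-difference offset)
    MPFB(t)      = mean of offset(t) over 83-87 MHz  (mean phase in feature band)

Both stages are element-wise subtractions, so cancelling before offsetting is
exactly equivalent to offsetting each hemisphere first and cancelling after.
The sign convention is lesion minus healthy, which makes the cytotoxic-edema
stage appear as a negative MPFB deviation.  No phase unwrapping or filtering
is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import (
    ALL_TIMES_H,
    FEATURE_BAND_MHZ,
    HEMISPHERES,
    MONITORING_TIMES_H,
    FrequencyGrid,
    PhaseSweep,
    grid_from_sweep_table,
)


@dataclass(frozen=True)
class MpfbSeries:
    """Per-subject hourly MPFB values after cancellation and offset."""

    subject_id: str
    group: str
    times_h: np.ndarray
    mpfb_deg: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times_h, dtype=float)
        vals = np.asarray(self.mpfb_deg, dtype=float)
        object.__setattr__(self, "times_h", times)
        object.__setattr__(self, "mpfb_deg", vals)
        if times.shape != vals.shape:
            raise ValueError("times_h and mpfb_deg must have the same length")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("times_h must be strictly increasing")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(vals))):
            raise ValueError("MPFB series must be finite")

    def value_at(self, t_h: float) -> float:
        idx = np.flatnonzero(self.times_h == t_h)
        if idx.size == 0:
            raise KeyError(
                f"subject {self.subject_id}: no MPFB value at t = {t_h} h"
            )
        return float(self.mpfb_deg[idx[0]])


def symmetric_cancellation(lesion: PhaseSweep, healthy: PhaseSweep) -> np.ndarray:
    """Element-wise lesion minus healthy phase for one subject and time."""
    if lesion.subject_id != healthy.subject_id:
        raise ValueError(
            f"subject mismatch: {lesion.subject_id!r} vs {healthy.subject_id!r}"
        )
    if lesion.time_h != healthy.time_h:
        raise ValueError(
            f"time mismatch for subject {lesion.subject_id}: "
            f"{lesion.time_h} h vs {healthy.time_h} h"
        )
    if lesion.phase_deg.shape != healthy.phase_deg.shape:
        raise ValueError("sweeps lie on different frequency grids")
    return lesion.phase_deg - healthy.phase_deg


def time_difference_offset(
    cancelled_t: np.ndarray, cancelled_reference: np.ndarray
) -> np.ndarray:
    """Element-wise subtraction of the pre-modeling reference sweep."""
    a = np.asarray(cancelled_t, dtype=float)
    b = np.asarray(cancelled_reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return a - b


def mpfb(
    offset_sweep: np.ndarray,
    grid: FrequencyGrid,
    band: tuple[float, float] = FEATURE_BAND_MHZ,
) -> float:
    """Mean phase in the feature band (arithmetic mean over band grid points).

    With the default 70-90 MHz / 201-point grid and 83-87 MHz band this
    averages 41 points (83.0, 83.1, ..., 87.0).
    """
    values = np.asarray(offset_sweep, dtype=float)
    if values.shape != (grid.n_points,):
        raise ValueError(
            f"sweep length {values.shape} does not match grid ({grid.n_points},)"
        )
    mask = grid.band_mask(band)
    if not mask.any():
        raise ValueError(f"no grid points inside band {band} MHz")
    return float(values[mask].mean())


def _subject_matrix(
    sub: pd.DataFrame, subject_id: str, hemisphere: str, n_points: int
) -> np.ndarray:
    """(n_times, n_points) phase matrix for one hemisphere, times in ALL_TIMES_H order."""
    hemi = sub[sub["hemisphere"] == hemisphere]
    counts = hemi.groupby("time_h").size()
    for t in ALL_TIMES_H:
        n = int(counts.get(t, 0))
        if n != n_points:
            raise ValueError(
                f"subject {subject_id}: {hemisphere} hemisphere has "
                f"{n} points at t = {t} h, expected {n_points}"
            )
    extra = set(counts.index) - set(ALL_TIMES_H)
    if extra:
        raise ValueError(
            f"subject {subject_id}: {hemisphere} hemisphere has sweeps at "
            f"unexpected time(s) {sorted(extra)}"
        )
    ordered = hemi.sort_values(["time_h", "freq_mhz"], kind="mergesort")
    return ordered["phase_deg"].to_numpy().reshape(len(ALL_TIMES_H), n_points)


def process_cohort(
    sweeps: pd.DataFrame,
    grid: FrequencyGrid | None = None,
    band: tuple[float, float] = FEATURE_BAND_MHZ,
) -> list[MpfbSeries]:
    """Cancellation -> offset -> MPFB for every subject in a sweep table.

    The reference used in the offset stage is the cancelled baseline (-1 h)
    sweep; by element-wise linearity this equals per-hemisphere offsetting
    followed by cancellation.
    """
    if grid is None:
        grid = grid_from_sweep_table(sweeps)
    mask = grid.band_mask(band)
    out: list[MpfbSeries] = []
    for subject_id, sub in sweeps.groupby("subject_id", sort=True):
        missing = set(HEMISPHERES) - set(sub["hemisphere"].unique())
        if missing:
            raise ValueError(
                f"subject {subject_id}: missing hemisphere(s) {sorted(missing)}"
            )
        lesion = _subject_matrix(sub, subject_id, "lesion", grid.n_points)
        healthy = _subject_matrix(sub, subject_id, "healthy", grid.n_points)
        cancelled = lesion - healthy
        offset = cancelled[1:] - cancelled[0]  # row 0 is the -1 h reference
        values = offset[:, mask].mean(axis=1)
        group = str(sub["group"].iloc[0])
        out.append(MpfbSeries(
            subject_id=str(subject_id),
            group=group,
            times_h=np.asarray(MONITORING_TIMES_H, dtype=float),
            mpfb_deg=values,
        ))
    return out


def mpfb_table(series: list[MpfbSeries]) -> pd.DataFrame:
    """Long-format MPFB table: subject_id, group, time_h, mpfb_deg."""
    frames = [
        pd.DataFrame({
            "subject_id": s.subject_id,
            "group": s.group,
            "time_h": s.times_h.astype(int),
            "mpfb_deg": s.mpfb_deg,
        })
        for s in series
    ]
    return pd.concat(frames, ignore_index=True)


def series_from_table(table: pd.DataFrame) -> list[MpfbSeries]:
    """Inverse of :func:`mpfb_table`."""
    out = []
    for subject_id, sub in table.groupby("subject_id", sort=True):
        sub = sub.sort_values("time_h")
        out.append(MpfbSeries(
            subject_id=str(subject_id),
            group=str(sub["group"].iloc[0]),
            times_h=sub["time_h"].to_numpy(dtype=float),
            mpfb_deg=sub["mpfb_deg"].to_numpy(dtype=float),
        ))
    return out


def group_mean_curve(series: list[MpfbSeries], group: str) -> tuple[np.ndarray, np.ndarray]:
    """Group-mean MPFB trajectory (times, mean values) for one group."""
    members = [s for s in series if s.group == group]
    if not members:
        raise ValueError(f"no subjects in group {group!r}")
    times = members[0].times_h
    for s in members[1:]:
        if not np.array_equal(s.times_h, times):
            raise ValueError("subjects have inconsistent time grids")
    return times, np.mean([s.mpfb_deg for s in members], axis=0)
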