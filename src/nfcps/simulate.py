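"""Synthetic dual-hemisphere NFCPS cohort simulator.

Emulates 24-h near-field coupling phase-shift (NFCPS) monitoring of a rabbit
cohort with unilateral focal-ischemia edema: each subject contributes one
pre-modeling baseline sweep and 25 hourly phase-vs-frequency sweeps (201
points, 70-90 MHz, degrees) per hemisphere.  The lesion hemisphere's tissue
conductivity first falls (cytotoxic edema, CE) and then rises (vasogenic
edema, VE) with a per-subject transition time eta in [5, 7] h; the healthy
hemisphere is unaffected by the unilateral lesion.  Controls show only a
small smooth drift.

The conductivity deviation is mapped to phase additively through a smooth
frequency-dependent sensitivity whose band-mean over the 83-87 MHz feature
band is normalised to one, so trajectory amplitudes are expressed directly
in cancelled band-mean degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("experimental", "control")
HEMISPHERES = ("lesion", "healthy")

#: Time stamps of one subject/hemisphere recording: -1 h is the pre-modeling
#: anesthetized reference sweep, 0..24 h are hourly post-modeling sweeps.
BASELINE_TIME_H = -1
MONITORING_TIMES_H = tuple(range(0, 25))
ALL_TIMES_H = (BASELINE_TIME_H,) + MONITORING_TIMES_H

FEATURE_BAND_MHZ = (83.0, 87.0)


@dataclass(frozen=True)
class FrequencyGrid:
    """Uniform sweep frequency grid (endpoints inclusive)."""

    f_min_mhz: float = 70.0
    f_max_mhz: float = 90.0
    n_points: int = 201

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")
        if not self.f_max_mhz > self.f_min_mhz:
            raise ValueError(
                f"f_max_mhz ({self.f_max_mhz}) must exceed f_min_mhz ({self.f_min_mhz})"
            )

    @property
    def frequencies_mhz(self) -> np.ndarray:
        return np.linspace(self.f_min_mhz, self.f_max_mhz, self.n_points)

    @property
    def spacing_mhz(self) -> float:
        return (self.f_max_mhz - self.f_min_mhz) / (self.n_points - 1)

    def band_mask(self, band: tuple[float, float], tol: float = 1e-6) -> np.ndarray:
        """Boolean mask of grid points inside the closed ``band`` (MHz)."""
        lo, hi = band
        if lo > hi:
            raise ValueError(f"band lower edge {lo} exceeds upper edge {hi}")
        if lo < self.f_min_mhz - tol or hi > self.f_max_mhz + tol:
            raise ValueError(
                f"band {band} not contained in grid range "
                f"[{self.f_min_mhz}, {self.f_max_mhz}] MHz"
            )
        f = self.frequencies_mhz
        return (f >= lo - tol) & (f <= hi + tol)


@dataclass(frozen=True)
class SensitivityProfile:
    """Phase response per unit conductivity deviation, per grid point.

    ``k_deg_per_unit`` is non-negative everywhere and normalised so that its
    mean over the feature band equals one degree per conductivity unit; the
    response maximum sits inside the feature band, reflecting that observed
    phase change is largest near the central sweep frequencies.
    """

    k_deg_per_unit: np.ndarray
    center_mhz: float

    def __post_init__(self) -> None:
        k = np.asarray(self.k_deg_per_unit, dtype=float)
        object.__setattr__(self, "k_deg_per_unit", k)
        if np.any(k < 0):
            raise ValueError("sensitivity must be non-negative everywhere")

    @classmethod
    def gaussian(
        cls,
        grid: FrequencyGrid,
        center_mhz: float = 85.0,
        width_mhz: float = 3.0,
        band: tuple[float, float] = FEATURE_BAND_MHZ,
    ) -> "SensitivityProfile":
        lo, hi = band
        if not lo <= center_mhz <= hi:
            raise ValueError(
                f"sensitivity peak {center_mhz} MHz must lie inside the feature band {band}"
            )
        f = grid.frequencies_mhz
        k = np.exp(-0.5 * ((f - center_mhz) / width_mhz) ** 2)
        k = k / k[grid.band_mask(band)].mean()
        return cls(k_deg_per_unit=k, center_mhz=center_mhz)


@dataclass(frozen=True)
class SubjectParams:
    """Generative parameters of one simulated subject.

    eta_h is the (continuous) CE-to-VE transition time; nadir_depth_deg the
    peak cancelled band-mean phase deviation (negative); recovery_fraction
    how far the deviation returns toward zero by 24 h; control_drift_deg the
    control group's net 24-h deviation.  Experimental subjects carry eta/nadir
    and no drift; controls the reverse.
    """

    subject_id: str
    group: str
    eta_h: float | None
    nadir_depth_deg: float | None
    recovery_fraction: float
    control_drift_deg: float | None
    noise_sd_deg: float
    seed: int
    lesion_hemisphere: str = "left"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.noise_sd_deg < 0:
            raise ValueError("noise_sd_deg must be >= 0")
        if not 0.0 <= self.recovery_fraction <= 1.0:
            raise ValueError("recovery_fraction must lie in [0, 1]")
        if self.group == "experimental":
            if self.eta_h is None or self.nadir_depth_deg is None:
                raise ValueError("experimental subjects need eta_h and nadir_depth_deg")
            if self.nadir_depth_deg >= 0:
                raise ValueError("nadir_depth_deg must be negative")
        else:
            if self.eta_h is not None:
                raise ValueError("eta_h is undefined for control subjects")
            if self.control_drift_deg is None:
                raise ValueError("control subjects need control_drift_deg")


@dataclass(frozen=True)
class PhaseSweep:
    """One phase-vs-frequency trace for one subject/hemisphere/time."""

    subject_id: str
    hemisphere: str
    time_h: int
    phase_deg: np.ndarray

    def __post_init__(self) -> None:
        phase = np.asarray(self.phase_deg, dtype=float)
        object.__setattr__(self, "phase_deg", phase)
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(
                f"unknown hemisphere {self.hemisphere!r}; expected one of {HEMISPHERES}"
            )
        if not np.all(np.isfinite(phase)):
            raise ValueError("phase values must all be finite")


def _recovery_progress(
    u: np.ndarray, span_h: float, fast_hours: float, fast_weight: float
) -> np.ndarray:
    """Normalised recovery (0 at the nadir, 1 at 24 h after modeling).

    Mixture of a fast half-cosine with characteristic time ``fast_hours`` and
    a slow half-cosine over the whole remaining span, giving an early visible
    rebound followed by a long decelerating tail.
    """
    fast = 0.5 * (1.0 - np.cos(np.pi * np.minimum(u, fast_hours) / fast_hours))
    slow = 0.5 * (1.0 - np.cos(np.pi * u / span_h))
    return fast_weight * fast + (1.0 - fast_weight) * slow


def conductivity_trajectory(
    params: SubjectParams,
    t_grid_h: np.ndarray,
    recovery_fast_hours: float = 8.0,
    recovery_fast_weight: float = 0.5,
    end_time_h: float = 24.0,
) -> np.ndarray:
    """Lesion-hemisphere conductivity deviation from baseline, Delta-sigma(t).

    Zero at t <= 0.  Experimental subjects fall monotonically to the nadir at
    eta (cytotoxic stage, conductivity drops) and recover monotonically
    afterwards to ``(1 - recovery_fraction)`` of the nadir at 24 h (vasogenic
    stage, conductivity rises).  Controls drift smoothly to their net 24-h
    deviation.  Units are cancelled band-mean degrees (the forward map's
    sensitivity is band-normalised).
    """
    t = np.asarray(t_grid_h, dtype=float)
    out = np.zeros_like(t)
    active = t > 0
    if params.group == "control":
        drift = float(params.control_drift_deg)
        out[active] = drift * 0.5 * (1.0 - np.cos(np.pi * t[active] / end_time_h))
        return out
    if params.group != "experimental":  # SubjectParams already validates; be safe
        raise ValueError(f"unknown group {params.group!r}")

    eta = float(params.eta_h)
    depth = -float(params.nadir_depth_deg)  # positive magnitude
    r = float(params.recovery_fraction)

    falling = active & (t <= eta)
    out[falling] = -depth * 0.5 * (1.0 - np.cos(np.pi * t[falling] / eta))
    rising = t > eta
    u = t[rising] - eta
    progress = _recovery_progress(
        u, span_h=end_time_h - eta, fast_hours=recovery_fast_hours,
        fast_weight=recovery_fast_weight,
    )
    out[rising] = -depth * (1.0 - r * progress)
    return out


def transition_hour(
    params: SubjectParams,
    recovery_fast_hours: float = 8.0,
    recovery_fast_weight: float = 0.5,
) -> int:
    """Transition time at the 1-h sampling resolution.

    The hour at which the noise-free sampled trajectory attains its minimum —
    the observable CE-to-VE transition given hourly sampling (no
    interpolation between samples is attempted).
    """
    if params.group != "experimental":
        raise ValueError("transition_hour is defined only for experimental subjects")
    t = np.asarray(MONITORING_TIMES_H, dtype=float)
    traj = conductivity_trajectory(
        params, t, recovery_fast_hours=recovery_fast_hours,
        recovery_fast_weight=recovery_fast_weight,
    )
    return int(t[np.argmin(traj)])


def forward_phase_sweep(
    delta_sigma: float,
    profile: SensitivityProfile,
    grid: FrequencyGrid,
    baseline_deg: np.ndarray,
    noise_sd_deg: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Additive linear forward map: baseline + k(f) * Delta-sigma + noise."""
    baseline = np.asarray(baseline_deg, dtype=float)
    if baseline.shape != (grid.n_points,):
        raise ValueError(
            f"baseline length {baseline.shape} does not match grid ({grid.n_points},)"
        )
    if profile.k_deg_per_unit.shape != (grid.n_points,):
        raise ValueError("sensitivity profile length does not match grid")
    phase = baseline + profile.k_deg_per_unit * float(delta_sigma)
    if noise_sd_deg > 0:
        phase = phase + rng.normal(0.0, noise_sd_deg, grid.n_points)
    return phase


@dataclass(frozen=True)
class CohortConfig:
    """Default study conditions of the simulated monitoring experiment."""

    n_experimental: int = 8
    n_control: int = 5
    grid: FrequencyGrid = field(default_factory=FrequencyGrid)
    sensitivity_center_mhz: float = 85.0
    sensitivity_width_mhz: float = 3.0
    band_mhz: tuple[float, float] = FEATURE_BAND_MHZ
    eta_range_h: tuple[float, float] = (5.0, 7.0)
    nadir_depth_mean_deg: float = -36.0
    nadir_depth_sd_deg: float = 6.0
    recovery_fraction_mean: float = 0.7
    recovery_fraction_sd: float = 0.08
    recovery_fast_hours: float = 8.0
    recovery_fast_weight: float = 0.5
    control_drift_mean_deg: float = -0.12
    control_drift_sd_deg: float = 0.05
    noise_sd_deg: float = 1.0
    # per-subject baseline spectrum: quadratic in x = (f - f_center)/half-span
    baseline_poly_mean: tuple[float, float, float] = (-25.0, 2.0, -3.0)
    baseline_poly_sd: tuple[float, float, float] = (5.0, 1.0, 1.0)
    # small static left-right asymmetry added to the lesion hemisphere baseline
    hemisphere_asym_sd_deg: float = 0.3

    def __post_init__(self) -> None:
        if self.n_experimental <= 0 or self.n_control <= 0:
            raise ValueError("group sizes must be positive")
        lo, hi = self.eta_range_h
        if not 0 < lo <= hi:
            raise ValueError(f"invalid eta range {self.eta_range_h}")
        if self.noise_sd_deg < 0:
            raise ValueError("noise_sd_deg must be >= 0")
        if self.nadir_depth_mean_deg >= 0:
            raise ValueError("nadir_depth_mean_deg must be negative")

    def sensitivity_profile(self) -> SensitivityProfile:
        return SensitivityProfile.gaussian(
            self.grid, self.sensitivity_center_mhz, self.sensitivity_width_mhz,
            self.band_mhz,
        )


@dataclass
class Cohort:
    """Generated cohort: long-format sweep table plus generative parameters."""

    sweeps: pd.DataFrame
    subject_params: list[SubjectParams]
    config: CohortConfig
    master_seed: int

    def params_table(self) -> pd.DataFrame:
        rows = []
        for p in self.subject_params:
            row = {
                "subject_id": p.subject_id,
                "group": p.group,
                "eta_h": p.eta_h,
                "nadir_depth_deg": p.nadir_depth_deg,
                "recovery_fraction": p.recovery_fraction,
                "control_drift_deg": p.control_drift_deg,
                "noise_sd_deg": p.noise_sd_deg,
                "seed": p.seed,
                "lesion_hemisphere": p.lesion_hemisphere,
            }
            if p.group == "experimental":
                row["transition_h"] = transition_hour(
                    p,
                    recovery_fast_hours=self.config.recovery_fast_hours,
                    recovery_fast_weight=self.config.recovery_fast_weight,
                )
            else:
                row["transition_h"] = np.nan
            rows.append(row)
        return pd.DataFrame(rows)


def _draw_subject_params(
    config: CohortConfig, rng: np.random.Generator
) -> list[SubjectParams]:
    subjects: list[SubjectParams] = []
    lo, hi = config.eta_range_h
    for i in range(config.n_experimental):
        eta = float(rng.uniform(lo, hi))
        depth = float(rng.normal(config.nadir_depth_mean_deg, config.nadir_depth_sd_deg))
        depth = min(depth, -5.0)  # keep a clearly negative nadir
        rec = float(np.clip(
            rng.normal(config.recovery_fraction_mean, config.recovery_fraction_sd),
            0.0, 1.0,
        ))
        subjects.append(SubjectParams(
            subject_id=f"E{i + 1:02d}",
            group="experimental",
            eta_h=eta,
            nadir_depth_deg=depth,
            recovery_fraction=rec,
            control_drift_deg=None,
            noise_sd_deg=config.noise_sd_deg,
            seed=int(rng.integers(0, 2**31 - 1)),
            lesion_hemisphere=str(rng.choice(["left", "right"])),
        ))
    for i in range(config.n_control):
        drift = float(rng.normal(config.control_drift_mean_deg, config.control_drift_sd_deg))
        subjects.append(SubjectParams(
            subject_id=f"C{i + 1:02d}",
            group="control",
            eta_h=None,
            nadir_depth_deg=None,
            recovery_fraction=config.recovery_fraction_mean,
            control_drift_deg=drift,
            noise_sd_deg=config.noise_sd_deg,
            seed=int(rng.integers(0, 2**31 - 1)),
            lesion_hemisphere=str(rng.choice(["left", "right"])),
        ))
    return subjects


def _subject_baseline(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject baseline spectra (healthy, lesion) in degrees."""
    f = config.grid.frequencies_mhz
    x = (f - 0.5 * (config.grid.f_min_mhz + config.grid.f_max_mhz)) / (
        0.5 * (config.grid.f_max_mhz - config.grid.f_min_mhz)
    )
    c = [rng.normal(m, s) for m, s in zip(config.baseline_poly_mean, config.baseline_poly_sd)]
    healthy = c[0] + c[1] * x + c[2] * x**2
    a = [rng.normal(0.0, config.hemisphere_asym_sd_deg) for _ in range(3)]
    lesion = healthy + a[0] + a[1] * x + a[2] * x**2
    return healthy, lesion


def generate_cohort(config: CohortConfig | None = None, master_seed: int = 0) -> Cohort:
    """Generate the full cohort sweep table, reproducible from ``master_seed``.

    Each subject gets one baseline (-1 h) and 25 hourly sweeps per hemisphere.
    The healthy hemisphere carries Delta-sigma = 0 at all times (the
    unilateral lesion does not affect it).
    """
    config = config or CohortConfig()
    master_rng = np.random.default_rng(master_seed)
    subjects = _draw_subject_params(config, master_rng)
    profile = config.sensitivity_profile()
    grid = config.grid
    n_pts = grid.n_points
    times = np.asarray(ALL_TIMES_H, dtype=float)
    n_t = times.size
    freqs = grid.frequencies_mhz

    block_rows = n_t * n_pts
    time_col = np.repeat(times.astype(int), n_pts)
    freq_col = np.tile(freqs, n_t)
    subject_col, group_col, hemi_col, phase_col = [], [], [], []
    for p in subjects:
        rng = np.random.default_rng(p.seed)
        healthy_base, lesion_base = _subject_baseline(config, rng)
        delta = conductivity_trajectory(
            p, times,
            recovery_fast_hours=config.recovery_fast_hours,
            recovery_fast_weight=config.recovery_fast_weight,
        )
        for hemi, base, dsig in (
            ("lesion", lesion_base, delta),
            ("healthy", healthy_base, np.zeros_like(delta)),
        ):
            phase = base[None, :] + profile.k_deg_per_unit[None, :] * dsig[:, None]
            if p.noise_sd_deg > 0:
                phase = phase + rng.normal(0.0, p.noise_sd_deg, (n_t, n_pts))
            subject_col.append(np.full(block_rows, p.subject_id, dtype=object))
            group_col.append(np.full(block_rows, p.group, dtype=object))
            hemi_col.append(np.full(block_rows, hemi, dtype=object))
            phase_col.append(phase.ravel())
    n_subj = len(subjects)
    sweeps = pd.DataFrame({
        "subject_id": np.concatenate(subject_col),
        "group": np.concatenate(group_col),
        "hemisphere": np.concatenate(hemi_col),
        "time_h": np.tile(time_col, 2 * n_subj),
        "freq_mhz": np.tile(freq_col, 2 * n_subj),
        "phase_deg": np.concatenate(phase_col),
    })
    return Cohort(sweeps=sweeps, subject_params=subjects, config=config,
                  master_seed=master_seed)


def grid_from_sweep_table(sweeps: pd.DataFrame) -> FrequencyGrid:
    """Recover the frequency grid from a long-format sweep table."""
    freqs = np.sort(sweeps["freq_mhz"].unique())
    if freqs.size < 2:
        raise ValueError("sweep table contains fewer than 2 distinct frequencies")
    spacing = np.diff(freqs)
    if not np.allclose(spacing, spacing[0], atol=1e-9):
        raise ValueError("sweep table frequencies are not uniformly spaced")
    return FrequencyGrid(float(freqs[0]), float(freqs[-1]), int(freqs.size))
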