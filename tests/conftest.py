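import numpy as np
import pytest

from nfcps.simulate import CohortConfig, FrequencyGrid, SensitivityProfile, SubjectParams


@pytest.fixture(scope="session")
def grid() -> FrequencyGrid:
    return FrequencyGrid()


@pytest.fixture(scope="session")
def profile(grid) -> SensitivityProfile:
    return SensitivityProfile.gaussian(grid)


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig()


@pytest.fixture(scope="session")
def noise_free_config() -> CohortConfig:
    """Default cohort with every stochastic disturbance switched off."""
    return CohortConfig(noise_sd_deg=0.0, control_drift_mean_deg=-1e-12,
                        control_drift_sd_deg=0.0, hemisphere_asym_sd_deg=0.0)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    from nfcps.simulate import generate_cohort
    return generate_cohort(default_config, master_seed=7)


@pytest.fixture(scope="session")
def default_series(default_cohort):
    from nfcps.processing import process_cohort
    return process_cohort(default_cohort.sweeps, default_cohort.config.grid)


@pytest.fixture(scope="session")
def default_features(default_cohort, default_series):
    from nfcps.features import window_features
    from nfcps.pipeline import transition_hours
    return window_features(default_series, transition_hours(default_cohort))


@pytest.fixture(scope="session")
def noise_free_cohort(noise_free_config):
    from nfcps.simulate import generate_cohort
    return generate_cohort(noise_free_config, master_seed=7)


@pytest.fixture(scope="session")
def noise_free_series(noise_free_cohort):
    from nfcps.processing import process_cohort
    return process_cohort(noise_free_cohort.sweeps, noise_free_cohort.config.grid)


@pytest.fixture(scope="session")
def noise_free_features(noise_free_cohort, noise_free_series):
    from nfcps.features import window_features
    from nfcps.pipeline import transition_hours
    return window_features(noise_free_series, transition_hours(noise_free_cohort))


def blob_features(n: int = 120, gap: float = 4.0, seed: int = 0):
    """Well-separated two-class feature frame (clear margin in beta)."""
    import pandas as pd
    rng = np.random.default_rng(seed)
    half = n // 2
    beta = np.concatenate([rng.normal(-gap, 0.5, half), rng.normal(gap, 0.5, n - half)])
    alpha = rng.normal(-20.0, 5.0, n)
    frame = pd.DataFrame({
        "alpha": alpha,
        "beta": beta,
        "gamma": beta + rng.normal(0, 0.2, n),
        "delta": beta / 2.0,
        "label": ["CE"] * half + ["VE"] * (n - half),
    })
    return frame


def make_experimental_params(
    eta_h: float = 6.0,
    nadir_depth_deg: float = -35.0,
    recovery_fraction: float = 0.7,
    noise_sd_deg: float = 0.0,
    seed: int = 0,
    subject_id: str = "E01",
) -> SubjectParams:
    return SubjectParams(
        subject_id=subject_id, group="experimental", eta_h=eta_h,
        nadir_depth_deg=nadir_depth_deg, recovery_fraction=recovery_fraction,
        control_drift_deg=None, noise_sd_deg=noise_sd_deg, seed=seed,
    )


def make_control_params(
    control_drift_deg: float = 0.0,
    noise_sd_deg: float = 0.0,
    seed: int = 0,
    subject_id: str = "C01",
) -> SubjectParams:
    return SubjectParams(
        subject_id=subject_id, group="control", eta_h=None,
        nadir_depth_deg=None, recovery_fraction=0.7,
        control_drift_deg=control_drift_deg, noise_sd_deg=noise_sd_deg, seed=seed,
    )
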