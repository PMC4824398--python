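import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gaitrisk.types import ClinicalFeatures, SubjectProfile
from gaitrisk.synthetic import generate_trial

settings.register_profile(
    "suite", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clinical():
    return ClinicalFeatures(
        abc_score=90.0,
        champs_frequency=20.0,
        champs_calories=3000.0,
        sixmwt_distance_m=450.0,
        st_walk_time_s=6.5,
        dt_walk_time_s=7.2,
        fear_of_falling=1,
    )


@pytest.fixture(scope="session")
def make_profile(clinical):
    """Factory for subject profiles; defaults are a clean symmetric walker."""

    def _make(**overrides) -> SubjectProfile:
        base = dict(
            subject_id="S0",
            is_faller=False,
            mass_kg=75.0,
            stride_time_mean_s=1.2,
            stride_time_cv_pct=0.0,
            stance_fraction=0.62,
            step_asymmetry_pct=0.0,
            harmonic_purity=0.6,
            noise_sd=0.0,
            clinical=clinical,
            pd_per_stance=0.0,
            ml_dev_per_stance=0.0,
        )
        base.update(overrides)
        return SubjectProfile(**base)

    return _make


@pytest.fixture(scope="session")
def clean_trial(make_profile):
    """Noise-free, symmetric, deviation-free 10 s trial (ground truth exact)."""
    return generate_trial(make_profile(), "ST", 10.0, seed=5)


@pytest.fixture(scope="session")
def logistic_series():
    """The r=4 logistic map, whose Lyapunov exponent is ln 2 per step."""
    x = np.empty(5000)
    x[0] = 0.34
    for i in range(4999):
        x[i + 1] = 4.0 * x[i] * (1.0 - x[i])
    return x


@pytest.fixture(scope="session")
def logistic_mle(logistic_series):
    """Pipeline MLE of the logistic map (computed once per session)."""
    import warnings

    from gaitrisk.accel import lyapunov_pipeline

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lyapunov_pipeline(logistic_series, fs_hz=1.0)
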