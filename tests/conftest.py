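import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ppgrr.pipeline import ExtractionConfig, build_features
from ppgrr.records import segment_windows
from ppgrr.simulate import generate_cohort

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def _cohort_features(profile, n_subjects, duration_s, seed):
    records = generate_cohort(
        n_subjects=n_subjects,
        duration_s=duration_s,
        quality_profile=profile,
        seed=seed,
    )
    windows = [w for r in records for w in segment_windows(r)]
    cfg = ExtractionConfig(ensemble_size=10, seed=seed)
    df, discarded = build_features(windows, cfg)
    return df, discarded, records, windows


@pytest.fixture(scope="session")
def clean_cohort():
    """Small clean cohort with its extracted feature table."""
    return _cohort_features("clean", n_subjects=4, duration_s=120, seed=7)


@pytest.fixture(scope="session")
def poor_cohort():
    """Small degraded cohort (quality-correlated corruption)."""
    return _cohort_features("poor", n_subjects=6, duration_s=120, seed=11)
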