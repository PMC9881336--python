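import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from hemigait import synthgait
from hemigait.synthgait import GaitParams


@pytest.fixture(scope="session")
def symmetric_trial():
    """Noiseless perfectly symmetric trial: every asymmetry index is 0."""
    params = GaitParams(n_strides=8, noise_sd=0.0, seed=1)
    return synthgait.generate_trial(params)


@pytest.fixture(scope="session")
def asymmetric_trial():
    """Noiseless hemiparetic-like trial with known parameter values."""
    params = GaitParams(
        step_length_left=0.45,
        step_length_right=0.60,
        stance_fraction_left=0.67,
        stance_fraction_right=0.60,
        knee_flexion_peak_left=40.0,
        knee_flexion_peak_right=58.0,
        hip_hike_amp_left=6.0,
        hip_hike_amp_right=1.5,
        circumduction_amp_left=0.035,
        circumduction_amp_right=0.008,
        tla_peak_left=13.0,
        tla_peak_right=20.0,
        n_strides=10,
        noise_sd=0.0,
        seed=2,
    )
    return synthgait.generate_trial(params, group="stroke", paretic_side="left")


@pytest.fixture(scope="session")
def small_cohort_tables():
    """Metrics table + metadata for a small heterogeneous two-group cohort."""
    from hemigait import pipeline

    cohort = synthgait.generate_cohort(10, seed=5, n_strides=10)
    table, metas = pipeline.cohort_metrics_table(cohort)
    return table, metas


from hemigait.validation import simulate_lmm_table  # noqa: E402,F401  (shared fixture helper)
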