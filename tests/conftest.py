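import numpy as np
import pytest

import pupilperim as pp


@pytest.fixture(scope="session")
def dim_blue_spec():
    return pp.STIMULI[pp.Condition.dim_blue]


@pytest.fixture
def default_shape():
    return pp.PLRShapeParams(
        baseline_mm=6.0, latency_s=0.478, amplitude_mm=0.9,
        time_to_peak_s=0.9, redilation_tau_s=1.5, noise_sd_mm=0.0,
    )


@pytest.fixture(scope="session")
def small_effect_cohort():
    """A reduced-size effect cohort: dim blue, right eye only."""
    cfg = pp.CohortConfig(
        n_subjects=60, n_fh_pos=40,
        conditions=(pp.Condition.dim_blue,), eyes=(pp.Eye.right,),
        missingness_rate=0.0, blink_rate=0.0, seed=42,
    )
    return pp.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_effect_features(small_effect_cohort):
    return pp.extract_features(small_effect_cohort.traces)


def random_shape(rng, noise_sd=0.0):
    return pp.PLRShapeParams(
        baseline_mm=rng.uniform(5.0, 7.0),
        latency_s=rng.uniform(0.3, 0.6),
        amplitude_mm=rng.uniform(0.5, 1.2),
        time_to_peak_s=rng.uniform(0.7, 1.1),
        redilation_tau_s=rng.uniform(1.0, 2.0),
        noise_sd_mm=noise_sd,
    )
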