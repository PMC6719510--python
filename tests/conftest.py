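import numpy as np
import pytest

from mmnload.synthetic_eeg import CohortSpec, NoiseSpec, SubjectGroundTruth
from mmnload.task_design import BlockDesign, compose_session

# the study's observed cell means, used as injected ground truth
TABLE1_MEANS = {
    ("n1", "low"): -0.49, ("n1", "high"): -0.15,
    ("oddball_mmn", "low"): -2.13, ("oddball_mmn", "high"): -2.26,
    ("corrected_mmn", "low"): -1.38, ("corrected_mmn", "high"): -1.26,
    ("p3a", "low"): 0.41, ("p3a", "high"): -0.18,
    ("visual_p3", "low"): 9.29, ("visual_p3", "high"): 2.73,
}


@pytest.fixture(scope="session")
def table1_truth():
    return SubjectGroundTruth("S1", dict(TABLE1_MEANS), wmc_pcu=0.7)


@pytest.fixture(scope="session")
def quiet_noise():
    return NoiseSpec(sd=0.0, artifact_rate=0.0, drift_sd=0.0)


@pytest.fixture(scope="session")
def small_design():
    # scaled-down block: 120 trials keeps every counting identity integral
    return BlockDesign(n_trials=120)


@pytest.fixture(scope="session")
def session_default():
    return compose_session(11)


@pytest.fixture(scope="session")
def session_small(small_design):
    return compose_session(11, small_design)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def quiet_cohort(n_subjects=3, seed=0, design=None, **kw):
    """Cohort spec with zero noise and zero between-subject variability."""
    zero_sds = {k: 0.0 for k in ("n1", "oddball_mmn", "corrected_mmn", "p3a", "visual_p3")}
    return CohortSpec(
        n_subjects=n_subjects,
        group_sds=zero_sds,
        effect_sds=zero_sds,
        wmc_effect_correlation=0.0,
        noise=NoiseSpec(sd=0.0, artifact_rate=0.0, drift_sd=0.0),
        design=design or BlockDesign(n_trials=120),
        sampling_rate=128.0,
        seed=seed,
        **kw,
    )
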