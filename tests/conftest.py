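import dataclasses

import pytest

from hamqc.cohort import CohortConfig, calibrate_latent, generate_cohort


@pytest.fixture(scope="session")
def calibrated_config():
    """Default-target config with calibrated latent parameters (shared:
    calibration is the expensive step)."""
    cfg, report = calibrate_latent(CohortConfig(seed=123))
    return cfg, report


@pytest.fixture(scope="session")
def cohort_5000(calibrated_config):
    """A 5000-animal cohort with every sample scored separately, for
    checking observed-scale correlation recovery."""
    cfg, _ = calibrated_config
    big = dataclasses.replace(cfg, n_animals=5000, seed=42, joint_fraction=0.0)
    return generate_cohort(big)
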