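import numpy as np
import pytest

from lcmri import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Three identical noise-free subjects with asymmetric contrast 1.30/1.25."""
    cfg = SimulationConfig(
        n_subjects=3, noise_sd=0.0, subject_jitter_sd=0.0, bias_field_amplitude=0.0, seed=7
    )
    volumes, truth, roispec = generate_cohort(cfg)
    return cfg, volumes, truth, roispec


@pytest.fixture(scope="session")
def flat_tube_cohort():
    """Noise-free cohort with flat (top-hat, uniform-slice) symmetric tubes.

    Every tube voxel has the same intensity, so threshold-based selections
    can recover the tube exactly.
    """
    cfg = SimulationConfig(
        n_subjects=3,
        lc_contrast_true=(1.25, 1.25),
        radial_profile="tophat",
        rostrocaudal_profile=np.ones(17),
        noise_sd=0.0,
        subject_jitter_sd=0.0,
        seed=11,
    )
    volumes, truth, roispec = generate_cohort(cfg)
    return cfg, volumes, truth, roispec
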