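import numpy as np
import pytest

from pupilstate import synthetic
from pupilstate.corrmaps import voxelwise_correlation


@pytest.fixture(scope="session")
def geom_small():
    return synthetic.generate_geometry((12, 12, 8), "ellipsoid", seed=0)


@pytest.fixture(scope="session")
def atlas_small(geom_small):
    return synthetic.generate_component_maps(geom_small, 6, 2.0, seed=1)


@pytest.fixture(scope="session")
def profiles():
    return synthetic.default_state_profiles(6)


@pytest.fixture(scope="session")
def cohort_small(geom_small, atlas_small, profiles):
    """4 planted states x 4 trials, short trials: quick but recoverable."""
    trials, truth = synthetic.generate_cohort(
        geom_small, atlas_small, profiles, [4, 4, 4, 4],
        T=256, noise_sd_fmri=1.0, noise_sd_pupil=0.2, seed=7,
    )
    return trials, truth


@pytest.fixture(scope="session")
def corr_maps_small(cohort_small, geom_small):
    trials, _ = cohort_small
    return [voxelwise_correlation(t.fmri, t.pupil, geom_small) for t in trials]


@pytest.fixture(scope="session")
def single_component_cohort(geom_small):
    """Noise-free single-component cohort for exact recovery checks."""
    atlas = synthetic.generate_component_maps(geom_small, 1, 2.0, seed=2)
    prof = [synthetic.StateProfile(state_id=0, coupling=np.array([1.0]),
                                   oscillation_freq=0.018)]
    trials, truth = synthetic.generate_cohort(
        geom_small, atlas, prof, [6], T=200,
        noise_sd_fmri=0.0, noise_sd_pupil=0.0, seed=11,
    )
    return trials, truth
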