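import numpy as np
import pytest

from neurosig.synthetic import CohortSpec, generate_cohort
from neurosig.volume_core import BrainMask, VolumeGrid


@pytest.fixture(scope="session")
def tiny_spec():
    """Small fast cohort: 8 subjects on a 10^3 grid, noiseless-ish defaults kept."""
    return CohortSpec(
        n_subjects=8,
        grid=VolumeGrid((10, 10, 10)),
        n_trials_per_condition=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def default_cohort():
    """The documented default cohort (40 subjects, ~2,000 voxels)."""
    return generate_cohort(CohortSpec(seed=20260930))


@pytest.fixture
def full_mask_222():
    grid = VolumeGrid((2, 2, 2))
    return BrainMask(grid, np.ones((2, 2, 2), dtype=bool))
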