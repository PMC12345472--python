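import numpy as np
import pytest

from sheepface import synthetic_faces as sf
from sheepface import train_eval as te


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 individuals x 6 ages x 2 reps, in memory (age-based splits)."""
    images, records = sf.generate_cohort(
        n_ids=4, ages=[1, 3, 5, 7, 9, 11], reps_per_cell=2, seed=11)
    return te.Cohort.from_images(images, records)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
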