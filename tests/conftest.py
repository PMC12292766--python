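import warnings

import numpy as np
import pytest

from coxmorph.landmarks import LANDMARK_NAMES, N_LANDMARKS, Cohort, LandmarkSet

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_bone(rng, individual_id="A1", side="right", sex="M", age=40.0,
                spread=120.0, min_sep=5.0):
    """A random well-separated 34-landmark configuration (not anatomical)."""
    while True:
        coords = rng.uniform(-spread, spread, size=(N_LANDMARKS, 3))
        from scipy.spatial.distance import pdist
        if pdist(coords).min() >= min_sep:
            return LandmarkSet(individual_id, side, sex, age, coords)


def random_cohort(rng, n_individuals=4, sides=("right", "left")):
    records = []
    for i in range(n_individuals):
        sex = "M" if i % 2 == 0 else "F"
        age = float(rng.uniform(20, 80))
        for side in sides:
            records.append(random_bone(rng, f"ID{i}", side, sex, age))
    return Cohort(records)


@pytest.fixture
def small_cohort(rng):
    return random_cohort(rng)


@pytest.fixture(scope="session")
def male_right_template():
    from coxmorph.synthetic import template_for
    return template_for("M", "right")
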