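import numpy as np
import pytest

from collinear import models, synthetic

#: Realistic generating values used across recovery-style tests.
TRUE_SIGMAS = (0.35, 0.55, 1.0, 2.0)


@pytest.fixture(scope="session")
def design():
    return synthetic.make_default_design()


@pytest.fixture(scope="session")
def noise(design):
    return models.NoiseProfile(design.eccentricity_levels, TRUE_SIGMAS)


@pytest.fixture(scope="session")
def single_level_noise():
    return models.NoiseProfile((0.0,), (0.5,))


def make_collinearity_trial(y_left, y_right, eccentricity=0.0, response=None):
    return synthetic.TrialRecord(
        subject_id="t",
        session=1,
        block=1,
        trial_index=1,
        task=synthetic.COLLINEARITY,
        eccentricity=eccentricity,
        y_left=y_left,
        y_right=y_right,
        category=synthetic.COLLINEAR if y_left == y_right else synthetic.NONCOLLINEAR,
        response=response,
    )


def make_height_trial(y_left, y_right, eccentricity=0.0, response=None):
    return synthetic.TrialRecord(
        subject_id="t",
        session=1,
        block=1,
        trial_index=1,
        task=synthetic.HEIGHT,
        eccentricity=eccentricity,
        y_left=y_left,
        y_right=y_right,
        category=synthetic.RIGHT_HIGHER if y_right > y_left else synthetic.LEFT_HIGHER,
        response=response,
    )
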