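import numpy as np
import pytest

import ordprofile as op


@pytest.fixture(scope="session")
def impact():
    return op.get_template("impact")


@pytest.fixture(scope="session")
def practise():
    return op.get_template("practise")


@pytest.fixture(scope="session")
def small_cohort(impact):
    """5 hospitals x 60 patients with true effects, TBI template."""
    effects = op.sample_center_effects(5, 0.35, "A", 11)
    return op.simulate_cohort(impact.generator, impact.cov_model,
                              5, 60, effects, 12), effects


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2021)
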