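"""Shared fixtures: small simulated cohorts and desk-scale model configs.

Everything is generated at test time from seeds; no stored data files.
"""

import numpy as np
import pytest

from metagait.data import prepare_clips
from metagait.pipeline import desk_model_config
from metagait.synthetic import GeneratorConfig, make_cohort, make_subject, simulate_trial


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def subject0(gen_config):
    return make_subject(0, gen_config)


@pytest.fixture(scope="session")
def trial60(subject0, gen_config):
    """One 60-s moderate-speed trial (full protocol rates)."""
    return simulate_trial(subject0, 4.5, 60.0, "ccw", seed=11, config=gen_config)


@pytest.fixture(scope="session")
def small_cohort():
    """2 subjects x 3 trials (one per speed), held in memory."""
    return make_cohort(2, 1, seed=42)


@pytest.fixture(scope="session")
def desk_config():
    return desk_model_config()


@pytest.fixture(scope="session")
def small_data(small_cohort, desk_config):
    return prepare_clips(small_cohort.clips(), desk_config)


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of scalar f() with respect to array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g
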