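from __future__ import annotations

import numpy as np
import pytest

from colonquant import PhantomSpec, generate_phantom
from colonquant.phantom import straight_cylinder_spec


def small_spec(**kwargs) -> PhantomSpec:
    """Desk-scale phantom used by the unit tests (fast to generate/segment)."""
    defaults = dict(shape=(64, 64, 48), spacing=(2.0, 2.0, 3.0), radius_mean=9.0)
    defaults.update(kwargs)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_truth():
    return generate_phantom(small_spec(seed=0))


@pytest.fixture(scope="session")
def small_truth_noiseless():
    return generate_phantom(small_spec(seed=0, noise_sigma={"T2": 0.0, "T1FS": 0.0}))


@pytest.fixture(scope="session")
def cylinder_truth():
    """Straight tube, 1 mm isotropic, noiseless: analytic ground truth."""
    return generate_phantom(straight_cylinder_spec(length=200.0, radius=10.0, spacing=1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
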