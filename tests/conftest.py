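import numpy as np
import pytest

from fogmap.config import RunConfig
from fogmap.pipeline import run_study
from fogmap.synth import make_toy_atlas


@pytest.fixture(scope="session")
def study():
    """The full synthetic study at the default conditions (master seed 0).

    n = 76 bilateral patients, planted sweet/sour spheres and bundles at
    the default gains, noise SD 40.  Shared across the whole suite: this
    is the expensive end-to-end computation every mapping-level test
    interrogates.
    """
    return run_study(RunConfig())


@pytest.fixture(scope="session")
def atlas():
    return make_toy_atlas()


@pytest.fixture(scope="session")
def truth_sweet():
    return {"right": np.array([13.1, -12.4, -4.9]), "left": np.array([-13.1, -12.4, -4.9])}
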