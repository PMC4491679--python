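import numpy as np
import pytest

from protonplan.synthetic import SyntheticPlanSpec, gen_plan


@pytest.fixture(scope="session")
def default_plan():
    """A seeded two-field synthetic plan with organ masks."""
    return gen_plan(SyntheticPlanSpec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
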