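import numpy as np
import pytest

import glycoage as ga


@pytest.fixture(scope="session")
def small_bundle():
    """A modest four-group synthetic cohort shared across tests."""
    cfg = ga.GeneratorConfig(
        n_per_group={
            ("F", "negative"): 80,
            ("F", "positive"): 80,
            ("M", "negative"): 80,
            ("M", "positive"): 80,
        },
        seed=11,
    )
    return ga.generate_cohort(cfg)


@pytest.fixture(scope="session")
def reference():
    return ga.default_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
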