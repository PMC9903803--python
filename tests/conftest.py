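import numpy as np
import pytest

from fpe_famkit.famsim import LiabilityParams, simulate_registry, simulate_trio_cohort


@pytest.fixture(scope="session")
def default_params():
    return LiabilityParams(seed=20260101)


@pytest.fixture(scope="session")
def registry_cohort(default_params):
    """A mid-sized registry population shared across read-only tests."""
    return simulate_registry(default_params, 60_000, seed=20260101)


@pytest.fixture(scope="session")
def quad_cohort(default_params):
    """Ascertained quads: affected child, unaffected parents, unaffected sibling."""
    return simulate_trio_cohort(
        default_params, 4_000,
        require_unaffected_parents=True, require_unaffected_sibling=True,
        seed=20260707,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
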