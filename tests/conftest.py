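import numpy as np
import pytest

from opencomplex import RateConstants
from opencomplex.pipeline import canonical_rates


@pytest.fixture(scope="session")
def fixture_rates() -> RateConstants:
    """Canonical fixture condition (KAc-like kinetics, K_D = 17 nM)."""
    return canonical_rates()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
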