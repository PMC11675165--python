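import warnings

import numpy as np
import pytest

from asecausal.cohort import default_pbihb_like_config, generate_cohort


@pytest.fixture(autouse=True)
def _quiet_vas_warnings():
    # interaction_ace cannot check a DAG for the product treatment; the
    # advisory warning is irrelevant to most tests
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="no DAG supplied", category=UserWarning)
        yield


@pytest.fixture(scope="session")
def default_cohort():
    """The stock synthetic cohort: N = 60, th3 = -0.48, seed 1234."""
    return generate_cohort(default_pbihb_like_config())


@pytest.fixture(scope="session")
def big_cohort():
    """A large draw from the same generating model, for consistency checks."""
    return generate_cohort(default_pbihb_like_config().with_(n=50_000, seed=99))


def seeds(meta: int, count: int) -> list[int]:
    """Replicate seeds derived from one meta-seed (all below 2**31)."""
    rng = np.random.default_rng(meta)
    return [int(s) for s in rng.integers(2**31, size=count)]
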