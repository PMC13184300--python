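import warnings

import numpy as np
import pytest

import gujerdsa as g


@pytest.fixture(scope="session")
def mbc14():
    return g.asm1_model("mbc14")


@pytest.fixture(scope="session")
def original13():
    return g.asm1_model("original13")


@pytest.fixture(scope="session")
def logistic():
    return g.logistic_model(r_g=1.0, K=2.0)


@pytest.fixture(scope="session")
def monod():
    return g.monod_batch_model()


@pytest.fixture(scope="session")
def rotation():
    return g.rotation_model()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


def random_asm1_states(model, rng, n, positive=True):
    """Random non-negative ASM1 state dicts with non-degenerate biomass."""
    lo = 0.1 if positive else 0.0
    out = []
    for _ in range(n):
        out.append(
            {name: float(rng.uniform(lo, 100.0)) for name in model.states.names}
        )
    return out


@pytest.fixture(autouse=True)
def _no_nonneg_warnings_noise():
    # tests evaluate models at arbitrary random states on purpose
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield
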