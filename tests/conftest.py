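import numpy as np
import pytest

import cicdyn as cd


@pytest.fixture(scope="session")
def wt_params():
    return cd.wild_type()


@pytest.fixture(scope="session")
def schedule():
    return cd.CycleSchedule()


@pytest.fixture(scope="session")
def wt_embryo():
    """One noisy wild-type-like kymograph with ground truth (seed 1)."""
    return cd.simulate_embryo(seed=1)


@pytest.fixture(scope="session")
def noiseless_embryo():
    return cd.simulate_embryo(noise=None, seed=1)


@pytest.fixture(scope="session")
def wt_movie():
    """One rendered noisy movie with its generating kymograph and truth."""
    return cd.simulate_movie(seed=4)


@pytest.fixture(scope="session")
def noiseless_movie():
    return cd.simulate_movie(noise=None, seed=3)


@pytest.fixture(scope="session")
def wt_analyses():
    """Analyses of a 10-embryo wild-type-like ensemble (seed 1)."""
    ens = cd.make_ensemble(cd.wild_type(), 10, base_seed=1)
    return [cd.analyze_embryo(stm) for stm, _ in ens], [tr for _, tr in ens]


def rel_rms(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(b**2)))
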