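import numpy as np
import pytest

from srmpmri.synthetic import CohortParams, simulate_patient


def random_spd(rng: np.random.Generator, b: int, cond: float = 50.0) -> np.ndarray:
    """Random symmetric positive-definite matrix with bounded conditioning."""
    q, _ = np.linalg.qr(rng.normal(size=(b, b)))
    lam = np.exp(rng.uniform(0.0, np.log(cond), size=b))
    return (q * lam) @ q.T


@pytest.fixture(scope="session")
def small_params() -> CohortParams:
    return CohortParams(n_patients=4, seed=7)


@pytest.fixture(scope="session")
def one_patient(small_params):
    """A single rendered patient shared across read-only tests."""
    return simulate_patient(small_params, 1)
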