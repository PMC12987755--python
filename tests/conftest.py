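import numpy as np
import pytest

from driftlink.irt_core import ResponseData, irf_2pl
from driftlink.simulation import base_item_bank


@pytest.fixture(scope="session")
def bank10():
    """The 10-item base bank."""
    return base_item_bank(10)


def simulate_two_groups(bank, n, mu2=1.0, sigma2=1.3, delta=None, seed=0):
    """Minimal two-time-point 2PL generator used by unit tests."""
    rng = np.random.default_rng(seed)
    delta = np.zeros(bank.n_items) if delta is None else np.asarray(delta)
    th1 = rng.normal(0.0, 1.0, n)
    th2 = rng.normal(mu2, sigma2, n)
    X1 = (rng.random((n, bank.n_items))
          < irf_2pl(th1[:, None], bank.a, bank.d)).astype(float)
    X2 = (rng.random((n, bank.n_items))
          < irf_2pl(th2[:, None], bank.a, bank.d + delta)).astype(float)
    return ResponseData(np.vstack([X1, X2]),
                        np.r_[np.ones(n, int), np.full(n, 2)],
                        bank.item_ids)


@pytest.fixture(scope="session")
def nodrift_data_small(bank10):
    """N=400 per time point, no drift — shared across calibration tests."""
    return simulate_two_groups(bank10, 400, seed=11)
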