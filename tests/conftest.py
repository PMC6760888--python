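import numpy as np
import pytest

from pdcthresh.claims_io import DispensationRecord, HospitalStay
from pdcthresh.pdc import ObservationWindow


def random_patient(rng: np.random.Generator):
    """One random patient's fills, stays, and observation window."""
    n_fills = int(rng.integers(0, 12))
    fills = [
        DispensationRecord(
            "P0",
            int(rng.integers(-60, 400)),
            int(rng.integers(1, 90)),
        )
        for _ in range(n_fills)
    ]
    n_stays = int(rng.integers(0, 4))
    stays = []
    for _ in range(n_stays):
        a = int(rng.integers(-30, 420))
        stays.append(HospitalStay("P0", a, a + int(rng.integers(1, 40))))
    start = int(rng.integers(-20, 60))
    window = ObservationWindow(start, start + int(rng.integers(30, 500)))
    return fills, stays, window


def random_survival_dataset(rng: np.random.Generator, n: int = 200):
    """(pdc, time, event) arrays with a mild threshold effect and ties."""
    pdc = np.round(rng.beta(2.0, 1.2, n), 2)
    rate = np.where(pdc < rng.uniform(0.3, 0.7), 2.0, 1.0) / 300.0
    time = np.ceil(rng.exponential(1.0 / rate)).astype(int)
    cens = np.ceil(rng.exponential(400.0, n)).astype(int)
    event = time <= cens
    time = np.minimum(time, cens)
    return pdc, time.astype(float), event


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
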