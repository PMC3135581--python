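import numpy as np
import pytest

from crsim import CompetingRisksDataset, build_law, calibrate, control_cohort, generate


@pytest.fixture
def hand_data() -> CompetingRisksDataset:
    """The four-subject worked example: events of cause 1 at t=1 and t=4,
    a competing event at t=2, a censoring at t=3."""
    return CompetingRisksDataset(time=[1.0, 2.0, 3.0, 4.0], status=[1, 2, 0, 1])


@pytest.fixture(scope="session")
def calibrated_spec():
    return calibrate()


@pytest.fixture(scope="session")
def control_data():
    """One surrogate control cohort (n=636) reused across tests."""
    return control_cohort(seed=20260929)


@pytest.fixture(scope="session")
def control_law(control_data):
    return build_law(control_data)


def random_dataset(rng: np.random.Generator, n: int, tie_pool: int | None = None,
                   with_group: bool = False) -> CompetingRisksDataset:
    """Small random dataset, optionally with heavy ties via a small time pool."""
    if tie_pool:
        times = rng.choice(np.linspace(0.5, 5.0, tie_pool), size=n)
    else:
        times = rng.exponential(2.0, size=n) + 1e-3
    status = rng.choice([0, 1, 2], size=n, p=[0.3, 0.45, 0.25])
    if not (status > 0).any():
        status[0] = 1
    group = rng.integers(0, 2, size=n) if with_group else None
    return CompetingRisksDataset(time=times, status=status, group=group)
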