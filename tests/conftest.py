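import numpy as np
import pytest

from sleepval import CohortDataset, Hypnogram


@pytest.fixture
def worked_pair():
    """The hand-worked 10-epoch scorer pair (agreement 8/10, kappa 14/19)."""
    a = Hypnogram.from_stages(["W", "W", "N2", "N2", "N2", "R", "R", "N3", "N3", "W"])
    b = Hypnogram.from_stages(["W", "N1", "N2", "N2", "N2", "R", "W", "N3", "N3", "W"])
    return a, b


@pytest.fixture
def worked_night():
    """The hand-worked metrics night: onset at epoch 2, 6 sleep epochs."""
    return Hypnogram.from_stages(
        ["W", "W", "N1", "N2", "N2", "N3", "R", "W", "R", "W"]
    )


@pytest.fixture
def two_scorer_cohort(worked_pair):
    a, b = worked_pair
    return CohortDataset(
        {
            ("s1", 1, "S1"): a,
            ("s1", 1, "S2"): b,
            ("s1", 2, "S1"): a,
            ("s1", 2, "S2"): a,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
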