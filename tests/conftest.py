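import numpy as np
import pytest

from relapse_frailty.data import CovariateVector, GapRecord, RecurrentEventDataset


def make_covariates(age=25.0, gender=1, marital=1, mode=0, head=0, fam=0):
    return CovariateVector(age, gender, marital, mode, head, fam)


def toy_dataset():
    """Two subjects, two gaps each (second subject censored at rank 2)."""
    covs = {
        "A": make_covariates(age=20.0, gender=1, fam=1),
        "B": make_covariates(age=30.0, gender=0),
    }
    records = [
        GapRecord("A", 1, 12.0, 1),
        GapRecord("A", 2, 6.5, 1),
        GapRecord("B", 1, 40.0, 1),
        GapRecord("B", 2, 10.0, 0),
    ]
    return RecurrentEventDataset(records=records, covariates=covs)


@pytest.fixture
def toy_ds():
    return toy_dataset()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
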