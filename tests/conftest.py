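import numpy as np
import pytest

from grayzone import MarkerDataset, generate_cohort, sii_config

#: hand-enumerated overlap example used across modules: the grey zone at
#: LR targets (3, 2/19) is [5, 9), with 4 non-diseased and 2 diseased inside
WORKED_NEG = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 15.0]
WORKED_POS = [5.0, 8.0, 10.0, 12.0, 14.0]


@pytest.fixture
def worked_dataset() -> MarkerDataset:
    return MarkerDataset.from_groups(WORKED_NEG, WORKED_POS, marker_name="toy")


@pytest.fixture(scope="session")
def sii_cohort() -> MarkerDataset:
    """One calibrated 400/110 SII cohort, fixed seed."""
    return generate_cohort(sii_config(seed=20230709))


def random_overlap_dataset(rng: np.random.Generator, max_per_class: int = 25) -> MarkerDataset:
    """Small random two-class dataset with overlap and occasional ties."""
    n_neg = int(rng.integers(2, max_per_class + 1))
    n_pos = int(rng.integers(2, max_per_class + 1))
    neg = rng.lognormal(mean=0.0, sigma=0.8, size=n_neg)
    pos = rng.lognormal(mean=float(rng.uniform(0.2, 1.5)), sigma=0.8, size=n_pos)
    if rng.uniform() < 0.5:  # force ties across classes, keeping each class
        neg_r, pos_r = np.round(neg, 1), np.round(pos, 1)  # with >= 2 distinct
        if np.unique(neg_r).size >= 2 and np.unique(pos_r).size >= 2:
            neg, pos = neg_r, pos_r
    return MarkerDataset(
        values=np.concatenate([neg, pos]),
        labels=np.concatenate([np.zeros(n_neg, int), np.ones(n_pos, int)]),
    )
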