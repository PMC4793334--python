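import datetime as dt

import numpy as np
import pytest

from bandmove import (
    BandingRecord,
    BetaPrior,
    PriorConfig,
    RecoveryMatrix,
    REGION_ORDER,
    SyntheticTruth,
)


@pytest.fixture
def uniform_psi():
    return np.full((7, 7), 1 / 7)


@pytest.fixture
def small_truth():
    """A small two-band-type scenario with a known movement matrix."""
    psi = np.full((7, 7), 0.05)
    np.fill_diagonal(psi, 0.70)
    psi /= psi.sum(axis=1, keepdims=True)
    cohorts = {
        (bt, region, year): 400
        for bt in ("legacy", "reward")
        for region in REGION_ORDER
        for year in (1970, 1971)
    }
    return SyntheticTruth(
        Psi_true=psi,
        lambda_true={"legacy": 0.4, "reward": 0.95},
        h_true=0.1,
        cohorts=cohorts,
        seed=42,
    )


@pytest.fixture
def toy_matrix():
    """Single-row two-region problem used against the grid oracle."""
    return RecoveryMatrix(
        band_type="toy",
        D=np.array([[30, 10], [0, 0]]),
        N=np.array([1000, 0]),
        regions=("A", "B"),
    )


@pytest.fixture
def flat_priors():
    return PriorConfig(lambda_priors={"toy": BetaPrior(1.0, 1.0)})


def make_record(
    band_id="B1",
    band_type="legacy",
    banding=dt.date(1960, 8, 15),
    banding_region="NE Canada",
    recovery=None,
    recovery_region=None,
):
    return BandingRecord(
        band_id=band_id,
        band_type=band_type,
        banding_date=banding,
        banding_region=banding_region,
        recovery_date=recovery,
        recovery_region=recovery_region,
    )
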