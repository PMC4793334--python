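"""Synthetic banding/recovery datasets with known truth.

The generator is the inverse of the movement model: for every cohort of
birds of band type k banded in region i in year y, a destination region is
drawn from row i of a known row-stochastic matrix Psi_true, and each bird
is independently harvested-and-reported with probability lambda_k * h —
a single Bernoulli collapsing harvest and reporting, mirroring the model's
confounding of the two.  Banding dates fall uniformly in the preseason
window (1 Jul - 30 Sep); recovery dates land in hunting-season months
(Oct-Feb) of the banding year's season or a later one.  Birds that stay in
their banding region are never given a direct (same-season) recovery, since
the selection rules would discard such records — unless they are planted
deliberately as filter bait (``filter_noise``).

A ledger of the exact per-cell recovery counts accompanies every simulated
dataset, so the preprocessing stages can be checked count-for-count.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .records import BandingRecord
from .regions import DEFAULT_REGISTRY, REGION_ORDER

__all__ = [
    "SyntheticTruth",
    "SimLedger",
    "simulate_dataset",
    "make_paper_scale_scenario",
    "PAPER_PSI",
]

# Movement matrix for the built-in demonstration scenario.  Region order is
# (NW Canada, SW Canada, NE Canada, SE Canada, N Atlantic, S Atlantic,
# Interior).  It encodes flyway fidelity (western breeders winter in the
# Interior, eastern breeders on the Atlantic coast), heavy coastal
# wintering mass, tiny stay probabilities for the three northern breeding
# regions, and modest northward movement out of the US regions.
PAPER_PSI = np.array(
    [
        #  NWc    SWc    NEc    SEc    NAtl   SAtl   Int
        [0.033, 0.020, 0.005, 0.022, 0.050, 0.170, 0.700],  # NW Canada
        [0.010, 0.002, 0.005, 0.080, 0.070, 0.130, 0.703],  # SW Canada
        [0.002, 0.003, 0.012, 0.390, 0.330, 0.200, 0.063],  # NE Canada
        [0.002, 0.003, 0.060, 0.135, 0.420, 0.280, 0.100],  # SE Canada
        [0.001, 0.004, 0.030, 0.140, 0.294, 0.420, 0.111],  # N Atlantic
        [0.001, 0.002, 0.010, 0.050, 0.230, 0.550, 0.157],  # S Atlantic
        [0.011, 0.040, 0.020, 0.090, 0.080, 0.209, 0.550],  # Interior
    ]
)

#: Placeholder reporting probabilities per band type.  The real per-type
#: reporting rates are unpublished; these are plausible stand-ins only
#: (mail-in solicitation-era bands report far below web-address bands;
#: reward bands are assumed to report at nearly 1).
PLACEHOLDER_REPORTING = {"mail-in": 0.32, "web": 0.70, "reward": 0.98}

_HUNT_MONTHS = (10, 11, 12, 1, 2)
_HUNT_MONTH_P = (0.30, 0.30, 0.20, 0.12, 0.08)


@dataclass
class SyntheticTruth:
    """Everything a simulation was generated from."""

    Psi_true: np.ndarray
    lambda_true: dict[str, float]
    h_true: float
    cohorts: dict[tuple[str, str, int], int]  # (band_type, region, year) -> banded
    seed: int
    regions: tuple[str, ...] = field(default_factory=lambda: REGION_ORDER)

    def __post_init__(self) -> None:
        self.Psi_true = np.asarray(self.Psi_true, dtype=float)
        if not np.allclose(self.Psi_true.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows of Psi_true must sum to 1")
        for bt, lam in self.lambda_true.items():
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"lambda_true[{bt!r}] outside [0, 1]")
        if not 0.0 <= self.h_true <= 1.0:
            raise ValueError("h_true outside [0, 1]")
        if any(n < 0 for n in self.cohorts.values()):
            raise ValueError("cohort counts must be non-negative")

    def banded_totals(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for (bt, region, _year), n in self.cohorts.items():
            out[(bt, region)] = out.get((bt, region), 0) + n
        return out

    def expected_recoveries(self) -> float:
        return sum(
            n * self.lambda_true[bt] * self.h_true for (bt, _r, _y), n in self.cohorts.items()
        )


@dataclass
class SimLedger:
    """Exact bookkeeping of what the simulator produced."""

    D: dict[str, np.ndarray]  # band_type -> (R, R) recovery counts
    banded: dict[tuple[str, str], int]
    planted: dict[str, int] = field(default_factory=dict)  # filter-rule bait counts

    def total_recoveries(self) -> int:
        return int(sum(m.sum() for m in self.D.values()))


def _preseason_date(rng: np.random.Generator, year: int) -> dt.date:
    start = dt.date(year, 7, 1).toordinal()
    end = dt.date(year, 9, 30).toordinal()
    return dt.date.fromordinal(int(rng.integers(start, end + 1)))


def _hunting_date(rng: np.random.Generator, season: int) -> dt.date:
    month = int(rng.choice(_HUNT_MONTHS, p=_HUNT_MONTH_P))
    year = season + 1 if month <= 2 else season
    return dt.date(year, month, int(rng.integers(1, 29)))


def simulate_dataset(
    truth: SyntheticTruth,
    filter_noise: bool = False,
    include_unrecovered: bool = True,
    n_bait_per_rule: int = 25,
) -> tuple[list[BandingRecord], SimLedger]:
    """Simulate a banding-record dataset from a known truth.

    Returns the record list and a :class:`SimLedger` with the exact per-cell
    recovery counts — after the selection rules, matrix construction must
    reproduce the ledger count-for-count (when ``filter_noise`` is off).

    With ``filter_noise`` on, ``n_bait_per_rule`` extra records violating
    each selection rule (banded outside the preseason; recovered outside the
    hunting months; direct same-region recoveries) are planted and their
    counts recorded in ``ledger.planted``, so filter audits can be checked
    against planted truth.  With ``include_unrecovered`` off, banding-only
    rows are omitted (banded totals must then come from the truth).
    Deterministic given ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    R = len(truth.regions)
    idx = {name: i for i, name in enumerate(truth.regions)}
    D = {bt: np.zeros((R, R), dtype=np.int64) for bt in truth.lambda_true}
    records: list[BandingRecord] = []
    serial = 0

    def new_id() -> str:
        nonlocal serial
        serial += 1
        return f"B{serial:08d}"

    for (bt, region, year), n in sorted(truth.cohorts.items()):
        if n == 0:
            continue
        i = idx[region]
        p_rec = truth.lambda_true[bt] * truth.h_true
        dest_counts = rng.multinomial(n, truth.Psi_true[i])
        recovered = rng.binomial(dest_counts, p_rec)
        D[bt][i] += recovered
        for j, (n_j, r_j) in enumerate(zip(dest_counts, recovered)):
            for _ in range(int(r_j)):
                # stayers must wait a season so the direct-recovery rule
                # cannot discard them; movers may be recovered directly
                min_off = 1 if j == i else 0
                offset = min_off + int(rng.choice([0, 1, 2], p=[0.6, 0.3, 0.1]))
                records.append(
                    BandingRecord(
                        band_id=new_id(),
                        band_type=bt,
                        banding_date=_preseason_date(rng, year),
                        banding_region=truth.regions[i],
                        recovery_date=_hunting_date(rng, year + offset),
                        recovery_region=truth.regions[j],
                    )
                )
            if include_unrecovered:
                for _ in range(int(n_j - r_j)):
                    records.append(
                        BandingRecord(
                            band_id=new_id(),
                            band_type=bt,
                            banding_date=_preseason_date(rng, year),
                            banding_region=truth.regions[i],
                        )
                    )

    planted: dict[str, int] = {}
    if filter_noise:
        bait_type = next(iter(truth.lambda_true))
        years = sorted({y for (_b, _r, y) in truth.cohorts}) or [1980]
        regs = list(truth.regions)
        nb = n_bait_per_rule
        for _ in range(nb):  # rule (a): banded outside the preseason
            y = int(rng.choice(years))
            r1, r2 = rng.choice(R, size=2, replace=False)
            records.append(
                BandingRecord(
                    band_id=new_id(),
                    band_type=bait_type,
                    banding_date=dt.date(y, 6, int(rng.integers(1, 29))),
                    banding_region=regs[r1],
                    recovery_date=_hunting_date(rng, y),
                    recovery_region=regs[r2],
                )
            )
        for _ in range(nb):  # rule (c): recovered outside the hunting months
            y = int(rng.choice(years))
            r1, r2 = rng.choice(R, size=2, replace=False)
            records.append(
                BandingRecord(
                    band_id=new_id(),
                    band_type=bait_type,
                    banding_date=_preseason_date(rng, y),
                    banding_region=regs[r1],
                    recovery_date=dt.date(y + 1, 3, int(rng.integers(1, 29))),
                    recovery_region=regs[r2],
                )
            )
        for _ in range(nb):  # rule (d): direct same-region recovery
            y = int(rng.choice(years))
            r1 = int(rng.integers(R))
            records.append(
                BandingRecord(
                    band_id=new_id(),
                    band_type=bait_type,
                    banding_date=_preseason_date(rng, y),
                    banding_region=regs[r1],
                    recovery_date=_hunting_date(rng, y),
                    recovery_region=regs[r1],
                )
            )
        planted = {
            "banded_outside_preseason": nb,
            "recovery_outside_season": nb,
            "direct_same_region": nb,
        }

    ledger = SimLedger(D=D, banded=truth.banded_totals(), planted=planted)
    return records, ledger


def make_paper_scale_scenario(seed: int = 0) -> SyntheticTruth:
    """A built-in scenario matching the scale of the real 1951-2011 dataset.

    Three band types with distinct (placeholder) reporting probabilities:
    mail-in bands through 1997, web-address bands from 1998, and reward
    bands every fifth year.  Cohort sizes are spread over seven regions and
    61 banding years so that the expected number of reported recoveries,
    sum(cohort * lambda_k * h), is close to 15,000 — the scale left after
    filtering the real data — with harvest rate h = 0.055.
    """
    regions = REGION_ORDER
    # relative banding effort per region (most effort in the eastern breeding
    # grounds and Atlantic coast, where most black ducks are banded)
    effort = {
        "NW Canada": 0.06,
        "SW Canada": 0.04,
        "NE Canada": 0.16,
        "SE Canada": 0.30,
        "N Atlantic": 0.18,
        "S Atlantic": 0.12,
        "Interior": 0.14,
    }
    type_years = {
        "mail-in": list(range(1951, 1998)),
        "web": list(range(1998, 2012)),
        "reward": list(range(1955, 2012, 5)),
    }
    type_totals = {"mail-in": 430_000, "web": 140_000, "reward": 30_000}

    cohorts: dict[tuple[str, str, int], int] = {}
    for bt, years in type_years.items():
        per_year = type_totals[bt] / len(years)
        for year in years:
            for region in regions:
                n = int(round(per_year * effort[region]))
                if n > 0:
                    cohorts[(bt, region, year)] = n

    return SyntheticTruth(
        Psi_true=PAPER_PSI.copy(),
        lambda_true=dict(PLACEHOLDER_REPORTING),
        h_true=0.055,
        cohorts=cohorts,
        seed=seed,
        regions=regions,
    )
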