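"""Record-selection rules and construction of per-band-type recovery matrices.

Only birds banded in the preseason (1 July - 30 September) and recovered
during the hunting season (October - February) enter the analysis.  A
"direct" recovery — one in the hunting season immediately following the
banding period — that occurred in the banding region is excluded, because
such a bird never had an opportunity to move.  A direct recovery in a
*different* region is kept.

Rules are applied in a fixed order so the audit counts are reproducible:

a. banding date inside the preseason window;
b. the record has a recovery at all;
c. recovery month inside the hunting-season months;
d. not a same-region direct recovery.

Hunting seasons straddle the new year: a January or February recovery
belongs to the season that began the previous calendar year
(:func:`season_of`), so a January direct recovery is correctly attributed
to the preceding banding period.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .records import BandingRecord, RecoveryMatrix
from .regions import DEFAULT_REGISTRY, RegionRegistry

__all__ = [
    "FilterConfig",
    "FilterAudit",
    "NOT_IN_SEASON",
    "season_of",
    "filter_records",
    "banded_totals",
    "build_matrices",
]

#: Sentinel returned by :func:`season_of` for dates outside the hunting season.
NOT_IN_SEASON = "not in season"

#: Audit keys, in rule-application order.
RULES = (
    "banded_outside_preseason",
    "no_recovery",
    "recovery_outside_season",
    "direct_same_region",
)


@dataclass(frozen=True)
class FilterConfig:
    """Window definitions for the selection rules.

    ``preseason_window`` is an inclusive (month, day) .. (month, day) range;
    ``hunting_season_months`` is the month set defining recovery
    eligibility.  Months <= 2 (Jan/Feb) are understood to belong to the
    season that started the previous calendar year.
    """

    preseason_window: tuple[tuple[int, int], tuple[int, int]] = ((7, 1), (9, 30))
    hunting_season_months: frozenset[int] = frozenset({10, 11, 12, 1, 2})
    drop_direct_same_region: bool = True

    def __post_init__(self) -> None:
        (m1, d1), (m2, d2) = self.preseason_window
        if (m1, d1) > (m2, d2):
            raise ValueError("preseason window must be non-empty")
        if not self.hunting_season_months:
            raise ValueError("hunting_season_months must be non-empty")

    def in_preseason(self, date: dt.date) -> bool:
        return self.preseason_window[0] <= (date.month, date.day) <= self.preseason_window[1]


@dataclass
class FilterAudit:
    """Per-rule drop counts, in rule order, plus totals."""

    n_input: int = 0
    n_kept: int = 0
    dropped: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict[str, int]:
        out = {"n_input": self.n_input, "n_kept": self.n_kept}
        out.update({rule: self.dropped.get(rule, 0) for rule in RULES})
        return out


def season_of(date: dt.date, cfg: FilterConfig = FilterConfig()) -> int | str:
    """Hunting-season label (year of season start) for a recovery date.

    October-December recoveries belong to the season starting that year;
    January/February recoveries to the season that started the previous
    year.  Dates outside the hunting months return :data:`NOT_IN_SEASON`.
    """
    if date.month not in cfg.hunting_season_months:
        return NOT_IN_SEASON
    return date.year - 1 if date.month <= 2 else date.year


def filter_records(
    records: Sequence[BandingRecord], cfg: FilterConfig = FilterConfig()
) -> tuple[list[BandingRecord], FilterAudit]:
    """Apply the selection rules; return kept records and an audit.

    Pure function: the input list is never mutated.  Idempotent — records
    that survive once survive a second pass unchanged.
    """
    audit = FilterAudit(n_input=len(records))
    kept: list[BandingRecord] = []
    for rec in records:
        if not cfg.in_preseason(rec.banding_date):
            audit.dropped["banded_outside_preseason"] += 1
            continue
        if not rec.recovered:
            audit.dropped["no_recovery"] += 1
            continue
        season = season_of(rec.recovery_date, cfg)
        if season == NOT_IN_SEASON:
            audit.dropped["recovery_outside_season"] += 1
            continue
        if (
            cfg.drop_direct_same_region
            and season == rec.banding_date.year
            and rec.recovery_region == rec.banding_region
        ):
            audit.dropped["direct_same_region"] += 1
            continue
        kept.append(rec)
    audit.n_kept = len(kept)
    return kept, audit


def banded_totals(
    records: Iterable[BandingRecord], cfg: FilterConfig = FilterConfig()
) -> dict[tuple[str, str], int]:
    """Tally birds banded per (band_type, region) over the preseason universe.

    Counts every record whose banding date falls in the preseason window,
    recovered or not: the binomial denominator N_i is the number of birds
    banded, which recoveries alone cannot supply.
    """
    totals: dict[tuple[str, str], int] = defaultdict(int)
    for rec in records:
        if cfg.in_preseason(rec.banding_date):
            totals[(rec.band_type, rec.banding_region)] += 1
    return dict(totals)


def build_matrices(
    records: Sequence[BandingRecord],
    banded: Mapping[tuple[str, str], int],
    registry: RegionRegistry = DEFAULT_REGISTRY,
) -> list[RecoveryMatrix]:
    """Count filtered recoveries into one :class:`RecoveryMatrix` per band type.

    ``banded`` supplies the per-(band_type, region) banded totals N_i (see
    :func:`banded_totals`).  A recovery from a (band_type, region) cell with
    zero banded total is an inconsistency and raises ``ValueError``.
    Matrices are emitted only for band types present in ``records``, sorted
    by band type for determinism.
    """
    R = len(registry.names)
    idx = {name: i for i, name in enumerate(registry.names)}
    by_type: dict[str, np.ndarray] = {}
    years: dict[str, list[int]] = defaultdict(list)
    for rec in records:
        if not rec.recovered:
            raise ValueError(f"band {rec.band_id}: unrecovered record reached build_matrices")
        D = by_type.setdefault(rec.band_type, np.zeros((R, R), dtype=np.int64))
        D[idx[rec.banding_region], idx[rec.recovery_region]] += 1
        years[rec.band_type] += [rec.banding_date.year, rec.recovery_date.year]

    matrices = []
    for band_type in sorted(by_type):
        D = by_type[band_type]
        N = np.zeros(R, dtype=np.int64)
        for region, i in idx.items():
            N[i] = banded.get((band_type, region), 0)
            if D[i].sum() > 0 and N[i] == 0:
                raise ValueError(
                    f"band type {band_type!r}, region {region!r}: recoveries "
                    "present but banded total is zero"
                )
        span = (min(years[band_type]), max(years[band_type]))
        matrices.append(
            RecoveryMatrix(band_type=band_type, D=D, N=N, regions=registry.names, year_span=span)
        )
    return matrices
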