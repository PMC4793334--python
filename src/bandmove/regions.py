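"""The seven-region registry used throughout the pipeline.

The analysis divides eastern North America into four breeding regions
(NW Canada, SW Canada, NE Canada, SE Canada) and three wintering regions
(N Atlantic, S Atlantic, Interior).  Regions are categorical labels here:
no coordinates or polygons are attached.  The registry is closed — any
operation that receives a name outside the seven canonical labels raises
``UnknownRegionError`` rather than silently creating an eighth region.

``north_rank`` is an integer ordering used only for the "moved north"
derived statistic: a movement i -> j counts as northward when
``north_rank(j) > north_rank(i)``.  Wintering regions rank south of all
breeding regions; ties within a latitude band (e.g. NE and NW Canada) are
deliberate so east-west movement within a band is never counted as
northward.  The ranking is overridable via :func:`make_registry`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "Region",
    "RegionRegistry",
    "UnknownRegionError",
    "BREEDING",
    "WINTERING",
    "REGION_ORDER",
    "DEFAULT_REGISTRY",
    "canonical_region",
]

BREEDING: tuple[str, ...] = ("NW Canada", "SW Canada", "NE Canada", "SE Canada")
WINTERING: tuple[str, ...] = ("N Atlantic", "S Atlantic", "Interior")

#: Canonical region order; defines row/column indices of every 7x7 matrix.
REGION_ORDER: tuple[str, ...] = BREEDING + WINTERING

#: Default northward ordering (larger = further north).  Wintering regions
#: sit below all breeding regions; Interior and N Atlantic tie, as do
#: SE/SW Canada and NE/NW Canada.
DEFAULT_NORTH_RANK: dict[str, int] = {
    "S Atlantic": 0,
    "Interior": 1,
    "N Atlantic": 1,
    "SE Canada": 2,
    "SW Canada": 2,
    "NE Canada": 3,
    "NW Canada": 3,
}


class UnknownRegionError(ValueError):
    """Raised when a region name cannot be resolved to a canonical label."""


@dataclass(frozen=True)
class Region:
    name: str
    role: str  # "breeding" | "wintering"
    north_rank: int

    def __post_init__(self) -> None:
        if self.role not in ("breeding", "wintering"):
            raise ValueError(f"role must be 'breeding' or 'wintering', got {self.role!r}")


def _normkey(name: str) -> str:
    """Normalisation key: case-insensitive, punctuation/whitespace tolerant."""
    return re.sub(r"[^a-z]", "", name.lower())


# Accepted spellings beyond the canonical ones (BBL-style exports vary).
_ALIASES: dict[str, str] = {
    "northatlantic": "N Atlantic",
    "natl": "N Atlantic",
    "southatlantic": "S Atlantic",
    "satl": "S Atlantic",
    "northwestcanada": "NW Canada",
    "southwestcanada": "SW Canada",
    "northeastcanada": "NE Canada",
    "southeastcanada": "SE Canada",
    "int": "Interior",
}


@dataclass(frozen=True)
class RegionRegistry:
    """Closed set of exactly seven regions with a fixed index order."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(names) != 7 or len(set(names)) != 7:
            raise ValueError("registry must hold exactly 7 distinct regions")
        n_breed = sum(r.role == "breeding" for r in self.regions)
        if n_breed != 4:
            raise ValueError("registry must hold 4 breeding and 3 wintering regions")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.regions)

    def index(self, name: str) -> int:
        return self.names.index(self.canonical(name))

    def canonical(self, name: str) -> str:
        key = _normkey(name)
        for r in self.regions:
            if _normkey(r.name) == key:
                return r.name
        alias = _ALIASES.get(key)
        if alias is not None and alias in self.names:
            return alias
        raise UnknownRegionError(f"unknown region name: {name!r}")

    def get(self, name: str) -> Region:
        canon = self.canonical(name)
        return next(r for r in self.regions if r.name == canon)

    def role_mask(self, role: str) -> list[bool]:
        return [r.role == role for r in self.regions]

    def north_rank(self, name: str) -> int:
        return self.get(name).north_rank


def make_registry(north_rank: dict[str, int] | None = None) -> RegionRegistry:
    """Build the canonical 7-region registry, optionally with custom ranks."""
    ranks = dict(DEFAULT_NORTH_RANK)
    if north_rank:
        ranks.update(north_rank)
    regions = tuple(
        Region(name, "breeding" if name in BREEDING else "wintering", ranks[name])
        for name in REGION_ORDER
    )
    return RegionRegistry(regions)


DEFAULT_REGISTRY = make_registry()


def canonical_region(name: str) -> str:
    """Resolve ``name`` against the default registry (raises if unknown)."""
    return DEFAULT_REGISTRY.canonical(name)
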