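"""Weighting per-band-type posteriors into one movement table, plus the
derived connectivity summaries (stay, to-wintering, northward).

Each band type is fitted separately because reporting probabilities differ
between types; the per-type posteriors are then combined with weights
proportional to the data each type contributed (its share of recoveries).
The combined posterior is the weighted mixture of the per-type posteriors:
every retained draw of type k enters a pooled sample with weight
w_k / (number of draws of type k).  Weighted pooling is the exact,
deterministic limit of mixture resampling — the combined mean is exactly
sum_k w_k * mean_k, and SDs and central credible intervals are weighted
moments/quantiles of the pooled draws, so uncertainty reflects every type.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import PosteriorDraws
from .records import RecoveryMatrix
from .regions import DEFAULT_REGISTRY, RegionRegistry

__all__ = [
    "PosteriorSummary",
    "band_type_weights",
    "combine_posteriors",
    "summarize_draws",
    "derived_summaries",
]


@dataclass
class PosteriorSummary:
    """Mean/SD/central-95%-CI tables of the movement matrix.

    ``draws``/``draw_weights`` carry the pooled weighted posterior sample
    the tables were computed from, so downstream derived quantities can
    propagate full uncertainty.
    """

    regions: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    weights_used: dict[str, float]
    draws: np.ndarray | None = None  # (M, R, R)
    draw_weights: np.ndarray | None = None  # (M,), sums to 1

    def to_dict(self) -> dict:
        return {
            "regions": list(self.regions),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "ci_low": self.ci_low.tolist(),
            "ci_high": self.ci_high.tolist(),
            "weights_used": self.weights_used,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def band_type_weights(
    matrices: Sequence[RecoveryMatrix], weight_by: str = "recoveries"
) -> dict[str, float]:
    """Weight per band type = its share of the data.

    ``weight_by="recoveries"`` (default) uses total recoveries sum_ij D_ij —
    recoveries are what enter the likelihood; ``"bandings"`` uses banded
    totals instead, for sensitivity checks.  Weights sum to 1.
    """
    if not matrices:
        raise ValueError("need at least one recovery matrix")
    if weight_by == "recoveries":
        raw = {m.band_type: float(m.D.sum()) for m in matrices}
    elif weight_by == "bandings":
        raw = {m.band_type: float(m.N.sum()) for m in matrices}
    else:
        raise ValueError(f"unknown weight_by: {weight_by!r}")
    total = sum(raw.values())
    if total == 0:
        raise ValueError(f"zero total {weight_by}; weights are undefined")
    return {bt: v / total for bt, v in raw.items()}


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> np.ndarray:
    """Weighted quantile along axis 0 of ``values`` (any trailing shape)."""
    order = np.argsort(values, axis=0)
    sorted_vals = np.take_along_axis(values, order, axis=0)
    w = weights[order]
    cum = np.cumsum(w, axis=0)
    cum /= cum[-1:]
    # first index where cumulative weight reaches q
    idx = (cum < q).sum(axis=0)
    idx = np.minimum(idx, values.shape[0] - 1)
    return np.take_along_axis(sorted_vals, idx[None, ...], axis=0)[0]


def _weighted_tables(draws: np.ndarray, w: np.ndarray, ci: float):
    mean = np.tensordot(w, draws, axes=(0, 0))
    var = np.tensordot(w, (draws - mean) ** 2, axes=(0, 0))
    sd = np.sqrt(var)
    lo = _weighted_quantile(draws, w, (1 - ci) / 2)
    hi = _weighted_quantile(draws, w, 1 - (1 - ci) / 2)
    return mean, sd, lo, hi


def combine_posteriors(
    per_type: Sequence[PosteriorDraws],
    weights: Mapping[str, float],
    ci: float = 0.95,
    mean_only: bool = False,
) -> PosteriorSummary:
    """Combine per-band-type posterior draws into one summary.

    Each type's pooled draws receive total weight ``weights[band_type]``,
    split evenly across its own draws, so unequal chain lengths between
    types cannot distort the weighting.  With ``mean_only`` the combination
    is applied to the per-type posterior mean tables alone and SD/CI are the
    weighted averages of the per-type SD/CI tables (a cruder mode kept for
    comparison with the full-posterior mixture).
    """
    if not per_type:
        raise ValueError("no posterior draws supplied")
    missing = [d.band_type for d in per_type if d.band_type not in weights]
    if missing:
        raise ValueError(f"no weight supplied for band type(s) {missing}")
    regions = per_type[0].regions
    if any(d.regions != regions for d in per_type):
        raise ValueError("posterior draws disagree on region order")

    if mean_only:
        mean = sum(weights[d.band_type] * d.mean_psi() for d in per_type)
        parts = [
            _weighted_tables(
                d.pooled_psi(), np.full(d.pooled_psi().shape[0], 1 / d.pooled_psi().shape[0]), ci
            )
            for d in per_type
        ]
        sd = sum(weights[d.band_type] * p[1] for d, p in zip(per_type, parts))
        lo = sum(weights[d.band_type] * p[2] for d, p in zip(per_type, parts))
        hi = sum(weights[d.band_type] * p[3] for d, p in zip(per_type, parts))
        return PosteriorSummary(regions, mean, sd, lo, hi, dict(weights))

    pooled = np.concatenate([d.pooled_psi() for d in per_type], axis=0)
    w = np.concatenate(
        [
            np.full(
                d.pooled_psi().shape[0],
                weights[d.band_type] / d.pooled_psi().shape[0],
            )
            for d in per_type
        ]
    )
    w = w / w.sum()
    mean, sd, lo, hi = _weighted_tables(pooled, w, ci)
    # the exact weighted-average mean; identical to the tensordot up to fp error
    mean = sum(weights[d.band_type] * d.mean_psi() for d in per_type)
    return PosteriorSummary(
        regions, mean, sd, lo, hi, dict(weights), draws=pooled, draw_weights=w
    )


def summarize_draws(draws: PosteriorDraws, ci: float = 0.95) -> PosteriorSummary:
    """Summary tables for a single band type (weight 1)."""
    return combine_posteriors([draws], {draws.band_type: 1.0}, ci=ci)


def derived_summaries(
    summary: PosteriorSummary,
    registry: RegionRegistry = DEFAULT_REGISTRY,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Connectivity summaries per banding region.

    For each banding region i:

    * ``stay``        — Psi_ii, the probability of remaining in the region;
    * ``to_wintering``— sum of Psi_ij over wintering-region columns j;
    * ``northward``   — sum of Psi_ij over regions j ranked north of i.

    Means and central credible intervals are propagated from the pooled
    posterior draws when the summary carries them; otherwise only the point
    values (from the mean table) are reported and CI columns are NaN.
    """
    names = list(summary.regions)
    R = len(names)
    winter = np.array([registry.get(n).role == "wintering" for n in names])
    ranks = np.array([registry.north_rank(n) for n in names])
    north_mask = ranks[None, :] > ranks[:, None]  # [i, j]: j north of i

    def stats(per_draw: np.ndarray | None, point: np.ndarray):
        if per_draw is None:
            nan = np.full(R, np.nan)
            return point, nan, nan
        w = summary.draw_weights
        mean = np.tensordot(w, per_draw, axes=(0, 0))
        lo = _weighted_quantile(per_draw, w, (1 - ci) / 2)
        hi = _weighted_quantile(per_draw, w, 1 - (1 - ci) / 2)
        return mean, lo, hi

    draws = summary.draws
    diag_point = np.diag(summary.mean)
    wint_point = summary.mean[:, winter].sum(axis=1)
    north_point = (summary.mean * north_mask).sum(axis=1)
    stay = stats(None if draws is None else np.diagonal(draws, axis1=1, axis2=2), diag_point)
    to_w = stats(None if draws is None else draws[:, :, winter].sum(axis=2), wint_point)
    north = stats(
        None if draws is None else (draws * north_mask[None]).sum(axis=2), north_point
    )

    return pd.DataFrame(
        {
            "region": names,
            "role": [registry.get(n).role for n in names],
            "stay_mean": stay[0],
            "stay_ci_low": stay[1],
            "stay_ci_high": stay[2],
            "to_wintering_mean": to_w[0],
            "to_wintering_ci_low": to_w[1],
            "to_wintering_ci_high": to_w[2],
            "northward_mean": north[0],
            "northward_ci_low": north[1],
            "northward_ci_high": north[2],
        }
    )
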