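"""Floating catchment area engine.

Implements the two-step floating catchment area (2SFCA) family:

* step 1 — each park j gets a supply-demand ratio
  ``R_j = S_j * W_j / sum_{i: t_ij <= t0} D_i * G(t_ij)``,
  its (quality-weighted) capacity divided by the decay-weighted population
  inside its catchment;
* step 2 — each residential area i sums the ratios of the parks it can
  reach, again decay-weighted:
  ``A_i = sum_{j: t_ij <= t0} R_j * G(t_ij)``.

``G`` is either a truncated Gaussian kernel (G2SFCA) or the classic 0/1
catchment indicator (plain 2SFCA).  With ``use_weights`` the park quality
score W_j enters step 1, expressing supply competition: a higher-rated park
draws demand from a wider pool but also offers more.  Per-mode fields are
combined into a single composite by the daily travel-mode split.

The engine is unit-agnostic: costs may be minutes against a time threshold
or straight-line distances against a distance threshold.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    AccessibilityField,
    DecaySpec,
    DemandSite,
    ModeMix,
    SupplySite,
    TravelCostMatrix,
    sort_sites,
)

logger = logging.getLogger(__name__)

__all__ = [
    "gaussian_decay",
    "indicator_decay",
    "decay_weights",
    "supply_demand_ratios",
    "accessibility",
    "combine_modes",
    "run_scm_g2sfca",
    "ScmResult",
]

_HALF = np.exp(-0.5)


def _check_costs(cost: np.ndarray, threshold: float) -> np.ndarray:
    cost = np.asarray(cost, dtype=float)
    if np.isnan(cost).any():
        raise ValueError("cost contains NaN")
    if np.isneginf(cost).any():
        raise ValueError("cost contains -inf (only +inf marks unreachable pairs)")
    if (cost[np.isfinite(cost)] < 0).any():
        raise ValueError("cost must be nonnegative")
    if not np.isfinite(threshold) or threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold!r}")
    return cost


def gaussian_decay(cost, threshold: float):
    """Truncated Gaussian distance-decay kernel.

    ``G(t) = (exp(-(1/2)(t/t0)^2) - exp(-1/2)) / (1 - exp(-1/2))`` for
    ``t <= t0`` and exactly 0 beyond, so G(0) = 1, G(t0) = 0 and G is
    continuous and strictly decreasing on [0, t0].  ``+inf`` (unreachable)
    maps to 0.  Accepts scalars or arrays.
    """
    cost_arr = _check_costs(cost, threshold)
    with np.errstate(over="ignore"):
        g = (np.exp(-0.5 * (cost_arr / threshold) ** 2) - _HALF) / (1.0 - _HALF)
    g = np.where(cost_arr <= threshold, g, 0.0)
    return float(g) if np.isscalar(cost) else g


def indicator_decay(cost, threshold: float):
    """Sharp catchment membership: 1 inside the threshold (inclusive), 0 out."""
    cost_arr = _check_costs(cost, threshold)
    g = np.where(cost_arr <= threshold, 1.0, 0.0)
    return float(g) if np.isscalar(cost) else g


def decay_weights(cost, decay: DecaySpec):
    """Evaluate the kernel named by ``decay`` on ``cost``."""
    fn = gaussian_decay if decay.kind == "gaussian" else indicator_decay
    return fn(cost, decay.threshold)


def _prepare(demand, supply, costs: TravelCostMatrix):
    demand = sort_sites(demand)
    supply = sort_sites(supply)
    d_ids = [s.site_id for s in demand]
    s_ids = [s.site_id for s in supply]
    if set(d_ids) != set(costs.origin_ids) or set(s_ids) != set(costs.dest_ids):
        raise ValueError(
            f"cost matrix for mode {costs.mode!r} covers "
            f"{len(costs.origin_ids)}x{len(costs.dest_ids)} sites; "
            f"scenario has {len(d_ids)} demand x {len(s_ids)} supply"
        )
    cost = costs.aligned(d_ids, s_ids)
    return demand, supply, d_ids, s_ids, cost


def supply_demand_ratios(
    demand: Sequence[DemandSite],
    supply: Sequence[SupplySite],
    costs: TravelCostMatrix,
    decay: DecaySpec,
    use_weights: bool = True,
) -> pd.Series:
    """First catchment step: per-park supply-demand ratios R_j.

    A park whose decay-weighted catchment population is zero (no demand site
    within the threshold, or only zero-population sites) gets R_j = 0 with a
    logged warning: an unreachable park serves nobody rather than raising.
    """
    demand, supply, d_ids, s_ids, cost = _prepare(demand, supply, costs)
    g = decay_weights(cost, decay)  # (n_demand, n_supply)
    pop = np.array([s.population for s in demand])
    denom = pop @ g  # per-supply decay-weighted population
    numer = np.array(
        [s.supply_scale * (s.weight if use_weights else 1.0) for s in supply]
    )
    empty = denom <= 0.0
    if empty.any():
        names = [s_ids[k] for k in np.flatnonzero(empty)]
        logger.warning(
            "%d supply site(s) with empty catchment get ratio 0: %s",
            len(names),
            ", ".join(names[:10]) + ("..." if len(names) > 10 else ""),
        )
    ratios = np.where(empty, 0.0, numer / np.where(empty, 1.0, denom))
    return pd.Series(ratios, index=pd.Index(s_ids, name="site_id"), name="R")


def accessibility(
    demand: Sequence[DemandSite],
    supply: Sequence[SupplySite],
    costs: TravelCostMatrix,
    decay: DecaySpec,
    use_weights: bool = True,
) -> AccessibilityField:
    """Both catchment steps for one mode: the accessibility field A_i.

    A demand site that can reach no park within the threshold gets exactly 0.
    """
    ratios = supply_demand_ratios(demand, supply, costs, decay, use_weights)
    demand, supply, d_ids, s_ids, cost = _prepare(demand, supply, costs)
    g = decay_weights(cost, decay)
    values = g @ ratios.to_numpy()
    return AccessibilityField(
        mode=costs.mode,
        values=pd.Series(values, index=pd.Index(d_ids, name="site_id"), name="A"),
        supply_ratios=ratios,
    )


def combine_modes(
    per_mode: Mapping[str, AccessibilityField], mix: ModeMix
) -> AccessibilityField:
    """Convex combination of per-mode fields by daily-trip shares.

    ``A_i = sum_n W_Mn * A_i,Mn``; every combined value therefore lies
    between the per-mode minimum and maximum for that site.
    """
    if set(per_mode.keys()) != set(mix.modes):
        raise ValueError(
            f"mode mismatch: fields for {sorted(per_mode)} vs mix {sorted(mix.modes)}"
        )
    index = None
    total = None
    for mode in mix.modes:
        f = per_mode[mode]
        vals = f.values.sort_index()
        if index is None:
            index = vals.index
            total = np.zeros(len(index))
        elif not vals.index.equals(index):
            raise ValueError(
                f"field for mode {mode!r} covers different demand sites"
            )
        total = total + mix.share(mode) * vals.to_numpy()
    return AccessibilityField(
        mode="combined", values=pd.Series(total, index=index, name="A")
    )


class ScmResult:
    """Output bundle of the multimodal model: per-mode fields + composite."""

    def __init__(self, per_mode: Mapping[str, AccessibilityField], combined: AccessibilityField):
        self.per_mode = dict(per_mode)
        self.combined = combined

    def values_frame(self) -> pd.DataFrame:
        """Long table: site_id, mode, A (per-mode rows then the composite)."""
        rows = []
        for mode in sorted(self.per_mode):
            f = self.per_mode[mode]
            rows.append(
                pd.DataFrame(
                    {"site_id": f.values.index, "mode": mode, "A": f.values.to_numpy()}
                )
            )
        c = self.combined
        rows.append(
            pd.DataFrame(
                {"site_id": c.values.index, "mode": "combined", "A": c.values.to_numpy()}
            )
        )
        return pd.concat(rows, ignore_index=True)

    def ratios_frame(self) -> pd.DataFrame:
        """Long table: park_id, mode, R."""
        rows = []
        for mode in sorted(self.per_mode):
            r = self.per_mode[mode].supply_ratios
            rows.append(
                pd.DataFrame(
                    {"park_id": r.index, "mode": mode, "R": r.to_numpy()}
                )
            )
        return pd.concat(rows, ignore_index=True)


def run_scm_g2sfca(
    demand: Sequence[DemandSite],
    supply: Sequence[SupplySite],
    costs: Union[Mapping[str, TravelCostMatrix], Sequence[TravelCostMatrix]],
    decay: DecaySpec,
    mix: ModeMix,
    use_weights: bool = True,
) -> ScmResult:
    """Full multimodal model: one catchment pass per mode, then compositing.

    ``costs`` supplies one travel-cost matrix per mode in ``mix``; per-mode
    supply-demand ratios are retained on the per-mode fields of the result.
    """
    if not isinstance(costs, Mapping):
        costs = {m.mode: m for m in costs}
    missing = [m for m in mix.modes if m not in costs]
    if missing:
        raise ValueError(f"no cost matrix for mode(s): {missing}")
    per_mode = {
        mode: accessibility(demand, supply, costs[mode], decay, use_weights)
        for mode in mix.modes
    }
    return ScmResult(per_mode, combine_modes(per_mode, mix))
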