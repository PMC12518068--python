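"""Loss-adjusted greenhouse gas footprints of composite foods.

A consumed food decomposes into primary commodities; each commodity carries a
footprint per gram and a farm-to-fork loss percentage.  The loss inflates the
footprint per *consumed* gram by 100/(100 - loss), so the footprint of a food
per 100 g is

    sum_i  weight_i (g/100 g) * ghge_i (kg CO2 eq/g) * 100 / (100 - loss_i)

Diet-level totals are linear in quantities (g/day) and can be attributed to
food groups under any classification without loss of mass balance.
"""

from __future__ import annotations

import logging
from typing import Mapping, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .food_system_io import Classification, Diet, FoodSystem

log = logging.getLogger(__name__)

#: key under which sub-threshold groups are pooled by group_ghge_contributions
SMALL_GROUPS_KEY = "_small_groups"


class FootprintError(ValueError):
    pass


def item_footprint(
    shares: Mapping[str, float],
    footprints: Mapping[str, float],
    losses: Mapping[str, float],
    *,
    missing_loss: str = "warn",
) -> float:
    """Loss-adjusted footprint of one food, kg CO2 eq per 100 g.

    Parameters
    ----------
    shares
        commodity_id -> grams of commodity per 100 g of food.
    footprints
        commodity_id -> kg CO2 eq per gram of commodity.
    losses
        commodity_id -> percent of commodity weight lost farm to fork,
        in [0, 100).
    missing_loss
        "warn" treats an absent loss factor as 0% with a logged warning;
        "error" raises.
    """
    total = 0.0
    for commodity_id, weight in shares.items():
        if weight < 0:
            raise FootprintError(f"negative weight for commodity {commodity_id!r}")
        if commodity_id not in footprints:
            raise FootprintError(f"unknown commodity {commodity_id!r}")
        if commodity_id in losses:
            loss = losses[commodity_id]
        elif missing_loss == "warn":
            log.warning("no loss factor for commodity %r; assuming 0%%", commodity_id)
            loss = 0.0
        else:
            raise FootprintError(f"no loss factor for commodity {commodity_id!r}")
        if not 0.0 <= loss < 100.0:
            raise FootprintError(
                f"commodity {commodity_id!r}: loss_pct {loss} outside [0, 100)"
            )
        total += weight * footprints[commodity_id] * 100.0 / (100.0 - loss)
    return total


def derive_item_footprints(system: "FoodSystem", *, missing_loss: str = "warn"
                           ) -> dict[str, float]:
    """Footprint per 100 g for every item with a commodity decomposition."""
    return {
        item_id: item_footprint(
            shares, system.commodity_ghge, system.loss_factors,
            missing_loss=missing_loss,
        )
        for item_id, shares in system.commodity_shares.items()
    }


def diet_ghge(diet: "Diet", item_footprints: Mapping[str, float]) -> float:
    """Total footprint of a diet, kg CO2 eq per day (linear in quantities)."""
    total = 0.0
    for item_id, grams in diet.quantities.items():
        if grams == 0:
            continue
        if item_id not in item_footprints:
            raise FootprintError(f"consumed item {item_id!r} has no footprint")
        total += grams / 100.0 * item_footprints[item_id]
    return total


def group_ghge_contributions(
    diet: "Diet",
    item_footprints: Mapping[str, float],
    classification: "Classification",
    *,
    min_items: int | None = None,
) -> dict[str, float]:
    """Attribute the diet footprint to food groups (fixed items included).

    Contributions always sum to :func:`diet_ghge`.  With ``min_items`` set
    (3 in the standard contribution report), groups with fewer assigned items
    are pooled under :data:`SMALL_GROUPS_KEY` so the total is conserved.
    """
    group_sizes: dict[str, int] = {}
    for group_id in classification.assignment.values():
        group_sizes[group_id] = group_sizes.get(group_id, 0) + 1

    out: dict[str, float] = {}
    for item_id, grams in diet.quantities.items():
        if grams == 0:
            continue
        if item_id not in item_footprints:
            raise FootprintError(f"consumed item {item_id!r} has no footprint")
        group_id = classification.assignment[item_id]
        if min_items is not None and group_sizes.get(group_id, 0) < min_items:
            group_id = SMALL_GROUPS_KEY
        out[group_id] = out.get(group_id, 0.0) + grams / 100.0 * item_footprints[
            item_id
        ]
    return out
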