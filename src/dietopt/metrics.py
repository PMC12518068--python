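"""Acceptability measures comparing optimized diets with observed diets.

Total dietary change is the aggregate absolute quantity difference relative
to total observed intake, 100 * sum|x - o| / sum(o).  It is zero only for
identical diets, unchanged under joint rescaling, and can exceed 100% (e.g.
doubling every quantity is a 100% change; replacing the whole diet with new
items approaches 200%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .food_system_io import Classification, Diet

#: quantities below this many g/day count as absent from a diet
PRESENCE_THRESHOLD = 0.01


class MetricsError(ValueError):
    pass


@dataclass
class DiversityReport:
    """Item-count and concentration measures of one optimized diet."""

    n_items: int
    pct_removed: float
    avg_max_share: float
    per_group_shares: dict[str, float] = field(default_factory=dict)
    n_empty_groups: int = 0


def total_dietary_change(observed: "Diet", optimized: "Diet") -> float:
    """Percent total dietary change: 100 * sum_i |x_i - o_i| / sum_i o_i."""
    items = set(observed.quantities) | set(optimized.quantities)
    denom = sum(observed.quantities.values())
    if denom <= 0:
        raise MetricsError("observed diet has zero total mass")
    num = sum(abs(optimized.get(i) - observed.get(i)) for i in items)
    return 100.0 * num / denom


def diversity_report(
    diet: "Diet",
    observed: "Diet",
    classification: "Classification",
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> DiversityReport:
    """Count surviving items and within-group concentration of a diet.

    An observed item counts as removed when its optimized quantity falls
    below ``presence_threshold``.  The max-share average runs over groups
    with positive optimized mass; emptied groups are counted separately.
    """
    if presence_threshold < 0:
        raise MetricsError("presence_threshold must be >= 0")

    present = {
        i for i, q in diet.quantities.items() if q >= presence_threshold and q > 0
    }
    observed_present = {
        i for i, q in observed.quantities.items()
        if q >= presence_threshold and q > 0
    }
    removed = observed_present - present
    pct_removed = (
        100.0 * len(removed) / len(observed_present) if observed_present else 0.0
    )

    group_totals: dict[str, float] = {}
    group_max: dict[str, float] = {}
    for item_id, q in diet.quantities.items():
        if q <= 0:
            continue
        g = classification.assignment.get(item_id)
        if g is None:
            continue
        group_totals[g] = group_totals.get(g, 0.0) + q
        group_max[g] = max(group_max.get(g, 0.0), q)

    shares = {
        g: group_max[g] / total
        for g, total in group_totals.items()
        if total > 0
    }
    n_empty = sum(
        1
        for g in classification.groups
        if any(classification.assignment.get(i) == g for i in observed_present)
        and group_totals.get(g, 0.0) <= 0
    )
    avg = sum(shares.values()) / len(shares) if shares else 0.0
    return DiversityReport(
        n_items=len(present),
        pct_removed=pct_removed,
        avg_max_share=avg,
        per_group_shares=shares,
        n_empty_groups=n_empty,
    )


def snap_to_zero(diet: "Diet", threshold: float) -> "Diet":
    """Zero out numerically-tiny quantities before computing metrics."""
    from .food_system_io import Diet as _Diet

    return _Diet(
        label=diet.label,
        quantities={
            i: (0.0 if q < threshold else q) for i, q in diet.quantities.items()
        },
    )
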