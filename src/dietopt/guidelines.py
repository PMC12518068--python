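"""Nutrient guideline sets, diet nutrient accounting, and deviation measures.

Deviations are minimax quantities: the largest relative violation across the
constraints of a block (macronutrient bounds, or micronutrient reference
amounts).  They are dimensionless fractions, zero exactly when every bound in
the block is met, and piecewise linear in diet quantities — which is what the
optimizer's linear formulation exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .food_system_io import Diet, FoodSystem

LEVEL_FULL = "full"
LEVEL_LOWERED = "lowered"

RDA = "rda"
EAR = "ear"

#: factor applied to macro bounds when lowering goals: lower * 0.8, upper * 1.2
RELAX_LOWER = 0.8
RELAX_UPPER = 1.2


class GuidelineError(ValueError):
    pass


@dataclass(frozen=True)
class MicroRef:
    """Reference intake amounts per day for one micronutrient."""

    rda: float
    ear: float
    unit: str = ""

    def __post_init__(self) -> None:
        if self.rda <= 0 or self.ear <= 0:
            raise GuidelineError("reference amounts must be positive")
        if self.ear > self.rda:
            raise GuidelineError("ear must not exceed rda")

    def amount(self, target: str) -> float:
        if target == RDA:
            return self.rda
        if target == EAR:
            return self.ear
        raise GuidelineError(f"unknown micronutrient target {target!r}")


@dataclass(frozen=True)
class GuidelineSet:
    """Macronutrient bounds plus micronutrient reference values.

    ``macro_energy_bounds`` maps a macro_energy nutrient to (lower, upper) in
    E%; either side may be None (e.g. SFA is upper-only).
    ``macro_mass_bounds`` maps a macro_mass nutrient to (lower, upper) in its
    own mass unit per day (fiber lower-only, sodium upper-only).
    """

    macro_energy_bounds: dict[str, tuple[float | None, float | None]]
    macro_mass_bounds: dict[str, tuple[float | None, float | None]]
    micro_refs: dict[str, MicroRef]
    level: str = LEVEL_FULL
    micro_target: str = RDA

    def __post_init__(self) -> None:
        for nid, (lo, hi) in {
            **self.macro_energy_bounds,
            **self.macro_mass_bounds,
        }.items():
            if lo is None and hi is None:
                raise GuidelineError(f"{nid!r}: bound with neither side set")
            if lo is not None and hi is not None and not lo < hi:
                raise GuidelineError(f"{nid!r}: lower bound must be < upper")

    def iter_bounds(self):
        """Yield (nutrient_id, scale, lower, upper) for every macro constraint.

        ``scale`` is "energy_pct" or "mass" and says in which space the bound
        lives.
        """
        for nid, (lo, hi) in sorted(self.macro_energy_bounds.items()):
            yield nid, "energy_pct", lo, hi
        for nid, (lo, hi) in sorted(self.macro_mass_bounds.items()):
            yield nid, "mass", lo, hi

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "micro_target": self.micro_target,
            "macro_energy_bounds": {
                n: list(b) for n, b in sorted(self.macro_energy_bounds.items())
            },
            "macro_mass_bounds": {
                n: list(b) for n, b in sorted(self.macro_mass_bounds.items())
            },
            "micro_refs": {
                n: {"rda": r.rda, "ear": r.ear, "unit": r.unit}
                for n, r in sorted(self.micro_refs.items())
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GuidelineSet":
        return cls(
            macro_energy_bounds={
                n: (b[0], b[1]) for n, b in d["macro_energy_bounds"].items()
            },
            macro_mass_bounds={
                n: (b[0], b[1]) for n, b in d["macro_mass_bounds"].items()
            },
            micro_refs={n: MicroRef(**r) for n, r in d["micro_refs"].items()},
            level=d.get("level", LEVEL_FULL),
            micro_target=d.get("micro_target", RDA),
        )


@dataclass(frozen=True)
class NutrientProfile:
    """Daily nutrient totals of a diet, with macronutrient energy shares."""

    totals: dict[str, float]  # nutrient_id -> amount/day
    energy: float  # kcal/day
    energy_shares: dict[str, float] = field(default_factory=dict)  # E%

    @property
    def degenerate(self) -> bool:
        """True for an empty/zero-energy diet where E% shares are undefined."""
        return self.energy <= 0


def diet_profile(diet: "Diet", system: "FoodSystem") -> NutrientProfile:
    """Quantity-weighted nutrient totals and energy of a diet (linear)."""
    totals = {nid: 0.0 for nid in system.nutrient_defs}
    energy = 0.0
    for item_id, grams in diet.quantities.items():
        item = system.items[item_id]
        frac = grams / 100.0
        energy += frac * item.energy
        for nid in totals:
            totals[nid] += frac * item.nutrients.get(nid, 0.0)
    shares: dict[str, float] = {}
    if energy > 0:
        for nid, ndef in system.nutrient_defs.items():
            if ndef.kind == "macro_energy":
                shares[nid] = 100.0 * ndef.atwater * totals[nid] / energy
    return NutrientProfile(totals=totals, energy=energy, energy_shares=shares)


def _relative_violation(value: float, lower: float | None, upper: float | None
                        ) -> float:
    dev = 0.0
    if lower is not None and lower > 0:
        dev = max(dev, (lower - value) / lower)
    if upper is not None and upper > 0:
        dev = max(dev, (value - upper) / upper)
    return max(dev, 0.0)


def macro_deviation(profile: NutrientProfile, guidelines: GuidelineSet) -> float:
    """Largest relative violation of the macronutrient (and sodium/fiber) bounds.

    macro_energy nutrients are evaluated in E%, macro_mass nutrients in their
    mass amount per day.  Returns 0 iff every bound is met.
    """
    if profile.degenerate:
        raise GuidelineError("macro deviation undefined at zero energy")
    worst = 0.0
    for nid, scale, lo, hi in guidelines.iter_bounds():
        value = (
            profile.energy_shares.get(nid, 0.0)
            if scale == "energy_pct"
            else profile.totals.get(nid, 0.0)
        )
        worst = max(worst, _relative_violation(value, lo, hi))
    return worst


def micro_deviation(
    profile: NutrientProfile,
    refs: Mapping[str, MicroRef],
    target: str = RDA,
) -> float:
    """Largest relative shortfall below the reference amounts (excess is free)."""
    if not refs:
        raise GuidelineError("no micronutrient references given")
    worst = 0.0
    for nid, ref in refs.items():
        amount = ref.amount(target)
        if amount <= 0:
            raise GuidelineError(f"{nid!r}: zero reference amount")
        intake = profile.totals.get(nid, 0.0)
        worst = max(worst, max(0.0, (amount - intake) / amount))
    return worst


def relax_guidelines(guidelines: GuidelineSet) -> GuidelineSet:
    """Lower the nutrient goals: stretch macro bounds by 20%, switch RDA→EAR.

    Every macro lower bound is multiplied by 0.8 and every upper bound by 1.2
    (e.g. protein 10–35 E% becomes 8–42 E%); the micronutrient target drops
    from RDA to EAR.  Applying this to an already-lowered set is an error so
    goals cannot silently be relaxed twice.
    """
    if guidelines.level != LEVEL_FULL:
        raise GuidelineError("guidelines already lowered")

    def stretch(bounds):
        return {
            n: (
                None if lo is None else lo * RELAX_LOWER,
                None if hi is None else hi * RELAX_UPPER,
            )
            for n, (lo, hi) in bounds.items()
        }

    return replace(
        guidelines,
        macro_energy_bounds=stretch(guidelines.macro_energy_bounds),
        macro_mass_bounds=stretch(guidelines.macro_mass_bounds),
        level=LEVEL_LOWERED,
        micro_target=EAR,
    )


def default_guidelines(fiber_lower_g: float = 28.0) -> GuidelineSet:
    """US-style default guideline set (config defaults, not ground truth).

    Protein 10–35 E%, carbohydrate 45–65 E%, fat 20–35 E%, SFA ≤10 E%,
    sodium ≤2,300 mg/day, fiber lower bound defaulting to 14 g per 1,000 kcal
    at a 2,000 kcal reference intake; micronutrient RDA/EAR values from adult
    (female where sex-specific) DRI tables.
    """
    return GuidelineSet(
        macro_energy_bounds={
            "protein": (10.0, 35.0),
            "carbohydrate": (45.0, 65.0),
            "fat": (20.0, 35.0),
            "sfa": (None, 10.0),
        },
        macro_mass_bounds={
            "fiber": (fiber_lower_g, None),
            "sodium": (None, 2300.0),
        },
        micro_refs={
            "calcium": MicroRef(rda=1000.0, ear=800.0, unit="mg"),
            "folate": MicroRef(rda=400.0, ear=320.0, unit="ug"),
            "iron": MicroRef(rda=18.0, ear=8.1, unit="mg"),
            "magnesium": MicroRef(rda=320.0, ear=265.0, unit="mg"),
            "vitamin_a": MicroRef(rda=700.0, ear=500.0, unit="ug"),
            "vitamin_e": MicroRef(rda=15.0, ear=12.0, unit="mg"),
        },
    )
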