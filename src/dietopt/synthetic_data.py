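"""Generation of synthetic food systems with known statistical structure.

The generator emulates the shape of national food-consumption data without
any download: hierarchically classified food items with heavy right-skewed
(log-normal) within-group spread of nutrient content and footprints,
Dirichlet-concentrated observed diets, a configurable set of guideline
violations ("bottlenecks") realized exactly in the female observed diet, and
commodity decompositions whose loss-adjusted footprints reproduce each item's
stored GHGE to numerical precision.

It also builds small adversarial instances with analytically known optima,
used as independent oracles for the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .food_system_io import (
    Classification,
    FoodSystemError,
    Diet,
    FoodItem,
    FoodSystem,
    NutrientDef,
    Respondent,
    mark_fixed_items,
)
from .guidelines import GuidelineSet, MicroRef, default_guidelines, diet_profile

SHORT = "short"
EXCESS = "excess"

KNOWN_OPTIMUM_KINDS = (
    "within_swap",
    "between_removal",
    "infeasible_cap",
    "adequacy_vs_ghge",
)


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Bottleneck:
    """A guideline the observed diet must violate, with its magnitude.

    ``direction`` is "short" (below a lower bound / reference) or "excess"
    (above an upper bound); ``magnitude`` is the relative violation, e.g. 0.3
    for a 30% shortfall.
    """

    nutrient_id: str
    direction: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.direction not in (SHORT, EXCESS):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not 0 < self.magnitude < 1:
            raise ValueError("magnitude must be in (0, 1)")


DEFAULT_BOTTLENECKS = (
    Bottleneck("iron", SHORT, 0.30),
    Bottleneck("vitamin_e", SHORT, 0.40),
    Bottleneck("fiber", SHORT, 0.30),
    Bottleneck("sodium", EXCESS, 0.20),
    Bottleneck("sfa", EXCESS, 0.10),
    Bottleneck("fat", EXCESS, 0.08),
)


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic food-system generator."""

    n_groups: int = 40
    n_groups_medium: int = 16
    n_groups_coarse: int = 6
    items_per_group: tuple[int, int] = (3, 12)
    nutrient_sigma: float = 0.5  # within-group log-scale sd, nutrients
    ghge_sigma: float = 0.6  # within-group log-scale sd, footprints
    frac_fixed_items: float = 0.10
    frac_unconsumed: float = 0.20  # items with zero observed quantity
    diet_mass_per_group: tuple[float, float] = (50.0, 400.0)
    bottlenecks: tuple[Bottleneck, ...] = DEFAULT_BOTTLENECKS
    max_retries: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nutrient_sigma < 0 or self.ghge_sigma < 0:
            raise ValueError("dispersions must be >= 0")
        if not 0 <= self.frac_fixed_items < 1:
            raise ValueError("frac_fixed_items must be in [0, 1)")


# global ranges the per-group means are drawn from (per 100 g)
_NUTRIENT_RANGES = {
    "protein": (2.0, 20.0),
    "carbohydrate": (5.0, 50.0),
    "fat": (1.0, 25.0),
    "fiber": (0.5, 6.0),
    "sodium": (50.0, 800.0),
    "calcium": (20.0, 300.0),
    "folate": (5.0, 120.0),
    "iron": (0.5, 6.0),
    "magnesium": (10.0, 120.0),
    "vitamin_a": (5.0, 300.0),
    "vitamin_e": (0.1, 4.0),
}
_GHGE_RANGE = (0.05, 1.5)  # kg CO2 eq per 100 g, group means


def default_nutrient_defs() -> dict[str, NutrientDef]:
    defs = {
        "protein": NutrientDef("protein", "Protein", "g", "macro_energy", 4.0),
        "carbohydrate": NutrientDef(
            "carbohydrate", "Carbohydrate", "g", "macro_energy", 4.0
        ),
        "fat": NutrientDef("fat", "Total fat", "g", "macro_energy", 9.0),
        "sfa": NutrientDef("sfa", "Saturated fatty acids", "g", "macro_energy", 9.0),
        "fiber": NutrientDef("fiber", "Dietary fiber", "g", "macro_mass"),
        "sodium": NutrientDef("sodium", "Sodium", "mg", "macro_mass"),
        "calcium": NutrientDef("calcium", "Calcium", "mg", "micro"),
        "folate": NutrientDef("folate", "Folate", "ug", "micro"),
        "iron": NutrientDef("iron", "Iron", "mg", "micro"),
        "magnesium": NutrientDef("magnesium", "Magnesium", "mg", "micro"),
        "vitamin_a": NutrientDef("vitamin_a", "Vitamin A", "ug", "micro"),
        "vitamin_e": NutrientDef("vitamin_e", "Vitamin E", "mg", "micro"),
    }
    return defs


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def generate_food_system(params: GeneratorParams) -> FoodSystem:
    """Generate a complete food system realizing the requested bottlenecks.

    The female observed diet violates each configured bottleneck guideline at
    exactly its target magnitude (nutrient columns are rescaled to the target,
    so the post-hoc check holds to numerical precision); remaining guidelines
    are calibrated to be met.  Item footprints are backed by commodity
    decompositions (1-4 commodities, losses in [0, 50)%) that reproduce the
    stored GHGE.  Deterministic under ``params.seed``.
    """
    last_error: Exception | None = None
    for attempt in range(params.max_retries):
        rng = np.random.default_rng((params.seed, attempt))
        try:
            return _generate_once(params, rng)
        except (GenerationError, FoodSystemError) as err:  # resample
            last_error = err
    raise GenerationError(
        f"retry cap exceeded ({params.max_retries}); last failure: {last_error}"
    )


def _generate_once(params: GeneratorParams, rng: np.random.Generator) -> FoodSystem:
    defs = default_nutrient_defs()
    lo_items, hi_items = params.items_per_group

    items: dict[str, FoodItem] = {}
    fine_assignment: dict[str, str] = {}
    fine_groups: dict[str, str] = {}
    for g in range(params.n_groups):
        gid = f"g{g:03d}"
        fine_groups[gid] = f"Group {g:03d}"
        group_means = {
            nid: rng.uniform(*bounds) for nid, bounds in _NUTRIENT_RANGES.items()
        }
        ghge_mean = rng.uniform(*_GHGE_RANGE)
        n_items = int(rng.integers(lo_items, hi_items + 1))
        for k in range(n_items):
            item_id = f"i{g:03d}_{k:02d}"
            nutrients = {
                nid: mean * _lognormal(rng, params.nutrient_sigma)
                for nid, mean in group_means.items()
            }
            nutrients["sfa"] = nutrients["fat"] * rng.uniform(0.15, 0.55)
            energy = (
                4.0 * (nutrients["protein"] + nutrients["carbohydrate"])
                + 9.0 * nutrients["fat"]
            )
            ghge = ghge_mean * _lognormal(rng, params.ghge_sigma)
            items[item_id] = FoodItem(
                item_id=item_id,
                name=f"Item {item_id}",
                energy=energy,
                nutrients=nutrients,
                ghge=ghge,
                occurrences=int(rng.integers(4, 500)),
            )
            fine_assignment[item_id] = gid

    # residual "other" group plus rare items -> fixed after marking
    n_fixed = int(round(params.frac_fixed_items * len(items)))
    fixed_ids = list(rng.choice(sorted(items), size=n_fixed, replace=False))
    if fixed_ids:
        fine_groups["other"] = "Other"
        for j, item_id in enumerate(fixed_ids):
            if j % 2 == 0:
                fine_assignment[item_id] = "other"
            else:
                items[item_id].occurrences = int(rng.integers(0, 4))

    fine = Classification("fine", fine_groups, fine_assignment)
    classifications = {
        "fine": fine,
        "medium": _merge_classification(fine, params.n_groups_medium, "medium"),
        "coarse": _merge_classification(fine, params.n_groups_coarse, "coarse"),
    }

    system = FoodSystem(
        items=items, nutrient_defs=defs, classifications=classifications
    )
    mark_fixed_items(system, "fine")

    # observed diets: Dirichlet shares within fine groups x group masses
    for sex in ("female", "male"):
        quantities: dict[str, float] = {}
        for gid in sorted(fine_groups):
            members = sorted(
                i for i, g in fine_assignment.items() if g == gid
            )
            if not members:
                continue
            mass = rng.uniform(*params.diet_mass_per_group)
            shares = rng.dirichlet(np.ones(len(members)))
            consumed = rng.random(len(members)) >= params.frac_unconsumed
            if not consumed.any():
                consumed[int(rng.integers(len(members)))] = True
            shares = shares * consumed
            total = shares.sum()
            if total <= 0:
                raise GenerationError(f"group {gid}: empty consumption draw")
            shares /= total
            for item_id, share in zip(members, shares):
                if share > 0:
                    quantities[item_id] = float(mass * share)
        system.diets[sex] = Diet(label=sex, quantities=quantities)

    # guidelines (fiber lower bound from each sex's observed energy)
    for sex in ("female", "male"):
        energy = diet_profile(system.diets[sex], system).energy
        system.guidelines[sex] = default_guidelines(
            fiber_lower_g=14.0 * energy / 1000.0
        )

    _calibrate_compositions(
        system, "female", system.guidelines["female"], params.bottlenecks, rng
    )
    _verify_bottlenecks(system, "female", system.guidelines["female"],
                        params.bottlenecks)
    _attach_commodities(system, rng)
    system.validate()
    return system


def _lognormal(rng: np.random.Generator, sigma: float) -> float:
    # unit-mean log-normal multiplier
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def _merge_classification(
    fine: Classification, n_groups: int, cid: str
) -> Classification:
    """Coarsen by merging consecutive fine groups; 'other' stays separate."""
    regular = sorted(g for g in fine.groups if g != "other")
    n_groups = max(1, min(n_groups, len(regular)))
    mapping = {
        g: f"{cid[0]}{idx * n_groups // len(regular):03d}"
        for idx, g in enumerate(regular)
    }
    groups = {m: f"{cid.capitalize()} {m}" for m in sorted(set(mapping.values()))}
    assignment = {}
    for item_id, g in fine.assignment.items():
        if g == "other":
            assignment[item_id] = "other"
        else:
            assignment[item_id] = mapping[g]
    if "other" in fine.groups:
        groups["other"] = "Other"
    return Classification(cid, groups, assignment)


def _calibrate_compositions(
    system: FoodSystem,
    diet_label: str,
    guidelines: GuidelineSet,
    bottlenecks: tuple[Bottleneck, ...],
    rng: np.random.Generator,
) -> None:
    """Rescale nutrient columns so the reference diet violates exactly the
    bottleneck guidelines and (roughly) meets all others."""
    by_nutrient = {b.nutrient_id: b for b in bottlenecks}
    diet = system.diets[diet_label]
    profile = diet_profile(diet, system)
    if profile.energy <= 0:
        raise GenerationError("generated diet has zero energy")

    def scale_column(nid: str, factor: float) -> None:
        for item in system.items.values():
            if nid in item.nutrients:
                item.nutrients[nid] *= factor

    # micronutrients: bottlenecked -> exact shortfall, others -> adequate
    for nid, ref in guidelines.micro_refs.items():
        current = profile.totals.get(nid, 0.0)
        if current <= 0:
            raise GenerationError(f"zero {nid!r} intake; cannot calibrate")
        b = by_nutrient.get(nid)
        target = (
            (1.0 - b.magnitude) * ref.rda
            if b is not None
            else float(rng.uniform(1.1, 1.4)) * ref.rda
        )
        scale_column(nid, target / current)

    # mass-bounded macros
    for nid, (lo, hi) in guidelines.macro_mass_bounds.items():
        current = profile.totals.get(nid, 0.0)
        if current <= 0:
            raise GenerationError(f"zero {nid!r} intake; cannot calibrate")
        b = by_nutrient.get(nid)
        if b is not None:
            target = (
                (1.0 - b.magnitude) * lo if b.direction == SHORT
                else (1.0 + b.magnitude) * hi
            )
        elif lo is not None:
            target = float(rng.uniform(1.1, 1.5)) * lo
        else:
            target = float(rng.uniform(0.6, 0.9)) * hi
        scale_column(nid, target / current)

    # energy-share-bounded macros (energy column stays fixed)
    for nid, (lo, hi) in guidelines.macro_energy_bounds.items():
        share = profile.energy_shares.get(nid, 0.0)
        if share <= 0:
            raise GenerationError(f"zero {nid!r} energy share; cannot calibrate")
        b = by_nutrient.get(nid)
        if b is not None:
            target = (
                (1.0 - b.magnitude) * lo if b.direction == SHORT
                else (1.0 + b.magnitude) * hi
            )
        elif lo is not None and hi is not None:
            target = 0.5 * (lo + hi)
        elif hi is not None:
            target = 0.8 * hi
        else:
            target = 1.2 * lo
        scale_column(nid, target / share)


def _verify_bottlenecks(
    system: FoodSystem,
    diet_label: str,
    guidelines: GuidelineSet,
    bottlenecks: tuple[Bottleneck, ...],
    tol: float = 0.02,
) -> None:
    profile = diet_profile(system.diets[diet_label], system)
    for b in bottlenecks:
        if b.nutrient_id in guidelines.micro_refs:
            ref = guidelines.micro_refs[b.nutrient_id].rda
            value = profile.totals[b.nutrient_id]
            violation = (ref - value) / ref
        else:
            bounds = guidelines.macro_energy_bounds.get(b.nutrient_id)
            if bounds is not None:
                value = profile.energy_shares[b.nutrient_id]
            else:
                bounds = guidelines.macro_mass_bounds[b.nutrient_id]
                value = profile.totals[b.nutrient_id]
            lo, hi = bounds
            violation = (
                (lo - value) / lo if b.direction == SHORT else (value - hi) / hi
            )
        if abs(violation - b.magnitude) > tol:
            raise GenerationError(
                f"bottleneck {b.nutrient_id!r} realized at {violation:.3f}, "
                f"target {b.magnitude:.3f}"
            )


def _attach_commodities(system: FoodSystem, rng: np.random.Generator) -> None:
    """Back each item's GHGE with a loss-adjusted commodity decomposition."""
    for item_id in sorted(system.items):
        item = system.items[item_id]
        if item.ghge is None or item.ghge <= 0:
            continue
        k = int(rng.integers(1, 5))
        weights = rng.uniform(10.0, 60.0, size=k)
        losses = rng.uniform(0.0, 50.0, size=k)
        contributions = item.ghge * rng.dirichlet(np.ones(k))
        shares: dict[str, float] = {}
        for j in range(k):
            cid = f"c_{item_id}_{j}"
            shares[cid] = float(weights[j])
            # contribution = w * q * 100/(100-loss)  =>  q
            system.commodity_ghge[cid] = float(
                contributions[j] * (100.0 - losses[j]) / (100.0 * weights[j])
            )
            system.loss_factors[cid] = float(losses[j])
        system.commodity_shares[item_id] = shares


# ---------------------------------------------------------------------------
# respondents
# ---------------------------------------------------------------------------


def generate_respondents(
    system: FoodSystem,
    n: int,
    seed: int = 0,
    *,
    dispersion: float = 0.5,
    report_prob: float = 0.7,
) -> list[Respondent]:
    """Simulate individual recall respondents around the observed diets.

    Sexes alternate; ages are uniform on [16, 70] and energies normal around
    sex-specific means with tails crossing the exclusion cutoffs, so the
    inclusion filter has work to do.  Item intakes are zero-inflated
    log-normal with expectation equal to the sex's observed diet.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    energy_dist = {"female": (2100.0, 450.0), "male": (2700.0, 500.0)}
    out: list[Respondent] = []
    for r in range(n):
        sex = "female" if r % 2 == 0 else "male"
        target = system.diets[sex]
        mu, sd = energy_dist[sex]
        intakes = {}
        item_ids = sorted(target.quantities)
        reported = rng.random(len(item_ids)) < report_prob
        noise = np.exp(
            rng.normal(-0.5 * dispersion**2, dispersion, size=len(item_ids))
        )
        for item_id, rep, mult in zip(item_ids, reported, noise):
            if rep:
                intakes[item_id] = float(
                    target.quantities[item_id] / report_prob * mult
                )
        out.append(
            Respondent(
                respondent_id=f"r{r:05d}",
                sex=sex,
                age=float(rng.uniform(16.0, 70.0)),
                energy_intake=float(max(rng.normal(mu, sd), 0.0)),
                intakes=intakes,
            )
        )
    return out


# ---------------------------------------------------------------------------
# known-optimum instances
# ---------------------------------------------------------------------------


def _minimal_defs() -> dict[str, NutrientDef]:
    return {
        "protein": NutrientDef("protein", "Protein", "g", "macro_energy", 4.0),
        "carbohydrate": NutrientDef(
            "carbohydrate", "Carbohydrate", "g", "macro_energy", 4.0
        ),
        "fat": NutrientDef("fat", "Total fat", "g", "macro_energy", 9.0),
        "iron": NutrientDef("iron", "Iron", "mg", "micro"),
    }


def _wide_guidelines(iron_rda: float) -> GuidelineSet:
    return GuidelineSet(
        macro_energy_bounds={
            "protein": (1.0, 90.0),
            "carbohydrate": (1.0, 95.0),
            "fat": (1.0, 90.0),
        },
        macro_mass_bounds={},
        micro_refs={"iron": MicroRef(rda=iron_rda, ear=0.8 * iron_rda, unit="mg")},
    )


def _item(item_id, energy, protein, carb, fat, iron, ghge, fixed=False):
    return FoodItem(
        item_id=item_id,
        name=item_id,
        energy=energy,
        nutrients={"protein": protein, "carbohydrate": carb, "fat": fat,
                   "iron": iron},
        ghge=ghge,
        fixed=fixed,
    )


def generate_known_optimum_instance(kind: str, seed: int = 0
                                    ) -> tuple[FoodSystem, dict]:
    """Build an adversarial instance together with its analytic optimum.

    Kinds
    -----
    within_swap
        Nutrient-identical item pair with a GHGE gap; the within-group
        optimum shifts all mass onto the low-GHGE item (33.3% reduction).
    between_removal
        A near-zero-energy group whose footprint must be cut; group scaling
        (between mode) must shrink both its items while item-level moves cut
        only the dirty one, so between-and-within needs strictly less change.
    infeasible_cap
        The sole iron source carries all the footprint, so the RDA forces a
        GHGE floor above the cap: experiment 3 is infeasible.
    adequacy_vs_ghge
        Meeting the iron reference requires shifting onto a high-GHGE item,
        so the stage-2 GHGE exceeds the observed GHGE.

    ``seed`` is accepted for interface uniformity; the instances are fully
    deterministic.
    """
    if kind not in KNOWN_OPTIMUM_KINDS:
        raise ValueError(f"unknown instance kind {kind!r}")
    defs = _minimal_defs()

    if kind == "within_swap":
        items = {
            "a": _item("a", 250.0, 10.0, 30.0, 10.0, 5.0, ghge=1.0),
            "b": _item("b", 250.0, 10.0, 30.0, 10.0, 5.0, ghge=2.0),
        }
        cls = Classification("groups", {"g1": "G1"}, {"a": "g1", "b": "g1"})
        diet = Diet("obs", {"a": 50.0, "b": 50.0})
        system = FoodSystem(
            items=items, nutrient_defs=defs, classifications={"groups": cls},
            diets={"obs": diet},
            guidelines={"obs": _wide_guidelines(iron_rda=1.0)},
        )
        expected = {
            "mode": "within_only",
            "allowed_change_pct": 100.0,
            "diet": {"a": 100.0, "b": 0.0},
            "ghge_observed": 1.5,
            "ghge": 1.0,
            "ghge_reduction": 1.0 / 3.0,
            "d_macro": 0.0,
            "d_micro": 0.0,
        }

    elif kind == "between_removal":
        items = {
            "a": _item("a", 500.0, 10.0, 30.0, 10.0, 20.0, ghge=0.1),
            "b1": _item("b1", 1.0, 0.0, 0.25, 0.0, 0.0, ghge=2.0),
            "b2": _item("b2", 1.0, 0.0, 0.25, 0.0, 0.0, ghge=0.2),
        }
        cls = Classification(
            "groups", {"ga": "GA", "gb": "GB"},
            {"a": "ga", "b1": "gb", "b2": "gb"},
        )
        diet = Diet("obs", {"a": 300.0, "b1": 100.0, "b2": 100.0})
        system = FoodSystem(
            items=items, nutrient_defs=defs, classifications={"groups": cls},
            diets={"obs": diet},
            guidelines={"obs": _wide_guidelines(iron_rda=30.0)},
        )
        # observed ghge = 0.3 + 2.0 + 0.2 = 2.5; target 0.6 -> cap 1.0
        # between: only GB worth scaling; 0.3 + 2.2 s <= 1.0 -> s = 7/22,
        #   change = 200 * 15/22 g over 500 g observed
        # both: shrink b1 alone to 25 g -> change = 75 g
        expected = {
            "ghge_reduction_target": 0.6,
            "between_c_total": 100.0 * (200.0 * 15.0 / 22.0) / 500.0,
            "both_c_total": 100.0 * 75.0 / 500.0,
        }

    elif kind == "infeasible_cap":
        items = {
            "a": _item("a", 400.0, 10.0, 40.0, 10.0, 0.0, ghge=0.0),
            "z": _item("z", 100.0, 5.0, 10.0, 2.0, 10.0, ghge=1.0),
        }
        cls = Classification(
            "groups", {"ga": "GA", "gz": "GZ"}, {"a": "ga", "z": "gz"}
        )
        diet = Diet("obs", {"a": 300.0, "z": 100.0})
        system = FoodSystem(
            items=items, nutrient_defs=defs, classifications={"groups": cls},
            diets={"obs": diet},
            # iron ref equals the observed intake: z cannot shrink at all,
            # so ghge >= 1.0 > cap for any reduction target > 0
            guidelines={"obs": _wide_guidelines(iron_rda=10.0)},
        )
        expected = {"ghge_reduction_target": 0.3, "status": "infeasible"}

    else:  # adequacy_vs_ghge
        items = {
            "a": _item("a", 250.0, 10.0, 30.0, 10.0, 1.0, ghge=0.5),
            "b": _item("b", 250.0, 10.0, 30.0, 10.0, 10.0, ghge=2.0),
        }
        cls = Classification("groups", {"g1": "G1"}, {"a": "g1", "b": "g1"})
        diet = Diet("obs", {"a": 100.0, "b": 0.0})
        system = FoodSystem(
            items=items, nutrient_defs=defs, classifications={"groups": cls},
            diets={"obs": diet},
            guidelines={"obs": _wide_guidelines(iron_rda=5.0)},
        )
        # stage 1 reaches d = 0 (iron needs x_b >= 400/9); stage 2 then
        # minimizes ghge = 0.5 + 0.015 x_b at x_b = 400/9 -> 7/6 > 0.5
        expected = {
            "mode": "within_only",
            "allowed_change_pct": 100.0,
            "d_micro": 0.0,
            "ghge_observed": 0.5,
            "ghge": 7.0 / 6.0,
        }

    system.validate()
    return system, expected
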