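"""Independent brute-force oracles for the optimizer tests.

These enumerate diets on a mass grid and evaluate objectives directly from
nutrient accounting — no linear programming, no shared code path with the
model builder beyond the data classes.  Instance shapes are kept small
enough (<= ~2e6 grid cells) for exhaustive search.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from dietopt.food_system_io import (
    Classification,
    Diet,
    FoodItem,
    FoodSystem,
    NutrientDef,
)
from dietopt.guidelines import GuidelineSet, MicroRef


# ---------------------------------------------------------------------------
# direct (non-LP) objective evaluation over a batch of candidate diets
# ---------------------------------------------------------------------------


@dataclass
class BatchEval:
    d_macro: np.ndarray
    d_micro: np.ndarray
    ghge: np.ndarray
    energy: np.ndarray
    change: np.ndarray  # sum |x - o| in grams


def evaluate_batch(
    quantities: np.ndarray,  # (n_cand, n_items) g/day, optimizable items
    item_ids: list[str],
    system: FoodSystem,
    guidelines: GuidelineSet,
    observed: Diet,
) -> BatchEval:
    items = [system.items[i] for i in item_ids]
    nut_ids = sorted(system.nutrient_defs)
    comp = np.array(
        [[it.nutrients.get(n, 0.0) for n in nut_ids] for it in items]
    )  # per 100 g
    energy_row = np.array([it.energy for it in items])
    ghge_row = np.array([it.ghge for it in items])
    fixed_ids = [i for i in system.items if i not in item_ids]
    fixed_tot = np.zeros(len(nut_ids))
    fixed_energy = 0.0
    fixed_ghge = 0.0
    for i in fixed_ids:
        q = observed.get(i) / 100.0
        it = system.items[i]
        fixed_tot += q * np.array([it.nutrients.get(n, 0.0) for n in nut_ids])
        fixed_energy += q * it.energy
        fixed_ghge += q * (it.ghge or 0.0)

    q100 = quantities / 100.0
    totals = q100 @ comp + fixed_tot
    energy = q100 @ energy_row + fixed_energy
    ghge = q100 @ ghge_row + fixed_ghge
    tot = {n: totals[:, k] for k, n in enumerate(nut_ids)}

    d_macro = np.zeros(len(quantities))
    with np.errstate(divide="ignore", invalid="ignore"):
        for nid, scale, lo, hi in guidelines.iter_bounds():
            if scale == "energy_pct":
                atw = system.nutrient_defs[nid].atwater
                value = 100.0 * atw * tot[nid] / energy
            else:
                value = tot[nid]
            if lo is not None and lo > 0:
                d_macro = np.maximum(d_macro, (lo - value) / lo)
            if hi is not None and hi > 0:
                d_macro = np.maximum(d_macro, (value - hi) / hi)
    d_macro = np.maximum(d_macro, 0.0)
    # zero-energy candidates have undefined E% shares: rule them out
    d_macro = np.where(energy > 0, d_macro, np.inf)

    d_micro = np.zeros(len(quantities))
    for nid, ref in guidelines.micro_refs.items():
        amount = ref.amount(guidelines.micro_target)
        d_micro = np.maximum(d_micro, (amount - tot[nid]) / amount)
    d_micro = np.maximum(d_micro, 0.0)

    obs_vec = np.array([observed.get(i) for i in item_ids])
    change = np.abs(quantities - obs_vec).sum(axis=1)
    return BatchEval(d_macro=d_macro, d_micro=d_micro, ghge=ghge,
                     energy=energy, change=change)


# ---------------------------------------------------------------------------
# within-group grid oracle (experiment-1 machinery)
# ---------------------------------------------------------------------------


def _group_allocations(observed: np.ndarray, mass: float, step: float,
                       allowed_pct: float, cap: float | None) -> np.ndarray:
    """All grid allocations of `mass` over len(observed) items obeying the
    within-group budget (and item cap when given)."""
    k = len(observed)
    n_steps = int(round(mass / step)) if step > 0 else 0
    if n_steps == 0 or mass <= 0:
        return observed.reshape(1, -1)
    grids = []
    for combo in itertools.product(range(n_steps + 1), repeat=k - 1):
        if sum(combo) > n_steps:
            continue
        alloc = [c * step for c in combo]
        alloc.append(mass - sum(alloc))
        grids.append(alloc)
    out = np.array(grids)
    budget = 2.0 * (allowed_pct / 100.0) * mass
    keep = np.abs(out - observed).sum(axis=1) <= budget + 1e-9
    out = out[keep]
    if cap is not None:
        out = out[(out <= cap + 1e-9).all(axis=1)]
    return out


def grid_oracle_within(
    system: FoodSystem,
    diet: Diet,
    classification: Classification,
    guidelines: GuidelineSet,
    allowed_pct: float = 100.0,
    step_frac: float = 0.01,
    item_cap: bool = False,
    energy_band: float = 0.05,
    stage_cut: float | None = None,
) -> dict:
    """Exhaustive lexicographic search on the within-group mass grid.

    Returns the grid-optimal stage values: minimal d = d_macro + d_micro,
    then minimal ghge among grid points with d below ``stage_cut`` plus the
    grid's deviation resolution (``stage_cut`` defaults to the grid minimum).
    Also returns computed grid-resolution bounds for fair comparison.
    """
    by_group: dict[str, list[str]] = {}
    for item_id in sorted(classification.assignment):
        if not system.items[item_id].fixed:
            by_group.setdefault(classification.assignment[item_id], []).append(
                item_id
            )

    group_allocs = []
    item_ids: list[str] = []
    sensitivities_d = []
    sensitivities_g = []
    for g in sorted(by_group):
        members = by_group[g]
        obs = np.array([diet.get(i) for i in members])
        mass = obs.sum()
        step = step_frac * mass
        cap = obs.max() if item_cap else None
        group_allocs.append(
            _group_allocations(obs, mass, step, allowed_pct, cap)
        )
        item_ids.extend(members)
        sensitivities_d.append(step * _dev_sensitivity(system, guidelines,
                                                       members, diet))
        sensitivities_g.append(
            step * _ghge_sensitivity(system, members)
        )

    combos = [np.arange(len(a)) for a in group_allocs]
    mesh = np.meshgrid(*combos, indexing="ij")
    idx = np.stack([m.ravel() for m in mesh], axis=1)
    quantities = np.hstack(
        [group_allocs[j][idx[:, j]] for j in range(len(group_allocs))]
    )

    ev = evaluate_batch(quantities, item_ids, system, guidelines, diet)
    e_obs = evaluate_batch(
        np.array([[diet.get(i) for i in item_ids]]), item_ids, system,
        guidelines, diet,
    ).energy[0]
    feasible = (
        (ev.energy >= (1 - energy_band) * e_obs - 1e-9)
        & (ev.energy <= (1 + energy_band) * e_obs + 1e-9)
    )
    d = ev.d_macro + ev.d_micro
    d = np.where(feasible, d, np.inf)
    d_min = float(d.min())
    tol_d = 2.0 * sum(sensitivities_d)
    tol_g = 2.0 * sum(sensitivities_g)
    near = d <= max(d_min, stage_cut if stage_cut is not None else d_min) + tol_d
    ghge_min = float(np.where(near, ev.ghge, np.inf).min())
    return {
        "d_min": d_min,
        "ghge_min": ghge_min,
        "tol_d": tol_d,
        "tol_ghge": tol_g,
        "n_cells": len(quantities),
    }


def _dev_sensitivity(system, guidelines, members, diet) -> float:
    """Max change of any relative violation per gram moved within the group."""
    e_obs = sum(
        diet.get(i) / 100.0 * system.items[i].energy for i in system.items
    )
    worst = 0.0
    for nid, scale, lo, hi in guidelines.iter_bounds():
        vals = [system.items[i].nutrients.get(nid, 0.0) for i in members]
        spread = (max(vals) - min(vals)) / 100.0
        if scale == "energy_pct":
            atw = system.nutrient_defs[nid].atwater
            for bound in (lo, hi):
                if bound:
                    worst = max(worst, 100.0 * atw * spread / (bound * e_obs))
        else:
            for bound in (lo, hi):
                if bound:
                    worst = max(worst, spread / bound)
    for nid, ref in guidelines.micro_refs.items():
        vals = [system.items[i].nutrients.get(nid, 0.0) for i in members]
        spread = (max(vals) - min(vals)) / 100.0
        worst = max(worst, spread / ref.amount(guidelines.micro_target))
    return worst


def _ghge_sensitivity(system, members) -> float:
    vals = [system.items[i].ghge for i in members]
    return (max(vals) - min(vals)) / 100.0


# ---------------------------------------------------------------------------
# between-group grid oracle (experiment-3 machinery)
# ---------------------------------------------------------------------------


def grid_oracle_between(
    system: FoodSystem,
    diet: Diet,
    classification: Classification,
    guidelines: GuidelineSet,
    ghge_cap: float,
    s_max: float = 2.0,
    s_step: float = 0.01,
    energy_band: float = 0.05,
) -> dict:
    """Exhaustive search over per-group scale factors for minimal change.

    Hard constraints: all macro bounds, all micronutrient references, the
    GHGE cap, and the energy band.  Returns the minimal sum |x - o| over
    feasible grid points (np.inf when the grid holds no feasible point).
    """
    by_group: dict[str, list[str]] = {}
    for item_id in sorted(classification.assignment):
        if not system.items[item_id].fixed:
            by_group.setdefault(classification.assignment[item_id], []).append(
                item_id
            )
    groups = sorted(g for g in by_group
                    if sum(diet.get(i) for i in by_group[g]) > 0)
    item_ids = [i for g in groups for i in by_group[g]]
    obs = np.array([diet.get(i) for i in item_ids])
    group_index = np.concatenate(
        [np.full(len(by_group[g]), j) for j, g in enumerate(groups)]
    )
    scales = np.arange(0.0, s_max + s_step / 2, s_step)
    mesh = np.meshgrid(*[scales] * len(groups), indexing="ij")
    svec = np.stack([m.ravel() for m in mesh], axis=1)  # (n_cand, n_groups)
    quantities = svec[:, group_index] * obs

    ev = evaluate_batch(quantities, item_ids, system, guidelines, diet)
    e_obs = evaluate_batch(
        obs.reshape(1, -1), item_ids, system, guidelines, diet
    ).energy[0]
    feasible = (
        (ev.d_macro <= 1e-9)
        & (ev.d_micro <= 1e-9)
        & (ev.ghge <= ghge_cap + 1e-9)
        & (ev.energy >= (1 - energy_band) * e_obs - 1e-9)
        & (ev.energy <= (1 + energy_band) * e_obs + 1e-9)
    )
    change = np.where(feasible, ev.change, np.inf)
    masses = np.array([sum(diet.get(i) for i in by_group[g]) for g in groups])
    return {
        "change_min": float(change.min()),
        "any_feasible": bool(feasible.any()),
        "min_feasible_ghge": float(
            np.where(
                (ev.d_macro <= 1e-9) & (ev.d_micro <= 1e-9)
                & (ev.energy >= (1 - energy_band) * e_obs - 1e-9)
                & (ev.energy <= (1 + energy_band) * e_obs + 1e-9),
                ev.ghge,
                np.inf,
            ).min()
        ),
        "tol_change": 2.0 * s_step * masses.max() * len(groups),
        "n_cells": len(quantities),
    }


# ---------------------------------------------------------------------------
# random small instances for the oracle-equivalence suite
# ---------------------------------------------------------------------------


def random_small_system(rng: np.random.Generator, *, n_groups: int,
                        items_per_group: list[int],
                        loose: bool = False) -> FoodSystem:
    """Tiny system with constant energy within each group, so within-group
    reallocation leaves total energy fixed and E% denominators exact."""
    defs = {
        "protein": NutrientDef("protein", "Protein", "g", "macro_energy", 4.0),
        "fat": NutrientDef("fat", "Fat", "g", "macro_energy", 9.0),
        "sodium": NutrientDef("sodium", "Sodium", "mg", "macro_mass"),
        "iron": NutrientDef("iron", "Iron", "mg", "micro"),
    }
    items: dict[str, FoodItem] = {}
    assignment: dict[str, str] = {}
    groups: dict[str, str] = {}
    quantities: dict[str, float] = {}
    for g in range(n_groups):
        gid = f"g{g}"
        groups[gid] = gid
        energy = float(rng.uniform(150.0, 400.0))
        mass = float(rng.uniform(80.0, 250.0))
        k = items_per_group[g]
        shares = rng.dirichlet(np.ones(k))
        for j in range(k):
            iid = f"i{g}_{j}"
            items[iid] = FoodItem(
                item_id=iid,
                name=iid,
                energy=energy,
                nutrients={
                    "protein": float(rng.uniform(2.0, 25.0)),
                    "fat": float(rng.uniform(1.0, 20.0)),
                    "sodium": float(rng.uniform(50.0, 600.0)),
                    "iron": float(rng.uniform(0.5, 8.0)),
                },
                ghge=float(rng.uniform(0.05, 2.0)),
            )
            assignment[iid] = gid
            quantities[iid] = float(mass * shares[j])
    system = FoodSystem(
        items=items, nutrient_defs=defs,
        classifications={"groups": Classification("groups", groups, assignment)},
        diets={"obs": Diet("obs", quantities)},
    )

    # guidelines anchored near the observed profile so instances are tight
    # but feasible-ish
    from dietopt.guidelines import diet_profile

    profile = diet_profile(system.diets["obs"], system)
    protein_share = profile.energy_shares["protein"]
    fat_share = profile.energy_shares["fat"]
    if loose:
        # observed diet feasible: bounds bracket the observed profile, so
        # experiment-3 grids are guaranteed a non-empty feasible set
        system.guidelines["obs"] = GuidelineSet(
            macro_energy_bounds={
                "protein": (protein_share * 0.6, protein_share * 1.8),
                "fat": (None, fat_share * float(rng.uniform(1.2, 1.5))),
            },
            macro_mass_bounds={
                "sodium": (None,
                           profile.totals["sodium"] * float(rng.uniform(1.3, 1.6))),
            },
            micro_refs={
                "iron": MicroRef(
                    rda=profile.totals["iron"] * float(rng.uniform(0.7, 0.9)),
                    ear=profile.totals["iron"] * 0.5,
                )
            },
        )
    else:
        system.guidelines["obs"] = GuidelineSet(
            macro_energy_bounds={
                "protein": (protein_share * float(rng.uniform(0.6, 0.95)),
                            protein_share * float(rng.uniform(1.15, 1.6))),
                "fat": (None, fat_share * float(rng.uniform(1.0, 1.4))),
            },
            macro_mass_bounds={
                "sodium": (None,
                           profile.totals["sodium"] * float(rng.uniform(0.9, 1.3))),
            },
            micro_refs={
                "iron": MicroRef(
                    rda=profile.totals["iron"] * float(rng.uniform(0.8, 1.3)),
                    ear=profile.totals["iron"] * 0.6,
                )
            },
        )
    system.validate()
    return system
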