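"""Linear goal programs for the three diet-optimization experiments.

Experiment 1 reallocates quantities *within* food groups (group totals
conserved) and lexicographically minimizes (1) the largest relative deviation
from macronutrient bounds plus the largest micronutrient shortfall, (2) diet
greenhouse gas emissions, (3) the within-group change fractions.  Experiment
2 is the same machinery under lowered nutrient goals (macro bounds stretched
by 20%, micronutrient targets at EAR).  Experiment 3 makes adequacy a hard
constraint together with a GHGE cap, and minimizes total dietary change —
either scaling whole groups (between mode) or moving individual items freely
(between-and-within mode).

Absolute changes are linearized with split variables: x_i = o_i + p_i - n_i,
p_i, n_i >= 0.  E% bounds are linearized as
``atwater * 100 * grams - bound * energy(x) <=> 0``; the deviation slack for a
bound is scaled by ``bound * observed energy`` so the reported deviation stays
a relative quantity.  Energy itself is constrained to the observed diet's
energy +/- 5% in every experiment (without an energy rule the E% and GHGE
objectives degenerate by shrinking the diet).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from . import metrics as _metrics
from .food_system_io import Classification, Diet, FoodSystem
from .footprint import derive_item_footprints
from .guidelines import (
    EAR,
    LEVEL_FULL,
    LEVEL_LOWERED,
    GuidelineSet,
    diet_profile,
    macro_deviation,
    micro_deviation,
    relax_guidelines,
)
from .lp import (
    STATUS_INFEASIBLE,
    STATUS_OPTIMAL,
    LinearModel,
    StageResult,
    lexicographic_solve,
)

log = logging.getLogger(__name__)

MODE_WITHIN = "within_only"
MODE_BETWEEN = "between_only"
MODE_BOTH = "between_and_within"
MODES = (MODE_WITHIN, MODE_BETWEEN, MODE_BOTH)

#: relative half-width of the energy band around the observed diet's energy
ENERGY_BAND = 0.05


class OptimizerError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioConfig:
    """One optimization scenario: mode, change budget, goal level, weights."""

    classification_id: str
    mode: str = MODE_WITHIN
    allowed_change_pct: float = 100.0
    item_cap_enabled: bool = False
    goal_level: str = LEVEL_FULL
    ghge_reduction_target: float | None = None
    epsilon1: float = 1e-3
    epsilon2: float = 1e-6
    epsilon: float = 1e-4
    solver_tol: float = 1e-6
    lexicographic: bool = True
    energy_band: float = ENERGY_BAND
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise OptimizerError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.allowed_change_pct <= 100.0:
            raise OptimizerError("allowed_change_pct must be in [0, 100]")
        if not self.epsilon1 > self.epsilon2 > 0:
            raise OptimizerError("need epsilon1 > epsilon2 > 0")
        if self.epsilon <= 0 or self.solver_tol <= 0:
            raise OptimizerError("epsilon and solver_tol must be positive")
        if self.goal_level not in (LEVEL_FULL, LEVEL_LOWERED):
            raise OptimizerError(f"unknown goal_level {self.goal_level!r}")


@dataclass
class SolveResult:
    """Optimized diet plus all objective components and diagnostics."""

    diet: Diet
    status: str
    d_macro: float | None = None
    d_micro: float | None = None
    ghge: float | None = None
    ghge_observed: float | None = None
    ghge_reduction: float | None = None
    c_within: dict[str, float] = field(default_factory=dict)
    c_total: float | None = None
    objective_stages: list[StageResult] = field(default_factory=list)
    solver_log: str = ""
    binding_blocks: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# affine bookkeeping
# ---------------------------------------------------------------------------


class _Affine:
    """const + sum(coeffs[v] * v); the linear currency of the model builder."""

    __slots__ = ("const", "coeffs")

    def __init__(self, const: float = 0.0, coeffs: dict[str, float] | None = None):
        self.const = const
        self.coeffs: dict[str, float] = coeffs or {}

    def add(self, other: "_Affine", scale: float = 1.0) -> None:
        self.const += scale * other.const
        for v, c in other.coeffs.items():
            self.coeffs[v] = self.coeffs.get(v, 0.0) + scale * c


def _resolve_footprints(system: FoodSystem) -> dict[str, float]:
    out = dict(derive_item_footprints(system)) if system.commodity_shares else {}
    for item_id, item in system.items.items():
        if item.ghge is not None:
            out[item_id] = item.ghge
    return out


@dataclass
class _Problem:
    """Shared scaffolding: variables, item expressions, linear accounts."""

    model: LinearModel
    item_exprs: dict[str, _Affine]
    observed: dict[str, float]
    classification: Classification
    by_group: dict[str, list[str]]
    group_mass: dict[str, float]  # optimizable observed mass per group
    energy: _Affine
    ghge: _Affine
    totals: dict[str, _Affine]  # nutrient_id -> amount/day
    energy_obs: float
    ghge_obs: float
    change_numerator: dict[str, float]  # var -> coefficient of sum|x - o|


def _build_problem(
    system: FoodSystem, diet: Diet, config: ScenarioConfig
) -> _Problem:
    cls = system.classifications[config.classification_id]
    model = LinearModel()
    footprints = _resolve_footprints(system)
    observed = {i: diet.get(i) for i in sorted(system.items)}

    by_group: dict[str, list[str]] = {g: [] for g in sorted(cls.groups)}
    for item_id in sorted(cls.assignment):
        if not system.items[item_id].fixed:
            by_group[cls.assignment[item_id]].append(item_id)
    group_mass = {
        g: sum(observed[i] for i in members) for g, members in by_group.items()
    }

    item_exprs: dict[str, _Affine] = {}
    change_numerator: dict[str, float] = {}

    if config.mode == MODE_BETWEEN:
        for g in sorted(by_group):
            if group_mass[g] <= 0:
                continue
            tp = model.add_var(f"up[{g}]", lb=0.0)
            tn = model.add_var(f"dn[{g}]", lb=0.0, ub=1.0)  # scale >= 0
            for i in by_group[g]:
                item_exprs[i] = _Affine(
                    observed[i], {tp: observed[i], tn: -observed[i]}
                )
            change_numerator[tp] = group_mass[g]
            change_numerator[tn] = group_mass[g]
    else:
        for g in sorted(by_group):
            for i in by_group[g]:
                p = model.add_var(f"p[{i}]", lb=0.0)
                n = model.add_var(f"n[{i}]", lb=0.0, ub=observed[i])
                item_exprs[i] = _Affine(observed[i], {p: 1.0, n: -1.0})
                change_numerator[p] = 1.0
                change_numerator[n] = 1.0
    for item_id, item in system.items.items():
        if item_id not in item_exprs:  # fixed or unclassified: pinned
            item_exprs[item_id] = _Affine(observed[item_id])

    energy = _Affine()
    ghge = _Affine()
    totals = {nid: _Affine() for nid in system.nutrient_defs}
    for item_id, expr in item_exprs.items():
        item = system.items[item_id]
        energy.add(expr, item.energy / 100.0)
        fp = footprints.get(item_id)
        if fp is not None:
            ghge.add(expr, fp / 100.0)
        elif observed[item_id] > 0 or not item.fixed:
            raise OptimizerError(f"item {item_id!r} has no footprint")
        for nid, total in totals.items():
            amount = item.nutrients.get(nid, 0.0)
            if amount:
                total.add(expr, amount / 100.0)

    profile_obs = diet_profile(diet, system)
    if profile_obs.energy <= 0:
        raise OptimizerError("observed diet has zero energy")

    return _Problem(
        model=model,
        item_exprs=item_exprs,
        observed=observed,
        classification=cls,
        by_group=by_group,
        group_mass=group_mass,
        energy=energy,
        ghge=ghge,
        totals=totals,
        energy_obs=profile_obs.energy,
        ghge_obs=ghge.const,  # all vars at 0 <=> x = o in every mode
        change_numerator=change_numerator,
    )


def _observed_ghge(problem: _Problem) -> float:
    # evaluate the ghge expression at the observed point (all vars at 0 give
    # x = o in within/both mode; in between mode up=dn=0 also gives x = o)
    return problem.ghge.const


def _add_energy_band(problem: _Problem, band: float) -> None:
    e = problem.energy
    problem.model.add_le(e.coeffs, (1 + band) * problem.energy_obs - e.const,
                         name="energy_hi")
    problem.model.add_ge(e.coeffs, (1 - band) * problem.energy_obs - e.const,
                         name="energy_lo")


def _macro_rows(system: FoodSystem, guidelines: GuidelineSet, problem: _Problem):
    """Yield (name, expr, slack_scale) rows meaning expr <= d_macro*slack_scale.

    Rows come from linearized E% bounds and mass-per-day bounds; with the
    slack forced to zero they are the hard adequacy constraints.
    """
    e_obs = problem.energy_obs
    for nid, scale, lo, hi in guidelines.iter_bounds():
        if scale == "energy_pct":
            atw = system.nutrient_defs[nid].atwater
            grams = problem.totals[nid]
            if hi is not None:
                expr = _Affine()
                expr.add(grams, 100.0 * atw)
                expr.add(problem.energy, -hi)
                yield f"{nid}_hi", expr, hi * e_obs
            if lo is not None:
                expr = _Affine()
                expr.add(problem.energy, lo)
                expr.add(grams, -100.0 * atw)
                yield f"{nid}_lo", expr, lo * e_obs
        else:
            value = problem.totals[nid]
            if hi is not None:
                expr = _Affine(-hi)
                expr.add(value)
                yield f"{nid}_hi", expr, hi
            if lo is not None:
                expr = _Affine(lo)
                expr.add(value, -1.0)
                yield f"{nid}_lo", expr, lo


def _micro_rows(guidelines: GuidelineSet, problem: _Problem):
    target = guidelines.micro_target
    for nid, ref in sorted(guidelines.micro_refs.items()):
        amount = ref.amount(target)
        expr = _Affine(amount)
        expr.add(problem.totals[nid], -1.0)
        yield f"{nid}_{target}", expr, amount


def _add_soft_deviations(
    system: FoodSystem, guidelines: GuidelineSet, problem: _Problem
) -> tuple[str, str]:
    model = problem.model
    d_macro = model.add_var("d_macro", lb=0.0)
    d_micro = model.add_var("d_micro", lb=0.0)
    for name, expr, slack in _macro_rows(system, guidelines, problem):
        coeffs = dict(expr.coeffs)
        coeffs[d_macro] = coeffs.get(d_macro, 0.0) - slack
        model.add_le(coeffs, -expr.const, name=f"macro_{name}")
    for name, expr, slack in _micro_rows(guidelines, problem):
        coeffs = dict(expr.coeffs)
        coeffs[d_micro] = coeffs.get(d_micro, 0.0) - slack
        model.add_le(coeffs, -expr.const, name=f"micro_{name}")
    return d_macro, d_micro


def _add_hard_adequacy(
    system: FoodSystem, guidelines: GuidelineSet, problem: _Problem
) -> None:
    model = problem.model
    for name, expr, _ in _macro_rows(system, guidelines, problem):
        model.add_le(expr.coeffs, -expr.const, name=f"macro_{name}")
    for name, expr, _ in _micro_rows(guidelines, problem):
        model.add_le(expr.coeffs, -expr.const, name=f"micro_{name}")


def _add_within_group_constraints(problem: _Problem, config: ScenarioConfig
                                  ) -> None:
    """Group-mass conservation, the change budget, and optional item caps."""
    budget_frac = config.allowed_change_pct / 100.0
    for g, members in sorted(problem.by_group.items()):
        if not members:
            # groups made up entirely of fixed items are inert by design
            if any(gid == g for gid in problem.classification.assignment.values()):
                log.debug("group %r has no optimizable items; skipped", g)
            else:
                log.warning("group %r is empty; skipped", g)
            continue
        conserve: dict[str, float] = {}
        budget: dict[str, float] = {}
        for i in members:
            expr = problem.item_exprs[i]
            for v, c in expr.coeffs.items():
                conserve[v] = conserve.get(v, 0.0) + c
                budget[v] = budget.get(v, 0.0) + abs(c)  # p_i + n_i
        problem.model.add_eq(conserve, 0.0, name=f"conserve_{g}")
        problem.model.add_le(
            budget, 2.0 * budget_frac * problem.group_mass[g], name=f"budget_{g}"
        )
        if config.item_cap_enabled:
            cap = max((problem.observed[i] for i in members), default=0.0)
            for i in members:
                expr = problem.item_exprs[i]
                problem.model.add_le(
                    expr.coeffs, cap - expr.const, name=f"cap_{i}"
                )


# ---------------------------------------------------------------------------
# result assembly
# ---------------------------------------------------------------------------


def _extract_diet(problem: _Problem, values: dict[str, float], label: str,
                  snap: float = 1e-9) -> Diet:
    quantities = {}
    for item_id, expr in problem.item_exprs.items():
        q = expr.const + sum(c * values.get(v, 0.0) for v, c in expr.coeffs.items())
        quantities[item_id] = 0.0 if abs(q) < snap else max(q, 0.0)
    return Diet(label=label, quantities=quantities)


def _assemble_result(
    system: FoodSystem,
    observed: Diet,
    guidelines: GuidelineSet,
    problem: _Problem,
    status: str,
    values: dict[str, float],
    stages: list[StageResult],
    label: str,
) -> SolveResult:
    if status != STATUS_OPTIMAL and not values:
        return SolveResult(
            diet=observed, status=status, objective_stages=stages,
            binding_blocks=[s.name for s in stages if s.status != STATUS_OPTIMAL],
        )
    diet = _extract_diet(problem, values, label)
    footprints = _resolve_footprints(system)
    profile = diet_profile(diet, system)
    ghge = sum(
        diet.get(i) / 100.0 * footprints[i] for i in diet.quantities
        if diet.get(i) > 0
    )
    ghge_obs = _observed_ghge(problem)
    c_within = {}
    for g, members in problem.by_group.items():
        mass = problem.group_mass[g]
        if mass > 0:
            c_within[g] = sum(abs(diet.get(i) - observed.get(i)) for i in members
                              ) / (2.0 * mass)
        else:
            c_within[g] = 0.0
    return SolveResult(
        diet=diet,
        status=status,
        d_macro=macro_deviation(profile, guidelines),
        d_micro=micro_deviation(profile, guidelines.micro_refs,
                                guidelines.micro_target),
        ghge=ghge,
        ghge_observed=ghge_obs,
        ghge_reduction=(1.0 - ghge / ghge_obs) if ghge_obs > 0 else 0.0,
        c_within=c_within,
        c_total=_metrics.total_dietary_change(observed, diet),
        objective_stages=stages,
        solver_log="; ".join(
            f"{s.name}: {s.status} opt={s.optimum}" for s in stages
        ),
    )


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


def _solve_within(
    system: FoodSystem,
    diet: Diet,
    guidelines: GuidelineSet,
    config: ScenarioConfig,
    label: str,
) -> SolveResult:
    problem = _build_problem(system, diet, config)
    _add_energy_band(problem, config.energy_band)
    _add_within_group_constraints(problem, config)
    d_macro, d_micro = _add_soft_deviations(system, guidelines, problem)

    ghge_obj = dict(problem.ghge.coeffs)
    n_active = sum(1 for m in problem.group_mass.values() if m > 0) or 1
    change_obj = {
        v: c / (2.0 * problem.group_mass[g]) / n_active
        for g, members in problem.by_group.items()
        if problem.group_mass[g] > 0
        for i in members
        for v, c in ((vv, abs(cc)) for vv, cc in problem.item_exprs[i].coeffs.items())
    }

    if config.lexicographic:
        status, values, stages = lexicographic_solve(
            problem.model,
            [
                ("deviation", {d_macro: 1.0, d_micro: 1.0}),
                ("ghge", ghge_obj),
                ("change", change_obj),
            ],
            tol=config.solver_tol,
        )
    else:
        ghge_obs = _observed_ghge(problem)
        scale = 1.0 / ghge_obs if ghge_obs > 0 else 1.0
        objective = {d_macro: 1.0, d_micro: 1.0}
        for v, c in ghge_obj.items():
            objective[v] = objective.get(v, 0.0) + config.epsilon1 * c * scale
        for v, c in change_obj.items():
            objective[v] = objective.get(v, 0.0) + config.epsilon2 * c
        outcome = problem.model.solve(objective)
        status, values = outcome.status, outcome.values
        stages = [StageResult("weighted", outcome.status, outcome.objective)]

    return _assemble_result(
        system, diet, guidelines, problem, status, values, stages, label
    )


def solve_experiment1(
    system: FoodSystem,
    diet: Diet,
    guidelines: GuidelineSet,
    config: ScenarioConfig,
) -> SolveResult:
    """Within-group optimization under full nutrient goals.

    Lexicographic stages: largest guideline deviation (macro + micro blocks),
    then GHGE, then within-group change.  x = o is always feasible, so the
    stage-1 optimum never exceeds the observed diet's deviation.
    """
    if config.mode != MODE_WITHIN:
        raise OptimizerError("experiment 1 requires mode='within_only'")
    if config.goal_level != LEVEL_FULL:
        raise OptimizerError("experiment 1 requires goal_level='full'")
    if guidelines.level != LEVEL_FULL:
        raise OptimizerError("experiment 1 requires full guidelines")
    return _solve_within(system, diet, guidelines, config,
                         label=f"{diet.label}:exp1")


def solve_experiment2(
    system: FoodSystem,
    diet: Diet,
    guidelines: GuidelineSet,
    config: ScenarioConfig,
) -> SolveResult:
    """Within-group optimization under lowered goals (macro +/-20%, EAR)."""
    if config.mode != MODE_WITHIN:
        raise OptimizerError("experiment 2 requires mode='within_only'")
    if config.goal_level != LEVEL_LOWERED:
        raise OptimizerError("experiment 2 requires goal_level='lowered'")
    if guidelines.level == LEVEL_FULL:
        guidelines = relax_guidelines(guidelines)
    return _solve_within(system, diet, guidelines, config,
                         label=f"{diet.label}:exp2")


def solve_experiment3(
    system: FoodSystem,
    diet: Diet,
    guidelines: GuidelineSet,
    config: ScenarioConfig,
) -> SolveResult:
    """Minimal dietary change reaching a GHGE cap under hard adequacy.

    Hard constraints: every macro bound, every micronutrient at or above its
    reference, GHGE at most (1 - target) times the observed GHGE, and the
    energy band.  The objective minimizes total dietary change with a small
    GHGE tiebreak.  ``between_only`` scales whole groups;
    ``between_and_within`` moves individual items without a within-group
    budget.
    """
    if config.mode not in (MODE_BETWEEN, MODE_BOTH):
        raise OptimizerError(
            "experiment 3 requires mode 'between_only' or 'between_and_within'"
        )
    if config.ghge_reduction_target is None:
        raise OptimizerError("experiment 3 requires ghge_reduction_target")

    problem = _build_problem(system, diet, config)
    _add_energy_band(problem, config.energy_band)
    _add_hard_adequacy(system, guidelines, problem)
    ghge_obs = _observed_ghge(problem)
    cap = (1.0 - config.ghge_reduction_target) * ghge_obs
    problem.model.add_le(problem.ghge.coeffs, cap - problem.ghge.const,
                         name="ghge_cap")

    total_obs = sum(problem.observed.values())
    if total_obs <= 0:
        raise OptimizerError("observed diet has zero mass")
    change_obj = dict(problem.change_numerator)

    if config.lexicographic:
        status, values, stages = lexicographic_solve(
            problem.model,
            [("change", change_obj), ("ghge", dict(problem.ghge.coeffs))],
            tol=config.solver_tol,
        )
    else:
        scale = config.epsilon / ghge_obs if ghge_obs > 0 else config.epsilon
        objective = {v: c / total_obs for v, c in change_obj.items()}
        for v, c in problem.ghge.coeffs.items():
            objective[v] = objective.get(v, 0.0) + scale * c
        outcome = problem.model.solve(objective)
        status, values = outcome.status, outcome.values
        stages = [StageResult("weighted", outcome.status, outcome.objective)]

    result = _assemble_result(
        system, diet, guidelines, problem, status, values, stages,
        label=f"{diet.label}:exp3:{config.mode}",
    )
    if result.status == STATUS_INFEASIBLE:
        result.binding_blocks = _diagnose_infeasibility(
            system, diet, guidelines, config
        )
    return result


def _diagnose_infeasibility(
    system: FoodSystem,
    diet: Diet,
    guidelines: GuidelineSet,
    config: ScenarioConfig,
) -> list[str]:
    """Report which constraint blocks, when dropped, restore feasibility."""
    blocks: list[str] = []
    relaxations = {
        "ghge_cap": replace(config, ghge_reduction_target=None),
    }
    for name, relaxed_cfg in relaxations.items():
        try:
            problem = _build_problem(system, diet, relaxed_cfg)
            _add_energy_band(problem, relaxed_cfg.energy_band)
            _add_hard_adequacy(system, guidelines, problem)
            outcome = problem.model.solve(dict(problem.change_numerator))
            if outcome.status == STATUS_OPTIMAL:
                blocks.append(name)
        except Exception:  # diagnosis is best-effort
            continue
    if not blocks:
        blocks.append("adequacy+energy")
    return blocks
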