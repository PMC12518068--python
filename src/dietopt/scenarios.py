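"""Experiment grids: run the three optimization experiments over sweeps of
classification x allowed-change x sex and collect one result row per cell."""

from __future__ import annotations

import logging
import time
from dataclasses import replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .food_system_io import FoodSystem
from .guidelines import LEVEL_FULL, LEVEL_LOWERED, relax_guidelines
from .metrics import diversity_report
from .optimizer import (
    MODE_BETWEEN,
    MODE_BOTH,
    MODE_WITHIN,
    ScenarioConfig,
    SolveResult,
    solve_experiment1,
    solve_experiment2,
    solve_experiment3,
)

log = logging.getLogger(__name__)

ALLOWED_CHANGE_LEVELS = (0.0, 25.0, 50.0, 75.0, 100.0)

_COLUMNS = [
    "experiment", "classification", "sex", "mode", "goal_level",
    "allowed_change_pct", "status", "d_macro", "d_micro", "ghge",
    "ghge_observed", "ghge_reduction", "c_total_pct", "n_items",
    "pct_removed", "avg_max_share",
]


def _row(system: FoodSystem, sex: str, config: ScenarioConfig, experiment: int,
         result: SolveResult) -> dict:
    row = {
        "experiment": experiment,
        "classification": config.classification_id,
        "sex": sex,
        "mode": config.mode,
        "goal_level": config.goal_level,
        "allowed_change_pct": config.allowed_change_pct,
        "status": result.status,
        "d_macro": result.d_macro,
        "d_micro": result.d_micro,
        "ghge": result.ghge,
        "ghge_observed": result.ghge_observed,
        "ghge_reduction": result.ghge_reduction,
        "c_total_pct": result.c_total,
        "n_items": None,
        "pct_removed": None,
        "avg_max_share": None,
    }
    if result.status == "optimal":
        report = diversity_report(
            result.diet, system.diets[sex],
            system.classifications[config.classification_id],
        )
        row.update(
            n_items=report.n_items,
            pct_removed=report.pct_removed,
            avg_max_share=report.avg_max_share,
        )
    return row


def run_experiment_grid(
    system: FoodSystem,
    experiment: int,
    *,
    classifications: Sequence[str] | None = None,
    sexes: Sequence[str] | None = None,
    allowed_change_levels: Sequence[float] = ALLOWED_CHANGE_LEVELS,
    modes: Sequence[str] = (MODE_BETWEEN, MODE_BOTH),
    ghge_reduction_target: float = 0.30,
    base_config: ScenarioConfig | None = None,
) -> pd.DataFrame:
    """Run one experiment over its sweep axes; one row per scenario cell.

    Infeasible or failed cells are recorded with their status, never dropped.
    """
    if experiment not in (1, 2, 3):
        raise ValueError("experiment must be 1, 2 or 3")
    classifications = list(classifications or sorted(system.classifications))
    sexes = list(sexes or sorted(system.diets))
    rows = []
    for cid in classifications:
        for sex in sexes:
            diet = system.diets[sex]
            guidelines = system.guidelines[sex]
            base = base_config or ScenarioConfig(classification_id=cid)
            base = replace(base, classification_id=cid)
            if experiment in (1, 2):
                for level in allowed_change_levels:
                    goal = LEVEL_FULL if experiment == 1 else LEVEL_LOWERED
                    config = replace(
                        base, mode=MODE_WITHIN, allowed_change_pct=level,
                        goal_level=goal,
                        item_cap_enabled=(level < 100.0),
                    )
                    solver = solve_experiment1 if experiment == 1 else solve_experiment2
                    t0 = time.perf_counter()
                    result = solver(system, diet, guidelines, config)
                    log.info(
                        "exp%d %s/%s change=%g: %s (%.2fs)", experiment, cid,
                        sex, level, result.status, time.perf_counter() - t0,
                    )
                    rows.append(_row(system, sex, config, experiment, result))
            else:
                for mode in modes:
                    config = replace(
                        base, mode=mode,
                        ghge_reduction_target=ghge_reduction_target,
                        allowed_change_pct=100.0, goal_level=LEVEL_FULL,
                    )
                    t0 = time.perf_counter()
                    result = solve_experiment3(system, diet, guidelines, config)
                    log.info(
                        "exp3 %s/%s mode=%s: %s (%.2fs)", cid, sex, mode,
                        result.status, time.perf_counter() - t0,
                    )
                    rows.append(_row(system, sex, config, 3, result))
    return pd.DataFrame(rows, columns=_COLUMNS)


def render_reports(tables: dict[str, pd.DataFrame], out_dir: str | Path
                   ) -> list[Path]:
    """Write scenario tables as deterministic CSV files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        path = out / f"{name}.csv"
        tables[name].to_csv(path, index=False, float_format="%.10g")
        written.append(path)
    return written
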