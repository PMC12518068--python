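# dietopt

Lexicographic goal programming for designing diets that are nutritionally
adequate, low in greenhouse gas emissions (GHGE), and close to what people
already eat.

Starting from an observed diet (average g/day per food item), the package
builds linear programs that reallocate quantities **within** food groups
(group totals conserved), **between** food groups (whole groups scaled), or
both, and solves three experiments:

1. **Within-group optimization** — lexicographically minimize the largest
   relative deviation from macronutrient bounds and micronutrient references
   (RDA), then GHGE, then within-group change, under a configurable
   within-group change budget (0–100%) and an optional cap of each item at
   its group's highest observed quantity.
2. **Lowered nutrient goals** — the same machinery with macro bounds
   stretched by 20% (e.g. protein 10–35 E% → 8–42 E%) and micronutrient
   targets lowered from RDA to EAR.
3. **Minimal dietary change under a GHGE cap** — adequacy becomes a hard
   constraint together with a GHGE reduction target (e.g. 30%), and the
   objective minimizes total dietary change, comparing between-group-only
   against unrestricted between-and-within optimization.

Supporting modules provide loss-adjusted footprint accounting for composite
foods (`sum_i weight_i · ghge_i · 100/(100 − loss_i)` over commodity
decompositions), guideline evaluation and deviation measures, acceptability
metrics (total dietary change, removed-item fraction, within-group share
concentration), a synthetic food-system generator with configurable
guideline "bottlenecks" and analytically-solvable adversarial instances, and
a CLI that sweeps scenario grids to CSV report tables.

## Layout

| Module | Role |
| --- | --- |
| `dietopt.food_system_io` | data model (items, classifications, diets, respondents), CSV/JSON persistence, survey inclusion filters |
| `dietopt.footprint` | loss-adjusted item footprints, diet totals, per-group attribution |
| `dietopt.guidelines` | guideline sets, nutrient profiles, deviation measures, goal relaxation |
| `dietopt.optimizer` | the three LP experiments (split-variable change linearization, lexicographic or weighted solves via HiGHS) |
| `dietopt.metrics` | total dietary change and diversity/concentration reports |
| `dietopt.synthetic_data` | seeded generators for food systems, respondents, and known-optimum instances |
| `dietopt.scenarios` / `dietopt.cli` | experiment grids, report rendering, command-line interface |

## CLI

```sh
# generate a synthetic food system (seeded, deterministic)
dietopt generate --preset default --seed 1 --out scratch/system

# run experiment 1 over classifications and change budgets
dietopt run --experiment 1 --system scratch/system \
    --classification fine --allowed-change 0 --allowed-change 100 \
    --sex female --out scratch/run1

# experiment 3: between vs between-and-within under a 30% GHGE cap
dietopt run --experiment 3 --system scratch/system --ghge-target 0.30 \
    --out scratch/run3
```

Exit codes: 0 on success, 2 when every scenario cell is infeasible, 1 on
errors. `dietopt generate --preset known-optimum:<kind>` emits one of the
adversarial instances (`within_swap`, `between_removal`, `infeasible_cap`,
`adequacy_vs_ghge`) together with its analytic optimum in `expected.json`.

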