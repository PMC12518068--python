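"""Food-system data model, CSV/JSON persistence, and intake-survey filters.

The food system bundles everything the pipeline needs: food items with
per-100 g compositions, optional per-100 g footprints, hierarchical
food-group classifications, observed diets (average g/day per item), and
nutrient guideline sets.  All tables round-trip through plain-text CSV/JSON
so generated systems can be inspected and versioned.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .guidelines import GuidelineSet

log = logging.getLogger(__name__)

FEMALE = "female"
MALE = "male"

#: sex -> (energy lower, energy upper) kcal/day, both inclusive
ENERGY_WINDOWS = {FEMALE: (1200.0, 3000.0), MALE: (1800.0, 3600.0)}
AGE_MIN, AGE_MAX = 18.0, 65.0

#: group ids treated as the non-optimizable residual category
OTHER_GROUP_IDS = frozenset({"other"})


class FoodSystemError(ValueError):
    """Raised on schema or cross-reference violations in food-system data."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

MACRO_ENERGY = "macro_energy"
MACRO_MASS = "macro_mass"
MICRO = "micro"
NUTRIENT_KINDS = (MACRO_ENERGY, MACRO_MASS, MICRO)


@dataclass(frozen=True)
class NutrientDef:
    """Declaration of one nutrient column: unit, constraint kind, Atwater factor.

    ``kind`` decides how the guideline engine treats the nutrient:

    * ``macro_energy`` -- bounded as a percentage of energy intake (E%);
      requires an Atwater factor (kcal per g) of 4 or 9.
    * ``macro_mass``   -- bounded in absolute mass per day (fiber, sodium).
    * ``micro``        -- compared against RDA/EAR reference amounts.
    """

    nutrient_id: str
    name: str
    unit: str
    kind: str
    atwater: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in NUTRIENT_KINDS:
            raise FoodSystemError(
                f"nutrient {self.nutrient_id!r}: unknown kind {self.kind!r}"
            )
        if self.kind == MACRO_ENERGY:
            if self.atwater not in (4.0, 9.0, 4, 9):
                raise FoodSystemError(
                    f"nutrient {self.nutrient_id!r}: macro_energy requires "
                    f"atwater in {{4, 9}}, got {self.atwater!r}"
                )
        elif self.atwater is not None:
            raise FoodSystemError(
                f"nutrient {self.nutrient_id!r}: atwater only valid for "
                f"macro_energy nutrients"
            )


@dataclass
class FoodItem:
    """One food item: energy and nutrient content per 100 g, footprint, flags."""

    item_id: str
    name: str
    energy: float  # kcal per 100 g
    nutrients: dict[str, float] = field(default_factory=dict)  # per 100 g
    ghge: float | None = None  # kg CO2 eq per 100 g
    fixed: bool = False
    occurrences: int | None = None

    def __post_init__(self) -> None:
        if self.energy < 0:
            raise FoodSystemError(f"item {self.item_id!r}: negative energy")
        for nid, amount in self.nutrients.items():
            if amount < 0:
                raise FoodSystemError(
                    f"item {self.item_id!r}: negative amount for {nid!r}"
                )
        if self.ghge is not None and self.ghge < 0:
            raise FoodSystemError(f"item {self.item_id!r}: negative ghge")


@dataclass
class Classification:
    """A partition of (at least) the optimizable items into food groups."""

    classification_id: str
    groups: dict[str, str]  # group_id -> display name
    assignment: dict[str, str]  # item_id -> group_id

    def group_of(self, item_id: str) -> str:
        return self.assignment[item_id]

    def members(self, group_id: str) -> list[str]:
        return [i for i, g in self.assignment.items() if g == group_id]

    def by_group(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {g: [] for g in self.groups}
        for item_id in sorted(self.assignment):
            out.setdefault(self.assignment[item_id], []).append(item_id)
        return out


@dataclass
class Diet:
    """Quantity vector in g/day over food items for one target group."""

    label: str
    quantities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for item_id, q in self.quantities.items():
            if q < 0:
                raise FoodSystemError(
                    f"diet {self.label!r}: negative quantity for {item_id!r}"
                )

    def get(self, item_id: str) -> float:
        return self.quantities.get(item_id, 0.0)

    def total_mass(self) -> float:
        return float(sum(self.quantities.values()))


@dataclass
class Respondent:
    respondent_id: str
    sex: str
    age: float
    energy_intake: float  # kcal/day
    intakes: dict[str, float] = field(default_factory=dict)  # item_id -> g/day

    def __post_init__(self) -> None:
        if self.age < 0:
            raise FoodSystemError(f"respondent {self.respondent_id!r}: negative age")
        if self.energy_intake < 0:
            raise FoodSystemError(
                f"respondent {self.respondent_id!r}: negative energy intake"
            )


@dataclass
class FoodSystem:
    """The complete modeling universe for one study population."""

    items: dict[str, FoodItem]
    nutrient_defs: dict[str, NutrientDef]
    classifications: dict[str, Classification] = field(default_factory=dict)
    diets: dict[str, Diet] = field(default_factory=dict)
    guidelines: dict[str, GuidelineSet] = field(default_factory=dict)
    # footprint inputs (optional; item ghge may be given directly instead)
    commodity_shares: dict[str, dict[str, float]] = field(default_factory=dict)
    commodity_ghge: dict[str, float] = field(default_factory=dict)  # kg/g
    loss_factors: dict[str, float] = field(default_factory=dict)  # percent

    # -- queries ------------------------------------------------------------

    def optimizable_items(self) -> list[str]:
        return sorted(i for i, it in self.items.items() if not it.fixed)

    def fixed_items(self) -> list[str]:
        return sorted(i for i, it in self.items.items() if it.fixed)

    def item_ghge(self, item_id: str) -> float:
        it = self.items[item_id]
        if it.ghge is None:
            raise FoodSystemError(f"item {item_id!r} has no footprint")
        return it.ghge

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check all cross-references and invariants; raise on the first failure."""
        for item in self.items.values():
            for nid in item.nutrients:
                if nid not in self.nutrient_defs:
                    raise FoodSystemError(
                        f"item {item.item_id!r}: undeclared nutrient {nid!r}"
                    )
        optimizable = set(self.optimizable_items())
        for cls in self.classifications.values():
            for item_id, group_id in cls.assignment.items():
                if item_id not in self.items:
                    raise FoodSystemError(
                        f"classification {cls.classification_id!r}: unknown "
                        f"item {item_id!r}"
                    )
                if group_id not in cls.groups:
                    raise FoodSystemError(
                        f"classification {cls.classification_id!r}: item "
                        f"{item_id!r} assigned to undeclared group {group_id!r}"
                    )
            missing = optimizable - set(cls.assignment)
            if missing:
                raise FoodSystemError(
                    f"classification {cls.classification_id!r}: optimizable "
                    f"items without a group: {sorted(missing)[:5]}"
                )
            for group_id in cls.groups:
                if not any(g == group_id for g in cls.assignment.values()):
                    raise FoodSystemError(
                        f"classification {cls.classification_id!r}: empty "
                        f"group {group_id!r}"
                    )
        for diet in self.diets.values():
            unknown = set(diet.quantities) - set(self.items)
            if unknown:
                raise FoodSystemError(
                    f"diet {diet.label!r}: unknown item(s) {sorted(unknown)[:5]}"
                )
        for item_id, shares in self.commodity_shares.items():
            if item_id not in self.items:
                raise FoodSystemError(
                    f"commodity shares reference unknown item {item_id!r}"
                )
            for cid in shares:
                if cid not in self.commodity_ghge:
                    raise FoodSystemError(
                        f"item {item_id!r}: commodity {cid!r} has no footprint"
                    )


# ---------------------------------------------------------------------------
# survey-derived operations
# ---------------------------------------------------------------------------


def filter_respondents(respondents: Iterable[Respondent]) -> list[Respondent]:
    """Apply the age and sex-specific energy-intake inclusion rules.

    Retains respondents aged 18-65 (inclusive) whose reported energy intake
    lies inside the sex-specific window: 1,200-3,000 kcal for females and
    1,800-3,600 kcal for males, bounds inclusive (the exclusion rule removes
    intakes strictly below/above the window).  Input order is preserved and
    the operation is idempotent.
    """
    kept: list[Respondent] = []
    for r in respondents:
        if r.sex not in ENERGY_WINDOWS:
            raise FoodSystemError(
                f"respondent {r.respondent_id!r}: unknown sex label {r.sex!r}"
            )
        lo, hi = ENERGY_WINDOWS[r.sex]
        if AGE_MIN <= r.age <= AGE_MAX and lo <= r.energy_intake <= hi:
            kept.append(r)
    return kept


def average_diet(respondents: Sequence[Respondent], sex: str) -> Diet:
    """Average daily intake per item (g/day) over respondents of one sex.

    Respondents not reporting an item contribute zero for that item.
    """
    group = [r for r in respondents if r.sex == sex]
    if not group:
        raise FoodSystemError(f"no respondents with sex {sex!r}")
    totals: dict[str, float] = {}
    for r in group:
        for item_id, grams in r.intakes.items():
            totals[item_id] = totals.get(item_id, 0.0) + grams
    n = len(group)
    return Diet(label=sex, quantities={i: t / n for i, t in sorted(totals.items())})


def mark_fixed_items(
    system: FoodSystem,
    classification_id: str,
    min_occurrences: int = 3,
) -> FoodSystem:
    """Flag rarely-consumed and residual-category items as non-optimizable.

    Items assigned to an ``other`` group in the given classification, or with
    at most ``min_occurrences`` reported consumption occurrences, get
    ``fixed = True`` (their quantities are never altered by optimization).
    Returns the same system, mutated in place.
    """
    cls = system.classifications[classification_id]
    for item in system.items.values():
        group = cls.assignment.get(item.item_id)
        in_other = group is not None and group.lower() in OTHER_GROUP_IDS
        rare = item.occurrences is not None and item.occurrences <= min_occurrences
        if in_other or rare:
            item.fixed = True
    return system


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_FOOD_BASE_COLS = ["item_id", "name", "energy", "fixed", "occurrences"]


def write_food_system(system: FoodSystem, out_dir: str | Path) -> list[Path]:
    """Write all food-system tables to ``out_dir`` (UTF-8 CSV/JSON).

    Emits foods.csv, nutrients.json, classification_<id>.csv, diet_<label>.csv,
    guidelines.json and, when present, the footprint input tables.  Returns
    the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    nutrient_ids = sorted(system.nutrient_defs)

    rows = []
    for item_id in sorted(system.items):
        it = system.items[item_id]
        row: dict[str, object] = {
            "item_id": it.item_id,
            "name": it.name,
            "energy": repr(it.energy),
            "fixed": int(it.fixed),
            "occurrences": "" if it.occurrences is None else it.occurrences,
        }
        for nid in nutrient_ids:
            row[nid] = repr(it.nutrients.get(nid, 0.0))
        row["ghge"] = "" if it.ghge is None else repr(it.ghge)
        rows.append(row)
    foods = out / "foods.csv"
    pd.DataFrame(rows, columns=_FOOD_BASE_COLS + nutrient_ids + ["ghge"]).to_csv(
        foods, index=False
    )
    written.append(foods)

    ndefs = out / "nutrients.json"
    ndefs.write_text(
        json.dumps(
            [dataclasses.asdict(system.nutrient_defs[n]) for n in nutrient_ids],
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
    written.append(ndefs)

    for cid in sorted(system.classifications):
        cls = system.classifications[cid]
        path = out / f"classification_{cid}.csv"
        pd.DataFrame(
            [
                {
                    "item_id": item_id,
                    "group_id": group_id,
                    "group_name": cls.groups[group_id],
                }
                for item_id, group_id in sorted(cls.assignment.items())
            ]
        ).to_csv(path, index=False)
        written.append(path)

    for label in sorted(system.diets):
        diet = system.diets[label]
        path = out / f"diet_{label}.csv"
        pd.DataFrame(
            [
                {"item_id": i, "grams_per_day": repr(q)}
                for i, q in sorted(diet.quantities.items())
            ],
            columns=["item_id", "grams_per_day"],
        ).to_csv(path, index=False)
        written.append(path)

    if system.guidelines:
        path = out / "guidelines.json"
        path.write_text(
            json.dumps(
                {label: g.to_dict() for label, g in sorted(system.guidelines.items())},
                indent=2,
            )
            + "\n",
            encoding="utf-8",
        )
        written.append(path)

    if system.commodity_shares:
        path = out / "commodity_shares.csv"
        pd.DataFrame(
            [
                {"item_id": i, "commodity_id": c, "weight_g_per_100g": repr(w)}
                for i in sorted(system.commodity_shares)
                for c, w in sorted(system.commodity_shares[i].items())
            ]
        ).to_csv(path, index=False)
        written.append(path)
        path = out / "commodity_ghge.csv"
        pd.DataFrame(
            [
                {"commodity_id": c, "ghge": repr(v), "unit": "kg_per_g"}
                for c, v in sorted(system.commodity_ghge.items())
            ]
        ).to_csv(path, index=False)
        written.append(path)
        path = out / "loss_factors.csv"
        pd.DataFrame(
            [
                {"commodity_id": c, "loss_pct": repr(v)}
                for c, v in sorted(system.loss_factors.items())
            ]
        ).to_csv(path, index=False)
        written.append(path)

    return written


def load_food_system(in_dir: str | Path) -> FoodSystem:
    """Load a food system previously written by :func:`write_food_system`.

    Round-trip stable: ``load(write(system))`` reproduces every numeric value
    (floats are serialized with ``repr`` so the round-trip is bit-exact).
    Cross-references are validated; violations raise :class:`FoodSystemError`
    naming the offending identifier.
    """
    src = Path(in_dir)
    foods_path = src / "foods.csv"
    if not foods_path.exists():
        raise FoodSystemError(f"missing foods.csv in {src}")

    ndefs_path = src / "nutrients.json"
    if not ndefs_path.exists():
        raise FoodSystemError(f"missing nutrients.json in {src}")
    nutrient_defs = {
        d["nutrient_id"]: NutrientDef(**d)
        for d in json.loads(ndefs_path.read_text(encoding="utf-8"))
    }

    foods = pd.read_csv(foods_path, dtype={"item_id": str})
    missing_cols = [c for c in _FOOD_BASE_COLS if c not in foods.columns]
    if missing_cols:
        raise FoodSystemError(f"foods.csv missing column(s) {missing_cols}")
    for nid in nutrient_defs:
        if nid not in foods.columns:
            raise FoodSystemError(f"foods.csv missing nutrient column {nid!r}")

    items: dict[str, FoodItem] = {}
    for rec in foods.to_dict("records"):
        occ = rec.get("occurrences")
        ghge = rec.get("ghge")
        items[str(rec["item_id"])] = FoodItem(
            item_id=str(rec["item_id"]),
            name=str(rec["name"]),
            energy=float(rec["energy"]),
            nutrients={nid: float(rec[nid]) for nid in nutrient_defs},
            ghge=None if pd.isna(ghge) else float(ghge),
            fixed=bool(int(rec["fixed"])),
            occurrences=None if pd.isna(occ) else int(occ),
        )

    system = FoodSystem(items=items, nutrient_defs=nutrient_defs)

    for path in sorted(src.glob("classification_*.csv")):
        cid = path.stem[len("classification_"):]
        df = pd.read_csv(path, dtype=str)
        groups = {
            str(g): str(n)
            for g, n in df[["group_id", "group_name"]].drop_duplicates().values
        }
        assignment = dict(zip(df["item_id"].astype(str), df["group_id"].astype(str)))
        system.classifications[cid] = Classification(cid, groups, assignment)

    for path in sorted(src.glob("diet_*.csv")):
        label = path.stem[len("diet_"):]
        df = pd.read_csv(path, dtype={"item_id": str})
        system.diets[label] = Diet(
            label=label,
            quantities={
                str(i): float(q)
                for i, q in zip(df["item_id"], df["grams_per_day"])
            },
        )

    gpath = src / "guidelines.json"
    if gpath.exists():
        payload = json.loads(gpath.read_text(encoding="utf-8"))
        system.guidelines = {
            label: GuidelineSet.from_dict(d) for label, d in payload.items()
        }

    spath = src / "commodity_shares.csv"
    if spath.exists():
        df = pd.read_csv(spath, dtype={"item_id": str, "commodity_id": str})
        for rec in df.to_dict("records"):
            system.commodity_shares.setdefault(str(rec["item_id"]), {})[
                str(rec["commodity_id"])
            ] = float(rec["weight_g_per_100g"])
        gdf = pd.read_csv(src / "commodity_ghge.csv", dtype={"commodity_id": str})
        for rec in gdf.to_dict("records"):
            value = float(rec["ghge"])
            unit = str(rec.get("unit", "kg_per_g"))
            if unit == "kg_per_kg":
                value /= 1000.0
            elif unit != "kg_per_g":
                raise FoodSystemError(f"unknown commodity ghge unit {unit!r}")
            system.commodity_ghge[str(rec["commodity_id"])] = value
        ldf = pd.read_csv(src / "loss_factors.csv", dtype={"commodity_id": str})
        system.loss_factors = {
            str(rec["commodity_id"]): float(rec["loss_pct"])
            for rec in ldf.to_dict("records")
        }

    system.validate()
    return system


def load_respondents(path: str | Path, intakes_path: str | Path | None = None
                     ) -> list[Respondent]:
    """Read respondents.csv (+ optional long-format respondent_intakes.csv)."""
    df = pd.read_csv(path, dtype={"respondent_id": str})
    respondents = {
        str(rec["respondent_id"]): Respondent(
            respondent_id=str(rec["respondent_id"]),
            sex=str(rec["sex"]),
            age=float(rec["age"]),
            energy_intake=float(rec["energy_intake"]),
        )
        for rec in df.to_dict("records")
    }
    if intakes_path is not None and Path(intakes_path).exists():
        idf = pd.read_csv(intakes_path, dtype={"respondent_id": str, "item_id": str})
        for rec in idf.to_dict("records"):
            rid = str(rec["respondent_id"])
            if rid not in respondents:
                raise FoodSystemError(f"intake row for unknown respondent {rid!r}")
            respondents[rid].intakes[str(rec["item_id"])] = float(
                rec["grams_per_day"]
            )
    return list(respondents.values())


def write_respondents(
    respondents: Sequence[Respondent], out_dir: str | Path
) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rpath = out / "respondents.csv"
    pd.DataFrame(
        [
            {
                "respondent_id": r.respondent_id,
                "sex": r.sex,
                "age": repr(r.age),
                "energy_intake": repr(r.energy_intake),
            }
            for r in respondents
        ]
    ).to_csv(rpath, index=False)
    ipath = out / "respondent_intakes.csv"
    pd.DataFrame(
        [
            {"respondent_id": r.respondent_id, "item_id": i, "grams_per_day": repr(q)}
            for r in respondents
            for i, q in sorted(r.intakes.items())
        ],
        columns=["respondent_id", "item_id", "grams_per_day"],
    ).to_csv(ipath, index=False)
    return rpath, ipath
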