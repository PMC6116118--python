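"""Reading and aggregation of food-composition libraries and 24 h dietary recalls.

The module turns two delimited-text inputs — a food-composition library
(per-100 g energy, macronutrients, simple sugars, MUFA/SFA, calcium, food-group
tags and beverage flags) and long-format recall lines (participant, day, meal,
food, grams) — into per-day intake aggregates. Breakfast is identified by an
explicit meal label, never by clock time. Nutrient resolution is linear in
grams: ``mass × per-100 g value / 100``.

Two recall days per participant are the unit of analysis: :func:`average_days`
takes the arithmetic mean of every quantity over the days a meal is present
(total daily energy is always the mean of both days), and
:func:`apply_exclusions` drops participants with fewer than two resolvable
recall days, logging a reason per exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DomainError, ResolutionError, SchemaError

#: Food-group tags the library may use.
FOOD_GROUPS = frozenset(
    {
        "cereal",
        "fruit_or_vegetable",
        "dairy",
        "olive_oil",
        "butter_margarine",
        "sugar_rich",
        "other",
    }
)

#: Meal labels accepted in recall files.
MEALS = ("breakfast", "mid_morning", "lunch", "snack", "dinner", "other")

_LIBRARY_COLUMNS = (
    "food_id",
    "name",
    "energy_kcal_per_100g",
    "carb_g",
    "simple_sugar_g",
    "fat_g",
    "mufa_g",
    "sfa_g",
    "protein_g",
    "calcium_mg_per_100g",
    "groups",
    "is_beverage",
    "is_energy_beverage",
)

_RECALL_COLUMNS = ("participant_id", "day_index", "meal", "food_id", "grams")

# tolerance for the compositional invariants on hand-entered per-100 g values
_TOL = 1e-9


@dataclass(frozen=True)
class FoodEntry:
    """One row of the food-composition library (all nutrient values per 100 g)."""

    food_id: str
    name: str
    energy_kcal_per_100g: float
    carb_g: float
    simple_sugar_g: float
    fat_g: float
    mufa_g: float
    sfa_g: float
    protein_g: float
    calcium_mg_per_100g: float
    groups: frozenset
    is_beverage: bool
    is_energy_beverage: bool

    def __post_init__(self) -> None:
        for f in (
            "energy_kcal_per_100g",
            "carb_g",
            "simple_sugar_g",
            "fat_g",
            "mufa_g",
            "sfa_g",
            "protein_g",
            "calcium_mg_per_100g",
        ):
            v = getattr(self, f)
            if not (v >= 0):
                raise SchemaError(f"food {self.food_id!r}: column {f} must be >= 0, got {v!r}")
        if self.simple_sugar_g > self.carb_g + _TOL:
            raise SchemaError(
                f"food {self.food_id!r}: simple_sugar_g ({self.simple_sugar_g}) exceeds carb_g ({self.carb_g})"
            )
        if self.mufa_g + self.sfa_g > self.fat_g + _TOL:
            raise SchemaError(
                f"food {self.food_id!r}: mufa_g + sfa_g exceeds fat_g"
            )
        bad = set(self.groups) - FOOD_GROUPS
        if bad:
            raise SchemaError(f"food {self.food_id!r}: unknown group tag(s) {sorted(bad)}")
        if self.is_energy_beverage and not (self.is_beverage and self.energy_kcal_per_100g > 0):
            raise SchemaError(
                f"food {self.food_id!r}: is_energy_beverage requires is_beverage and positive energy"
            )


@dataclass(frozen=True)
class RecallLine:
    """One food line of a 24 h recall."""

    participant_id: str
    day_index: int
    meal: str
    food_id: str
    grams: float

    def __post_init__(self) -> None:
        if self.day_index not in (1, 2):
            raise SchemaError(f"day_index must be 1 or 2, got {self.day_index!r}")
        if self.meal not in MEALS:
            raise SchemaError(f"unknown meal label {self.meal!r}")
        if not (self.grams > 0):
            raise SchemaError(
                f"participant {self.participant_id!r} day {self.day_index}: grams must be > 0"
            )


@dataclass(frozen=True)
class ResolvedFood:
    """A recall line with nutrients resolved from the library (absolute masses)."""

    food_id: str
    grams: float
    energy_kcal: float
    carb_g: float
    simple_sugar_g: float
    fat_g: float
    mufa_g: float
    sfa_g: float
    protein_g: float
    calcium_mg: float
    groups: frozenset
    is_beverage: bool
    is_energy_beverage: bool

    @property
    def is_solid(self) -> bool:
        return not self.is_beverage


@dataclass(frozen=True)
class BreakfastTotals:
    """Additive breakfast aggregates (the quantities the indices consume)."""

    energy_kcal: float
    mass_g: float
    calcium_mg: float
    mufa_g: float
    sfa_g: float
    sugar_rich_energy_kcal: float
    solid_mass_g: float
    solid_energy_kcal: float
    energy_beverage_mass_g: float
    energy_beverage_energy_kcal: float


class BreakfastRecord:
    """Resolved breakfast of one recall day.

    Holds the per-food resolved lines; totals are sums over lines. The solid
    and energy-beverage partitions are disjoint: solids are non-beverages,
    energy beverages are beverages with positive energy density, and
    non-energy beverages (e.g. water) belong to neither energy partition.
    """

    def __init__(self, foods: Sequence[ResolvedFood]):
        self.foods = tuple(foods)

    def has_group(self, tag: str) -> bool:
        return any(tag in f.groups for f in self.foods)

    @property
    def totals(self) -> BreakfastTotals:
        s = lambda key: sum(getattr(f, key) for f in self.foods)  # noqa: E731
        solids = [f for f in self.foods if f.is_solid]
        ebev = [f for f in self.foods if f.is_energy_beverage]
        return BreakfastTotals(
            energy_kcal=s("energy_kcal"),
            mass_g=s("grams"),
            calcium_mg=s("calcium_mg"),
            mufa_g=s("mufa_g"),
            sfa_g=s("sfa_g"),
            sugar_rich_energy_kcal=sum(
                f.energy_kcal for f in self.foods if "sugar_rich" in f.groups
            ),
            solid_mass_g=sum(f.grams for f in solids),
            solid_energy_kcal=sum(f.energy_kcal for f in solids),
            energy_beverage_mass_g=sum(f.grams for f in ebev),
            energy_beverage_energy_kcal=sum(f.energy_kcal for f in ebev),
        )


@dataclass
class DayIntake:
    """One resolved recall day; ``breakfast`` is None when no breakfast line exists."""

    participant_id: str
    day_index: int
    total_energy_kcal: float
    breakfast: BreakfastRecord | None


@dataclass
class AveragedIntake:
    """Two-day average of one participant's intake.

    Breakfast-level totals are averaged over the days a breakfast is present;
    when present on a single day they equal that day's totals and
    ``partial_breakfast`` is set. Total daily energy is always the mean of
    both days.
    """

    participant_id: str
    total_energy_kcal: float
    breakfast: BreakfastTotals | None
    breakfast_days: int
    partial_breakfast: bool


def _parse_bool(value, *, row: int, column: str) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"1", "true", "yes"}:
        return True
    if text in {"0", "false", "no"}:
        return False
    raise SchemaError(f"row {row}, column {column}: cannot parse boolean from {value!r}")


def load_food_library(path: str | Path) -> dict[str, FoodEntry]:
    """Load and validate a food-composition library.

    Parameters
    ----------
    path
        Comma-delimited UTF-8 file whose header matches the
        :class:`FoodEntry` schema; ``groups`` is a semicolon-separated tag list.

    Returns
    -------
    dict mapping food_id to validated :class:`FoodEntry`.

    Raises
    ------
    SchemaError
        On a missing column, negative nutrient, unknown tag, duplicate id or
        any other invariant violation; the message names the row and column.
    """
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _LIBRARY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"food library {path}: missing column(s) {missing}")
    library: dict[str, FoodEntry] = {}
    for i, row in enumerate(table.itertuples(index=False), start=2):  # header is row 1
        food_id = row.food_id.strip()
        numeric = {}
        for col in (
            "energy_kcal_per_100g",
            "carb_g",
            "simple_sugar_g",
            "fat_g",
            "mufa_g",
            "sfa_g",
            "protein_g",
            "calcium_mg_per_100g",
        ):
            raw = getattr(row, col)
            try:
                numeric[col] = float(raw)
            except ValueError as exc:
                raise SchemaError(f"row {i}, column {col}: not a number: {raw!r}") from exc
        groups = frozenset(t.strip() for t in row.groups.split(";") if t.strip())
        try:
            entry = FoodEntry(
                food_id=food_id,
                name=row.name,
                groups=groups,
                is_beverage=_parse_bool(row.is_beverage, row=i, column="is_beverage"),
                is_energy_beverage=_parse_bool(
                    row.is_energy_beverage, row=i, column="is_energy_beverage"
                ),
                **numeric,
            )
        except SchemaError as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
        if food_id in library:
            raise SchemaError(f"row {i}: duplicate food_id {food_id!r}")
        library[food_id] = entry
    return library


def load_recalls(path: str | Path) -> list[RecallLine]:
    """Load long-format recall lines (participant_id, day_index, meal, food_id, grams)."""
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _RECALL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"recall file {path}: missing column(s) {missing}")
    lines = []
    for i, row in enumerate(table.itertuples(index=False), start=2):
        try:
            lines.append(
                RecallLine(
                    participant_id=row.participant_id.strip(),
                    day_index=int(row.day_index),
                    meal=row.meal.strip(),
                    food_id=row.food_id.strip(),
                    grams=float(row.grams),
                )
            )
        except (ValueError, SchemaError) as exc:
            raise SchemaError(f"recall file row {i}: {exc}") from exc
    return lines


def resolve_line(line: RecallLine, library: Mapping[str, FoodEntry]) -> ResolvedFood:
    """Resolve one recall line to absolute nutrient masses (grams × per-100 g / 100)."""
    entry = library.get(line.food_id)
    if entry is None:
        raise ResolutionError(
            f"participant {line.participant_id!r} day {line.day_index}: "
            f"unknown food_id {line.food_id!r}"
        )
    k = line.grams / 100.0
    return ResolvedFood(
        food_id=entry.food_id,
        grams=line.grams,
        energy_kcal=k * entry.energy_kcal_per_100g,
        carb_g=k * entry.carb_g,
        simple_sugar_g=k * entry.simple_sugar_g,
        fat_g=k * entry.fat_g,
        mufa_g=k * entry.mufa_g,
        sfa_g=k * entry.sfa_g,
        protein_g=k * entry.protein_g,
        calcium_mg=k * entry.calcium_mg_per_100g,
        groups=entry.groups,
        is_beverage=entry.is_beverage,
        is_energy_beverage=entry.is_energy_beverage,
    )


def resolve_day(
    lines: Iterable[RecallLine], library: Mapping[str, FoodEntry]
) -> DayIntake:
    """Aggregate one participant-day of recall lines into a :class:`DayIntake`.

    All lines must share participant and day. Breakfast is the subset of
    lines labelled ``breakfast`` and is absent when no such line exists.
    """
    lines = list(lines)
    if not lines:
        raise DomainError("resolve_day requires at least one recall line")
    pids = {l.participant_id for l in lines}
    days = {l.day_index for l in lines}
    if len(pids) > 1 or len(days) > 1:
        raise DomainError(
            f"resolve_day received mixed participants {sorted(pids)} / days {sorted(days)}"
        )
    resolved = [resolve_line(l, library) for l in lines]
    breakfast_foods = [
        r for l, r in zip(lines, resolved) if l.meal == "breakfast"
    ]
    return DayIntake(
        participant_id=lines[0].participant_id,
        day_index=lines[0].day_index,
        total_energy_kcal=sum(r.energy_kcal for r in resolved),
        breakfast=BreakfastRecord(breakfast_foods) if breakfast_foods else None,
    )


def average_days(d1: DayIntake, d2: DayIntake) -> AveragedIntake:
    """Average two resolved recall days of the same participant.

    Breakfast totals are averaged field-wise over the days a breakfast is
    present; daily energy is the mean of both days regardless.
    """
    if d1.participant_id != d2.participant_id:
        raise DomainError(
            f"cannot average days of different participants "
            f"({d1.participant_id!r} vs {d2.participant_id!r})"
        )
    present = [d.breakfast.totals for d in (d1, d2) if d.breakfast is not None]
    if present:
        avg = BreakfastTotals(
            **{
                f.name: sum(getattr(t, f.name) for t in present) / len(present)
                for f in fields(BreakfastTotals)
            }
        )
    else:
        avg = None
    return AveragedIntake(
        participant_id=d1.participant_id,
        total_energy_kcal=(d1.total_energy_kcal + d2.total_energy_kcal) / 2.0,
        breakfast=avg,
        breakfast_days=len(present),
        partial_breakfast=len(present) == 1,
    )


@dataclass(frozen=True)
class Exclusion:
    participant_id: str
    reason: str


def apply_exclusions(
    days_by_participant: Mapping[str, Sequence[DayIntake]],
) -> tuple[dict[str, tuple[DayIntake, DayIntake]], list[Exclusion]]:
    """Drop participants without two resolvable recall days.

    Returns the retained mapping (participant -> day pair ordered by
    day_index) and an exclusion log with one reason per dropped participant
    ("no recalls" or "single recall").
    """
    retained: dict[str, tuple[DayIntake, DayIntake]] = {}
    log: list[Exclusion] = []
    for pid, days in days_by_participant.items():
        distinct = {d.day_index: d for d in days}
        if len(distinct) >= 2:
            ordered = sorted(distinct.values(), key=lambda d: d.day_index)
            retained[pid] = (ordered[0], ordered[1])
        elif len(distinct) == 1:
            log.append(Exclusion(pid, "single recall"))
        else:
            log.append(Exclusion(pid, "no recalls"))
    return retained, log
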