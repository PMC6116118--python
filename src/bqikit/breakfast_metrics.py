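"""Breakfast adequacy indices computed from a resolved breakfast.

Three families of metrics, all operating on one recall day's
:class:`~bqikit.recall_io.BreakfastRecord`:

* the 10-item Breakfast Quality Index (BQI, 0–10), a Mediterranean-pattern
  itemized score — one point per criterion met;
* breakfast energy density split into solids (BEDs) and energy-containing
  beverages (BEDb), each in kcal/g, with non-energy beverages (water,
  zero-kcal drinks) excluded from both denominators;
* two breakfast-skipping classifications: recall-based (no breakfast on
  either recall day) and questionnaire-based (the KIDMED breakfast item,
  echoed as reported, unknown when missing).

The BQI criteria, with the package's operational conventions:

i    any food tagged ``cereal``
ii   any food tagged ``fruit_or_vegetable``
iii  any food tagged ``dairy``
iv   energy from ``sugar_rich`` foods at breakfast < 5% of daily energy
v    any food tagged ``olive_oil``
vi   MUFA/SFA ratio >= 2 (met when SFA is zero and MUFA positive; not met
     when both are zero)
vii  breakfast energy within 20–25% of daily energy, inclusive at both ends
viii cereals, fruit/vegetables and dairy all present in the same meal
ix   breakfast calcium >= 200 mg (lower bound of the published 200–300 mg
     range; configurable)
x    no food tagged ``butter_margarine``
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError
from .recall_io import AveragedIntake, BreakfastRecord, BreakfastTotals, DayIntake

#: Ordered item keys (i–x) of the BQI.
BQI_ITEMS = (
    "cereal",
    "fruit_vegetable",
    "dairy",
    "low_simple_sugar",
    "olive_oil",
    "mufa_sfa_ratio",
    "energy_share",
    "cereal_fruit_dairy",
    "calcium",
    "no_butter_margarine",
)


@dataclass(frozen=True)
class BqiResult:
    """Outcome of scoring one breakfast: per-item booleans plus the total."""

    items: dict
    score: int
    inputs_echo: BreakfastTotals | None

    def __post_init__(self) -> None:
        assert tuple(self.items) == BQI_ITEMS
        assert self.score == sum(self.items.values())
        assert 0 <= self.score <= 10
        if self.items["cereal_fruit_dairy"]:
            assert (
                self.items["cereal"] and self.items["fruit_vegetable"] and self.items["dairy"]
            )


@dataclass(frozen=True)
class EnergyDensityResult:
    """BEDs / BEDb in kcal/g; a value is None when its mass denominator is zero."""

    beds_kcal_per_g: float | None
    bedb_kcal_per_g: float | None


@dataclass(frozen=True)
class SkippingStatus:
    """Breakfast-skipping classification under both definitions."""

    by_recall: bool
    by_kidmed: bool | None


def score_bqi(
    breakfast: BreakfastRecord | None,
    daily_energy_kcal: float,
    *,
    calcium_min_mg: float = 200.0,
    energy_share_band: tuple[float, float] = (0.20, 0.25),
    sugar_rich_energy_max: float = 0.05,
    mufa_sfa_min: float = 2.0,
) -> BqiResult:
    """Score one breakfast on the 10-item BQI.

    Parameters
    ----------
    breakfast
        The day's resolved breakfast, or None when no breakfast was eaten —
        an absent breakfast scores 0 with all items false.
    daily_energy_kcal
        Total energy intake of the same day (denominator of items iv and vii);
        must be positive.
    calcium_min_mg, energy_share_band, sugar_rich_energy_max, mufa_sfa_min
        Operational thresholds for items ix, vii, iv and vi. Defaults: 200 mg,
        the inclusive 20–25% band, 5% and a 2:1 ratio.
    """
    if not daily_energy_kcal > 0:
        raise DomainError(f"daily_energy_kcal must be > 0, got {daily_energy_kcal!r}")
    if breakfast is None or not breakfast.foods:
        items = {k: False for k in BQI_ITEMS}
        return BqiResult(items=items, score=0, inputs_echo=None)

    t = breakfast.totals
    if t.sfa_g > 0:
        ratio_ok = t.mufa_g / t.sfa_g >= mufa_sfa_min
    else:
        ratio_ok = t.mufa_g > 0
    lo, hi = energy_share_band
    share = t.energy_kcal / daily_energy_kcal
    items = {
        "cereal": breakfast.has_group("cereal"),
        "fruit_vegetable": breakfast.has_group("fruit_or_vegetable"),
        "dairy": breakfast.has_group("dairy"),
        "low_simple_sugar": t.sugar_rich_energy_kcal < sugar_rich_energy_max * daily_energy_kcal,
        "olive_oil": breakfast.has_group("olive_oil"),
        "mufa_sfa_ratio": ratio_ok,
        "energy_share": lo <= share <= hi,
        "cereal_fruit_dairy": False,  # filled below from i–iii
        "calcium": t.calcium_mg >= calcium_min_mg,
        "no_butter_margarine": not breakfast.has_group("butter_margarine"),
    }
    items["cereal_fruit_dairy"] = (
        items["cereal"] and items["fruit_vegetable"] and items["dairy"]
    )
    return BqiResult(items=items, score=sum(items.values()), inputs_echo=t)


def compute_energy_density(breakfast: BreakfastRecord) -> EnergyDensityResult:
    """Energy density of one breakfast, split into solids and energy beverages.

    BEDs = solid energy / solid mass; BEDb = energy-beverage energy /
    energy-beverage mass. Non-energy beverages are excluded from both
    denominators. A density is None when its mass denominator is zero.
    """
    t = breakfast.totals
    beds = t.solid_energy_kcal / t.solid_mass_g if t.solid_mass_g > 0 else None
    bedb = (
        t.energy_beverage_energy_kcal / t.energy_beverage_mass_g
        if t.energy_beverage_mass_g > 0
        else None
    )
    return EnergyDensityResult(beds_kcal_per_g=beds, bedb_kcal_per_g=bedb)


def classify_skipping(
    day1: DayIntake, day2: DayIntake, kidmed_item: bool | None = None
) -> SkippingStatus:
    """Classify breakfast skipping from the recall pair and the KIDMED item.

    The recall definition is conservative: a child is a recall-based skipper
    only when breakfast is absent on BOTH recall days, since eating breakfast
    on an interviewed day by chance does not make a habitual consumer.
    The questionnaire item is echoed as reported (unknown when missing).
    """
    by_recall = day1.breakfast is None and day2.breakfast is None
    return SkippingStatus(by_recall=by_recall, by_kidmed=kidmed_item)


def summarize_participant(
    day1: DayIntake,
    day2: DayIntake,
    kidmed_item: bool | None = None,
    **bqi_options,
) -> dict:
    """Per-participant breakfast metrics averaged over the two recall days.

    The BQI and energy densities are computed per day against that day's
    total energy, then averaged over the days a breakfast is present (a
    participant with breakfast on neither day scores 0 and has missing
    densities). Item columns hold the mean of the per-day booleans, so a
    criterion met on one of two breakfast days reads 0.5.
    """
    avg = (day1.total_energy_kcal + day2.total_energy_kcal) / 2.0
    per_day_scores: list[BqiResult] = []
    beds_vals: list[float] = []
    bedb_vals: list[float] = []
    breakfast_energy: list[float] = []
    for day in (day1, day2):
        if day.breakfast is None:
            continue
        per_day_scores.append(score_bqi(day.breakfast, day.total_energy_kcal, **bqi_options))
        dens = compute_energy_density(day.breakfast)
        if dens.beds_kcal_per_g is not None:
            beds_vals.append(dens.beds_kcal_per_g)
        if dens.bedb_kcal_per_g is not None:
            bedb_vals.append(dens.bedb_kcal_per_g)
        breakfast_energy.append(day.breakfast.totals.energy_kcal)
    skipping = classify_skipping(day1, day2, kidmed_item)

    def _mean(vals):
        return sum(vals) / len(vals) if vals else None

    row: dict = {
        "participant_id": day1.participant_id,
        "energy_intake": avg,
        "breakfast_days": len(per_day_scores),
        "breakfast_energy_kcal": _mean(breakfast_energy),
        "bqi_score": (
            sum(r.score for r in per_day_scores) / len(per_day_scores)
            if per_day_scores
            else 0.0
        ),
        "beds": _mean(beds_vals),
        "bedb": _mean(bedb_vals),
        "skip_recall": skipping.by_recall,
        "skip_kidmed": skipping.by_kidmed,
    }
    for key in BQI_ITEMS:
        row[f"item_{key}"] = (
            sum(r.items[key] for r in per_day_scores) / len(per_day_scores)
            if per_day_scores
            else 0.0
        )
    return row


def summarize_averaged(avg: AveragedIntake) -> dict:
    """Convenience echo of averaged breakfast totals for descriptive output."""
    t = avg.breakfast
    return {
        "participant_id": avg.participant_id,
        "energy_intake": avg.total_energy_kcal,
        "breakfast_days": avg.breakfast_days,
        "partial_breakfast": avg.partial_breakfast,
        "breakfast_energy_kcal": t.energy_kcal if t else None,
        "breakfast_mass_g": t.mass_g if t else None,
    }
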