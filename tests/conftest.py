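"""Shared fixtures: the packaged food library, breakfast builders, a toy
MetS reference, and a generator -> analysis-cohort shortcut."""

from __future__ import annotations

import pandas as pd
import pytest

from bqikit import pipeline
from bqikit.cardiometabolic import MetsReference
from bqikit.recall_io import BreakfastRecord, RecallLine, load_food_library, resolve_line
from bqikit.synthetic_cohort import packaged_library_path

# Hand-scored breakfast panel: (label, [(food_id, grams)], daily_energy_kcal,
# expected true items). Expected sets were worked out by hand from the demo
# library's per-100 g values and the ten criteria.
BQI_PANEL = [
    (
        "all_criteria_met",
        [("wholegrain_bread", 50), ("apple", 100), ("semi_milk", 200), ("olive_oil", 12)],
        1600.0,
        {
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
        },
    ),
    (
        "sugary_biscuits_milk_butter",
        [("biscuit_maria", 55), ("whole_milk", 200), ("butter", 10)],
        437.5 / 0.3,  # breakfast pinned at 30% of daily energy
        {"cereal", "dairy", "calcium"},
    ),
    (
        "cocoa_milk_croissant",
        [("milk_cocoa", 200), ("croissant", 60)],
        1800.0,
        {"cereal", "dairy", "energy_share", "calcium", "no_butter_margarine"},
    ),
    (
        "juice_toast_margarine",
        [("juice_packaged", 200), ("white_bread", 70), ("margarine", 10)],
        2000.0,
        {"cereal", "low_simple_sugar"},
    ),
    (
        "milk_only",
        [("semi_milk", 250)],
        1600.0,
        {"dairy", "low_simple_sugar", "calcium", "no_butter_margarine"},
    ),
]


@pytest.fixture(scope="session")
def demo_library():
    return load_food_library(packaged_library_path())


@pytest.fixture(scope="session")
def make_breakfast(demo_library):
    """Build a BreakfastRecord from (food_id, grams) pairs via the resolve path."""

    def _make(foods):
        lines = [RecallLine("PX", 1, "breakfast", fid, g) for fid, g in foods]
        return BreakfastRecord([resolve_line(l, demo_library) for l in lines])

    return _make


@pytest.fixture(scope="session")
def toy_mets_reference():
    """Single-stratum reference: every component N(mean, sd), waist p90 = 80."""
    rows = []
    stats = {
        "triglycerides": (75.0, 30.0),
        "hdl": (55.0, 11.0),
        "glucose": (85.0, 6.0),
        "sbp": (102.0, 10.0),
        "dbp": (62.0, 8.0),
    }
    for sex in ("girl", "boy"):
        for age in range(8, 13):
            for comp, (mean, sd) in stats.items():
                rows.append(
                    {"sex": sex, "age_year": age, "component": comp, "mean": mean, "sd": sd}
                )
    waist = pd.DataFrame(
        [
            {"sex": sex, "age_year": age, "waist_p90": 80.0}
            for sex in ("girl", "boy")
            for age in range(8, 13)
        ]
    )
    return MetsReference(pd.DataFrame(rows), waist)


@pytest.fixture(scope="session")
def cohort_from_sim():
    """Shortcut: synthetic cohort object -> analysis-ready DataFrame."""

    def _build(sim):
        cohort, _ = pipeline.build_cohort(sim.library, sim.recall_lines, sim.participants)
        return cohort

    return _build
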