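"""Synthetic two-center cohort generator.

Emulates the statistical structure the analysis assumes: ~200 children aged
8–12 with overweight/obesity from two study centers, each contributing two
weekday 24 h recalls whose breakfasts are drawn from the packaged demo food
library, plus anthropometry, fasting biomarkers and summarized accelerometry.

Cardiometabolic outcomes are simulated as linear (or log-linear, for the
right-skewed biomarkers) functions of the *computed* breakfast exposures —
the generator feeds its own recalls through ``recall_io`` and
``breakfast_metrics``, so configured exposure effects act on exactly the
quantities the downstream regression sees — plus configurable confounder
contributions and Gaussian noise scaled so each standardized outcome has
unit variance. Insulin is back-derived from the generated HOMA and glucose,
so an effect placed on (log) HOMA survives the pipeline's re-derivation.

The packaged food library carries hand-entered plausible per-100 g values;
it is a test fixture, not a nutrition reference. Default parameters are
fixed once to mirror the target cohort's descriptive profile (sample size,
sex and center split, age/adiposity/activity distributions, breakfast
composition, skipping and missingness rates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import breakfast_metrics, recall_io
from .errors import ConfigError

#: Exposures an effect may act on.
EFFECT_EXPOSURES = ("bqi_score", "beds", "bedb")

#: Outcomes generated on the natural scale: (location, scale).
LINEAR_OUTCOME_SCALES = {
    "fmi": (10.7, 2.5),
    "abdominal_fat": (1.7, 0.6),
    "glucose": (85.9, 6.2),
    "sbp": (105.2, 15.0),
    "dbp": (65.4, 9.8),
    "uric_acid": (4.7, 0.9),
    "cholesterol": (170.3, 30.6),
    "hdl": (51.1, 11.6),
    "ldl": (102.8, 24.9),
}

#: Outcomes generated on the log scale: (meanlog, sdlog). HOMA is generated
#: directly and insulin back-derived from it and glucose.
LOG_OUTCOME_SCALES = {
    "triglycerides": (math.log(80.0), 0.45),
    "ggt": (math.log(16.2), 0.30),
    "homa": (math.log(2.6), 0.45),
}

#: Generation order (fmi first: it feeds the default confounding of the rest).
_OUTCOME_ORDER = (
    "fmi",
    "abdominal_fat",
    "glucose",
    "sbp",
    "dbp",
    "uric_acid",
    "cholesterol",
    "hdl",
    "ldl",
    "triglycerides",
    "ggt",
    "homa",
)

#: Default confounder loadings (standardized scale) per outcome.
DEFAULT_CONFOUNDING = {
    "fmi": {},
    "abdominal_fat": {"fmi": 0.80},
    "glucose": {"age": 0.10},
    "sbp": {"fmi": 0.30, "age": 0.20, "total_pa": -0.10},
    "dbp": {"fmi": 0.20, "age": 0.15},
    "uric_acid": {"fmi": 0.25, "sex_girl": 0.10},
    "cholesterol": {"age": -0.10},
    "hdl": {"fmi": -0.20, "total_pa": 0.15},
    "ldl": {"fmi": 0.10},
    "triglycerides": {"fmi": 0.30},
    "ggt": {"fmi": 0.20},
    "homa": {"fmi": 0.35, "total_pa": -0.15, "age": 0.15},
}

_CONFOUNDER_KEYS = ("fmi", "age", "total_pa", "sex_girl", "energy")


@dataclass
class BreakfastProfile:
    """Probabilities and gram ranges the breakfast simulator draws from."""

    beverage_prob: float = 0.97
    beverage_choices: tuple = (
        ("semi_milk", 0.33),
        ("milk_cocoa", 0.38),
        ("whole_milk", 0.15),
        ("juice_packaged", 0.09),
        ("orange_juice_fresh", 0.05),
    )
    beverage_grams: dict = field(
        default_factory=lambda: {
            "semi_milk": (150.0, 250.0),
            "milk_cocoa": (150.0, 250.0),
            "whole_milk": (150.0, 250.0),
            "juice_packaged": (150.0, 220.0),
            "orange_juice_fresh": (150.0, 220.0),
        }
    )
    solid_prob: float = 0.90
    solid_choices: tuple = (
        ("biscuit_maria", 0.28, (30.0, 60.0)),
        ("breakfast_cereal_sugar", 0.18, (30.0, 50.0)),
        ("white_bread", 0.22, (40.0, 80.0)),
        ("wholegrain_bread", 0.08, (40.0, 80.0)),
        ("croissant", 0.12, (45.0, 80.0)),
        ("pastry_chocolate", 0.12, (45.0, 80.0)),
    )
    olive_oil_prob: dict = field(
        default_factory=lambda: {"vitoria": 0.25, "granada": 0.55}
    )
    olive_oil_grams: tuple = (8.0, 15.0)
    butter_prob: float = 0.15
    butter_grams: tuple = (8.0, 12.0)
    ham_prob: float = 0.20
    ham_grams: tuple = (20.0, 40.0)
    fruit_prob: float = 0.15
    fruit_choices: tuple = ("apple", "banana", "orange")
    fruit_grams: tuple = (80.0, 150.0)
    water_prob: float = 0.20
    water_grams: tuple = (100.0, 250.0)


@dataclass
class GeneratorConfig:
    """Every dial of the generator; defaults mirror the emulated cohort."""

    n_children: int = 203
    seed: int = 0
    girls_fraction: float = 0.473
    center_split: float = 0.552  # share of children at the "vitoria" center
    age_mean: float = 10.3
    age_sd: float = 1.1
    effects: dict = field(default_factory=dict)  # (exposure, outcome) -> std beta
    confounding: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CONFOUNDING.items()})
    mediator_effects: dict = field(default_factory=dict)  # exposure -> total PA path
    p_habitual_skipper: float = 0.12
    p_skip_day_skipper: float = 0.70
    p_skip_day_regular: float = 0.02
    p_single_recall: float = 0.0
    kidmed_missing_rate: float = 0.15
    biomarker_missing_rate: float = 0.04
    puberty_missing_rate: float = 0.03
    mvpa_mean: float = 54.4
    mvpa_sd: float = 20.9
    total_pa_mean: float = 63.0
    total_pa_sd: float = 15.4
    maternal_high_rate: float = 0.262
    profile: BreakfastProfile = field(default_factory=BreakfastProfile)
    min_noise_var: float = 0.04

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ConfigError("n_children must be positive")
        for name in (
            "girls_fraction",
            "center_split",
            "p_habitual_skipper",
            "p_skip_day_skipper",
            "p_skip_day_regular",
            "p_single_recall",
            "kidmed_missing_rate",
            "biomarker_missing_rate",
            "puberty_missing_rate",
            "maternal_high_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("age_sd", "mvpa_sd", "total_pa_sd"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        for (exposure, outcome), beta in self.effects.items():
            if exposure not in EFFECT_EXPOSURES:
                raise ConfigError(f"unknown effect exposure {exposure!r}")
            if outcome == "mets_z":
                raise ConfigError(
                    "effects on the MetS z composite must target its components "
                    "(triglycerides, hdl, glucose, sbp, dbp)"
                )
            if outcome not in _OUTCOME_ORDER:
                raise ConfigError(f"unknown effect outcome {outcome!r}")
            if not np.isfinite(beta):
                raise ConfigError(f"effect ({exposure}, {outcome}) must be finite")
        if self.effects and self.p_habitual_skipper >= 1.0:
            raise ConfigError(
                "exposure effects are requested but every child skips breakfast"
            )
        for exposure in self.mediator_effects:
            if exposure not in EFFECT_EXPOSURES:
                raise ConfigError(f"unknown mediator exposure {exposure!r}")
        m2 = sum(v**2 for v in self.mediator_effects.values())
        if m2 > 1.0 - self.min_noise_var:
            raise ConfigError("mediator path coefficients leave no PA variance")
        for outcome in _OUTCOME_ORDER:
            var = sum(
                beta**2 for (e, o), beta in self.effects.items() if o == outcome
            ) + sum(v**2 for v in self.confounding.get(outcome, {}).values())
            if var > 1.0 - self.min_noise_var:
                raise ConfigError(
                    f"outcome {outcome!r}: structural variance {var:.3f} leaves "
                    f"less than the minimum noise variance"
                )


@dataclass
class SyntheticCohort:
    """In-memory result of one generation run."""

    config: GeneratorConfig
    library: dict
    library_table: pd.DataFrame
    recalls: pd.DataFrame
    recall_lines: list
    participants: pd.DataFrame
    metrics: pd.DataFrame  # per-participant breakfast metrics (generator's view)
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the three pipeline inputs plus the truth record as CSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "library": outdir / "food_library.csv",
            "recalls": outdir / "recalls.csv",
            "participants": outdir / "participants.csv",
            "truth": outdir / "truth.csv",
        }
        self.library_table.to_csv(paths["library"], index=False)
        self.recalls.to_csv(paths["recalls"], index=False)
        self.participants.to_csv(paths["participants"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def packaged_library_path() -> Path:
    """Path of the packaged demo food library (a hand-entered fixture)."""
    return Path(resources.files("bqikit").joinpath("data/demo_food_library.csv"))


def packaged_mets_reference_paths() -> tuple[Path, Path]:
    """Paths of the packaged synthetic MetS reference tables (stats, waist p90)."""
    data = resources.files("bqikit")
    return (
        Path(data.joinpath("data/synthetic_mets_reference.csv")),
        Path(data.joinpath("data/synthetic_waist_p90.csv")),
    )


def _pick(rng, choices):
    names = [c[0] for c in choices]
    probs = np.array([c[1] for c in choices], dtype=float)
    probs = probs / probs.sum()
    return names[rng.choice(len(names), p=probs)]


def _breakfast_lines(rng, center: str, profile: BreakfastProfile) -> list[tuple[str, float]]:
    lines: list[tuple[str, float]] = []
    if rng.random() < profile.beverage_prob:
        food = _pick(rng, profile.beverage_choices)
        lo, hi = profile.beverage_grams[food]
        lines.append((food, rng.uniform(lo, hi)))
    if rng.random() < profile.solid_prob:
        names = [c[0] for c in profile.solid_choices]
        probs = np.array([c[1] for c in profile.solid_choices], dtype=float)
        idx = rng.choice(len(names), p=probs / probs.sum())
        lo, hi = profile.solid_choices[idx][2]
        solid = names[idx]
        lines.append((solid, rng.uniform(lo, hi)))
        if solid in ("white_bread", "wholegrain_bread"):
            if rng.random() < profile.olive_oil_prob.get(center, 0.3):
                lines.append(("olive_oil", rng.uniform(*profile.olive_oil_grams)))
            elif rng.random() < profile.butter_prob:
                lines.append(("butter", rng.uniform(*profile.butter_grams)))
            if rng.random() < profile.ham_prob:
                lines.append(("ham_serrano", rng.uniform(*profile.ham_grams)))
    if rng.random() < profile.fruit_prob:
        fruit = profile.fruit_choices[rng.choice(len(profile.fruit_choices))]
        lines.append((fruit, rng.uniform(*profile.fruit_grams)))
    if rng.random() < profile.water_prob:
        lines.append(("water", rng.uniform(*profile.water_grams)))
    return lines


def _other_meal_lines(rng) -> list[tuple[str, str, float]]:
    lines = [
        ("lunch", "lunch_mixed", rng.uniform(280.0, 450.0)),
        ("lunch", "water", rng.uniform(150.0, 250.0)),
        ("dinner", "dinner_mixed", rng.uniform(220.0, 400.0)),
    ]
    if rng.random() < 0.5:
        if rng.random() < 0.6:
            lines.append(("mid_morning", "snack_sandwich", rng.uniform(80.0, 150.0)))
        else:
            lines.append(("mid_morning", "apple", rng.uniform(100.0, 150.0)))
    if rng.random() < 0.6:
        if rng.random() < 0.5:
            lines.append(("snack", "yogurt_sweet", rng.uniform(120.0, 130.0)))
        else:
            lines.append(("snack", "biscuit_maria", rng.uniform(25.0, 40.0)))
    return lines


def _sample_z(values: np.ndarray) -> np.ndarray:
    """Sample z-score with missing values imputed at the mean (z = 0)."""
    obs = values[~np.isnan(values)]
    sd = obs.std(ddof=1)
    if not sd > 0:
        return np.zeros_like(values)
    z = (values - obs.mean()) / sd
    z[np.isnan(z)] = 0.0
    return z


def generate_cohort(
    config: GeneratorConfig | None = None, outdir: str | Path | None = None
) -> SyntheticCohort:
    """Generate one synthetic cohort; optionally write its files to ``outdir``.

    The run is fully determined by ``config.seed``: the same configuration
    produces bit-identical tables and files.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_children
    library = recall_io.load_food_library(packaged_library_path())
    library_table = pd.read_csv(packaged_library_path())

    pids = [f"P{i + 1:04d}" for i in range(n)]
    sex = np.where(rng.random(n) < config.girls_fraction, "girl", "boy")
    center = np.where(rng.random(n) < config.center_split, "vitoria", "granada")
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 8.0, 12.9)
    maternal = np.where(rng.random(n) < config.maternal_high_rate, "high", "low")
    p_puberty = np.clip(0.02 + 0.06 * (age - 8.0) + 0.12 * (sex == "girl"), 0.0, 1.0)
    puberty_high = rng.random(n) < p_puberty

    # --- recalls -----------------------------------------------------------
    skipper = rng.random(n) < config.p_habitual_skipper
    single_recall = rng.random(n) < config.p_single_recall
    recall_rows: list[dict] = []
    day_lines: dict[tuple[str, int], list[recall_io.RecallLine]] = {}
    for i, pid in enumerate(pids):
        n_days = 1 if single_recall[i] else 2
        p_skip = (
            config.p_skip_day_skipper if skipper[i] else config.p_skip_day_regular
        )
        for day in range(1, n_days + 1):
            meals: list[tuple[str, str, float]] = []
            if rng.random() >= p_skip:
                meals.extend(
                    ("breakfast", food, grams)
                    for food, grams in _breakfast_lines(rng, center[i], config.profile)
                )
            meals.extend(_other_meal_lines(rng))
            lines = [
                recall_io.RecallLine(pid, day, meal, food, round(grams, 1))
                for meal, food, grams in meals
            ]
            day_lines[(pid, day)] = lines
            recall_rows.extend(
                {
                    "participant_id": pid,
                    "day_index": day,
                    "meal": l.meal,
                    "food_id": l.food_id,
                    "grams": l.grams,
                }
                for l in lines
            )
    recalls = pd.DataFrame(recall_rows)

    # --- breakfast metrics through the real scoring path -------------------
    metric_rows = []
    for i, pid in enumerate(pids):
        d1 = recall_io.resolve_day(day_lines[(pid, 1)], library)
        if (pid, 2) in day_lines:
            d2 = recall_io.resolve_day(day_lines[(pid, 2)], library)
        else:
            d2 = d1  # single-recall children are excluded downstream anyway
        metric_rows.append(breakfast_metrics.summarize_participant(d1, d2))
    metrics = pd.DataFrame(metric_rows)

    exposures_z = {
        e: _sample_z(metrics[e].to_numpy(dtype=float)) for e in EFFECT_EXPOSURES
    }

    # --- physical activity (optionally a mediator of the exposures) --------
    m2 = sum(v**2 for v in config.mediator_effects.values())
    pa_struct = math.sqrt(max(1.0 - m2, 0.0)) * rng.normal(size=n)
    for exposure, coef in config.mediator_effects.items():
        pa_struct = pa_struct + coef * exposures_z[exposure]
    total_pa = np.clip(config.total_pa_mean + config.total_pa_sd * pa_struct, 1.0, None)
    mvpa = np.clip(
        config.mvpa_mean
        + config.mvpa_sd * (0.75 * pa_struct + math.sqrt(1 - 0.75**2) * rng.normal(size=n)),
        0.0,
        None,
    )

    covariate_z = {
        "age": _sample_z(age),
        "sex_girl": _sample_z((sex == "girl").astype(float)),
        "total_pa": _sample_z(total_pa),
        "energy": _sample_z(metrics["energy_intake"].to_numpy(dtype=float)),
    }

    # --- outcomes ----------------------------------------------------------
    outcomes: dict[str, np.ndarray] = {}
    noise_sds: dict[str, float] = {}
    for outcome in _OUTCOME_ORDER:
        eta = np.zeros(n)
        var = 0.0
        for (exposure, target), beta in config.effects.items():
            if target == outcome:
                eta += beta * exposures_z[exposure]
                var += beta**2
        for conf, coef in config.confounding.get(outcome, {}).items():
            eta += coef * covariate_z[conf]
            var += coef**2
        noise_sd = math.sqrt(max(1.0 - var, config.min_noise_var))
        noise_sds[outcome] = noise_sd
        std = eta + noise_sd * rng.normal(size=n)
        if outcome in LINEAR_OUTCOME_SCALES:
            loc, scale = LINEAR_OUTCOME_SCALES[outcome]
            outcomes[outcome] = np.clip(loc + scale * std, 0.01, None)
        else:
            meanlog, sdlog = LOG_OUTCOME_SCALES[outcome]
            outcomes[outcome] = np.exp(meanlog + sdlog * std)
        if outcome == "fmi":
            covariate_z["fmi"] = _sample_z(outcomes["fmi"])

    # keep the lipid panel internally consistent (HDL below total cholesterol)
    outcomes["hdl"] = np.minimum(outcomes["hdl"], outcomes["cholesterol"] - 1.0)
    insulin = outcomes["homa"] * 22.5 / (outcomes["glucose"] / 18.016)

    fmi_z = _sample_z(outcomes["fmi"])
    waist = np.clip(
        84.1 + 10.5 * (0.75 * fmi_z + math.sqrt(1 - 0.75**2) * rng.normal(size=n)),
        50.0,
        None,
    )
    bmi = np.clip(
        26.1 + 3.5 * (0.85 * fmi_z + math.sqrt(1 - 0.85**2) * rng.normal(size=n)),
        18.0,
        None,
    )

    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "sex": sex,
            "age": np.round(age, 2),
            "center": center,
            "maternal_education": maternal,
            "puberty_high": puberty_high,
            "bmi": np.round(bmi, 2),
            "waist": np.round(waist, 1),
            "fmi": np.round(outcomes["fmi"], 2),
            "abdominal_fat": np.round(outcomes["abdominal_fat"], 3),
            "sbp": np.round(outcomes["sbp"], 1),
            "dbp": np.round(outcomes["dbp"], 1),
            "glucose": np.round(outcomes["glucose"], 1),
            "insulin": np.round(insulin, 2),
            "uric_acid": np.round(outcomes["uric_acid"], 2),
            "cholesterol": np.round(outcomes["cholesterol"], 1),
            "hdl": np.round(outcomes["hdl"], 1),
            "ldl": np.round(outcomes["ldl"], 1),
            "triglycerides": np.round(outcomes["triglycerides"], 1),
            "ggt": np.round(outcomes["ggt"], 1),
            "total_pa_enmo": np.round(total_pa, 1),
            "mvpa_min_day": np.round(mvpa, 1),
            "kidmed_breakfast_skipper": skipper,
        }
    )

    # --- missingness (measurement-wise, completely at random) ---------------
    r = config.biomarker_missing_rate
    if r > 0:
        for group in (
            ("fmi", "abdominal_fat"),
            ("sbp", "dbp"),
            ("total_pa_enmo", "mvpa_min_day"),
            ("glucose",),
            ("insulin",),
            ("uric_acid",),
            ("cholesterol", "hdl", "ldl"),
            ("triglycerides",),
            ("ggt",),
        ):
            mask = rng.random(n) < r
            participants.loc[mask, list(group)] = np.nan
    if config.puberty_missing_rate > 0:
        mask = rng.random(n) < config.puberty_missing_rate
        participants["puberty_high"] = participants["puberty_high"].astype(object)
        participants.loc[mask, "puberty_high"] = np.nan
    if config.kidmed_missing_rate > 0:
        mask = rng.random(n) < config.kidmed_missing_rate
        participants["kidmed_breakfast_skipper"] = participants[
            "kidmed_breakfast_skipper"
        ].astype(object)
        participants.loc[mask, "kidmed_breakfast_skipper"] = np.nan

    # --- truth record -------------------------------------------------------
    truth_rows = [
        {"kind": "config", "exposure": "", "target": "seed", "value": float(config.seed)},
        {"kind": "config", "exposure": "", "target": "n_children", "value": float(n)},
    ]
    truth_rows += [
        {"kind": "effect", "exposure": e, "target": o, "value": b}
        for (e, o), b in sorted(config.effects.items())
    ]
    truth_rows += [
        {"kind": "mediator", "exposure": e, "target": "total_pa", "value": b}
        for e, b in sorted(config.mediator_effects.items())
    ]
    truth_rows += [
        {"kind": "confounder", "exposure": c, "target": o, "value": v}
        for o in _OUTCOME_ORDER
        for c, v in sorted(config.confounding.get(o, {}).items())
    ]
    truth_rows += [
        {"kind": "noise_sd", "exposure": "", "target": o, "value": noise_sds[o]}
        for o in _OUTCOME_ORDER
    ]
    truth = pd.DataFrame(truth_rows)

    cohort = SyntheticCohort(
        config=config,
        library=library,
        library_table=library_table,
        recalls=recalls,
        recall_lines=[l for lines in day_lines.values() for l in lines],
        participants=participants,
        metrics=metrics,
        truth=truth,
    )
    if outdir is not None:
        cohort.write(outdir)
    return cohort
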