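"""Cardiometabolic outcome derivation.

Covers the homeostatic model assessment of insulin resistance (HOMA-IR), the
IDF pediatric metabolic-syndrome classification (three or more of five risk
factors), the continuous MetS z-score (sum of sex/age-standardized z-scores
of triglycerides, HDL, glucose, systolic and diastolic blood pressure, with
the HDL term negated so a higher composite means a worse profile), study-
center-wise z-scoring of adiposity measures (to absorb between-device
systematic differences), and the log-transform policy for right-skewed
biomarkers (triglycerides, GGT, insulin, HOMA).

HOMA uses fasting insulin in µU/mL and fasting glucose converted from mg/dL
to mmol/L (divisor 18.016): HOMA = insulin × glucose_mmol / 22.5.

IDF pediatric factor cutoffs: central obesity (waist >= sex/age 90th
percentile from a reference table), SBP >= 130 or DBP >= 85 mmHg (one
combined blood-pressure factor), triglycerides >= 150 mg/dL, HDL < 40 mg/dL,
fasting glucose >= 100 mg/dL. All >= / < boundaries are as printed
(inclusive on the elevated side).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, ReferenceLookupError, SchemaError

#: mg/dL of glucose per mmol/L.
GLUCOSE_MGDL_PER_MMOL = 18.016

#: Components entering the MetS z-score and classification references.
METS_COMPONENTS = ("triglycerides", "hdl", "glucose", "sbp", "dbp")

#: IDF pediatric risk-factor cutoffs (central obesity comes from the waist reference).
SBP_CUTOFF = 130.0
DBP_CUTOFF = 85.0
TG_CUTOFF = 150.0
HDL_CUTOFF = 40.0
GLUCOSE_CUTOFF = 100.0

#: Outcomes modelled on the log scale.
LOG_TRANSFORMED = ("triglycerides", "ggt", "insulin", "homa")


@dataclass(frozen=True)
class BiomarkerPanel:
    """Fasting biomarkers, blood pressure and waist of one participant.

    Any field may be None (missing). Units: mg/dL for glucose, uric acid,
    lipids; µU/mL insulin; U/L GGT; mmHg blood pressure; cm waist.
    """

    glucose_mg_dl: float | None = None
    insulin_uU_ml: float | None = None
    uric_acid_mg_dl: float | None = None
    total_chol_mg_dl: float | None = None
    hdl_mg_dl: float | None = None
    ldl_mg_dl: float | None = None
    triglycerides_mg_dl: float | None = None
    ggt_u_l: float | None = None
    sbp_mmHg: float | None = None
    dbp_mmHg: float | None = None
    waist_cm: float | None = None

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if v is not None and not v >= 0:
                raise DomainError(f"{name} must be nonnegative, got {v!r}")
        if (
            self.hdl_mg_dl is not None
            and self.total_chol_mg_dl is not None
            and self.hdl_mg_dl > self.total_chol_mg_dl
        ):
            raise DomainError("HDL cannot exceed total cholesterol")


def compute_homa(insulin_uU_ml: float, glucose_mg_dl: float) -> float:
    """HOMA-IR from fasting insulin (µU/mL) and glucose (mg/dL)."""
    if insulin_uU_ml < 0 or glucose_mg_dl < 0:
        raise DomainError("insulin and glucose must be nonnegative")
    return insulin_uU_ml * (glucose_mg_dl / GLUCOSE_MGDL_PER_MMOL) / 22.5


class MetsReference:
    """Sex/age-specific reference for the MetS z-score and waist cutoffs.

    Built from two delimited tables: component statistics
    (sex, age_year, component, mean, sd) for the five MetS components, and
    waist 90th-percentile cutoffs (sex, age_year, waist_p90). Age strata are
    whole years; a participant's stratum is floor(age).
    """

    def __init__(self, stats: pd.DataFrame, waist: pd.DataFrame):
        for col in ("sex", "age_year", "component", "mean", "sd"):
            if col not in stats.columns:
                raise SchemaError(f"MetS reference stats: missing column {col!r}")
        for col in ("sex", "age_year", "waist_p90"):
            if col not in waist.columns:
                raise SchemaError(f"MetS waist reference: missing column {col!r}")
        if (stats["sd"] <= 0).any():
            bad = stats.loc[stats["sd"] <= 0].iloc[0]
            raise SchemaError(
                f"MetS reference stats: nonpositive SD in stratum "
                f"({bad['sex']}, {bad['age_year']}, {bad['component']})"
            )
        self._stats = {
            (r.sex, int(r.age_year), r.component): (float(r.mean), float(r.sd))
            for r in stats.itertuples(index=False)
        }
        self._waist = {
            (r.sex, int(r.age_year)): float(r.waist_p90)
            for r in waist.itertuples(index=False)
        }

    @classmethod
    def from_csv(cls, stats_path: str | Path, waist_path: str | Path) -> "MetsReference":
        return cls(pd.read_csv(stats_path), pd.read_csv(waist_path))

    @staticmethod
    def _stratum(age: float) -> int:
        return int(math.floor(age))

    def component_stats(self, sex: str, age: float, component: str) -> tuple[float, float]:
        key = (sex, self._stratum(age), component)
        try:
            return self._stats[key]
        except KeyError:
            raise ReferenceLookupError(
                f"no reference stratum for sex={sex!r}, age_year={self._stratum(age)}, "
                f"component={component!r}"
            ) from None

    def waist_cutoff(self, sex: str, age: float) -> float:
        key = (sex, self._stratum(age))
        try:
            return self._waist[key]
        except KeyError:
            raise ReferenceLookupError(
                f"no waist p90 for sex={sex!r}, age_year={self._stratum(age)}"
            ) from None


@dataclass(frozen=True)
class MetsResult:
    """IDF classification outcome: five factor flags, their count, and has_mets.

    ``has_mets`` is None when any component needed for a flag is missing
    (``complete`` False); otherwise has_mets <=> factor_count >= 3.
    """

    factor_flags: dict
    factor_count: int
    has_mets: bool | None
    complete: bool

    def __post_init__(self) -> None:
        if self.complete:
            assert self.has_mets == (self.factor_count >= 3)


def classify_mets(
    panel: BiomarkerPanel, sex: str, age: float, ref: MetsReference
) -> MetsResult:
    """Classify metabolic syndrome by the IDF pediatric criteria.

    Five factors: central obesity (waist >= reference p90), elevated blood
    pressure (SBP >= 130 or DBP >= 85, one factor), elevated triglycerides
    (>= 150), low HDL (< 40), impaired fasting glucose (>= 100). MetS is
    three or more factors. Missing components make the result incomplete
    (has_mets unknown); available flags are still evaluated.
    """
    flags: dict[str, bool | None] = {}
    if panel.waist_cm is not None:
        flags["central_obesity"] = panel.waist_cm >= ref.waist_cutoff(sex, age)
    else:
        flags["central_obesity"] = None
    if panel.sbp_mmHg is not None and panel.dbp_mmHg is not None:
        flags["elevated_bp"] = panel.sbp_mmHg >= SBP_CUTOFF or panel.dbp_mmHg >= DBP_CUTOFF
    else:
        flags["elevated_bp"] = None
    flags["elevated_tg"] = (
        panel.triglycerides_mg_dl >= TG_CUTOFF
        if panel.triglycerides_mg_dl is not None
        else None
    )
    flags["low_hdl"] = panel.hdl_mg_dl < HDL_CUTOFF if panel.hdl_mg_dl is not None else None
    flags["impaired_glucose"] = (
        panel.glucose_mg_dl >= GLUCOSE_CUTOFF if panel.glucose_mg_dl is not None else None
    )
    complete = all(v is not None for v in flags.values())
    count = sum(bool(v) for v in flags.values() if v is not None)
    return MetsResult(
        factor_flags=flags,
        factor_count=count,
        has_mets=(count >= 3) if complete else None,
        complete=complete,
    )


def compute_mets_z(
    panel: BiomarkerPanel,
    sex: str,
    age: float,
    ref: MetsReference,
    *,
    invert_hdl: bool = True,
) -> float:
    """Continuous MetS z-score: sum of sex/age-standardized component z-scores.

    Components: triglycerides, HDL, glucose, SBP, DBP. With ``invert_hdl``
    (default) the HDL term enters negated, so a higher composite always means
    a worse risk profile.
    """
    values = {
        "triglycerides": panel.triglycerides_mg_dl,
        "hdl": panel.hdl_mg_dl,
        "glucose": panel.glucose_mg_dl,
        "sbp": panel.sbp_mmHg,
        "dbp": panel.dbp_mmHg,
    }
    missing = [k for k, v in values.items() if v is None]
    if missing:
        raise DomainError(f"MetS z-score needs all five components; missing {missing}")
    total = 0.0
    for component, value in values.items():
        mean, sd = ref.component_stats(sex, age, component)
        z = (value - mean) / sd
        if component == "hdl" and invert_hdl:
            z = -z
        total += z
    return total


def center_zscore(values: pd.Series, centers: pd.Series) -> pd.Series:
    """Standardize a measure within each study center.

    Within each center the returned values are (x − center mean)/center SD
    (sample SD, ddof=1). Missing values propagate; each center needs at
    least two non-missing observations and a nonzero SD.
    """
    values = pd.Series(values).astype(float)
    out = pd.Series(np.nan, index=values.index)
    for center, idx in values.groupby(pd.Series(centers, index=values.index)).groups.items():
        sub = values.loc[idx]
        obs = sub.dropna()
        if len(obs) < 2:
            raise DomainError(
                f"center {center!r}: need >= 2 non-missing values to standardize"
            )
        sd = obs.std(ddof=1)
        if not sd > 0:
            raise DomainError(f"center {center!r}: degenerate (zero) standard deviation")
        out.loc[idx] = (sub - obs.mean()) / sd
    return out


def transform_outcomes(
    table: pd.DataFrame,
    log_columns: tuple[str, ...] = LOG_TRANSFORMED,
    id_column: str = "participant_id",
) -> tuple[pd.DataFrame, dict]:
    """Apply the log-transform policy to an outcome table.

    The four right-skewed measures (triglycerides, GGT, insulin, HOMA by
    default) are replaced by their natural logarithms in place; every other
    column passes through unchanged. Returns the transformed copy and a
    manifest mapping each column to "ln" or "identity".

    Raises DomainError, identifying the participant, when a value to be
    logged is zero or negative (missing values propagate untouched).
    """
    out = table.copy()
    manifest: dict[str, str] = {}
    for col in out.columns:
        if col in log_columns:
            series = out[col].astype(float)
            bad = series.index[(series <= 0) & series.notna()]
            if len(bad):
                ident = (
                    out.loc[bad[0], id_column] if id_column in out.columns else bad[0]
                )
                raise DomainError(
                    f"column {col!r}: nonpositive value for participant {ident!r} "
                    f"cannot be log-transformed"
                )
            out[col] = np.log(series)
            manifest[col] = "ln"
        else:
            manifest[col] = "identity"
    return out, manifest
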