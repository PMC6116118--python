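"""Exposure–outcome association ladder.

For each breakfast exposure (BQI score, BEDs, BEDb) and each cardiometabolic
outcome, three nested ordinary-least-squares models are fitted on complete
cases:

* Model 1: sex, age, study center, maternal educational level, daily energy
  intake;
* Model 2: Model 1 + fat mass index (FMI);
* Model 3: Model 2 + total physical activity.

Exposure and outcome are z-standardized on the analysis sample before
fitting, so the reported coefficient is a standardized β (unitless and
invariant to affine rescaling of either variable). Categorical covariates
(sex, center, maternal education) enter as indicator terms. Two-sided
p-values come from the coefficient t-statistic; no multiplicity correction
is applied. The FMI-based adiposity outcome is never adjusted for FMI
(Model 1 only).

Extensions: activity-stratified fits (Model 2 covariates within each
stratum — total PA is the conditioning variable and is dropped), a sex ×
exposure interaction test on the Model 1 covariates, and a puberty
sensitivity ladder where age is replaced by a binary high-puberty indicator
(Tanner stage >= III).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FitError

#: Breakfast exposures.
EXPOSURES = ("bqi_score", "beds", "bedb")

#: Outcome columns in Table order. triglycerides/homa/ggt are expected on the
#: log scale (the pipeline's transform step); mets_z is the composite.
OUTCOMES = (
    "fmi_z",
    "abdominal_fat_z",
    "sbp",
    "dbp",
    "uric_acid",
    "cholesterol",
    "hdl",
    "ldl",
    "triglycerides",
    "homa",
    "ggt",
    "mets_z",
)

#: Outcomes for which the FMI-adjusted tiers are not defined.
FMI_OUTCOMES = ("fmi_z",)

CATEGORICAL_COVARIATES = ("sex", "center", "maternal_education")

_TIER1 = ("sex", "age", "center", "maternal_education", "energy_intake")


def covariates_for_tier(tier: int, *, age_variable: str = "age") -> tuple[str, ...]:
    """Covariate set of a model tier (1, 2 or 3); tiers are strictly nested."""
    base = tuple(age_variable if c == "age" else c for c in _TIER1)
    if tier == 1:
        return base
    if tier == 2:
        return base + ("fmi",)
    if tier == 3:
        return base + ("fmi", "total_pa")
    raise ValueError(f"tier must be 1, 2 or 3, got {tier!r}")


@dataclass(frozen=True)
class AssociationResult:
    """One cell of the results table: standardized β, p, complete-case n."""

    exposure: str
    outcome: str
    tier: int
    beta: float
    se: float
    p_value: float
    n_used: int


def _zscore(series: pd.Series, label: str) -> pd.Series:
    sd = series.std(ddof=1)
    if not sd > 0:
        raise FitError(f"{label} has zero variance on the analysis sample")
    return (series - series.mean()) / sd


def _design(frame: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    parts = []
    for cov in covariates:
        col = frame[cov]
        if cov in CATEGORICAL_COVARIATES or col.dtype == object:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(col.astype(float).rename(cov))
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=frame.index)


def _fit_cell(
    frame: pd.DataFrame,
    exposure: str,
    outcome: str,
    covariates: tuple[str, ...],
    tier: int,
    extra_terms: pd.DataFrame | None = None,
) -> tuple[AssociationResult, sm.regression.linear_model.RegressionResultsWrapper]:
    cols = [exposure, outcome, *covariates]
    sub = frame.dropna(subset=cols)
    n = len(sub)
    X = pd.DataFrame(index=sub.index)
    X["exposure_std"] = _zscore(sub[exposure].astype(float), exposure)
    cov_design = _design(sub, covariates)
    X = pd.concat([X, cov_design], axis=1)
    if extra_terms is not None:
        X = pd.concat([X, extra_terms.loc[sub.index]], axis=1)
    X = sm.add_constant(X, has_constant="add")
    if n < X.shape[1] + 1:
        raise FitError(
            f"{exposure} -> {outcome} (tier {tier}): only {n} complete cases for "
            f"{X.shape[1]} design columns"
        )
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise FitError(f"{exposure} -> {outcome} (tier {tier}): rank-deficient design")
    y = _zscore(sub[outcome].astype(float), outcome)
    fit = sm.OLS(y.to_numpy(), X).fit()
    result = AssociationResult(
        exposure=exposure,
        outcome=outcome,
        tier=tier,
        beta=float(fit.params["exposure_std"]),
        se=float(fit.bse["exposure_std"]),
        p_value=float(fit.pvalues["exposure_std"]),
        n_used=n,
    )
    return result, fit


def fit_ladder(
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str,
    tiers: tuple[int, ...] = (1, 2, 3),
    *,
    age_variable: str = "age",
) -> list[AssociationResult]:
    """Fit the nested covariate ladder for one exposure–outcome pair.

    Returns one :class:`AssociationResult` per requested tier; for the FMI
    outcome only Model 1 is fitted regardless of ``tiers``.
    """
    if outcome in FMI_OUTCOMES:
        tiers = tuple(t for t in tiers if t == 1)
    results = []
    for tier in tiers:
        covs = covariates_for_tier(tier, age_variable=age_variable)
        result, _ = _fit_cell(cohort, exposure, outcome, covs, tier)
        results.append(result)
    return results


def fit_stratified(
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str,
    stratum_column: str = "is_active",
) -> dict:
    """Fit the Model 2 covariate set within each activity stratum.

    Total physical activity defines the strata and is therefore not entered
    as a covariate; FMI stays in. Rows with missing stratum are dropped.
    Returns {stratum value: AssociationResult}.
    """
    covs = covariates_for_tier(2)
    out: dict = {}
    with_stratum = cohort.dropna(subset=[stratum_column])
    for value, sub in with_stratum.groupby(stratum_column):
        result, _ = _fit_cell(sub, exposure, outcome, covs, tier=2)
        out[value] = result
    if not out:
        raise FitError(f"no usable strata in column {stratum_column!r}")
    return out


def test_sex_interaction(
    cohort: pd.DataFrame, exposure: str, outcome: str
) -> float:
    """Two-sided p-value of the exposure × sex product term on the Model 1 fit.

    The product multiplies the standardized exposure by a 0/1 sex indicator;
    a sample with a single sex is inestimable and raises FitError.
    """
    covs = covariates_for_tier(1)
    cols = [exposure, outcome, *covs]
    sub = cohort.dropna(subset=cols)
    if sub["sex"].nunique() < 2:
        raise FitError("sex is constant in the sample; interaction term inestimable")
    sex_levels = sorted(sub["sex"].unique())
    indicator = (sub["sex"] == sex_levels[-1]).astype(float)
    exposure_std = _zscore(sub[exposure].astype(float), exposure)
    extra = pd.DataFrame({"exposure_x_sex": exposure_std * indicator}, index=sub.index)
    _, fit = _fit_cell(sub, exposure, outcome, covs, tier=1, extra_terms=extra)
    return float(fit.pvalues["exposure_x_sex"])


def sensitivity_puberty(
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str,
    tiers: tuple[int, ...] = (1, 2, 3),
    puberty_column: str = "puberty_high",
) -> list[AssociationResult]:
    """The same ladder with the puberty indicator replacing age as confounder."""
    return fit_ladder(cohort, exposure, outcome, tiers, age_variable=puberty_column)


def run_association_table(
    cohort: pd.DataFrame,
    exposures: tuple[str, ...] = EXPOSURES,
    outcomes: tuple[str, ...] = OUTCOMES,
    tiers: tuple[int, ...] = (1, 2, 3),
) -> pd.DataFrame:
    """Long-format results over every exposure × outcome × tier cell.

    Columns: exposure, outcome, model, beta, p, n — one row per fitted cell,
    mirroring the published tables' structure.
    """
    rows = []
    for exposure in exposures:
        for outcome in outcomes:
            for result in fit_ladder(cohort, exposure, outcome, tiers):
                rows.append(
                    {
                        "exposure": result.exposure,
                        "outcome": result.outcome,
                        "model": result.tier,
                        "beta": result.beta,
                        "p": result.p_value,
                        "n": result.n_used,
                    }
                )
    return pd.DataFrame(rows)
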