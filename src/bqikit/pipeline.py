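"""End-to-end assembly: input files -> analysis-ready cohort table.

Chains the modules in the order the analysis needs them: read and validate
the food library and recalls, resolve each recall day, drop participants
without two recall days, compute per-participant breakfast metrics, merge
the participant table, derive HOMA / MetS / center-wise adiposity z-scores /
the activity label, and apply the log-transform policy. The returned frame
has exactly the exposure, outcome and covariate columns the association
ladder consumes.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import breakfast_metrics, recall_io
from .activity import classify_activity
from .cardiometabolic import (
    BiomarkerPanel,
    MetsReference,
    center_zscore,
    classify_mets,
    compute_homa,
    compute_mets_z,
    transform_outcomes,
)
from .errors import DomainError
from .synthetic_cohort import packaged_mets_reference_paths


def _parse_tristate(value) -> bool | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"", "nan", "unknown"}:
        return None
    return text in {"true", "1", "yes"}


def score_participants(
    library: dict,
    recall_lines: list[recall_io.RecallLine],
    kidmed: dict | None = None,
    **bqi_options,
) -> tuple[pd.DataFrame, list[recall_io.Exclusion]]:
    """Per-participant breakfast metrics from resolved recalls.

    Returns the metrics table (one row per retained participant: BQI score,
    per-item means, BEDs, BEDb, skipping flags, mean daily energy) and the
    exclusion log of participants without two recall days.
    """
    by_participant: dict[str, dict[int, list]] = defaultdict(lambda: defaultdict(list))
    for line in recall_lines:
        by_participant[line.participant_id][line.day_index].append(line)
    days_by_participant = {
        pid: [recall_io.resolve_day(lines, library) for lines in days.values()]
        for pid, days in by_participant.items()
    }
    retained, exclusions = recall_io.apply_exclusions(days_by_participant)
    kidmed = kidmed or {}
    rows = [
        breakfast_metrics.summarize_participant(
            d1, d2, kidmed.get(pid), **bqi_options
        )
        for pid, (d1, d2) in retained.items()
    ]
    return pd.DataFrame(rows), exclusions


def _derive_mets(row: pd.Series, ref: MetsReference) -> tuple[object, float]:
    def val(col):
        v = row.get(col)
        return None if pd.isna(v) else float(v)

    panel = BiomarkerPanel(
        glucose_mg_dl=val("glucose"),
        uric_acid_mg_dl=val("uric_acid"),
        total_chol_mg_dl=val("cholesterol"),
        hdl_mg_dl=val("hdl"),
        ldl_mg_dl=val("ldl"),
        triglycerides_mg_dl=val("triglycerides"),
        ggt_u_l=val("ggt"),
        sbp_mmHg=val("sbp"),
        dbp_mmHg=val("dbp"),
        waist_cm=val("waist"),
    )
    mets = classify_mets(panel, row["sex"], float(row["age"]), ref)
    try:
        z = compute_mets_z(panel, row["sex"], float(row["age"]), ref)
    except DomainError:
        z = np.nan
    has = mets.has_mets if mets.complete else np.nan
    return has, z


def build_cohort(
    library: dict,
    recall_lines: list[recall_io.RecallLine],
    participants: pd.DataFrame,
    mets_reference: MetsReference | None = None,
    **bqi_options,
) -> tuple[pd.DataFrame, list[recall_io.Exclusion]]:
    """Assemble the analysis cohort from in-memory inputs.

    Participants missing from either source drop out of the merge; the
    exclusion log covers recall-based exclusions.
    """
    if mets_reference is None:
        stats_path, waist_path = packaged_mets_reference_paths()
        mets_reference = MetsReference.from_csv(stats_path, waist_path)
    participants = participants.copy()
    kidmed = {}
    if "kidmed_breakfast_skipper" in participants.columns:
        kidmed = {
            str(r.participant_id): _parse_tristate(r.kidmed_breakfast_skipper)
            for r in participants.itertuples(index=False)
        }
    metrics, exclusions = score_participants(library, recall_lines, kidmed, **bqi_options)
    cohort = metrics.merge(participants, on="participant_id", how="inner")

    cohort["homa"] = [
        compute_homa(float(ins), float(glu)) if pd.notna(ins) and pd.notna(glu) else np.nan
        for ins, glu in zip(cohort["insulin"], cohort["glucose"])
    ]
    mets_derived = [_derive_mets(row, mets_reference) for _, row in cohort.iterrows()]
    cohort["has_mets"] = [m[0] for m in mets_derived]
    cohort["mets_z"] = [m[1] for m in mets_derived]
    cohort["fmi_z"] = center_zscore(cohort["fmi"], cohort["center"])
    cohort["abdominal_fat_z"] = center_zscore(cohort["abdominal_fat"], cohort["center"])
    cohort["total_pa"] = cohort["total_pa_enmo"]
    cohort["is_active"] = [
        classify_activity(float(v)) if pd.notna(v) else np.nan
        for v in cohort["mvpa_min_day"]
    ]
    if "puberty_high" in cohort.columns:
        cohort["puberty_high"] = [
            _parse_tristate(v) if not isinstance(v, (bool, np.bool_)) else bool(v)
            for v in cohort["puberty_high"]
        ]
        cohort["puberty_high"] = cohort["puberty_high"].astype(float)

    cohort, manifest = transform_outcomes(cohort)
    cohort.attrs["transform_manifest"] = manifest
    return cohort, exclusions


def build_cohort_from_files(
    library_path: str | Path,
    recalls_path: str | Path,
    participants_path: str | Path,
    mets_stats_path: str | Path | None = None,
    waist_path: str | Path | None = None,
    **bqi_options,
) -> tuple[pd.DataFrame, list[recall_io.Exclusion]]:
    """File-based variant of :func:`build_cohort`."""
    library = recall_io.load_food_library(library_path)
    lines = recall_io.load_recalls(recalls_path)
    participants = pd.read_csv(participants_path)
    participants["participant_id"] = participants["participant_id"].astype(str)
    ref = None
    if mets_stats_path is not None and waist_path is not None:
        ref = MetsReference.from_csv(mets_stats_path, waist_path)
    return build_cohort(library, lines, participants, ref, **bqi_options)
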