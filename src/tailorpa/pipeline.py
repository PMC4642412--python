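"""End-to-end processing: minute counts -> day summaries -> assessments.

Chains the ingest, energy and aggregation stages for single participants
and for whole simulated cohorts. Non-wear detection runs on the continuous
minute series; runs are then split at local midnight for daily accounting.
Intensity classification applies only to worn, recorded minutes; for bout
scanning, non-wear and missing minutes behave as below-moderate
interruptions and contribute no credit.
"""
from __future__ import annotations

import datetime as dt
from typing import Mapping

import numpy as np
import pandas as pd

from . import simulate as sim
from .accel import MinuteSeries, detect_nonwear, summarize_day
from .assessment import (
    AssessmentResult,
    aggregate_assessment,
    assessments_to_frame,
)
from .baecke import score_baecke
from .energy import (
    MINUTES_PER_DAY,
    PAL_INTERCEPT,
    PAL_SLOPE_PER_COUNT,
    BMREquationTable,
    Intensity,
    IntensityThresholds,
    PositionCorrectionTable,
    aee_rate_per_minute,
    bmr_kcal_per_day,
    bouted_moderate_equivalent,
    classify_minute,
    corrected_counts,
    daily_aee,
    daily_pal,
    moderate_equivalent,
)


def complete_day_summaries(
    series: MinuteSeries,
    profile: Mapping,
    *,
    correction_table: PositionCorrectionTable | None = None,
    bmr_table: BMREquationTable | None = None,
    thresholds: IntensityThresholds | None = None,
) -> pd.DataFrame:
    """Per-day wear, validity, PAL/AEE and intensity minutes for one series."""
    correction_table = correction_table or PositionCorrectionTable.default()
    thresholds = thresholds or IntensityThresholds()
    bmr = bmr_kcal_per_day(
        str(profile["sex"]), float(profile["age"]), float(profile["weight"]),
        bmr_table,
    )
    weight = float(profile["weight"])

    grid = series.full_grid()
    present = ~grid["counts"].isna().to_numpy()
    counts = np.nan_to_num(grid["counts"].to_numpy(dtype=float))
    positions = grid["position"].to_numpy(dtype=object)
    positions[~present] = "belt"  # factor irrelevant for zeroed missing counts
    corr = corrected_counts(counts, positions, correction_table)

    pal_min = np.where(
        present,
        PAL_INTERCEPT + PAL_SLOPE_PER_COUNT * corr * MINUTES_PER_DAY,
        np.nan,
    )
    wear = detect_nonwear(pal_min)

    n_days = len(grid) // MINUTES_PER_DAY
    rate = aee_rate_per_minute(np.nan_to_num(pal_min, nan=1.354), bmr, weight)
    classes = classify_minute(rate, thresholds)

    rows = []
    for d in range(n_days):
        sl = slice(d * MINUTES_PER_DAY, (d + 1) * MINUTES_PER_DAY)
        date = grid.index[d * MINUTES_PER_DAY].date()
        day_wear = wear[sl] & present[sl]
        summary = summarize_day(date, wear[sl], present[sl])
        counts_day = float(corr[sl].sum())
        pal = daily_pal(counts_day)
        # class tallies restricted to worn, recorded minutes
        cls_counts = {
            c: int(((classes[sl] == int(c)) & day_wear).sum())
            for c in Intensity
        }
        mpa = cls_counts[Intensity.MODERATE]
        vpa = cls_counts[Intensity.VIGOROUS]
        # non-wear minutes act as below-moderate interruptions in bout scans
        bout_classes = np.where(day_wear, classes[sl], int(Intensity.SEDENTARY))
        rows.append(
            {
                "participant_id": series.participant_id,
                "date": date,
                "wear_time": summary.wear_time,
                "nonwear_time": summary.nonwear_time,
                "is_valid": summary.is_valid,
                "is_weekend": summary.is_weekend,
                "counts_day": counts_day,
                "daily_pal": pal,
                "daily_aee": daily_aee(pal, bmr),
                "sedentary": cls_counts[Intensity.SEDENTARY],
                "lpa": cls_counts[Intensity.LIGHT],
                "mpa": mpa,
                "vpa": vpa,
                "moderate_equivalent": moderate_equivalent(mpa, vpa),
                "moderate_equivalent_bouted": bouted_moderate_equivalent(
                    bout_classes
                ),
            }
        )
    return pd.DataFrame(rows)


def assess_participant(
    series: MinuteSeries,
    profile: Mapping,
    timepoint: str,
    window: tuple[dt.date, dt.date],
    **tables,
) -> AssessmentResult:
    """Process one participant's window into an assessment result."""
    days = complete_day_summaries(series, profile, **tables)
    return aggregate_assessment(
        days, series.participant_id, timepoint, window
    )


def run_cohort_assessments(
    profiles: pd.DataFrame,
    config: sim.SimulationConfig,
    timepoints: tuple[str, ...] = ("baseline", "month3", "month6"),
) -> pd.DataFrame:
    """Simulate and process a whole cohort; one row per participant-timepoint.

    Streams one participant-window at a time so memory stays flat.
    """
    results = []
    for tp in timepoints:
        for i in range(len(profiles)):
            simulated = sim.participant_window(profiles, config, i, tp)
            row = profiles.iloc[i]
            window = (
                simulated.series.frame.index[0].date(),
                simulated.series.frame.index[-1].date(),
            )
            results.append(
                assess_participant(simulated.series, row, tp, window)
            )
    return assessments_to_frame(results)


def cohort_advice(
    profiles: pd.DataFrame,
    assessments: pd.DataFrame,
    baecke_indices: pd.DataFrame | None = None,
    timepoint: str = "baseline",
) -> pd.DataFrame:
    """Advice decisions for every participant at one timepoint.

    Uses the accelerometer assessment when sufficient, else the Baecke
    fallback when indices are available; participants with neither are
    skipped. L0 rows carry the counterfactual advised_to_increase flag.
    """
    from .assessment import AssessmentResult
    from .baecke import BaeckeIndices
    from .feedback import FeedbackError, derive_advice

    ass = assessments[assessments["timepoint"] == timepoint].set_index(
        "participant_id"
    )
    bae = (
        baecke_indices[baecke_indices["timepoint"] == timepoint].set_index(
            "participant_id"
        )
        if baecke_indices is not None
        else None
    )
    rows = []
    for _, profile in profiles.iterrows():
        pid = str(profile["id"])
        result = None
        if pid in ass.index:
            a = ass.loc[pid]
            result = AssessmentResult(
                participant_id=pid,
                timepoint=timepoint,
                window_start=a["window_start"],
                window_end=a["window_end"],
                n_valid_weekdays=int(a["n_valid_weekdays"]),
                n_valid_weekend_days=int(a["n_valid_weekend_days"]),
                sufficient=bool(a["sufficient"]),
                daily_means={"daily_pal": a["daily_pal"]} if a["sufficient"] else {},
            )
        indices = None
        if bae is not None and pid in bae.index:
            b = bae.loc[pid]
            work = b["work_index"]
            indices = BaeckeIndices(
                work_index=None if pd.isna(work) else float(work),
                sport_index=float(b["sport_index"]),
                leisure_index=float(b["leisure_index"]),
            )
        try:
            decision = derive_advice(
                profile, result, indices, timepoint=timepoint
            )
        except FeedbackError:
            continue
        rows.append(
            {
                "participant_id": pid,
                "timepoint": timepoint,
                "group": decision.group,
                "source": decision.source,
                "adequacy": decision.adequacy.value if decision.adequacy else None,
                "color": decision.color,
                "advice_category": (
                    decision.advice_category.value
                    if decision.advice_category
                    else None
                ),
                "message_components": ";".join(decision.message_components),
                "advised_to_increase": decision.advised_to_increase,
            }
        )
    return pd.DataFrame(rows)


def run_cohort_baecke(
    profiles: pd.DataFrame,
    config: sim.SimulationConfig,
    timepoints: tuple[str, ...] = ("baseline", "month3", "month6"),
) -> pd.DataFrame:
    """Simulated Baecke responses scored into indices per participant-timepoint."""
    rows = []
    for tp in timepoints:
        for i in range(len(profiles)):
            resp = sim.participant_baecke(profiles, config, i, tp)
            idx = score_baecke(resp)
            rows.append(
                {
                    "participant_id": profiles.iloc[i]["id"],
                    "timepoint": tp,
                    "work_index": idx.work_index,
                    "sport_index": idx.sport_index,
                    "leisure_index": idx.leisure_index,
                    "total_index": idx.total_index,
                }
            )
    return pd.DataFrame(rows)
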