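"""Aggregation of valid days within a 2-week assessment window.

Each trial timepoint (baseline, month 3, month 6) is assessed over the 14
calendar days preceding feedback derivation. A window is *sufficient* when
it holds at least 3 valid weekdays and 2 valid weekend days. Outcomes are
weekday/weekend weighted::

    daily mean  = (weekday mean * 5 + weekend mean * 2) / 7
    weekly total = weekday mean * 5 + weekend mean * 2

PAL and AEE are intrinsically per-day and get daily means only; the
time-based variables (sedentary, LPA, MPA, VPA, moderate-equivalent and its
bouted variant) additionally get weekly totals, which by construction equal
7x the daily mean. Mean wear time uses the same daily weighting so that the
wear-time-change covariate is on the same footing as the outcomes.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import pandas as pd

TIMEPOINTS = ("baseline", "month3", "month6")

#: Outcome columns aggregated from day summaries.
DAILY_OUTCOMES = (
    "daily_pal",
    "daily_aee",
    "sedentary",
    "lpa",
    "mpa",
    "vpa",
    "moderate_equivalent",
    "moderate_equivalent_bouted",
)
#: Subset with a meaningful min/wk total.
TIME_BASED_OUTCOMES = (
    "sedentary",
    "lpa",
    "mpa",
    "vpa",
    "moderate_equivalent",
    "moderate_equivalent_bouted",
)

ASSESSMENT_DAYS = 14
MIN_VALID_WEEKDAYS = 3
MIN_VALID_WEEKEND_DAYS = 2


def assessment_window(feedback_date: dt.date) -> tuple[dt.date, dt.date]:
    """The 14 calendar days ending the day before feedback derivation."""
    end = feedback_date - dt.timedelta(days=1)
    start = feedback_date - dt.timedelta(days=ASSESSMENT_DAYS)
    return start, end


def check_sufficiency(day_summaries: pd.DataFrame) -> tuple[int, int, bool]:
    """Counts of valid weekdays/weekend days and the sufficiency flag."""
    valid = day_summaries[day_summaries["is_valid"]]
    n_weekend = int(valid["is_weekend"].sum())
    n_weekday = int(len(valid) - n_weekend)
    ok = n_weekday >= MIN_VALID_WEEKDAYS and n_weekend >= MIN_VALID_WEEKEND_DAYS
    return n_weekday, n_weekend, ok


def weighted_daily_mean(weekday_mean: float, weekend_mean: float) -> float:
    """(weekday mean * 5 + weekend mean * 2) / 7."""
    return (5.0 * weekday_mean + 2.0 * weekend_mean) / 7.0


def weekly_estimate(weekday_mean: float, weekend_mean: float) -> float:
    """weekday mean * 5 + weekend mean * 2 (identically 7x the daily mean)."""
    return 5.0 * weekday_mean + 2.0 * weekend_mean


@dataclass
class AssessmentResult:
    """Per-participant per-timepoint aggregated physical-activity outcomes."""

    participant_id: str
    timepoint: str
    window_start: dt.date
    window_end: dt.date
    n_valid_weekdays: int
    n_valid_weekend_days: int
    sufficient: bool
    daily_means: dict[str, float] = field(default_factory=dict)
    weekly_totals: dict[str, float] = field(default_factory=dict)
    mean_wear_time: float | None = None

    @property
    def pal(self) -> float | None:
        return self.daily_means.get("daily_pal")


def aggregate_assessment(
    day_summaries: pd.DataFrame,
    participant_id: str,
    timepoint: str,
    window: tuple[dt.date, dt.date],
) -> AssessmentResult:
    """Aggregate completed day summaries inside the window into one result.

    ``day_summaries`` needs columns ``date``, ``is_valid``, ``is_weekend``,
    ``wear_time`` plus the outcome columns in :data:`DAILY_OUTCOMES`.
    Only valid days contribute; when the window is insufficient all outcome
    fields are left absent.
    """
    start, end = window
    dates = pd.to_datetime(day_summaries["date"]).dt.date
    in_window = day_summaries[(dates >= start) & (dates <= end)]
    n_weekday, n_weekend, sufficient = check_sufficiency(in_window)
    result = AssessmentResult(
        participant_id=participant_id,
        timepoint=timepoint,
        window_start=start,
        window_end=end,
        n_valid_weekdays=n_weekday,
        n_valid_weekend_days=n_weekend,
        sufficient=sufficient,
    )
    if not sufficient:
        return result
    valid = in_window[in_window["is_valid"]]
    weekday = valid[~valid["is_weekend"]]
    weekend = valid[valid["is_weekend"]]
    for col in DAILY_OUTCOMES:
        wd = float(weekday[col].mean())
        we = float(weekend[col].mean())
        result.daily_means[col] = weighted_daily_mean(wd, we)
        if col in TIME_BASED_OUTCOMES:
            result.weekly_totals[col] = weekly_estimate(wd, we)
    result.mean_wear_time = weighted_daily_mean(
        float(weekday["wear_time"].mean()), float(weekend["wear_time"].mean())
    )
    return result


def assessments_to_frame(results: list[AssessmentResult]) -> pd.DataFrame:
    """Flatten assessment results into the per-participant-per-timepoint table."""
    rows = []
    for r in results:
        row: dict = {
            "participant_id": r.participant_id,
            "timepoint": r.timepoint,
            "window_start": r.window_start,
            "window_end": r.window_end,
            "n_valid_weekdays": r.n_valid_weekdays,
            "n_valid_weekend_days": r.n_valid_weekend_days,
            "sufficient": r.sufficient,
            "mean_wear_time": r.mean_wear_time,
        }
        for col in DAILY_OUTCOMES:
            row[col] = r.daily_means.get(col)
        for col in TIME_BASED_OUTCOMES:
            row[f"{col}_weekly"] = r.weekly_totals.get(col)
        rows.append(row)
    return pd.DataFrame(rows)
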