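"""Minute-epoch accelerometer ingest, per-minute PAL, non-wear detection.

The wearable records one activity-count total per minute. Per-minute PAL is
derived by applying the daily count-to-PAL regression to the minute's count
rate sustained over a whole day (corrected counts * 1440 minutes), so a
constant count rate gives the same value per minute as the daily equation
gives for the day.

Non-wear time is detected with an adaptation of the Choi et al. algorithm:
an interval of at least 90 consecutive minutes with per-minute PAL below
1.3889, allowing embedded spikes of at most 2 consecutive above-threshold
minutes provided the 30 values immediately upstream or downstream of the
spike are all below the threshold. Missing epochs are treated as
sub-threshold for detection and as non-wear for wear-time accounting, so
every minute of a day is classified. A valid day has 10-18 h of wear
(600-1080 min inclusive).
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import rle
from .energy import (
    MINUTES_PER_DAY,
    PAL_INTERCEPT,
    PAL_SLOPE_PER_COUNT,
    PositionCorrectionTable,
    corrected_counts,
)

#: Per-minute PAL below this value counts toward non-wear intervals.
NONWEAR_PAL_THRESHOLD = 1.3889
NONWEAR_MIN_PERIOD = 90
NONWEAR_MAX_SPIKE = 2
NONWEAR_FLANK = 30

VALID_DAY_MIN_WEAR = 600
VALID_DAY_MAX_WEAR = 1080

KNOWN_POSITIONS = ("pocket", "belt", "necklace", "bra")


class EpochParseError(ValueError):
    """Malformed minute-epoch input."""


@dataclass
class MinuteSeries:
    """Per-participant minute-epoch counts.

    ``frame`` is indexed by minute-resolution timestamps (strictly
    increasing; missing epochs are simply absent rows, never silently
    filled) with columns ``counts`` (float, >= 0) and ``position`` (str).
    """

    participant_id: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.frame.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise EpochParseError("epoch index must be datetimes")
        if idx.has_duplicates:
            first = idx[idx.duplicated()][0]
            raise EpochParseError(f"duplicated epoch timestamp {first}")
        if not idx.is_monotonic_increasing:
            raise EpochParseError("epoch timestamps must be strictly increasing")
        if (self.frame["counts"] < 0).any():
            raise EpochParseError("counts must be >= 0")

    @property
    def n_epochs(self) -> int:
        return len(self.frame)

    def full_grid(self) -> pd.DataFrame:
        """Reindex onto the complete 1-min grid covering whole days.

        Missing epochs appear with NaN counts. The grid spans local
        midnight of the first recorded day through the end of the last.
        """
        start = self.frame.index[0].normalize()
        end = self.frame.index[-1].normalize() + pd.Timedelta(days=1)
        grid = pd.date_range(start, end, freq="min", inclusive="left")
        return self.frame.reindex(grid)


def read_minute_epochs(path, participant_id: str | None = None) -> MinuteSeries:
    """Read the minute-epoch CSV dialect (participant_id,timestamp,counts,position)."""
    df = pd.read_csv(path, comment="#")
    required = {"participant_id", "timestamp", "counts", "position"}
    if not required.issubset(df.columns):
        raise EpochParseError(f"epoch CSV must have columns {sorted(required)}")
    if participant_id is not None:
        df = df[df["participant_id"] == participant_id]
    ids = df["participant_id"].unique()
    if len(ids) != 1:
        raise EpochParseError(f"expected a single participant per series, got {list(ids)}")
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise EpochParseError(f"unparseable timestamp: {exc}") from exc
    counts = pd.to_numeric(df["counts"], errors="coerce")
    if counts.isna().any():
        line = int(df.index[counts.isna()][0]) + 2  # 1-based, plus header
        raise EpochParseError(f"malformed counts value at line {line}")
    bad_pos = ~df["position"].isin(KNOWN_POSITIONS)
    if bad_pos.any():
        line = int(df.index[bad_pos][0]) + 2
        raise EpochParseError(f"unknown wearing position at line {line}")
    frame = pd.DataFrame(
        {"counts": counts.to_numpy(float), "position": df["position"].to_numpy()},
        index=pd.DatetimeIndex(ts),
    )
    return MinuteSeries(participant_id=str(ids[0]), frame=frame)


def write_minute_epochs(series: MinuteSeries, path) -> None:
    out = pd.DataFrame(
        {
            "participant_id": series.participant_id,
            "timestamp": series.frame.index.strftime("%Y-%m-%dT%H:%M:%S"),
            "counts": series.frame["counts"].to_numpy(),
            "position": series.frame["position"].to_numpy(),
        }
    )
    out.to_csv(path, index=False)


def pal_per_minute(counts_min, position, table: PositionCorrectionTable):
    """Per-minute PAL from a minute's counts and wearing position.

    Equals the daily-equation PAL that the same corrected count rate would
    give if sustained over all 1440 minutes of a day.
    """
    counts_min = np.asarray(counts_min, dtype=float)
    if np.any(counts_min < 0):
        raise ValueError("counts_min must be >= 0")
    corr = corrected_counts(counts_min, position, table)
    out = PAL_INTERCEPT + PAL_SLOPE_PER_COUNT * corr * MINUTES_PER_DAY
    return float(out) if out.ndim == 0 else out


def detect_nonwear(
    pal_minute,
    *,
    threshold: float = NONWEAR_PAL_THRESHOLD,
    min_period: int = NONWEAR_MIN_PERIOD,
    max_spike: int = NONWEAR_MAX_SPIKE,
    flank: int = NONWEAR_FLANK,
) -> np.ndarray:
    """Boolean wear mask (True = worn) from a per-minute PAL sequence.

    NaN values (missing epochs) are treated as sub-threshold. A maximal
    candidate interval is marked non-wear when it spans >= ``min_period``
    minutes of sub-threshold values plus admissible spikes; a spike is
    admissible when it is <= ``max_spike`` consecutive above-threshold
    minutes and the ``flank`` values immediately before or immediately
    after it are all sub-threshold. Inadmissible spikes terminate the
    interval. Intervals start and end on sub-threshold minutes.
    """
    pal = np.asarray(pal_minute, dtype=float)
    low = ~(pal >= threshold)  # NaN compares False, so missing -> low
    n = low.size
    nonwear = np.zeros(n, dtype=bool)
    if n == 0:
        return ~nonwear
    values, starts, lengths = rle(low)
    n_runs = len(values)
    # admissibility of each above-threshold run as an embedded spike
    spike_ok = np.zeros(n_runs, dtype=bool)
    for k in range(n_runs):
        if values[k] or lengths[k] > max_spike:
            continue
        up = lengths[k - 1] if k > 0 else 0
        down = lengths[k + 1] if k + 1 < n_runs else 0
        spike_ok[k] = (up >= flank) or (down >= flank)
    k = 0
    while k < n_runs:
        if not values[k]:
            k += 1
            continue
        w_start = int(starts[k])
        w_end = int(starts[k] + lengths[k] - 1)
        j = k + 1
        while j + 1 < n_runs and not values[j] and spike_ok[j]:
            w_end = int(starts[j + 1] + lengths[j + 1] - 1)
            j += 2
        if w_end - w_start + 1 >= min_period:
            nonwear[w_start : w_end + 1] = True
        k = j + 1
    return ~nonwear


@dataclass
class DayWearSummary:
    """Wear-time accounting for a single calendar day."""

    date: dt.date
    wear_time: int
    nonwear_time: int
    is_valid: bool
    is_weekend: bool


def summarize_day(
    date: dt.date, wear_mask: np.ndarray, present: np.ndarray | None = None
) -> DayWearSummary:
    """Wear fields for one day given its 1440-minute wear mask.

    ``present`` marks minutes with a recorded epoch; missing minutes count
    as non-wear regardless of the mask.
    """
    wear_mask = np.asarray(wear_mask, dtype=bool)
    if wear_mask.size != MINUTES_PER_DAY:
        raise ValueError("day mask must have exactly 1440 minutes")
    if present is not None:
        wear_mask = wear_mask & np.asarray(present, dtype=bool)
    wear = int(wear_mask.sum())
    return DayWearSummary(
        date=date,
        wear_time=wear,
        nonwear_time=MINUTES_PER_DAY - wear,
        is_valid=VALID_DAY_MIN_WEAR <= wear <= VALID_DAY_MAX_WEAR,
        is_weekend=date.isoweekday() >= 6,
    )
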