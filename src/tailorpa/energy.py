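"""Energy-expenditure metrics from minute-epoch accelerometer counts.

The device's native output is an activity-count total per one-minute epoch.
Daily physical activity level (PAL, the ratio of total to basal energy
expenditure) is a linear function of the summed daily counts::

    PAL = 1.354 + 256e-9 * counts_day

Activity energy expenditure (AEE) follows from PAL and the basal metabolic
rate (BMR)::

    AEE [kcal/d] = (0.9 * PAL - 1) * BMR

BMR is predicted from sex, age band, and body weight with the Henry/Oxford
weight-only equations, shipped as a CSV fixture in ``data/``.

Minute-level intensity classes (sedentary, light, moderate, vigorous) come
from the per-minute AEE rate in kcal/(kg*min) against cut-points of 0.025,
0.05 and 0.1, i.e. 1.5, 3 and 6 METs under the 1 MET = 1 kcal/(kg*h)
convention. Moderate-equivalent PA counts each vigorous minute twice
(MPA + 2*VPA), and its "bouted" variant credits only minutes inside
modified >=10-minute bouts that allow interruptions of <=2 consecutive
below-moderate minutes.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import rle

#: Intercept and slope of the daily count-to-PAL regression.
PAL_INTERCEPT = 1.354
PAL_SLOPE_PER_COUNT = 256e-9

MINUTES_PER_DAY = 1440
KCAL_PER_MJ = 239.005


class Intensity(enum.IntEnum):
    SEDENTARY = 0
    LIGHT = 1
    MODERATE = 2
    VIGOROUS = 3


@dataclass(frozen=True)
class IntensityThresholds:
    """AEE-rate cut-points, each tied to its MET equivalent (MET/60)."""

    met_equivalents: tuple[float, float, float] = (1.5, 3.0, 6.0)

    def __post_init__(self) -> None:
        if not all(a < b for a, b in zip(self.met_equivalents, self.met_equivalents[1:])):
            raise ValueError("MET equivalents must be strictly increasing")

    @property
    def boundaries(self) -> np.ndarray:
        """Cut-points in kcal/(kg*min): sedentary/light, light/moderate, moderate/vigorous."""
        return np.array([m / 60.0 for m in self.met_equivalents])

    @property
    def sedentary_light(self) -> float:
        return self.met_equivalents[0] / 60.0

    @property
    def light_moderate(self) -> float:
        return self.met_equivalents[1] / 60.0

    @property
    def moderate_vigorous(self) -> float:
        return self.met_equivalents[2] / 60.0


@dataclass(frozen=True)
class PositionCorrectionTable:
    """Multiplicative count corrections by wearing position (belt = reference)."""

    factors: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.factors.get("belt") != 1.0:
            raise ValueError("belt position must have correction factor exactly 1.0")
        for pos, f in self.factors.items():
            if not f > 0:
                raise ValueError(f"correction factor for position {pos!r} must be > 0")

    def factor(self, position: str) -> float:
        try:
            return self.factors[position]
        except KeyError:
            raise KeyError(f"unknown wearing position {position!r}") from None

    def factors_for(self, positions: Sequence[str] | np.ndarray) -> np.ndarray:
        pos = pd.Series(np.asarray(positions, dtype=object))
        mapped = pos.map(self.factors)
        if mapped.isna().any():
            bad = sorted(set(pos[mapped.isna()]))
            raise KeyError(f"unknown wearing position(s): {bad}")
        return mapped.to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path) -> "PositionCorrectionTable":
        df = pd.read_csv(path, comment="#")
        return cls(dict(zip(df["position"], df["factor"].astype(float))))

    @classmethod
    def default(cls) -> "PositionCorrectionTable":
        with resources.as_file(
            resources.files("tailorpa.data") / "position_correction.csv"
        ) as p:
            return cls.from_csv(p)


@dataclass(frozen=True)
class BMREquationTable:
    """Henry/Oxford weight-only BMR equations by sex and age band.

    Bands partition ages >= 18; ``age_max`` is exclusive and NaN means
    open-ended. Coefficients are stored in MJ/d and converted to kcal/d.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        req = {"sex", "age_min", "age_max", "slope_mj_per_kg", "intercept_mj"}
        if not req.issubset(self.frame.columns):
            raise ValueError(f"BMR table must have columns {sorted(req)}")
        if not (self.frame["slope_mj_per_kg"] > 0).all():
            raise ValueError("all BMR slopes must be > 0")
        for sex, grp in self.frame.groupby("sex"):
            g = grp.sort_values("age_min")
            lo = g["age_min"].to_numpy(dtype=float)
            hi = g["age_max"].to_numpy(dtype=float)
            if lo[0] > 18:
                raise ValueError(f"BMR bands for {sex} do not cover age 18")
            if np.any(lo[1:] != hi[:-1]) or not np.isnan(hi[-1]):
                raise ValueError(f"BMR age bands for {sex} must partition [18, inf)")

    def bmr_kcal_per_day(self, sex: str, age: float, weight: float) -> float:
        if weight <= 0:
            raise ValueError("weight must be > 0")
        rows = self.frame[self.frame["sex"] == sex]
        if rows.empty:
            raise ValueError(f"unknown sex {sex!r} in BMR table")
        hi = rows["age_max"].fillna(np.inf)
        hit = rows[(rows["age_min"] <= age) & (age < hi)]
        if hit.empty:
            raise ValueError(f"age {age} outside BMR table range for sex {sex!r}")
        row = hit.iloc[0]
        mj = row["slope_mj_per_kg"] * weight + row["intercept_mj"]
        return float(mj * KCAL_PER_MJ)

    @classmethod
    def from_csv(cls, path) -> "BMREquationTable":
        return cls(pd.read_csv(path, comment="#"))

    @classmethod
    def default(cls) -> "BMREquationTable":
        with resources.as_file(
            resources.files("tailorpa.data") / "henry_oxford_bmr.csv"
        ) as p:
            return cls.from_csv(p)


def bmr_kcal_per_day(
    sex: str, age: float, weight: float, table: BMREquationTable | None = None
) -> float:
    """Basal metabolic rate in kcal/d from the Henry/Oxford equations."""
    if age < 18:
        raise ValueError("age must be >= 18")
    table = table or BMREquationTable.default()
    return table.bmr_kcal_per_day(sex, age, weight)


def daily_pal(counts_day: float) -> float:
    """Daily PAL from position-corrected counts summed over 24 h."""
    if counts_day < 0:
        raise ValueError("counts_day must be >= 0")
    return PAL_INTERCEPT + PAL_SLOPE_PER_COUNT * counts_day


def corrected_counts(
    counts: np.ndarray, positions: Sequence[str] | np.ndarray | str,
    table: PositionCorrectionTable,
) -> np.ndarray:
    """Scale per-epoch counts by the wearing-position correction factor."""
    counts = np.asarray(counts, dtype=float)
    if isinstance(positions, str):
        return counts * table.factor(positions)
    return counts * table.factors_for(positions)


def daily_aee(pal: float, bmr: float) -> float:
    """Daily activity energy expenditure, (0.9*PAL - 1) * BMR, kcal/d.

    May be negative for PAL below 1/0.9; reported as computed.
    """
    if bmr <= 0:
        raise ValueError("bmr must be > 0")
    return (0.9 * pal - 1.0) * bmr


def aee_rate_per_minute(pal_min, bmr: float, weight: float):
    """Per-minute AEE rate in kcal/(kg*min), floored at 0.

    Scales the daily AEE relation to a single minute: the per-minute PAL is
    treated as if sustained all day, and the resulting daily AEE is divided
    by body weight and the 1440 minutes of the day.
    """
    if bmr <= 0 or weight <= 0:
        raise ValueError("bmr and weight must be > 0")
    pal_min = np.asarray(pal_min, dtype=float)
    rate = (0.9 * pal_min - 1.0) * bmr / (weight * MINUTES_PER_DAY)
    out = np.maximum(rate, 0.0)
    return float(out) if out.ndim == 0 else out


def classify_minute(rate, thresholds: IntensityThresholds | None = None):
    """Intensity class for an AEE rate; boundary values go to the class above."""
    thresholds = thresholds or IntensityThresholds()
    rate_arr = np.asarray(rate, dtype=float)
    if np.any(rate_arr < 0):
        raise ValueError("rate must be >= 0")
    idx = np.searchsorted(thresholds.boundaries, rate_arr, side="right")
    if idx.ndim == 0:
        return Intensity(int(idx))
    return idx.astype(np.int8)


def moderate_equivalent(mpa: float, vpa: float) -> float:
    """Moderate-equivalent PA minutes: MPA + 2 * VPA."""
    if mpa < 0 or vpa < 0:
        raise ValueError("minute totals must be >= 0")
    return mpa + 2.0 * vpa


def bouted_moderate_equivalent(
    minute_classes: Sequence[int] | np.ndarray,
    *,
    min_bout_minutes: int = 10,
    max_interruption_minutes: int = 2,
) -> float:
    """Moderate-equivalent minutes occurring inside modified bouts.

    A bout is a maximal window of at least ``min_bout_minutes`` that starts
    and ends on an at-or-above-moderate minute and whose every minute is
    at-or-above-moderate except interruptions of at most
    ``max_interruption_minutes`` consecutive below-moderate minutes.
    Interruption minutes contribute 0; vigorous minutes inside bouts count
    double (MPA + 2*VPA).
    """
    cls = np.asarray(minute_classes, dtype=np.int64)
    if cls.size == 0:
        return 0.0
    above = cls >= int(Intensity.MODERATE)
    if not above.any():
        return 0.0
    credit = np.where(cls >= int(Intensity.VIGOROUS), 2.0,
                      np.where(above, 1.0, 0.0))
    values, starts, lengths = rle(above)
    total = 0.0
    k = 0
    n_runs = len(values)
    while k < n_runs:
        if not values[k]:
            k += 1
            continue
        w_start = int(starts[k])
        w_end = int(starts[k] + lengths[k] - 1)
        j = k + 1
        # absorb interruption + following above-run pairs
        while (
            j + 1 < n_runs
            and not values[j]
            and lengths[j] <= max_interruption_minutes
        ):
            w_end = int(starts[j + 1] + lengths[j + 1] - 1)
            j += 2
        if w_end - w_start + 1 >= min_bout_minutes:
            total += float(credit[w_start : w_end + 1].sum())
        k = j + 1
    return total
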