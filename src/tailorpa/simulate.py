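"""Synthetic trial cohort with known ground truth.

Generates participant profiles, minute-epoch accelerometer counts for the
three 2-week assessment windows, and Baecke questionnaire responses, so the
whole processing and analysis chain is testable without any study data.

Model
-----
Each participant carries a latent true PAL drawn from a shifted lognormal
(floored at the count-to-PAL intercept 1.354, calibrated to the configured
mean and SD; PAL is bounded below by the device floor and right-skewed in
cohorts). Minute counts are generated by a two-regime Markov process —
low-count background vs high-count activity bouts — with lognormal counts
in each regime. The bout occupancy of each day is calibrated so that the
day's summed counts reproduce that day's target PAL through the daily
count-to-PAL equation; intervention effects therefore enter through the
bout rate, not as a direct count offset. Weekdays and weekend days get
separate targets tied together by the 5/2 weighting so the weekly weighted
mean equals the participant's true PAL.

Non-wear is embedded as zero-count gaps: per day a Poisson number of gaps,
the first anchored at midnight (overnight device-off, long), later ones
shorter, all at least 90 min so the detection rule can recover them.
With ``nonwear_gap_rate = 0`` no gaps are generated at all and the
ground-truth wear mask is all-wear.

Baecke responses are generated from a piecewise-linear calibration map
from true PAL to a latent 1-5 item level; there is no published generative
link between PAL and Baecke items, so the map is explicitly a documented
test scaffold. ``reporting_bias`` shifts each item's latent level by
bias/3 so the expected *total* index inflates by approximately the bias.

Determinism: every random stream is derived from (seed, participant index,
stage), so identical (seed, config) gives identical output regardless of
call order.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .accel import MinuteSeries
from .baecke import BaeckeResponse, LEISURE_ITEMS, SPORT_ITEMS, SportEntry, WORK_ITEMS
from .energy import MINUTES_PER_DAY, PAL_INTERCEPT, PAL_SLOPE_PER_COUNT

COUNTRIES = (
    "Germany",
    "Greece",
    "Ireland",
    "Netherlands",
    "Poland",
    "Spain",
    "United Kingdom",
)
SEASONS = ("winter", "spring", "summer", "autumn")
GROUPS = ("L0", "L1", "L2", "L3")
TIMEPOINT_OFFSETS_DAYS = {"baseline": 14, "month3": 104, "month6": 194}

#: FTO rs9939609 risk-allele (A) frequency giving a carrier fraction of
#: ~0.693 under Hardy-Weinberg: 1 - (1-p)^2 = 0.693.
FTO_RISK_ALLELE_FREQ = 1.0 - np.sqrt(1.0 - 0.693)

# stage codes for per-participant random substreams
_STAGE_PROFILE = 1
_STAGE_COUNTS = {"baseline": 10, "month3": 11, "month6": 12}
_STAGE_BAECKE = {"baseline": 20, "month3": 21, "month6": 22}
_STAGE_TRUTH = 30


class ConfigError(ValueError):
    """Invalid simulation configuration value."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults echo the trial's baseline table: cohort mean PAL 1.73 (SD
    0.18), four balanced arms, ~69% FTO risk-allele carriers, Baecke total
    index near 7.8, and small intervention-induced PAL changes at months 3
    and 6.
    """

    n_participants: int = 200
    seed: int = 0
    true_pal_mean: float = 1.73
    true_pal_sd: float = 0.18
    #: expected non-wear gaps per day (0 disables non-wear entirely)
    nonwear_gap_rate: float = 1.4
    #: mean length (min) of the overnight gap; secondary gaps are shorter
    mean_gap_length: float = 420.0
    weekend_activity_ratio: float = 0.9
    #: group -> (PAL change at month 3, at month 6)
    effect_size_by_level: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "L0": (0.02, 0.01),
            "L1": (0.02, 0.01),
            "L2": (0.02, 0.01),
            "L3": (0.02, 0.01),
        }
    )
    #: additive inflation of simulated Baecke indices (self-report bias)
    reporting_bias: float = 0.0

    # cohort composition (baseline-table targets)
    female_fraction: float = 0.585
    age_mean: float = 39.9
    age_sd: float = 13.0
    bmi_mean: float = 25.5
    bmi_sd: float = 4.8
    smoking_fractions: tuple[float, float, float] = (0.12, 0.255, 0.625)  # current/ex/never
    fto_risk_allele_freq: float = FTO_RISK_ALLELE_FREQ
    employment_inactive_rate: float = 0.1

    # count-generation model
    background_mean_counts: float = 900.0
    background_sigma: float = 0.7
    bout_mean_counts: float = 12000.0
    bout_sigma: float = 0.5
    mean_bout_minutes: float = 6.0
    day_level_sigma: float = 0.08
    #: SD of individual deviation around the group PAL effect at follow-up
    response_sd: float = 0.02
    #: SD of latent item noise in Baecke generation
    baecke_item_sigma: float = 0.7

    start_date: dt.date = dt.date(2012, 9, 3)

    def validate(self) -> None:
        checks = {
            "n_participants": self.n_participants >= 4,
            "true_pal_sd": self.true_pal_sd >= 0,
            "nonwear_gap_rate": self.nonwear_gap_rate >= 0,
            "mean_gap_length": self.mean_gap_length >= 90,
            "weekend_activity_ratio": self.weekend_activity_ratio > 0,
            "female_fraction": 0 <= self.female_fraction <= 1,
            "fto_risk_allele_freq": 0 <= self.fto_risk_allele_freq <= 1,
            "bout_mean_counts": self.bout_mean_counts > self.background_mean_counts,
            "mean_bout_minutes": self.mean_bout_minutes >= 1,
            "smoking_fractions": abs(sum(self.smoking_fractions) - 1) < 1e-9,
        }
        for name, ok in checks.items():
            if not ok:
                raise ConfigError(f"invalid configuration value for {name!r}")
        for g in GROUPS:
            if g not in self.effect_size_by_level:
                raise ConfigError(f"effect_size_by_level missing group {g!r}")


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *key])


def _true_pal_draw(rng: np.random.Generator, mean: float, sd: float, size: int):
    """Shifted-lognormal true PAL: floor at the count-to-PAL intercept."""
    shift_mean = mean - PAL_INTERCEPT
    if shift_mean <= 0:
        raise ConfigError("true_pal_mean must exceed the PAL intercept 1.354")
    if sd == 0:
        return np.full(size, mean)
    cv2 = (sd / shift_mean) ** 2
    sigma = np.sqrt(np.log1p(cv2))
    mu = np.log(shift_mean) - sigma**2 / 2
    return PAL_INTERCEPT + rng.lognormal(mu, sigma, size=size)


def generate_profiles(config: SimulationConfig) -> pd.DataFrame:
    """Participant profile table with block-randomized group assignment."""
    config.validate()
    n = config.n_participants
    rng = _rng(config, _STAGE_PROFILE)

    # block randomization in blocks of 4 over L0-L3
    groups = []
    for _ in range((n + 3) // 4):
        block = list(GROUPS)
        rng.shuffle(block)
        groups.extend(block)
    groups = np.array(groups[:n])

    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18, 79)
    age = np.floor(age).astype(int)
    height = np.where(
        sex == "male", rng.normal(178.0, 7.0, n), rng.normal(164.5, 6.5, n)
    )
    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n), 17.0, 45.0)
    weight = bmi * (height / 100.0) ** 2
    waist = np.clip(
        2.1 * bmi + np.where(sex == "male", 39.0, 33.0) + rng.normal(0, 5.0, n),
        55,
        150,
    )
    chol = np.clip(rng.normal(5.2, 1.0, n), 2.5, 9.5)
    smoking = rng.choice(
        ["current", "ex", "never"], size=n, p=list(config.smoking_fractions)
    )
    country = rng.choice(COUNTRIES, size=n)
    p = config.fto_risk_allele_freq
    genotype = rng.choice(
        ["AA", "AT", "TT"], size=n, p=[p**2, 2 * p * (1 - p), (1 - p) ** 2]
    )
    enrollment = np.array(
        [config.start_date + dt.timedelta(days=int(d)) for d in rng.integers(0, 365, n)]
    )
    season = np.array(
        [SEASONS[(d.month % 12) // 3] for d in enrollment]
    )
    employment = np.where(
        rng.random(n) < config.employment_inactive_rate,
        "retired_or_unemployed",
        "employed",
    )
    true_pal = _true_pal_draw(rng, config.true_pal_mean, config.true_pal_sd, n)
    positions_m = np.array(["pocket", "belt", "necklace"])
    positions_f = np.array(["pocket", "belt", "necklace", "bra"])
    position = np.where(
        sex == "male",
        positions_m[rng.integers(0, 3, n)],
        positions_f[rng.integers(0, 4, n)],
    )

    return pd.DataFrame(
        {
            "id": [f"P{i:04d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "height": np.round(height, 1),
            "weight": np.round(weight, 1),
            "waist": np.round(waist, 1),
            "total_cholesterol": np.round(chol, 2),
            "smoking": smoking,
            "country": country,
            "group": groups,
            "fto_genotype": genotype,
            "baseline_season": season,
            "enrollment_date": enrollment,
            "employment_status": employment,
            "wearing_position": position,
            "true_pal": true_pal,
        }
    )


def true_pal_at(
    profiles: pd.DataFrame, config: SimulationConfig, timepoint: str
) -> pd.Series:
    """Latent true PAL per participant at a timepoint (group effect applied)."""
    if timepoint == "baseline":
        return profiles["true_pal"].copy()
    idx = 0 if timepoint == "month3" else 1
    effects = profiles["group"].map(
        {g: config.effect_size_by_level[g][idx] for g in GROUPS}
    )
    rng = _rng(config, _STAGE_TRUTH, 0 if timepoint == "month3" else 1)
    noise = rng.normal(0.0, config.response_sd, len(profiles))
    return (profiles["true_pal"] + effects + noise).clip(lower=PAL_INTERCEPT + 0.01)


@dataclass
class SimulatedSeries:
    """Minute counts plus ground truth for one participant-window."""

    series: MinuteSeries
    wear_truth: np.ndarray  # bool per minute, True = worn
    true_daily_pal: np.ndarray  # per-day target PAL including day noise
    true_window_pal: float


def _day_gaps(
    rng: np.random.Generator, config: SimulationConfig
) -> list[tuple[int, int]]:
    """Non-wear gaps (start, length) within one 1440-min day."""
    if config.nonwear_gap_rate == 0:
        return []
    n_gaps = rng.poisson(config.nonwear_gap_rate)
    gaps: list[tuple[int, int]] = []
    for k in range(n_gaps):
        if k == 0:
            length = int(
                np.clip(
                    rng.normal(config.mean_gap_length, 0.2 * config.mean_gap_length),
                    90,
                    900,
                )
            )
            start = 0  # overnight block anchored at midnight
        else:
            length = int(min(90 + rng.exponential(60.0), 600))
            start = int(rng.integers(0, MINUTES_PER_DAY - length))
        gaps.append((start, min(length, MINUTES_PER_DAY - start)))
    return gaps


def _regime_chain(
    rng: np.random.Generator, n: int, f_bout: float, mean_bout: float
) -> np.ndarray:
    """Two-state Markov occupancy (True = activity bout) over n minutes."""
    p_exit = 1.0 / mean_bout
    p_enter = f_bout * p_exit / max(1.0 - f_bout, 1e-9)
    p_enter = min(p_enter, 0.95)
    state = rng.random() < f_bout
    out = np.empty(n, dtype=bool)
    i = 0
    while i < n:
        p = p_exit if state else p_enter
        run = int(rng.geometric(p))
        j = min(i + run, n)
        out[i:j] = state
        state = not state
        i = j
    return out


def simulate_minute_counts(
    profile: Mapping,
    window_start: dt.date,
    n_days: int,
    config: SimulationConfig,
    true_pal: float,
    *,
    rng: np.random.Generator | None = None,
) -> SimulatedSeries:
    """Simulate a participant's minute-count series over an assessment window."""
    config.validate()
    if n_days < 1:
        raise ConfigError("n_days must be >= 1")
    if rng is None:
        rng = _rng(config, _STAGE_COUNTS["baseline"], 0)

    r = config.weekend_activity_ratio
    delta = max(true_pal - PAL_INTERCEPT, 0.005)
    # weekday/weekend targets whose 5/2-weighted weekly mean is true_pal
    delta_weekday = 7.0 * delta / (5.0 + 2.0 * r)
    counts = np.zeros(n_days * MINUTES_PER_DAY)
    wear_truth = np.ones(n_days * MINUTES_PER_DAY, dtype=bool)
    true_daily_pal = np.empty(n_days)

    for d in range(n_days):
        date = window_start + dt.timedelta(days=d)
        weekend = date.isoweekday() >= 6
        day_delta = delta_weekday * (r if weekend else 1.0)
        day_mult = rng.lognormal(
            -config.day_level_sigma**2 / 2, config.day_level_sigma
        )
        day_pal = PAL_INTERCEPT + day_delta * day_mult
        true_daily_pal[d] = day_pal
        target_counts = (day_pal - PAL_INTERCEPT) / PAL_SLOPE_PER_COUNT

        wear = np.ones(MINUTES_PER_DAY, dtype=bool)
        for start, length in _day_gaps(rng, config):
            wear[start : start + length] = False
        w = int(wear.sum())
        day = np.zeros(MINUTES_PER_DAY)
        if w > 0:
            per_min = target_counts / w
            f_bout = (per_min - config.background_mean_counts) / (
                config.bout_mean_counts - config.background_mean_counts
            )
            f_bout = float(np.clip(f_bout, 0.002, 0.7))
            bout = _regime_chain(rng, w, f_bout, config.mean_bout_minutes)
            m = int(bout.sum())
            # condition the background mean on the realized bout occupancy so
            # the day's expected count total hits the target exactly
            bout_mean = config.bout_mean_counts
            if m > 0 and bout_mean * m > 0.95 * target_counts:
                bout_mean = 0.95 * target_counts / m
            bg_mean = (
                (target_counts - m * bout_mean) / (w - m) if w > m else bout_mean
            )
            bg_mean = max(bg_mean, 30.0)
            vals = np.where(
                bout,
                rng.lognormal(
                    np.log(bout_mean) - config.bout_sigma**2 / 2,
                    config.bout_sigma,
                    w,
                ),
                rng.lognormal(
                    np.log(bg_mean) - config.background_sigma**2 / 2,
                    config.background_sigma,
                    w,
                ),
            )
            day[wear] = np.round(vals)
        sl = slice(d * MINUTES_PER_DAY, (d + 1) * MINUTES_PER_DAY)
        counts[sl] = day
        wear_truth[sl] = wear

    index = pd.date_range(
        pd.Timestamp(window_start), periods=n_days * MINUTES_PER_DAY, freq="min"
    )
    frame = pd.DataFrame(
        {"counts": counts, "position": profile.get("wearing_position", "belt")},
        index=index,
    )
    series = MinuteSeries(participant_id=str(profile.get("id", "sim")), frame=frame)
    return SimulatedSeries(
        series=series,
        wear_truth=wear_truth,
        true_daily_pal=true_daily_pal,
        true_window_pal=true_pal,
    )


# --- Baecke generation -----------------------------------------------------

#: Piecewise-linear calibration from true PAL to the latent 1-5 item level.
#: Knots chosen so a cohort at PAL 1.73 lands near the trial's mean total
#: activity index of ~7.8; documented test scaffold, not a published model.
_BAECKE_PAL_KNOTS = (1.354, 1.73, 2.40)
_BAECKE_LEVEL_KNOTS = (1.0, 2.6, 5.0)

#: Concrete sport entries realizing each sport-score ordinal.
_SPORT_BY_LEVEL: dict[int, tuple[SportEntry, ...]] = {
    1: (),
    2: (SportEntry("low", 2, 2),),
    3: (SportEntry("medium", 4, 5),),
    4: (SportEntry("high", 5, 5), SportEntry("low", 2, 5)),
    5: (SportEntry("high", 5, 5), SportEntry("medium", 5, 5)),
}


def _latent_item_level(true_pal: float) -> float:
    return float(
        np.interp(true_pal, _BAECKE_PAL_KNOTS, _BAECKE_LEVEL_KNOTS)
    )


def simulate_baecke(
    profile: Mapping,
    true_pal: float,
    config: SimulationConfig,
    *,
    rng: np.random.Generator | None = None,
) -> BaeckeResponse:
    """Generate a Baecke questionnaire response consistent with a true PAL."""
    if not 1.0 < true_pal < 2.5:
        raise ConfigError("true_pal must lie in (1, 2.5) for Baecke generation")
    if rng is None:
        rng = _rng(config, _STAGE_BAECKE["baseline"], 0)
    level = _latent_item_level(true_pal) + config.reporting_bias / 3.0

    def draw_item(reversed_: bool) -> int:
        v = int(np.clip(round(level + rng.normal(0, config.baecke_item_sigma)), 1, 5))
        return 6 - v if reversed_ else v

    items = {}
    for group_items in (WORK_ITEMS, SPORT_ITEMS, LEISURE_ITEMS):
        for name, reversed_ in group_items.items():
            items[name] = draw_item(reversed_)

    occ_latent = level + rng.normal(0, config.baecke_item_sigma)
    occupation = "low" if occ_latent < 2.34 else ("middle" if occ_latent < 3.67 else "high")
    sport_level = int(np.clip(round(level + rng.normal(0, config.baecke_item_sigma)), 1, 5))

    return BaeckeResponse(
        employment_status=str(profile.get("employment_status", "employed")),
        occupation_activity=occupation,
        items=items,
        sports=_SPORT_BY_LEVEL[sport_level],
    )


# --- cohort-level convenience ----------------------------------------------

def participant_window(
    profiles: pd.DataFrame,
    config: SimulationConfig,
    participant_index: int,
    timepoint: str,
) -> SimulatedSeries:
    """Deterministic minute-count series for one participant at one timepoint."""
    row = profiles.iloc[participant_index]
    true_pal = float(
        true_pal_at(profiles, config, timepoint).iloc[participant_index]
    )
    feedback_date = row["enrollment_date"] + dt.timedelta(
        days=TIMEPOINT_OFFSETS_DAYS[timepoint]
    )
    window_start = feedback_date - dt.timedelta(days=14)
    rng = _rng(config, _STAGE_COUNTS[timepoint], participant_index)
    return simulate_minute_counts(
        row, window_start, 14, config, true_pal, rng=rng
    )


def participant_baecke(
    profiles: pd.DataFrame,
    config: SimulationConfig,
    participant_index: int,
    timepoint: str,
) -> BaeckeResponse:
    row = profiles.iloc[participant_index]
    true_pal = float(
        true_pal_at(profiles, config, timepoint).iloc[participant_index]
    )
    rng = _rng(config, _STAGE_BAECKE[timepoint], participant_index)
    return simulate_baecke(row, min(true_pal, 2.49), config, rng=rng)


def weight_changes(
    profiles: pd.DataFrame, config: SimulationConfig, timepoint: str
) -> pd.Series:
    """Simulated body-weight change (kg) from baseline to the timepoint."""
    if timepoint == "baseline":
        return pd.Series(0.0, index=profiles.index)
    rng = _rng(config, _STAGE_TRUTH, 5 if timepoint == "month3" else 6)
    sd = 1.0 if timepoint == "month3" else 1.5
    return pd.Series(rng.normal(0.0, sd, len(profiles)), index=profiles.index)
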