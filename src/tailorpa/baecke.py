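"""Scoring of the Baecke habitual physical activity questionnaire.

The questionnaire has three sections — physical activity at work, sport,
and leisure time excluding sport — each scored to an index from 1 to 5;
the total activity index is their sum (3 to 15). Items are stored in the
questionnaire's raw ordinal orientation (1 = never/lowest frequency,
5 = always/highest); two items are inversely related to activity (sitting
at work, watching television) and enter their index reversed as (6 - x).

Work index
    mean of the occupation activity score (low=1, middle=3, high=5), the
    reversed sitting item, and six further 1-5 items.
Sport index
    mean of the sport-score ordinal and three further 1-5 items. The sport
    score sums, over up to two named sports, intensity x hours/week x
    months/year factors and is mapped to an ordinal: 0 -> 1, (0,4) -> 2,
    [4,8) -> 3, [8,12) -> 4, >= 12 -> 5.
Leisure index
    mean of the reversed television item and three further 1-5 items.

For retired or unemployed respondents the work index — and therefore the
total index — cannot be calculated and is reported missing.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import math

#: Factors entering the sport score.
SPORT_INTENSITY_FACTORS = {"low": 0.76, "medium": 1.26, "high": 1.76}
#: Weekly-hours ordinal (1: <1 h ... 5: >4 h) -> representative hours.
SPORT_HOURS_FACTORS = {1: 0.5, 2: 1.5, 3: 2.5, 4: 3.5, 5: 4.5}
#: Months-per-year ordinal (1: <1 month ... 5: >9 months) -> proportion of year.
SPORT_MONTHS_FACTORS = {1: 0.04, 2: 0.17, 3: 0.42, 4: 0.67, 5: 0.92}

OCCUPATION_SCORES = {"low": 1.0, "middle": 3.0, "high": 5.0}

#: Raw questionnaire items entering each index; True marks items reversed
#: in the formula (higher raw response = less activity).
WORK_ITEMS = {
    "work_sit": True,
    "work_stand": False,
    "work_walk": False,
    "work_lift": False,
    "work_tired": False,
    "work_sweat": False,
    "work_heavier_than_peers": False,
}
SPORT_ITEMS = {
    "leisure_activity_vs_peers": False,
    "leisure_sweat": False,
    "leisure_sport_frequency": False,
}
LEISURE_ITEMS = {
    "leisure_tv": True,
    "leisure_walk": False,
    "leisure_cycle": False,
    "commute_minutes": False,
}


class BaeckeValidationError(ValueError):
    """An item response outside its ordinal range."""


@dataclass(frozen=True)
class SportEntry:
    """One named sport: intensity class, weekly hours and yearly months ordinals."""

    intensity: str
    hours_per_week: int
    months_per_year: int

    def score(self) -> float:
        if self.intensity not in SPORT_INTENSITY_FACTORS:
            raise BaeckeValidationError(
                f"sport intensity must be one of {sorted(SPORT_INTENSITY_FACTORS)}"
            )
        if self.hours_per_week not in SPORT_HOURS_FACTORS:
            raise BaeckeValidationError("sport hours_per_week must be an ordinal 1-5")
        if self.months_per_year not in SPORT_MONTHS_FACTORS:
            raise BaeckeValidationError("sport months_per_year must be an ordinal 1-5")
        return (
            SPORT_INTENSITY_FACTORS[self.intensity]
            * SPORT_HOURS_FACTORS[self.hours_per_week]
            * SPORT_MONTHS_FACTORS[self.months_per_year]
        )


@dataclass
class BaeckeResponse:
    """Raw questionnaire responses for one participant at one timepoint."""

    employment_status: str  # employed | retired_or_unemployed
    occupation_activity: str = "low"  # low | middle | high
    items: dict[str, int] = field(default_factory=dict)
    sports: tuple[SportEntry, ...] = ()

    def validate(self) -> None:
        if self.employment_status not in ("employed", "retired_or_unemployed"):
            raise BaeckeValidationError(
                "employment_status must be 'employed' or 'retired_or_unemployed'"
            )
        if self.occupation_activity not in OCCUPATION_SCORES:
            raise BaeckeValidationError(
                f"occupation_activity must be one of {sorted(OCCUPATION_SCORES)}"
            )
        needed = set(SPORT_ITEMS) | set(LEISURE_ITEMS)
        if self.employment_status == "employed":
            needed |= set(WORK_ITEMS)
        for name in sorted(needed):
            if name not in self.items:
                raise BaeckeValidationError(f"missing item {name!r}")
            v = self.items[name]
            if not isinstance(v, (int,)) or not 1 <= v <= 5:
                raise BaeckeValidationError(
                    f"item {name!r} response {v!r} outside ordinal range 1-5"
                )
        if len(self.sports) > 2:
            raise BaeckeValidationError("at most two sports can be reported")
        for s in self.sports:
            s.score()  # validates fields

    # Convenience constructors used in worked examples and tests.
    @classmethod
    def least_active(cls) -> "BaeckeResponse":
        """Every item at its least-active option (employed respondent)."""
        items = {}
        for group in (WORK_ITEMS, SPORT_ITEMS, LEISURE_ITEMS):
            for name, reversed_ in group.items():
                items[name] = 5 if reversed_ else 1
        return cls(
            employment_status="employed",
            occupation_activity="low",
            items=items,
            sports=(),
        )

    @classmethod
    def most_active(cls) -> "BaeckeResponse":
        """Every item at its most-active option (employed respondent)."""
        items = {}
        for group in (WORK_ITEMS, SPORT_ITEMS, LEISURE_ITEMS):
            for name, reversed_ in group.items():
                items[name] = 1 if reversed_ else 5
        sports = (
            SportEntry("high", 5, 5),
            SportEntry("medium", 5, 5),
        )
        return cls(
            employment_status="employed",
            occupation_activity="high",
            items=items,
            sports=sports,
        )


@dataclass(frozen=True)
class BaeckeIndices:
    work_index: Optional[float]
    sport_index: float
    leisure_index: float

    @property
    def total_index(self) -> Optional[float]:
        if self.work_index is None:
            return None
        return self.work_index + self.sport_index + self.leisure_index


def sport_score_ordinal(score: float) -> float:
    """Map the continuous sport score onto its 1-5 ordinal."""
    if score < 0 or math.isnan(score):
        raise BaeckeValidationError("sport score must be >= 0")
    if score == 0:
        return 1.0
    if score < 4:
        return 2.0
    if score < 8:
        return 3.0
    if score < 12:
        return 4.0
    return 5.0


def _item_value(response: BaeckeResponse, name: str, reversed_: bool) -> float:
    v = response.items[name]
    return float(6 - v) if reversed_ else float(v)


def score_baecke(response: BaeckeResponse) -> BaeckeIndices:
    """Score a validated questionnaire response into the three indices."""
    response.validate()

    if response.employment_status == "employed":
        work_terms = [OCCUPATION_SCORES[response.occupation_activity]]
        work_terms += [_item_value(response, n, r) for n, r in WORK_ITEMS.items()]
        work_index: Optional[float] = sum(work_terms) / len(work_terms)
    else:
        work_index = None

    sport_score = sum(s.score() for s in response.sports)
    sport_terms = [sport_score_ordinal(sport_score)]
    sport_terms += [_item_value(response, n, r) for n, r in SPORT_ITEMS.items()]
    sport_index = sum(sport_terms) / len(sport_terms)

    leisure_terms = [_item_value(response, n, r) for n, r in LEISURE_ITEMS.items()]
    leisure_index = sum(leisure_terms) / len(leisure_terms)

    return BaeckeIndices(
        work_index=work_index, sport_index=sport_index, leisure_index=leisure_index
    )
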