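"""Rule-based derivation of tailored physical-activity feedback.

Adequacy of current PA is classified from the objective PAL when a
sufficient accelerometer assessment exists, otherwise from the Baecke total
activity index:

=============  ==================  =======================
adequacy       objective PAL       Baecke total index
=============  ==================  =======================
adequate       >= 1.8              >= 8.5
low            >= 1.5 and < 1.8    >= 5.5 and < 8.5
very_low       < 1.5               < 5.5
=============  ==================  =======================

The adequacy class maps onto the report's three-colour line (green/amber/
red). Personalized groups (L1-L3) additionally receive an advice category
from adequacy and BMI — maintain when adequate, increase when low,
increase strongly when very low or when low with obesity (BMI >= 30) —
and message components that grow with the personalization level: PA level
(L1-L3, with BMI flagged when >= 25), waist circumference and total
cholesterol above their cut-offs (L2-L3), and FTO risk-allele status for
AA/AT carriers (L3 only; non-carriers get the L2 decision). Controls (L0)
receive only the generic 150-minutes-per-week guideline; their
``advised_to_increase`` flag is the counterfactual decision they would have
received in a personalized group, which also defines the matched-control
subset of the targeted trial analysis.

The advice decision table and the phenotype cut-offs were internal study
algorithms; the defaults here are documented surrogates and both are
configurable.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .assessment import AssessmentResult
from .baecke import BaeckeIndices

PAL_ADEQUATE = 1.8
PAL_LOW = 1.5
BAECKE_ADEQUATE = 8.5
BAECKE_LOW = 5.5

#: Default phenotype cut-offs (configurable surrogates).
WAIST_CUTOFF_CM = {"male": 102.0, "female": 88.0}
CHOLESTEROL_CUTOFF_MMOL_L = 5.0
BMI_OVERWEIGHT = 25.0
BMI_OBESE = 30.0

FTO_CARRIER_GENOTYPES = ("AA", "AT")

GROUPS = ("L0", "L1", "L2", "L3")


class Adequacy(str, enum.Enum):
    ADEQUATE = "adequate"
    LOW = "low"
    VERY_LOW = "very_low"


class AdviceCategory(str, enum.Enum):
    MAINTAIN = "maintain"
    INCREASE = "increase"
    INCREASE_STRONGLY = "increase_strongly"


COLOR_BY_ADEQUACY = {
    Adequacy.ADEQUATE: "green",
    Adequacy.LOW: "amber",
    Adequacy.VERY_LOW: "red",
}


class FeedbackError(ValueError):
    """Missing or contradictory inputs to feedback derivation."""


def classify_adequacy(
    pal: float | None = None, baecke_total: float | None = None
) -> Adequacy:
    """Adequacy class from exactly one of objective PAL / Baecke total index."""
    if (pal is None) == (baecke_total is None):
        raise FeedbackError("supply exactly one of pal or baecke_total")
    if pal is not None:
        if pal >= PAL_ADEQUATE:
            return Adequacy.ADEQUATE
        if pal >= PAL_LOW:
            return Adequacy.LOW
        return Adequacy.VERY_LOW
    if baecke_total >= BAECKE_ADEQUATE:
        return Adequacy.ADEQUATE
    if baecke_total >= BAECKE_LOW:
        return Adequacy.LOW
    return Adequacy.VERY_LOW


def advice_category(adequacy: Adequacy, bmi: float) -> AdviceCategory:
    """Advice category from the (adequacy x BMI) decision table.

    BMI escalates wording only when PA is not adequate: low PA with obesity
    is advised to increase strongly.
    """
    if adequacy is Adequacy.ADEQUATE:
        return AdviceCategory.MAINTAIN
    if adequacy is Adequacy.VERY_LOW:
        return AdviceCategory.INCREASE_STRONGLY
    if bmi >= BMI_OBESE:
        return AdviceCategory.INCREASE_STRONGLY
    return AdviceCategory.INCREASE


@dataclass
class AdviceDecision:
    participant_id: str
    timepoint: str
    group: str
    source: str  # accelerometer | baecke_fallback
    adequacy: Optional[Adequacy]
    color: Optional[str]
    advice_category: Optional[AdviceCategory]
    message_components: tuple[str, ...]
    advised_to_increase: bool


def _bmi(profile: Mapping) -> float:
    height_m = float(profile["height"]) / 100.0
    return float(profile["weight"]) / (height_m * height_m)


def _pa_input(
    assessment: AssessmentResult | BaeckeIndices | None,
    baecke: BaeckeIndices | None,
) -> tuple[str, float]:
    """Resolve the PA measurement: accelerometer when sufficient, else Baecke."""
    if isinstance(assessment, BaeckeIndices) and baecke is None:
        baecke = assessment
        assessment = None
    if assessment is not None and assessment.sufficient:
        return "accelerometer", float(assessment.pal)
    if baecke is None:
        raise FeedbackError(
            "no sufficient accelerometer assessment and no Baecke fallback available"
        )
    if baecke.total_index is None:
        raise FeedbackError(
            "Baecke fallback requires a total index (work index missing "
            "for retired/unemployed respondents)"
        )
    return "baecke_fallback", float(baecke.total_index)


def derive_advice(
    profile: Mapping,
    assessment: AssessmentResult | BaeckeIndices | None,
    baecke: BaeckeIndices | None = None,
    *,
    timepoint: str = "baseline",
    as_level: str | None = None,
) -> AdviceDecision:
    """Advice decision for one participant at one timepoint.

    ``profile`` is a mapping with the participant's id, group, sex, height,
    weight and — for L2/L3 — waist and total cholesterol, plus the FTO
    genotype for L3. ``as_level`` overrides the group's level, which is how
    the counterfactual decision for matched controls is computed.
    """
    group = str(profile["group"])
    if group not in GROUPS:
        raise FeedbackError(f"unknown randomization group {group!r}")
    level = as_level if as_level is not None else group
    if level not in GROUPS:
        raise FeedbackError(f"unknown personalization level {level!r}")
    pid = str(profile.get("id", profile.get("participant_id", "")))

    if level == "L0":
        # Controls get the generic guideline; the advised flag is the
        # counterfactual L1 decision used for matched-control selection.
        counterfactual = derive_advice(
            profile, assessment, baecke, timepoint=timepoint, as_level="L1"
        )
        return AdviceDecision(
            participant_id=pid,
            timepoint=timepoint,
            group=group,
            source=counterfactual.source,
            adequacy=None,
            color=None,
            advice_category=None,
            message_components=("generic_guideline",),
            advised_to_increase=counterfactual.advised_to_increase,
        )

    missing = [k for k in ("height", "weight") if profile.get(k) in (None, "")]
    if level in ("L2", "L3"):
        missing += [
            k for k in ("waist", "total_cholesterol") if profile.get(k) in (None, "")
        ]
    if level == "L3" and profile.get("fto_genotype") in (None, ""):
        missing.append("fto_genotype")
    if missing:
        raise FeedbackError(f"missing required fields for level {level}: {missing}")

    source, value = _pa_input(assessment, baecke)
    adequacy = (
        classify_adequacy(pal=value)
        if source == "accelerometer"
        else classify_adequacy(baecke_total=value)
    )
    bmi = _bmi(profile)
    category = advice_category(adequacy, bmi)

    components = ["pa_level"]
    if bmi >= BMI_OVERWEIGHT:
        components.append("bmi")
    if level in ("L2", "L3"):
        sex = str(profile["sex"])
        if float(profile["waist"]) >= WAIST_CUTOFF_CM[sex]:
            components.append("waist")
        if float(profile["total_cholesterol"]) >= CHOLESTEROL_CUTOFF_MMOL_L:
            components.append("cholesterol")
    if level == "L3" and profile["fto_genotype"] in FTO_CARRIER_GENOTYPES:
        components.append("fto_risk")

    return AdviceDecision(
        participant_id=pid,
        timepoint=timepoint,
        group=group,
        source=source,
        adequacy=adequacy,
        color=COLOR_BY_ADEQUACY[adequacy],
        advice_category=category,
        message_components=tuple(components),
        advised_to_increase=category
        in (AdviceCategory.INCREASE, AdviceCategory.INCREASE_STRONGLY),
    )


def select_matched_controls(
    l0_profiles: Iterable[Mapping],
    assessments: Mapping[str, AssessmentResult],
    baecke: Mapping[str, BaeckeIndices] | None = None,
) -> list[str]:
    """Controls who would have been advised to increase PA if personalized.

    Applies the same derivation algorithm counterfactually at level L1 to
    each L0 participant's baseline assessment; returns the selected ids.
    """
    baecke = baecke or {}
    selected = []
    for profile in l0_profiles:
        pid = str(profile.get("id", profile.get("participant_id", "")))
        decision = derive_advice(
            profile,
            assessments.get(pid),
            baecke.get(pid),
            as_level="L1",
        )
        if decision.advised_to_increase:
            selected.append(pid)
    return selected
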