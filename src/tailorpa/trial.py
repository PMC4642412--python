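"""Orthogonal-contrast analysis of intervention effects.

Three orthogonal contrasts over the four arms answer the trial's questions:

* C1 — control vs personalization: L0 against the mean of L1-L3;
* C2 — added phenotype/genotype information: L1 against the mean of L2-L3;
* C3 — added genotype information: L2 against L3.

The contrast columns are Helmert-type vectors scaled so each regression
coefficient estimates the corresponding difference of group means. Models
regress the outcome at the follow-up timepoint on the contrast columns
plus the covariates used by the study: the baseline value of the outcome,
sex, age, country, smoking, baseline BMI, baseline season, and change in
body weight; accelerometer-derived outcomes additionally adjust for change
in accelerometer wear time. Analysis is complete-case within each outcome.

The robust fit uses iteratively reweighted least squares with the
redescending Tukey biweight psi-function and MAD scale; an ordinary
least squares fallback is provided and, on Gaussian data, must agree with
the robust fit within confidence-interval overlap. Confidence intervals
and p-values come from the fit's asymptotic covariance at the 0.05 level.

Two analysis cohorts mirror the study: *generic* (all analyzable
participants) and *targeted* (participants advised to increase PA plus the
counterfactually matched L0 controls).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as smapi
from scipy import stats

GROUPS = ("L0", "L1", "L2", "L3")

#: Contrast vectors scaled so the coefficient is a difference of group means.
CONTRAST_VECTORS: dict[str, dict[str, float]] = {
    "C1": {"L0": -0.75, "L1": 0.25, "L2": 0.25, "L3": 0.25},
    "C2": {"L0": 0.0, "L1": -2.0 / 3.0, "L2": 1.0 / 3.0, "L3": 1.0 / 3.0},
    "C3": {"L0": 0.0, "L1": 0.0, "L2": -0.5, "L3": 0.5},
}

#: Accelerometer-derived outcomes get the wear-time-change covariate.
ACCELEROMETER_OUTCOMES = frozenset(
    {
        "daily_pal",
        "daily_aee",
        "sedentary",
        "lpa",
        "mpa",
        "vpa",
        "moderate_equivalent",
        "moderate_equivalent_bouted",
        "sedentary_weekly",
        "lpa_weekly",
        "mpa_weekly",
        "vpa_weekly",
        "moderate_equivalent_weekly",
        "moderate_equivalent_bouted_weekly",
    }
)

CATEGORICAL_COVARIATES = ("country", "smoking", "baseline_season")


class DesignError(ValueError):
    """Ill-posed model frame (e.g. aliased columns)."""


@dataclass
class EffectEstimate:
    outcome: str
    cohort: str
    timepoint: str
    contrast: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_per_group: dict[str, int]
    method: str = "robust"


def contrast_columns(groups: pd.Series) -> pd.DataFrame:
    """Contrast-coded design columns for a group assignment vector."""
    out = {}
    for name, vec in CONTRAST_VECTORS.items():
        col = groups.map(vec)
        if col.isna().any():
            bad = sorted(set(groups[col.isna()]))
            raise DesignError(f"unknown group label(s): {bad}")
        out[name] = col.astype(float)
    return pd.DataFrame(out, index=groups.index)


def build_design(
    outcome: str,
    profiles: pd.DataFrame,
    assessments: pd.DataFrame,
    timepoint: str,
    *,
    baseline_timepoint: str = "baseline",
    weight_change: pd.Series | None = None,
) -> pd.DataFrame:
    """Model frame for one outcome at one follow-up timepoint.

    ``assessments`` holds per-participant-per-timepoint outcome columns
    (accelerometer or questionnaire); participants lacking the outcome at
    either timepoint, or any covariate, are dropped (complete-case).
    ``weight_change`` is indexed by participant id.
    """
    base = assessments[assessments["timepoint"] == baseline_timepoint]
    follow = assessments[assessments["timepoint"] == timepoint]
    merged = follow.merge(
        base[["participant_id", outcome]],
        on="participant_id",
        suffixes=("", "_baseline"),
    ).merge(
        profiles.rename(columns={"id": "participant_id"}),
        on="participant_id",
    )
    frame = pd.DataFrame(
        {
            "participant_id": merged["participant_id"],
            "group": merged["group"],
            "response": merged[outcome],
            "baseline_outcome": merged[f"{outcome}_baseline"],
            "age": merged["age"].astype(float),
            "sex_male": (merged["sex"] == "male").astype(float),
            "baseline_bmi": merged["weight"].astype(float)
            / (merged["height"].astype(float) / 100.0) ** 2,
        }
    )
    for cov in CATEGORICAL_COVARIATES:
        dummies = pd.get_dummies(merged[cov], prefix=cov, drop_first=True, dtype=float)
        frame = pd.concat([frame, dummies], axis=1)
    if weight_change is not None:
        frame["weight_change"] = merged["participant_id"].map(weight_change).to_numpy()
    if outcome in ACCELEROMETER_OUTCOMES:
        wear = assessments.pivot_table(
            index="participant_id", columns="timepoint", values="mean_wear_time"
        )
        change = wear[timepoint] - wear[baseline_timepoint]
        frame["wear_time_change"] = merged["participant_id"].map(change).to_numpy()
    frame = pd.concat([frame, contrast_columns(frame["group"])], axis=1)
    frame = frame.dropna().reset_index(drop=True)
    return frame


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank == mat.shape[1]:
        return
    # identify aliased columns incrementally
    aliased = []
    kept: list[int] = []
    for j in range(mat.shape[1]):
        sub = mat[:, kept + [j]]
        if np.linalg.matrix_rank(sub) == len(kept) + 1:
            kept.append(j)
        else:
            aliased.append(X.columns[j])
    raise DesignError(f"rank-deficient design; aliased columns: {aliased}")


def fit_contrast_model(
    frame: pd.DataFrame,
    *,
    outcome: str = "",
    cohort: str = "generic",
    timepoint: str = "",
    method: str = "robust",
    min_per_group: int = 10,
) -> list[EffectEstimate]:
    """Fit the contrast model on a built frame; one estimate per contrast.

    ``method`` is ``"robust"`` (IRLS, Tukey biweight) or ``"ols"``.
    """
    n_per_group = frame["group"].value_counts().to_dict()
    if any(n_per_group.get(g, 0) < min_per_group for g in GROUPS if g in set(frame["group"])):
        raise DesignError(
            f"need >= {min_per_group} participants per analyzed group, got {n_per_group}"
        )
    drop = {"participant_id", "group", "response"}
    xcols = [c for c in frame.columns if c not in drop]
    X = frame[xcols].astype(float)
    X.insert(0, "const", 1.0)
    _check_rank(X)
    y = frame["response"].astype(float).to_numpy()

    if method == "robust":
        fit = smapi.RLM(y, X, M=smapi.robust.norms.TukeyBiweight()).fit()
    elif method == "ols":
        fit = smapi.OLS(y, X).fit()
    else:
        raise ValueError("method must be 'robust' or 'ols'")

    z = stats.norm.ppf(0.975)
    out = []
    for name in CONTRAST_VECTORS:
        if name not in X.columns:
            continue
        est = float(fit.params[name])
        se = float(fit.bse[name])
        pz = est / se if se > 0 else np.inf
        out.append(
            EffectEstimate(
                outcome=outcome,
                cohort=cohort,
                timepoint=timepoint,
                contrast=name,
                estimate=est,
                ci_low=est - z * se,
                ci_high=est + z * se,
                p_value=float(2 * stats.norm.sf(abs(pz))),
                n_per_group={g: int(n_per_group.get(g, 0)) for g in GROUPS},
                method=method,
            )
        )
    return out


def run_generic_and_targeted(
    outcomes: Sequence[str],
    profiles: pd.DataFrame,
    assessments: pd.DataFrame,
    advised_to_increase: Mapping[str, bool],
    *,
    timepoints: Iterable[str] = ("month3", "month6"),
    weight_change_by_timepoint: Mapping[str, pd.Series] | None = None,
    method: str = "robust",
) -> pd.DataFrame:
    """Effect-estimate table over outcomes x timepoints x cohorts.

    ``advised_to_increase`` maps participant id to the baseline advice flag
    (counterfactual for L0); the targeted cohort is the advised subset.
    """
    advised_ids = {pid for pid, flag in advised_to_increase.items() if flag}
    targeted_profiles = profiles[
        profiles["id"].astype(str).isin(advised_ids)
    ]
    if targeted_profiles.empty:
        raise DesignError("targeted subset is empty: nobody was advised to increase PA")
    rows = []
    for tp in timepoints:
        wchange = (
            weight_change_by_timepoint.get(tp)
            if weight_change_by_timepoint
            else None
        )
        for cohort, prof in (("generic", profiles), ("targeted", targeted_profiles)):
            for outcome in outcomes:
                frame = build_design(
                    outcome, prof, assessments, tp, weight_change=wchange
                )
                for est in fit_contrast_model(
                    frame, outcome=outcome, cohort=cohort, timepoint=tp, method=method
                ):
                    rows.append(est.__dict__)
    return pd.DataFrame(rows)
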