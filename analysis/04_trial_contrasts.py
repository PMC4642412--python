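#!/usr/bin/env python
"""Estimate intervention effects with the three orthogonal contrasts.

Fits the covariate-adjusted robust contrast models (C1: control vs
personalized; C2: basic vs phenotype/genotype personalization; C3:
phenotype vs genotype) for objective PAL and the Baecke total index, in
both the generic (whole-cohort) and targeted (advised-to-increase plus
matched controls) cohorts, at months 3 and 6.
"""
import pathlib

import pandas as pd

from tailorpa.simulate import SimulationConfig, weight_changes
from tailorpa.trial import run_generic_and_targeted

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
N_PARTICIPANTS = 120
SEED = 7


def main() -> None:
    cfg = SimulationConfig(n_participants=N_PARTICIPANTS, seed=SEED)
    profiles = pd.read_csv(OUT / "profiles.csv")
    assessments = pd.read_csv(OUT / "assessments.csv")
    advice = pd.read_csv(OUT / "advice_baseline.csv")

    advised = dict(
        zip(advice["participant_id"].astype(str), advice["advised_to_increase"])
    )
    wchange = {}
    for tp in ("month3", "month6"):
        s = weight_changes(profiles, cfg, tp)
        s.index = profiles["id"].astype(str)
        wchange[tp] = s

    table = run_generic_and_targeted(
        ["daily_pal"],
        profiles,
        assessments,
        advised,
        weight_change_by_timepoint=wchange,
        method="robust",
    )
    table.to_csv(OUT / "contrast_estimates.csv", index=False)

    print("robust contrast estimates for objective PAL "
          "(positive C1 = personalized > control):")
    for _, row in table.iterrows():
        print(f"  {row['timepoint']:7s} {row['cohort']:8s} {row['contrast']}: "
              f"{row['estimate']:+.4f} "
              f"[{row['ci_low']:+.4f}, {row['ci_high']:+.4f}]  p={row['p_value']:.3f}")
    print("note: the generator injects the same small PAL change in every arm "
          "by default, so all contrasts should cover zero.")


if __name__ == "__main__":
    main()
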