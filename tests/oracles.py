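"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive window enumeration,
literal rule application or direct arithmetic, independent of the package's
run-length-scan implementations.
"""
from __future__ import annotations

import numpy as np
import pandas as pd


def nonwear_oracle(
    pal,
    threshold: float = 1.3889,
    min_period: int = 90,
    max_spike: int = 2,
    flank: int = 30,
) -> np.ndarray:
    """Non-wear mask by enumerating candidate windows and applying the rule.

    A window [a, b] (both endpoints sub-threshold) is non-wear when it is at
    least ``min_period`` minutes long and every above-threshold run inside
    it has length <= ``max_spike`` and is immediately preceded or followed
    by ``flank`` consecutive sub-threshold minutes. The non-wear set is the
    union of all such windows. Returns True for non-wear minutes.
    """
    pal = np.asarray(pal, dtype=float)
    low = [not (v >= threshold) for v in pal]  # NaN -> sub-threshold
    n = len(low)
    # literal admissibility of every above-threshold run
    bad_spike_start = {}
    i = 0
    while i < n:
        if low[i]:
            i += 1
            continue
        j = i
        while j < n and not low[j]:
            j += 1
        length = j - i
        up_ok = i >= flank and all(low[i - flank : i])
        down_ok = j + flank <= n and all(low[j : j + flank])
        ok = length <= max_spike and (up_ok or down_ok)
        if not ok:
            bad_spike_start[i] = j  # window may not cross this run
        i = j
    nonwear = np.zeros(n, dtype=bool)
    for a in range(n):
        if not low[a]:
            continue
        # furthest b reachable from a without crossing an inadmissible spike
        last_low = a
        j = a
        while j < n:
            if not low[j]:
                if j in bad_spike_start:
                    break
                # admissible spike: skip over it
                while j < n and not low[j]:
                    j += 1
                continue
            last_low = j
            j += 1
        b = last_low
        if b - a + 1 >= min_period:
            nonwear[a : b + 1] = True
    return nonwear


def bout_union_oracle_bits(x: int, length: int, min_bout: int = 10) -> int:
    """Union of valid modified-bout windows over a bitmask sequence.

    Bit i of ``x`` is 1 when minute i is at-or-above moderate. A window
    [s, e] is valid when bits s and e are set, it spans >= ``min_bout``
    minutes, and no 3 consecutive zero bits lie inside it (interruptions
    are at most 2 minutes). Returns the bitmask union of valid windows.
    """
    notx = ~x
    zero3 = notx & (notx >> 1) & (notx >> 2)
    union = 0
    for s in range(length):
        if not (x >> s) & 1:
            continue
        for e in range(s + min_bout - 1, length):
            if not (x >> e) & 1:
                continue
            width = e - s - 1  # zero3 positions s .. e-2
            if width > 0 and (zero3 >> s) & ((1 << width) - 1):
                continue
            union |= ((1 << (e - s + 1)) - 1) << s
    return union


def bouted_minutes_oracle(classes, min_bout: int = 10) -> float:
    """Moderate-equivalent bouted minutes via window enumeration.

    Accepts a sequence of intensity codes (0-3); credits MPA minutes once
    and VPA minutes twice inside the union of valid windows.
    """
    cls = list(int(c) for c in classes)
    length = len(cls)
    x = 0
    for i, c in enumerate(cls):
        if c >= 2:
            x |= 1 << i
    union = bout_union_oracle_bits(x, length, min_bout=min_bout)
    total = 0.0
    for i, c in enumerate(cls):
        if (union >> i) & 1:
            if c == 3:
                total += 2.0
            elif c == 2:
                total += 1.0
    return total


def nonwear_grammar_sequences(
    low_lengths=(1, 29, 30, 31, 90),
    high_lengths=(1, 2, 3),
    max_runs: int = 5,
    max_total: int = 300,
    low_value: float = 1.30,
    high_value: float = 1.50,
):
    """All two-level PAL sequences of alternating low/high runs.

    Enumerates every alternating run-length pattern with up to ``max_runs``
    runs drawn from the given length menus (both starting phases),
    truncated to sequences of at most ``max_total`` minutes. Covers every
    boundary of the 90-min / 2-min-spike / 30-min-flank rule.
    """
    from itertools import product

    for start_low in (True, False):
        for k in range(1, max_runs + 1):
            menus = [
                low_lengths if (start_low == (i % 2 == 0)) else high_lengths
                for i in range(k)
            ]
            for lens in product(*menus):
                if sum(lens) > max_total:
                    continue
                seq = []
                is_low = start_low
                for ln in lens:
                    seq.extend([low_value if is_low else high_value] * ln)
                    is_low = not is_low
                yield np.array(seq)


def make_null_outcome_frame(
    rng: np.random.Generator,
    n: int = 200,
    effect_l1_to_l3: float = 0.0,
) -> pd.DataFrame:
    """Outcome-level trial data with realistic covariates and no (or a
    uniform) personalized-group effect; ready for the contrast fitter."""
    from tailorpa.simulate import COUNTRIES, SEASONS
    from tailorpa.trial import contrast_columns

    n = (n // 4) * 4
    groups = np.tile(["L0", "L1", "L2", "L3"], n // 4)
    rng.shuffle(groups)
    age = rng.uniform(18, 70, n)
    sex_male = rng.integers(0, 2, n).astype(float)
    bmi = rng.normal(25.5, 4.5, n)
    country = rng.choice(COUNTRIES, n)
    smoking = rng.choice(["current", "ex", "never"], n)
    season = rng.choice(SEASONS, n)
    baseline = rng.normal(1.73, 0.18, n)
    weight_change = rng.normal(0, 1.2, n)
    wear_change = rng.normal(0, 60, n)
    response = (
        0.6 * baseline
        + 0.002 * (age - 40)
        + 0.01 * sex_male
        + rng.normal(0, 0.08, n)
        + np.where(groups != "L0", effect_l1_to_l3, 0.0)
    )
    frame = pd.DataFrame(
        {
            "participant_id": [f"S{i}" for i in range(n)],
            "group": groups,
            "response": response,
            "baseline_outcome": baseline,
            "age": age,
            "sex_male": sex_male,
            "baseline_bmi": bmi,
            "weight_change": weight_change,
            "wear_time_change": wear_change,
        }
    )
    for name, values in (("country", country), ("smoking", smoking), ("baseline_season", season)):
        d = pd.get_dummies(pd.Series(values), prefix=name, drop_first=True, dtype=float)
        frame = pd.concat([frame, d], axis=1)
    return pd.concat([frame, contrast_columns(frame["group"])], axis=1)
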