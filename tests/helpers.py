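"""Independent oracles shared by test modules."""

import numpy as np
import pandas as pd


def greedy_oracle(ps: pd.DataFrame, caliper_sd: float, seed: int):
    """Step-by-step pure-python greedy matcher, independent of the library path.

    Mirrors the protocol (seeded random treated order, nearest unused
    control within a pooled-SD caliper, no replacement) with scalar loops.
    """
    rng = np.random.default_rng(seed)
    treated = ps[ps["arm"] == 1].reset_index(drop=True)
    control = ps[ps["arm"] == 0].reset_index(drop=True)
    caliper = caliper_sd * float(np.std(ps["ps"].to_numpy(), ddof=1))
    order = list(rng.permutation(len(treated)))
    used = set()
    pairs = []
    for ti in order:
        tp = float(treated.loc[ti, "ps"])
        best_d, best_j = None, None
        for j in range(len(control)):
            if j in used:
                continue
            d = abs(float(control.loc[j, "ps"]) - tp)
            if best_d is None or d < best_d:
                best_d, best_j = d, j
        if best_d is None or best_d > caliper:
            continue
        used.add(best_j)
        pairs.append((treated.loc[ti, "patient_id"], control.loc[best_j, "patient_id"], best_d))
    return pairs
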