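"""Reference group-level values from the Betta splendens foraging study.

These are the published summary statistics of the cross-maze experiment the
model emulates: 86 fish, 82 valid cortisol assays (3 failed, 1 outlier),
five ascending-cortisol groups, 21 trials.  The fish-side numbers are
measured data — they cannot be recomputed, only used as fixtures and as the
biological column in fish-versus-simulation comparisons.  The simulation
column is what the pipeline reproduces.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

N_FISH = 86
N_ASSAY_FAILED = 3
N_OUTLIER = 1
N_VALID = 82
N_TRIALS = 21
N_ARMS = 4

GROUP_LABELS = (1, 2, 3, 4, 5)
GROUP_SIZES = (16, 17, 16, 16, 17)

#: Measured basal cortisol range per group, ng/mL (min, max).
CORTISOL_RANGES_NG_ML = (
    (1.68, 10.69),
    (12.78, 28.55),
    (32.18, 87.35),
    (90.50, 117.33),
    (117.44, 135.40),
)

#: Group-mean min-max-normalized cortisol — the ε assigned to each group's
#: digital twin — with the published standard errors.
GROUP_MEAN_EPSILON = (0.0289, 0.1413, 0.4103, 0.8137, 0.9251)
GROUP_MEAN_EPSILON_SE = (5.22e-3, 9.85e-3, 4.32e-2, 1.53e-2, 9.74e-3)

#: Mean average reward after 21 trials, ε-greedy simulation column.
SIM_MEAN_AVG_REWARD = (0.2946, 0.4048, 0.4650, 0.3165, 0.2687)
SIM_SE_AVG_REWARD = (0.1031, 0.0899, 0.0605, 0.0271, 0.0307)

#: Mean average reward after 21 trials, live-fish column.
FISH_MEAN_AVG_REWARD = (0.2976, 0.4034, 0.3690, 0.2054, 0.3165)
FISH_SE_AVG_REWARD = (0.0346, 0.0548, 0.0500, 0.0425, 0.0200)


def reference_group_table(side: str) -> pd.DataFrame:
    """Published group table as a GroupTable-shaped DataFrame.

    ``side`` is ``"fish"`` or ``"sim"``.
    """
    if side == "fish":
        mean, se = FISH_MEAN_AVG_REWARD, FISH_SE_AVG_REWARD
    elif side == "sim":
        mean, se = SIM_MEAN_AVG_REWARD, SIM_SE_AVG_REWARD
    else:
        raise ValueError(f"side must be 'fish' or 'sim', got {side!r}")
    return pd.DataFrame(
        {
            "group": np.array(GROUP_LABELS, dtype=int),
            "n": np.array(GROUP_SIZES, dtype=int),
            "mean_epsilon": GROUP_MEAN_EPSILON,
            "mean_avg_reward": mean,
            "se": se,
        }
    )
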