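"""Systematic vs random exploration of the eight-arm radial maze.

Runs the discrete model with and without cholinergic depression and prints
the distribution of the first rewarded trial.  Without acetylcholine the
agent picks arms at random every trial (geometric law, mean 8); with it,
each unrewarded arm is depressed and excluded, so the reward is always found
within 8 trials (uniform law on 1..8).
"""

import numpy as np

from snplast import protocols
from snplast.analysis import first_reward_trials, theoretical_first_reward_cdf

M = 200

for ach, label in ((False, "-ACh"), (True, "+ACh")):
    res = protocols.run_radial_experiment(
        ach=ach, m=M, n_trials=60, master_seed=7, stop_after_first_reward=True)
    firsts = first_reward_trials(res.table()).dropna()
    print(f"{label}: mean first rewarded trial {firsts.mean():.2f}, "
          f"max {int(firsts.max())}")
    ks = np.arange(1, 9)
    emp = np.array([(firsts <= k).mean() for k in ks])
    if ach:
        theo = theoretical_first_reward_cdf("uniform", ks, n=8)
        print("  empirical CDF(1..8):", np.round(emp, 2))
        print("  uniform{1..8} CDF :", np.round(theo, 2))
    else:
        theo = theoretical_first_reward_cdf("geometric", ks, p=1 / 8)
        print("  empirical CDF(1..8):", np.round(emp, 2))
        print("  geometric(1/8) CDF:", np.round(theo, 2))

print("\nThe -ACh mean sits near 8 (geometric); the +ACh agent never needs "
      "more than 8 trials because tried arms are excluded.")
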