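"""Region-wise mixed-model progression maps, compared with the ground truth.

Each region gets a linear mixed model (random intercept + age slope per
subject); the group x age interaction coefficient is the atrophy-progression
estimate, FDR-corrected across regions.
"""

import numpy as np
from scipy import stats

import atroprop as ap

cfg = ap.SimulationConfig(R=40, n_per_group=40, visits=3, rng_seed=5)
sim = ap.simulate_cohort(cfg)

res = ap.progression_maps(sim.dataset, q=0.05)
print(f"{res.fdr.n_rejected}/{len(res.table)} regions significant "
      f"(omnibus group x age, FDR q=0.05)")
for c in ("FHAD-HC", "AD-HC"):
    pos = len(res.significant_positive[c])
    neg = len(res.significant_negative[c])
    print(f"  {c}: {pos} regions faster, {neg} slower than controls")

est = res.beta_maps["AD-HC"].values
true = sim.ground_truth.true_beta["AD"]
rho = stats.spearmanr(est, true).statistic
print(f"rank correlation of estimated vs generating AD-HC beta map: {rho:.3f}")
print("High rank agreement means the per-region estimates order the cortex"
      " the same way the generating pattern does.")

# network-level summary on the cohort's 7-network partition
net = ap.network_progression(sim.dataset, sim.network_partition)
print(net.table[["region_id", "beta_AD-HC", "p_omnibus_fdr"]]
      .rename(columns={"region_id": "network"}).round(4).to_string(index=False))
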