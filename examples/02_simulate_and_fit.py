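"""Simulate replicate MST titrations and recover the Kd.

Replays the myosin head–tail preset (Kd 0.6 μmol/l, n = 8): a 16-point
two-fold ladder topping at 50 × Kd, labeled species at 0.1 μmol/l, and
Gaussian noise of SD 0.03 on the normalized signal.  Each replicate is
fitted with both the logistic (EC50) and the depletion-exact (Kd) model.
"""

import numpy as np

from mstbind import aggregate, fit_depletion, fit_logistic, head_tail_scenario, make_replicates

scen = head_tail_scenario()
reps = make_replicates(scen, base_seed=1)  # seeds 1..8

dep_fits = [fit_depletion(s) for s in reps.series]
log_fits = [fit_logistic(s) for s in reps.series]

agg = aggregate(dep_fits)
ec50s = [f.kd_or_ec50 for f in log_fits]

print(f"scenario: {scen.titrant_name} titrated into labeled {scen.target_name}")
print(f"true Kd = {float(scen.kd_true)} μmol/l, {reps.n} replicates, seeds 1..{reps.n}")
print(f"depletion-model Kd  = {agg.mean_kd:.3f} ± {agg.sem:.3f} μmol/l (mean ± SEM)")
print(f"logistic EC50 mean  = {np.mean(ec50s):.3f} μmol/l")
print()
print("The logistic midpoint sits ~R_t/2 = 0.05 μmol/l above the true Kd;")
print("the depletion fit removes that bias by modelling titrant consumption.")
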