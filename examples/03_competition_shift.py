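"""Competitive binding: two central cMyBP-C fragments share one site on S1.

Predicts the EC50 for C5C7 (Kd 0.77 μmol/l) binding labeled myosin S1 in
the presence of 1.5 μmol/l C2C4 (Kd 0.38 μmol/l), using the exact ternary
equilibrium, and compares it with the Cheng–Prusoff low-receptor limit.
A noisy competition titration is then simulated from the same model.
"""

import numpy as np

from mstbind import predict_competition_ec50, make_competition_titration
from mstbind.synthetic_data import competition_preset

kd_a, kd_b = 0.38, 0.77  # C2C4 and C5C7 vs myosin S1
a_total, r_total = 1.5, 0.1

alone = predict_competition_ec50(kd_a, kd_b, 0.0, r_total)
shifted = predict_competition_ec50(kd_a, kd_b, a_total, r_total)
cheng_prusoff = kd_b * (1 + a_total / kd_a)

print(f"C5C7 EC50 alone                : {alone:.2f} μmol/l")
print(f"C5C7 EC50 with 1.5 μmol/l C2C4 : {shifted:.2f} μmol/l (exact ternary)")
print(f"Cheng–Prusoff limit            : {cheng_prusoff:.2f} μmol/l")
print()
print("Competition shifts the apparent EC50 ~5-fold (≈0.8 → ≈3.8 μmol/l):")
print("the signature that both fragments occupy the same site on the head.")

ladder = np.geomspace(0.01, 100.0, 16)
series = make_competition_titration(competition_preset(), ladder, seed=1)
print()
print("simulated competition titration (B total μmol/l -> composite signal):")
for lt, y in list(zip(series.titrant_totals, series.signals))[::5]:
    print(f"  {lt:8.3f}  {y:6.3f}")
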