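"""Evaluate the two postprandial curve families and their derived summaries.

The LinExp curve describes gastric volume emptying; the power-exponential
curve describes delta-over-baseline (DOB) hormone/metabolite responses.
"""

import numpy as np

from gastrokin import (
    LinExpParams,
    PowerExpParams,
    linexp_peak_time,
    linexp_volume,
    powerexp_curve,
    powerexp_derived,
)

# Gastric secretion volume: initial 25 mL, shape k = 2.6 (initial rise),
# emptying time constant T = 112 min.
secretion = LinExpParams(v0=25.0, k=2.6, t_const=112.0)
t = np.array([0, 20, 60, 120, 210], dtype=float)
print("secretion volume (mL) at t =", t.astype(int), "min:")
print(" ", np.round(linexp_volume(secretion, t), 1))
print(f"  peak at t = {linexp_peak_time(secretion):.0f} min "
      "(interior maximum because k > 1)")

# CCK response: total area over baseline 76 pmol/L x min, rate 0.0115/min,
# shape beta 1.8.  t_max/A_max locate the response peak.
cck = PowerExpParams(aob=76.0, k=0.0115, beta=1.8)
t_max, a_max = powerexp_derived(cck)
print(f"\nCCK DOB curve: t_max = {t_max:.0f} min, A_max = {a_max:.3f} pmol/L")
print("  C(t) at blood-draw times 10/50/140/300 min:",
      np.round(powerexp_curve(cck, [10.0, 50.0, 140.0, 300.0]), 3))
# The area over baseline is recovered by integrating the curve; A_max and
# t_max describe the height and timing of the peak response.
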