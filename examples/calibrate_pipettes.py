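"""Photometric pipette calibration on a simulated high-range plate set.

Simulates 8 biased tips dispensing a dichromate standard at 8 levels in
triplicate, fits the absorbance standard curve, derives per-tip calibration
lines, then dispenses corrected volumes in a second simulated round to show
the accuracy gain.
"""

import warnings

import numpy as np

from phenoplate import calibration as cal
from phenoplate import synth

bias = synth.TipBiasModel()  # slopes 0.62..1.38: errors up to ~40%
spec = cal.DEFAULT_RANGES["high"]  # 50-200 uL, 2 mM-range stock at 350 nm

sim = synth.gen_calibration_plate(bias, spec, seed=42)
curve = cal.fit_standard_curve(sim.standard_volumes, sim.standard_absorbances, spec)
reports, cals = cal.calibrate_plates(curve, sim.plates, spec)

print(f"standard curve: A = {curve.slope:.5f} * V + {curve.intercept:.4f} "
      f"(r^2 = {curve.r_squared:.5f})")
pre = np.median([abs(r.systematic_error) for r in reports])
print(f"pre-calibration median |systematic error|: {pre:.1f}%  "
      "(biased tips dispense the wrong volumes)")

for c in cals[:3]:
    print(f"  tip {c.tip_id}: actual = {c.a:.3f} x programmed + {c.b:.2f} uL "
          f"(truth a = {bias.slopes[c.tip_id]})")

# second round: program the corrected volume for each desired level
# (the most biased tips need programmed volumes beyond the calibrated
# range for the top level and clip there with a warning — silenced here)
post = []
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for level in spec.levels:
        for c in cals:
            actual = bias.actual_volume(c.tip_id, cal.corrected_volume(c, level))
            post.append(abs(100 * (actual - level) / level))
print(f"post-calibration median |systematic error|: {np.median(post):.2f}%  "
      "(inverting the per-tip line restores accuracy)")
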