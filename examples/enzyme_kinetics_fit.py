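"""Michaelis-Menten kinetics of an NADPH-depletion assay from kinetic A340 reads.

Simulates falling A340 traces across a substrate titration (truth
K_M = 0.35 mM, V_max = 0.05 umol/min), extracts initial rates from the
earliest well-fitting window, converts them via Beer-Lambert
(eps = 6.3 mM^-1 cm^-1, path 0.56 cm, 0.2 mL), and fits the MM curve.
"""

import numpy as np

from phenoplate import enzyme_kinetics as ek
from phenoplate import synth

ctx = ek.AssayContext()
sim = synth.gen_mm_traces(0.35, 0.05, (0.05, 0.1, 0.25, 0.5, 1, 2, 5),
                          noise_sd=0.005, seed=11)

S, v = [], []
for well, substrate in sim.layout.items():
    rate = ek.extract_initial_rate(sim.reader.times, sim.reader.values[well],
                                   well, min_r2=0.9)
    S.append(substrate)
    v.append(ek.rate_to_activity(rate.slope, ctx))

fit = ek.fit_michaelis_menten(np.array(S), np.array(v))
print(f"K_M   = {fit.K_M:.3f} +/- {fit.se_K_M:.3f} mM   (truth 0.35)")
print(f"V_max = {fit.V_max:.4f} +/- {fit.se_V_max:.4f} umol/min (truth 0.05)")
print(f"fit r^2 = {fit.r_squared:.4f} over {fit.n_points} wells")
print("\nK_M is the substrate concentration at half-maximal rate; recovering the")
print("generating values shows the trace -> rate -> fit pipeline is unbiased.")
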