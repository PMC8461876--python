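"""Growth-rate profiling of three-regime anaerobic growth curves.

Simulated OD600 curves show a dissolved-oxygen regime, an (aerobic-only)
oxygen-transfer regime, and a slower anaerobic regime.  The instantaneous
rate mu(t) = d ln OD / dt exposes the regimes; the exponential-phase mean
is the headline growth rate.
"""

import numpy as np

from phenoplate import phenotyping as ph
from phenoplate import synth

sim = synth.gen_growth_curves(noise_sd=0.003, seed=5)
truth = sim.truth.set_index("culture_id")

for curve in sim.curves:
    t, mu = ph.instantaneous_growth_rate(curve)
    window = ph.detect_exponential_phase(t, mu)
    rate = ph.mean_growth_rate(t, mu, window)
    late = (t > truth.loc[curve.culture_id, "t2"] + 0.3) & \
           (curve.od600 < 0.9) & np.isfinite(mu)
    print(f"{curve.culture_id:>15}: exponential phase {window[0]:.1f}-{window[1]:.1f} h, "
          f"mean mu = {rate:.3f} /h; anaerobic-regime mu = "
          f"{np.nanmedian(mu[late]):.3f} /h (truth {truth.loc[curve.culture_id, 'mu3']})")

print("\nThe oil-sealed cultures lack the accelerated middle regime: mineral oil")
print("only limits gas exchange, it does not alter intrinsic growth.")
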