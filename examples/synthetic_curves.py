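"""Synthetic pseudo-experimental data with known ground truth.

Generates a noisy velocity-vs-[MgATP] hyperbola and a noisy T1 (tension vs
length-step) curve, then recovers the generating parameters, demonstrating
the fitting utilities on data of known origin.
"""

import numpy as np

from crossbridge.protocols import fit_km_v
from crossbridge.synthetic import gen_hyperbola, gen_t1_curve

curve = gen_hyperbola(15000.0, 0.4, np.geomspace(0.05, 5, 12),
                      noise_sd=0.05, seed=42)
fit = fit_km_v(curve.to_frame())
print(f"hyperbola truth Km = 0.4 mM; recovered {fit['km_mM']:.3f} mM "
      f"(Vmax {fit['vmax_nm_s']:.0f} vs truth 15000)")

t1 = gen_t1_curve(47.0, np.linspace(-1, 2, 13), noise_sd=0.05, seed=42,
                  tension0_kPa=68.0)
slope = np.polyfit(t1.predictor, t1.response, 1)[0]
print(f"T1-curve truth slope = 47 kPa/nm; recovered {slope:.1f} kPa/nm")
print("Multiplicative 5% noise leaves both parameters recoverable to a few %.")
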