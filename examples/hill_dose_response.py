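"""Quantify the steepness of an antibiotic dose-response curve.

Fits the Hill function g(c)/g0 = 1/(1 + (c/IC50)^n) to a synthetic
dose-response curve and derives the IC50 and IC90. The Hill exponent n
("dose-sensitivity") measures steepness: shallow drugs like trimethoprim
have n near 1, most antibiotics 2-3.5, beta-lactams above 6.
"""

import numpy as np

import growthfeedback as gf

conc = np.concatenate([[0.0], np.logspace(-2, 1, 10)])  # ug/ml
rng = np.random.default_rng(0)
growth = 0.9 * gf.hill(conc, 1.1, 0.5) + rng.normal(0, 0.01, len(conc))
curve = gf.DoseResponseCurve(conc=conc, growth=np.clip(growth, 0, None))

fit = gf.fit_hill(curve)
ic90 = gf.inhibitory_concentration(fit, 0.9)

print(f"dose-sensitivity n: {fit.n:.2f} +/- {fit.sd_n:.2f}")
print(f"IC50:               {fit.ic50:.3f} +/- {fit.sd_ic50:.3f} ug/ml")
print(f"IC90:               {ic90:.3f} ug/ml")
print(f"IC90/IC50 ratio:    {ic90 / fit.ic50:.1f}")
# A shallow curve (n ~ 1) needs a large concentration ratio (here ~9x)
# between 50% and 90% inhibition; a steep curve would need far less.
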