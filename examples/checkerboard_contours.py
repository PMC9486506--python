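"""Inhibition contours of a drug x nutrient-limitation checkerboard.

Generates a growth-rate checkerboard from the calibrated feedback model
(rows: glucose-limitation ratio a, columns: drug concentration) and
extracts per-row inhibition contours. In this parameterization the
drug-target expression converges across limitation levels by ~0.4 ug/ml,
so deep-inhibition contours (IC90) coincide across rows, while the
shallow-inhibition contour (30%), which falls inside the feedback-active
concentration range, shifts right under limitation.
"""

import dataclasses

import numpy as np

import growthfeedback as gf
from growthfeedback.synthetic_data import generate_checkerboard

cfg = dataclasses.replace(gf.default_synth_config(seed=2, noise_cv=0.02),
                          a_grid=(0.0, 1.0, 2.5, 5.0, 10.0),
                          c_grid=tuple(np.linspace(0.0, 6.0, 31)))
board = generate_checkerboard(cfg)

for level in (0.3, 0.9):
    contour = gf.ic_contour_from_checkerboard(board, level=level)
    fc = gf.fold_change_ic(contour, reference_row=0, center_row=2,
                           neighbor_halfwidth=1)
    concs = " ".join(f"{c:6.3f}" for c in contour.conc)
    print(f"IC{int(level * 100)} per row (a = 0, 1, 2.5, 5, 10): {concs}")
    print(f"  fold-change at a = 2.5 vs a = 0: {fc.value:.2f} +/- {fc.sd:.2f}")
# The 30% contour rises with limitation (feedback buffering is active
# there); by the IC90 the expression clamp has equalized all rows, so the
# deep contours coincide in this calibration.
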