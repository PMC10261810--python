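"""Analytical method-validation arithmetic.

Runs the QC computations on a small synthetic validation data set: a
five-level calibration series, blank measurements for LOD/LOQ, spiked
recoveries, replicate precision (RSD), and below-LOD substitution.
"""

import numpy as np

from pcbrisk import (
    CalibrationSeries,
    compute_lod_loq,
    compute_recovery,
    compute_rsd,
    fit_calibration,
    substitute_censored,
)

rng = np.random.default_rng(1)

levels = np.array([0.10, 1.0, 8.0, 20.0, 40.0])  # ng/mL spiking levels
responses = 1.85 * levels + 0.02 + rng.normal(0, 0.15, size=levels.size)
slope, intercept, r2 = fit_calibration(CalibrationSeries(levels, responses))
print(f"calibration: response = {slope:.4f} x conc + {intercept:.4f}, r^2 = {r2:.5f}")

blanks = [0.021, 0.026, 0.019, 0.024, 0.022]
lod, loq = compute_lod_loq(blanks)
print(f"blank-based LOD = {lod:.4f}, LOQ = {loq:.4f} ng/g (mean+3SD / mean+10SD)")

measured = [8.21, 7.92, 8.05]
for m in measured:
    print(f"recovery at 8 ng/mL spike: {compute_recovery(m, 8.0):.2f}%")
print(f"replicate RSD: {compute_rsd(measured):.2f}% (method gate: < 15.94%)")

values = [0.35, 0.0, 0.12]
flags = [False, True, False]
print("after <LOD substitution (LOD/2 rule):",
      substitute_censored(values, flags, lod=lod, loq=loq).round(4).tolist())
print()
print("r^2 near 1 confirms linearity over the working range; recoveries near")
print("100% and RSD below the gate indicate accurate, repeatable extraction.")
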