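"""Extrapolating retention to 100% aqueous mobile phase with the LSS model.

Isocratic log k falls linearly with the methanol fraction phi; the intercept
log k_w at phi = 0 is the chromatographic lipophilicity index the QSRR
models consume. Here we simulate a solute with known log k_w = 2.0 and
slope S = 3.0, add instrument noise, and recover the line.
"""

import numpy as np

from chromlogd import Mode, RetentionMeasurement, dp_rtc_correct, fit_lss

rng = np.random.default_rng(0)
t_0 = 1.2  # dead time, minutes (uracil marker)

# raw retention times at six methanol fractions, three injections each
measurements = []
for phi in (0.2, 0.3, 0.4, 0.5, 0.6, 0.7):
    k_true = 10 ** (2.0 - 3.0 * phi)
    for _ in range(3):
        t_r = t_0 * (1 + k_true) + rng.normal(0, 0.01)
        # recalibrate against two reference compounds (here: a pure shift)
        t_r = dp_rtc_correct(t_r, ref_obs=(2.0, 10.0), ref_nominal=(2.0, 10.0))
        measurements.append(
            RetentionMeasurement("demo", Mode.IS, phi, t_r, t_0)
        )

from chromlogd.retention import average_replicates

fit = fit_lss(average_replicates(measurements), r2_gate=0.99)
print(f"log k_w = {fit.log_kw:.3f}   (true 2.000)")
print(f"S       = {fit.s:.3f}   (true 3.000)")
print(f"r2      = {fit.r2:.5f} over {fit.n_points} phi levels")

# log k_w lands within a few thousandths of the true value; r2 > 0.999
# mirrors the quality gate used for real solutes on this column.
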