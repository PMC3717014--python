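"""Estimate amplification efficiency from a serial-dilution curve.

Cq is regressed on log10 relative template amount; the efficiency is
E = 10^(-1/slope) - 1, so a slope of -3.32 cycles per decade means perfect
doubling (E = 1).
"""

import refstab as rs

for true_e in (0.70, 0.78, 0.89):
    series = rs.simulate_dilution_series(
        true_e, anchor_cq=15.0, dilutions=(1, 10, 100, 1000), noise_sd=0.05, seed=4
    )
    fit = rs.estimate_efficiency(series)
    print(f"true E={true_e:.2f}  ->  fitted E={fit.efficiency:.3f}  "
          f"slope={fit.slope:.3f} cycles/decade  R2={fit.r_squared:.4f}")
# With only 0.05 cycles of noise on four points the inversion recovers the
# efficiency to a few percent; noiseless curves invert exactly.
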