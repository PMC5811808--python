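"""Simulate a splitting-enhanced glucose C6 multiplet.

Builds the glucose C4–C6 spin system, simulates the ¹³C trace of the C6
HSQC cross peak for a [U-¹³C] species at several enhancement levels, and
prints the measured doublet separation at each level.  The separation
grows as (1+k)·J while the multiplet integral stays constant — the
enhancement moves intensity apart, it does not create any.
"""

import numpy as np

from tracernmr import (
    AcquisitionParams,
    Isotopomer,
    IsotopomerMixture,
    glucose_c6_template,
    measure_splitting,
    simulate_carbon_trace,
    with_enhancement,
)

template = glucose_c6_template()
species = Isotopomer({4: True, 5: True, 6: True})  # [U-13C] fragment
mixture = IsotopomerMixture(((species, 1.0),))

acq = AcquisitionParams(
    spectral_width=2048.0,  # Hz in the 13C dimension
    n_points=4096,
    r2=np.pi,  # 1 Hz linewidth
    carrier=63.2,  # ppm, on the C6 resonance
    field_mhz=1.0,  # Hz-per-ppm of 1 keeps the axis in plain Hz
    zero_fill_factor=2,
)

# the outermost lines are separated by the sum of both active couplings:
# the one-bond 1J(C5,C6) = 43 Hz plus the long-range J(C4,C6) = 4 Hz
print("k   outer-line separation   expected (1+k)*(43+4) Hz")
for k in (0, 1, 3, 7):
    spec = simulate_carbon_trace(template, mixture, 6, with_enhancement(acq, k_cc=k))
    sep = measure_splitting(spec, rel_threshold=0.1)
    print(f"{k}   {sep:8.1f} Hz             {(1 + k) * 47.0:8.1f} Hz")

print()
print("The separation tracks (1+k)*J exactly: each extra dwell-time echo")
print("increment adds one full period of C-C coupling evolution per t1")
print("point without moving the chemical shift.  The 4 Hz long-range")
print("coupling, hidden in the linewidth at k=0, is cleanly resolved once")
print("enhanced: (1+k)*4 Hz exceeds the ~1 Hz lines from k=1 on.")
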