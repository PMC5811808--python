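"""Absolute %13C incorporation from one sample via paired filter spectra.

Generates the paired all-proton / 13C-bound-proton lactate spectra with a
known 40% labelled fraction and a peak J_CH of 130 Hz (the filter is tuned
to 145 Hz), then quantifies the peak with and without the sin^2(2*pi*delta*J)
attenuation correction.
"""

from tracernmr import (
    PeakRegion,
    attenuation_factor,
    get_fixture,
    incorporation_percent,
    make_filter_pair,
    max_downscaling,
)

case = get_fixture("fig2_filter_lactate")
pair, sidecar = make_filter_pair(case, percent_13c=40.0, j_ch_actual=130.0)
region = PeakRegion("lactate CH3", 1.12, 1.52, j_ch_actual=130.0)

corrected = incorporation_percent(pair, region, correct_attenuation=True,
                                  noise_region=(8.0, 10.0))
raw = incorporation_percent(pair, region, correct_attenuation=False,
                            noise_region=(8.0, 10.0))

print(f"ground truth:           {sidecar['truth_percent_13c']:.1f} %")
print(f"uncorrected estimate:   {raw.percent:.1f} +/- {raw.sigma:.1f} %")
print(f"corrected estimate:     {corrected.percent:.1f} +/- {corrected.sigma:.1f} %")
print(f"filter transmission at J=130 Hz: "
      f"{attenuation_factor(130.0, pair.delta):.4f}")
print(f"worst-case loss over J in [120, 165] Hz: "
      f"{max_downscaling(120.0, 165.0, pair.delta):.1f} %")
print()
print("Both spectra share one intensity scale, so the filtered/all integral")
print("ratio is an absolute labelled fraction from a single sample; dividing")
print("by the J-dependent filter transmission removes the mistuning bias.")
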