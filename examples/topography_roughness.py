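"""Roughness and buckle geometry of synthetic compressed-film topographies.

First measures the RMS roughness of a pure sinusoidal wrinkle field
(amplitude 6.2225 nm, eight periods), then extracts buckle geometry from
a separate map containing one 600-nm-wide, 50-nm-high delamination
buckle on a gently noisy baseline.
"""

import lamellaflex as lf

wrinkles = lf.generate_topography(
    nx=512, ny=128, pixel_size=10.0,
    wrinkle_amplitude=6.2225, wrinkle_wavelength=640.0,
)
rms = lf.rms_roughness(wrinkles, detrend="none")
print(f"RMS roughness of the wrinkle field = {rms:.2f} nm")
print("A pure sinusoid of amplitude A has RMS A/sqrt(2): 6.2225 nm -> 4.4 nm.")

buckled = lf.generate_topography(
    nx=512, ny=128, pixel_size=10.0,
    buckles=[(2560.0, 600.0, 50.0)],
    noise_sd=0.3, seed=0,
)
profile = buckled.heights[64]
regions = lf.extract_buckle_geometry(profile, buckled.pixel_size, max_buckle_width=600.0)
for width, height in regions:
    print(f"buckle: width = {width:.0f} nm, height = {height:.1f} nm "
          "(constructed: 600 nm wide, 50 nm high)")
print("Width is read at the baseline-crossing level of a running-median "
      "baseline; feeding (width, thickness, strain) triples like these to "
      "fit_adhesion_energy yields the film-substrate adhesion energy.")
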