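"""Cone-opponent color space: calibration, transform, luminance projection.

Builds a monitor calibration from measured CRT phosphor chromaticities,
converts an RGB pixel to LMS cone excitations and into the opponent
space (Lum, L/M, S/(L+M)), and shows that projecting onto the luminance
axis removes chromatic content while preserving luminance exactly.
"""

import numpy as np

from shadowedge import colorspace as cs

primaries = [
    (0.6207, 0.3380, 15.0485),  # red phosphor (x, y, Y)
    (0.2822, 0.6068, 57.0515),  # green
    (0.1495, 0.0683, 6.9209),   # blue
]
cal = cs.build_calibration(primaries, gamma=2.2)
print("RGB -> LMS calibration matrix:")
print(np.array_str(cal.rgb_to_lms, precision=4))

rgb = np.array([[[0.8, 0.4, 0.2]]])  # a gamma-encoded orange pixel
lms = cs.rgb_to_lms(cs.gamma_correct(rgb, cal), cal)
opp = cs.lms_to_opponent(lms, cal.alpha, cal.beta)
print(f"\npixel RGB {rgb[0,0]} -> LMS {np.round(lms[0,0], 3)}")
print(f"opponent (Lum, L/M, S/(L+M)) = {np.round(opp[0,0], 4)}")
# Lum is L+M in cd/m^2-scaled units; L/M > 0 means redder than the
# monitor's achromatic balance point, S/(L+M) < 0 means yellower.

proj = cs.project_luminance_only(opp)
print(f"after luminance projection     = {np.round(proj[0,0], 4)}")

back = cs.opponent_to_lms(opp, cal.alpha, cal.beta)
print(f"\nround-trip LMS error: {np.abs(back - lms).max():.2e}")
# the opponent transform is exactly invertible: chromatic channels are
# pixel-normalized ratios, so no information is lost
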