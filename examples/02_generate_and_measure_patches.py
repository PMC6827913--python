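"""Synthetic shadow/material edges and their six image properties.

Generates one shadow and one material edge patch, extracts the four
luminance properties (Michelson contrast, mean luminance, contrast
difference, edge slope) and the two chromatic differences, and prints
them side by side.  Shadows attenuate L and M equally (d_LM ~ 0) but
shift S/(L+M) toward blue; material edges change the L/M balance.
"""

import numpy as np

from shadowedge import GeneratorParams, extract_features, synth

params = GeneratorParams(sizes=(144,))
rng = np.random.default_rng(42)

print(f"{'property':<12}{'shadow':>12}{'material':>12}")
fvs = {}
for category in ("shadow", "other"):
    patch = synth.generate_opponent_patch(category, 144, params, rng)
    fvs[category] = extract_features(patch)
for name in ("C_Lum", "m_Lum", "sigma_Lum", "rho_Lum", "d_LM", "d_Sop"):
    print(f"{name:<12}{getattr(fvs['shadow'], name):>12.4f}"
          f"{getattr(fvs['other'], name):>12.4f}")

print(
    "\nd_LM (red-green difference) is near zero for the shadow -- equal\n"
    "L,M attenuation cancels in the pixel-normalized ratio -- but nonzero\n"
    "for the material edge, whose two surfaces differ in L/M balance.\n"
    "d_Sop is nonzero for both: shadows are relatively blue, and\n"
    "surfaces also vary in S/(L+M)."
)
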