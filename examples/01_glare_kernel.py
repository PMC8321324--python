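"""Build the CIE veiling-glare kernel and inspect its properties.

The CIE disability-glare curve gives relative veiling luminance versus
glare angle; the kernel samples it on the pixel grid with the searched
glare angle acting as the curve's angular scale.
"""

import numpy as np

from deglare import GSFCurveParams, build_kernel, gsf_value

params = GSFCurveParams(age=70.0, pigment_factor=0.5)

print("CIE curve values (relative veiling luminance):")
for angle in (0.0, 0.1, 1.0, 5.0, 10.0):
    print(f"  GSF({angle:>4} deg) = {gsf_value(angle, params):12.4g}")
# the curve spans ~9 orders of magnitude: an enormous forward peak plus a
# wide, shallow veil -- the veil is what destroys retinal image contrast.

dpp = 45.0 / 400.0  # 45-degree fundus camera field over 400 pixels
for alpha in (0.0, 1.0, 5.0):
    kernel = build_kernel((400, 400), alpha, dpp, params)
    centre = kernel.weights[kernel.radius, kernel.radius]
    print(
        f"alpha={alpha:>3} deg: grid {kernel.weights.shape}, "
        f"sum={kernel.weights.sum():.12f}, central weight={centre:.3f}"
    )
# the central weight drops as the glare angle grows: more of the light is
# scattered into the veil, which is exactly the degradation to invert.
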