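"""Show that restoration re-reveals vessel edges hidden by veiling glare.

A synthetic fundus-like chart (bright optic disc, faint dark vessels) is
degraded, restored, and segmented with the Canny pipeline at a fixed
sensitivity; edge pixels lost to the veil come back after restoration.
"""

import numpy as np

import deglare as dg

chart = dg.fundus_chart(400, seed=3)
references = [dg.fundus_chart(400, seed=s) for s in (10, 11, 12, 13, 14)]
model = dg.train_niqe(references)

degraded = np.clip(dg.degrade(chart, 4.0), 0, 1)
result = dg.itsd_restore(degraded, model)
restored = np.clip(result.restored, 0.0, 1.0)

sensitivity = 0.2
seg_clean = dg.segment(chart, sensitivity)
seg_degraded, seg_restored = dg.segment_pair(degraded, restored, sensitivity)

print(f"detected glare angle: {result.detected_alpha:g} deg "
      f"(iterations: {result.optimal_iterations})")
print(f"edge pixels, clean chart    : {seg_clean.edge_pixel_count}")
print(f"edge pixels, degraded chart : {seg_degraded.edge_pixel_count}")
print(f"edge pixels, restored chart : {seg_restored.edge_pixel_count}")
# the degraded count drops because faint vessel edges fall below the Canny
# threshold under the veil; restoration recovers (most of) them.
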