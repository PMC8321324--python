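# deglare

Semi-blind Richardson-Lucy restoration of images degraded by
intraocular-straylight **veiling glare**, with the CIE disability-glare
curve as the degradation kernel.

Cataracts, corneal oedema and vitreous opacification scatter light over
wide angles inside the eye.  In fundus photography this straylight
superimposes a veil on the retinal image that crushes local contrast and
hides vessels, drusen and the optic-disc margin.  The veil is well
described by the CIE glare-spread function (GSF): relative veiling
luminance as a function of glare angle θ, observer age and ocular
pigmentation.  `deglare` treats the acquired image as

```
i' = GSF_α ⊗ i
```

where the kernel's functional form is known but its angular scale α (the
*glare angle*) is not — a semi-blind deconvolution problem.  Restoration
runs in two steps:

1. **Glare-angle detection** — walk α upward in 1° steps; at each
   candidate run a short Richardson-Lucy probe deconvolution and measure
   the sharpness S = mean √(Gx² + Gy²) of the probe in display range.
   Undersized kernels leave veil behind, oversized kernels overcorrect and
   inflate the dynamic range faster than they add gradient, so S peaks at
   the true angle; greedy hill climbing stops at the first decrease.
2. **Iteration optimisation** — with the detected kernel fixed, iterate
   the Richardson-Lucy update
   `î_{N+1} = î_N · [ (i' / (î_N ⊗ GSF)) ⊗ GSF^T ]`
   while scoring every iterate with a trained no-reference quality model
   (a NIQE-style Gaussian over per-block mean luminance, variance and
   sharpness of clean reference images); stop once the score passes its
   maximum and return the best-scoring iterate.

The package also ships the forward simulator (Siemens-star and
fundus-like charts degraded by exact GSF convolution), the quality
metrics (sharpness, SSIM, trained quality score) and the Canny
edge-segmentation pipeline used to demonstrate recovered structure.

## Worked example

```python
import numpy as np
import deglare as dg

star = dg.siemens_star()                 # 400x400 ground-truth chart
degraded = dg.degrade(star, 2.0)         # induce 2 deg of veiling glare

refs, _ = dg.make_fixture_set(5, 1, seed=1)
model = dg.train_niqe(refs)              # clean-chart reference statistics

result = dg.itsd_restore(degraded, model)
restored = np.clip(result.restored, 0, 1)
print(result.detected_alpha, result.optimal_iterations,
      round(dg.ssim(np.clip(degraded, 0, 1), star).index, 4),
      round(dg.ssim(restored, star).index, 4))
```

prints

```
2.0 18 0.6817 0.9861
```

the detected glare angle equals the induced 2°, the iteration optimiser
stopped after 18 Richardson-Lucy updates, and SSIM against the clean
chart rises from 0.68 (degraded) to 0.99 (restored).  The
`examples/` directory has one short script per capability (kernel
construction, restoration, quality model, edge segmentation).

A thin CLI wraps the same API:

```sh
deglare simulate --alpha 2 --out degraded.png
deglare train-niqe --references refs/ --block-size 40 --out model.json
deglare restore degraded.png --model model.json --out restored.png --trace trace.csv
deglare segment restored.png --sensitivity 0.2 --out edges.png
deglare evaluate --original orig.png --degraded degraded.png \
    --restored restored.png --out report.json
```

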