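# casdn

Segmentation of bright lesions in single-channel breast images
(thermograms, mammograms, ultrasound frames) for researchers who need a
fully deterministic, auditable pipeline rather than a trained network.
Real acquisitions suffer from inhomogeneous brightness, low contrast and
noise; this toolkit couples an eight-stage **advanced image preprocessing**
chain (AIPT) with a **context-aware spatial decomposition** segmenter
(CASDN), plus the six standard segmentation-quality metrics and a
synthetic phantom generator with exact ground-truth masks.

The preprocessing chain fuses Sobel and adaptive-threshold Canny edges
(`E = α·E_Sobel + (1−α)·E_Canny`), removes illumination with sliding-window
standardization at multiple pyramid scales, blends in Gaussian context
maps, sharpens across scales, extracts a center-surround saliency map `S`,
equalizes histograms tile-locally and globally, applies an adaptive
Wiener-style noise filter, and synthesizes
`I_pre = clip(I + 0.25·E + 0.25·(S − mean S))`.

The segmenter decomposes `I_pre` into a grid of cells `{R_i}`, weights
cells by softmax over their structure scores,
`w_i = exp(α_ctx·Rel(R_i)) / Σ_j exp(α_ctx·Rel(R_j))`, assembles a
weighted local-contrast score map, gates it by saliency, integrates coarser
context hierarchically, refines with a sigmoid-contrast step
`F ← F + β_refine·(g(F) − F)`, and thresholds into a mask. Parameters are
fitted by coordinate descent on the compound loss
`L = λ·[α_spatial·(soft-Dice + TV) + α_ctx_w·BCE]`. Metrics: Dice
`2|A∩B|/(|A|+|B|)`, IoU, boundary accuracy, exact Hausdorff distance, SSIM
and proportion of correct patches. See `docs/methods.md` for the full
model description, parameter meanings and measured limitations.

## Worked example

```python
import numpy as np
import casdn

# a 128x128 phantom: textured background, one soft-edged lesion,
# illumination ramp and noise, with its exact ground-truth mask
img, truth = casdn.generate_phantom(casdn.PhantomSpec(seed=10))

pre, trace = casdn.run_aipt(img)                 # eight-stage preprocessing
fitted, history = casdn.fit([pre], [truth], casdn.CasdnConfig(),
                            saliencies=[trace["S_map"]])
res = casdn.predict(pre, fitted, trace["S_map"])
report = casdn.evaluate(res.mask, truth,
                        np.clip(res.scores, 0, 1), truth.astype(float))
for name, value in report.as_dict().items():
    print(f"{name:18s} {value:.3f}")
```

prints

```
dsc                0.905
iou                0.827
boundary_accuracy  0.000
hausdorff          2.000
ssim               0.253
pcp                0.984
```

The mask overlaps the true lesion at Dice 0.905 / IoU 0.827 and agrees on
98% of 16-px patches; its boundary sits about 2 px inside the truth
contour (Hausdorff 2.0), so no predicted boundary pixel coincides exactly
with a truth boundary pixel (boundary accuracy 0) — the strictness of that
metric is discussed in `docs/methods.md`. The SSIM entry compares the
continuous score map against the binary truth image.

The same flow is available from the shell:

```sh
aipt-casdn phantom --n 20 --out data/
aipt-casdn preprocess --in data/img_000.png --out pre.png --trace-dir trace/
aipt-casdn segment --in pre.png --saliency trace/S_map.png --out mask.png
aipt-casdn evaluate --pred mask.png --truth data/mask_000.png --out report.json
aipt-casdn pipeline --in data/img_000.png --truth data/mask_000.png --out-dir run/
```

Every subcommand writes a JSON manifest (resolved configuration, paths,
wall time, version) next to its output, and reruns are bitwise identical.

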