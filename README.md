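# ir2 — paired-volume restoration for deep-tissue light-sheet microscopy

Fluorescence light-sheet images of whole embryos lose contrast with depth:
scattering of visible emission blurs and attenuates every plane below the
sample surface. When the same structures are also imaged in a
scattering-resistant channel (e.g. a near-infrared dye bound to the same
nuclear marker), the two co-registered volumes form a supervised training
pair — visible channel as degraded input, infrared channel as ground truth —
and a small image-to-image network can learn to restore the visible channel.

`ir2` implements that workflow for people who have (or want to simulate)
such paired volumes:

* **Selective patch sampling** — training patches are drawn with per-voxel
  probability `P = B/N_f` on foreground and `P = (1−B)/N_b` on background
  (Otsu split, default `B = 0.9`, so ~10 % of patches are
  background-centered); extraction stops when ≥ 95 % of foreground voxels
  are covered by at least one patch.
* **Patch registration** — residual chromatic misalignment is removed per
  patch by exhaustively maximizing the normalized cross-correlation
  `C(dz, dy, dx) = R(I(v), GT(v + d))` over an integer search box.
* **Restoration network** — a compact volumetric U-Net (two pooling levels,
  3×3×3 convolutions, skip connections, linear output) trained with MSE
  loss, 9:1 train/validation split, Adam; implemented directly on numpy so
  it runs anywhere, at desk scale, on one CPU core. Whole volumes are
  restored by overlapped tiling with feather blending.
* **Quality metrics** — `NRMSE(x,y) = sqrt(<(x−y)²>)/<y>`, patchwise Pearson
  correlation, SSIM, and spectral-entropy information content
  `IIC = −Σ p_ij ln p_ij` with `p = F/ΣF`, `F = DCT(I)²/N²`; the
  information-content *gain* of one image over another is their IIC ratio.
  Depth-resolved summaries and time×depth gain kymographs quantify where
  restoration helps.
* **Synthetic phantom** — ellipsoidal "embryo" with Gaussian-blob nuclei and
  a depth-dependent degradation model (plane-wise exponential attenuation,
  depth-growing blur, shot + read noise, optional chromatic offset), so the
  entire pipeline is testable without microscope data.

See `docs/methods.md` for the model details, parameter defaults and known
limitations.

## Worked example

```python
import numpy as np
from ir2 import (PhantomSpec, DegradationSpec, generate_phantom,
                 degrade_volume, SamplingConfig, extract_training_set)
from ir2.metrics import evaluate_patchwise, surface_patch_selector

# default study conditions: 64x256x256 voxels at 1x0.5x0.5 um, 300 nuclei
pair = degrade_volume(generate_phantom(PhantomSpec(seed=7)),
                      DegradationSpec(seed=7))

result = extract_training_set(pair, SamplingConfig(seed=7))
print(f"extracted {len(result.pairs)} patch pairs, "
      f"foreground coverage {100 * result.coverage:.1f}% ({result.status})")
bg = np.mean([not p.is_foreground_center for p in result.pairs])
print(f"background-centered fraction: {bg:.2f}")

centers = surface_patch_selector(pair.ground_truth.data, None, 20.0,
                                 (32, 128, 128), n=20, seed=7,
                                 spacing_um=pair.spacing_um)
records, summary = evaluate_patchwise(
    {"degraded": pair.degraded.data, "truth": pair.ground_truth.data},
    centers, (32, 128, 128), spacing_um=pair.spacing_um, mask=pair.mask)
print(summary["overall"].loc[["mean", "sd"],
                             ["nrmse", "pearson", "ssim", "gain"]].round(3))
```

prints

```
extracted 50 patch pairs, foreground coverage 99.5% (converged)
background-centered fraction: 0.12
      nrmse  pearson   ssim   gain
mean  0.926    0.779  0.791  1.558
sd    0.120    0.076  0.068  0.247
```

Reading the numbers: the coverage stopping rule halted extraction once 99.5 %
of foreground voxels were inside at least one patch, and 12 % of the 50
patch centers landed on background, consistent with the `B = 0.9` sampling
law. On surface-proximal 128×128×32 patches the degraded channel correlates
0.78 with the ground truth (SSIM 0.79), and the ground truth carries on
average 1.56× the spectral information content of the degraded channel —
the gap restoration is meant to close. Training and prediction follow with
`train_model(...)` and `predict_volume(...)` (see the pipeline smoke tests
for a complete miniature run), or from the shell:

```bash
ir2 simulate --config spec.yaml --out data/
ir2 extract  --degraded data/degraded.tif --truth data/truth.tif --out patches/
ir2 register --patches patches/ --radius 2,10,10
ir2 train    --patches patches/ --out model/
ir2 predict  --model model/ --in data/degraded.tif --out restored.tif
ir2 evaluate --truth data/truth.tif --degraded data/degraded.tif \
             --restored restored.tif --report report.csv
```

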