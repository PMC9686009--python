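# mvmar — metal artifact reduction for kV-CT via MV-CBCT translation

Metal dentures and implants produce bright/dark streaks in kilovoltage CT
(beam hardening, photon starvation), corrupting the Hounsfield units and
therefore the relative electron densities (RED) that radiotherapy dose
engines rely on.  Megavoltage cone-beam CT (MV-CBCT) of the same patient
is nearly artifact-free around metal — the ~6 MV beam is insensitive to
the photoelectric effect — but noisy, low-contrast, and HU-capped at
1400.  `mvmar` implements the pipeline that combines the two:

1. **Scale** MV HU into (−1, 1) with three tanh variants, each
   linearizing a different HU band:
   P1 `tanh(HU/400)` (both modalities), P2 `tanh(HU/150)` MV /
   `tanh(HU/300)` CT, P3 `tanh((HU−800)/400)` MV /
   `tanh((HU−1600)/960)` CT.
2. **Translate** MV→synthetic-CT with a cycle-consistent adversarial
   model (two generators, two least-squares discriminators, adversarial +
   λ·cycle L1 objective) — or with a deterministic surrogate intensity
   map, so the rest of the pipeline is testable without training.
3. **Fuse** the three candidates per pixel by HU band (P2 below 400 HU,
   P1 in [400, 800), P3 at or above 800 HU).
4. **Copy back metal**: segment metal as (CT > 2500 HU) ∧ (MV > 300 HU)
   and overwrite those pixels with the original CT values.
5. **Evaluate** with PSNR/SSIM (overall and HU-banded), CT-to-RED
   conversion and ROI RED statistics, a streak artifact index, global
   gamma analysis (2 mm/2% and 1 mm/1%), and DVH metrics
   (Dmean, Dx, Vx%, D0.1cc) from a toy dose engine.

Because no clinical data ship with the package, a seeded **phantom
simulator** generates intrinsically-registered (ground truth, kV-CT,
MV-CBCT) head-slice triples with real streak physics: polychromatic
projection with water-linearization, Poisson noise, photon starvation
behind metal, and FBP reconstruction.  It is first-class, tested code —
the study conditions for everything above.

The package is for medical-physics and image-analysis researchers who
want a fully inspectable, CPU-scale implementation of this MAR strategy
to study, extend, or benchmark against.

## Worked example

```python
import numpy as np
from mvmar.phantom import make_pair
from mvmar.fusion import apply_mar
from mvmar.translator import SurrogateTranslator
from mvmar.metrics import artifact_index, psnr, ssim

pair = make_pair(seed=200, with_metal=True)      # steel/titanium dentures
sct, metal = apply_mar(pair.ct, pair.mv, SurrogateTranslator())

soft = pair.mask("soft_core")
print("metal pixels:", int(metal.mask.sum()))
print("streak index CT :", round(artifact_index(pair.ct, soft, pair.mask("metal"), truth=pair.truth), 1))
print("streak index sCT:", round(artifact_index(sct, soft, pair.mask("metal"), truth=pair.truth), 1))
print("PSNR sCT vs truth:", round(psnr(pair.truth, sct), 1), "dB")
print("SSIM sCT vs truth:", round(ssim(pair.truth.plane, sct.plane), 3))
```

prints

```
metal pixels: 69
streak index CT : 669.9
streak index sCT: 73.7
PSNR sCT vs truth: 30.3 dB
SSIM sCT vs truth: 0.947
```

The streak index (the excess 5–95 HU spread over soft tissue near metal)
drops by ~90%: the sCT inherits the MV image's freedom from streaks while
restoring CT-like contrast, and the metal itself is the original CT
pixels.  A CLI wraps the same steps
(`mvmar simulate`, `mvmar mar`, `mvmar eval-image`, `mvmar eval-dose`,
`mvmar run`); see `mvmar --help`.

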