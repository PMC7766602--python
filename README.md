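# capedema

Quantitative assessment of **pericapillary edema** from optical microscopy of
the skin, for researchers working with nailfold video capillaroscopy (NVC)
and in-vivo reflectance confocal laser scanning microscopy (CLSM).

Fluid accumulation in the interstitial space and viable epidermis changes how
capillaries look long before it is clinically obvious: NVC frames acquire a
"foggy" appearance as scattering contrast is lost, capillary lumina dilate
under raised venous pressure, and dermal papillae in CLSM cross-sections
become hyporefractive. `capedema` turns those observations into numbers:

* **NVC image sharpness** — the frame (or a first-row-capillary ROI) is
  band-pass filtered with a difference of Gaussians,
  `DoG(I) = G_{σ_low} * I − G_{σ_high} * I` with σ_low = 0.5 px and
  σ_high = 8 px, and scored by the mean absolute amplitude
  `S = mean |DoG(I)|`. `S` is zero on featureless frames, linear in
  intensity, and drops monotonically as edema blurs the capillaries.
  Time courses of `S` around an intervention are summarized by a cubic
  least-squares smoothing spline (minimum and recovery time reported).
* **Vessel size** — in a CLSM cross-section the dark lumen is segmented by
  Gaussian smoothing (σ = 15 px default) followed by a relative threshold
  (pixels below 20% of the smoothed maximum), keeping the largest connected
  component; size is `√area`, reported in px and μm.
* **Papilla brightness** — the gain-invariant contrast ratio
  `B = 100 · mean(papilla) / (mean(ring) − mean(lumen))` over supplied
  papilla / melanin-ring / lumen masks; hyporefractivity lowers `B`.
* **Group statistics** — Kruskal–Wallis omnibus (tie-corrected; exact
  permutation enumeration for n ≤ 10) with Bonferroni-corrected pairwise
  Mann–Whitney tests and 1.5×IQR box summaries.
* **Phantoms** — seeded synthetic generators (blurred hairpin capillaries,
  concentric papilla cross-sections, before/after effect datasets, sharpness
  time courses) with exact ground truth, so the whole pipeline is validated
  closed-loop.

## Worked example

```python
import numpy as np
from capedema import phantoms as ph
from capedema import sharpness, segment_vessel, papilla_brightness, VesselSegParams

# 1. sharpness collapses as a model capillary is blurred
for sigma in (0.5, 3.8, 7.2, 11, 14, 17):
    img, _ = ph.make_capillary_phantom(ph.CapillaryPhantomSpec(blur_sigma=sigma))
    print(f"blur sigma {sigma:5.1f}  sharpness {sharpness(img).value:.5f}")

# 2. lumen size of a papilla cross-section phantom (true radius 20 px)
img, seg = ph.make_papilla_phantom(ph.PapillaPhantomSpec(lumen_radius_px=20.0))
m = segment_vessel(img, VesselSegParams(smooth_sigma=0.5))
print(f"lumen size {m.size_px:.2f} px (ideal {20*np.sqrt(np.pi):.2f})")

# 3. papilla brightness of an exact-mask phantom
img, seg = ph.make_papilla_phantom(ph.PapillaPhantomSpec(intensities=(0.0, 0.25, 1.0, 0.5)))
print(f"papilla brightness {papilla_brightness(img, seg).value:.1f}")
```

prints

```
blur sigma   0.5  sharpness 0.02772
blur sigma   3.8  sharpness 0.01713
blur sigma   7.2  sharpness 0.00990
blur sigma  11.0  sharpness 0.00544
blur sigma  14.0  sharpness 0.00340
blur sigma  17.0  sharpness 0.00218
lumen size 35.45 px (ideal 35.45)
papilla brightness 25.0
```

The sharpness column falls strictly with blur — the behaviour that makes the
score usable as an edema marker; the segmented lumen size matches the ideal
disk value `r√π`; and the brightness ratio reproduces its closed form
`100 × 0.25 / (1.0 − 0.0) = 25`.

The same operations are available from the shell:

```bash
capedema simulate capillary --out scratch/phantom
capedema sharpness scratch/phantom/capillary.tiff
capedema validate --seed 1234 --out scratch/validation   # full closed-loop suite
```

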