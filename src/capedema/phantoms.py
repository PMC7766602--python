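"""Synthetic phantoms with exact ground truth for pipeline validation.

No microscopy images ship with this package; phantoms emulate the image
structure the metrics assume, so every downstream quantity has an
analytically known true value:

* a dark hairpin (U-shaped) capillary on a bright background, optionally
  Gaussian-blurred — the geometry nailfold capillaries show in NVC, with
  edges at many orientations so the sharpness score is orientation-fair;
* a concentric CLSM papilla cross-section: dark lumen disk, gray papilla
  annulus, melanin-bright ring, mid-gray background;
* paired before/after datasets for three effect models — venous-occlusion
  dilation, histamine hyporefractivity, histamine blur;
* sharpness time courses with a step drop at an event time and
  exponential recovery.

All generators are bit-reproducible given (spec, seed).  The hairpin is
rendered with 4x supersampling (box down-sampling) so sub-pixel edge
placement keeps blur-series monotonicity robust; the papilla phantom uses
pixel-center assignment so its intensity regions coincide exactly with
the ground-truth masks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from capedema.imagemodel import CalibratedImage, RoiMask
from capedema.clsm_morphometry import PapillaSegmentation
from capedema.nvc_sharpness import SharpnessSeries


class SpecError(ValueError):
    """Phantom specification violates its invariants."""


_SUPERSAMPLE = 4


# ---------------------------------------------------------------------------
# Hairpin capillary phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CapillaryPhantomSpec:
    """Single dark hairpin capillary on a uniform bright background.

    The tube follows two vertical limbs joined by a semicircular apex;
    ``limb_separation_px`` is the centre-to-centre limb distance (also
    the apex arc diameter).  ``contrast`` is the background-minus-lumen
    intensity gap on the [0, 1] scale.
    """

    frame_px: tuple[int, int] = (256, 256)
    limb_length_px: float = 120.0
    limb_separation_px: float = 48.0
    tube_width_px: float = 12.0
    contrast: float = 0.5
    background: float = 0.9
    blur_sigma: float = 0.0
    noise_sigma: float = 0.0
    pitch_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.contrast <= self.background <= 1):
            raise SpecError("need 0 < contrast <= background <= 1")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise SpecError("blur_sigma and noise_sigma must be >= 0")
        if self.tube_width_px <= 0 or self.limb_separation_px <= 0 or self.limb_length_px <= 0:
            raise SpecError("hairpin geometry must be positive")
        rows, cols = self.frame_px
        half = self.tube_width_px / 2
        arc_r = self.limb_separation_px / 2
        height = arc_r + half + self.limb_length_px
        width = self.limb_separation_px + self.tube_width_px
        if height > rows - 4 or width > cols - 4:
            raise SpecError(
                f"hairpin ({height:.0f}x{width:.0f} px) does not fit frame {self.frame_px}")


def _hairpin_distance(y: np.ndarray, x: np.ndarray, spec: CapillaryPhantomSpec
                      ) -> np.ndarray:
    """Distance from each point to the hairpin centreline."""
    rows, cols = spec.frame_px
    arc_r = spec.limb_separation_px / 2
    half = spec.tube_width_px / 2
    cx = cols / 2
    cy = (rows - (arc_r + half + spec.limb_length_px)) / 2 + arc_r + half
    y0 = cy                       # apex-circle centre row; limbs run downward
    y1 = cy + spec.limb_length_px

    dy = np.clip(y, y0, y1) - y   # 0 inside limb extent
    d_left = np.hypot(x - (cx - arc_r), dy)
    d_right = np.hypot(x - (cx + arc_r), dy)
    r = np.hypot(x - cx, y - y0)
    d_arc = np.abs(r - arc_r)
    d_arc = np.where(y <= y0, d_arc, np.inf)  # arc only above the limb tops
    return np.minimum(np.minimum(d_left, d_right), d_arc)


def make_capillary_phantom(spec: CapillaryPhantomSpec
                           ) -> tuple[CalibratedImage, RoiMask]:
    """Render the hairpin phantom and its pre-blur ground-truth lumen mask."""
    rows, cols = spec.frame_px
    ss = _SUPERSAMPLE
    # supersampled pixel centres
    yy = (np.arange(rows * ss) + 0.5) / ss
    xx = (np.arange(cols * ss) + 0.5) / ss
    Y, X = np.meshgrid(yy, xx, indexing="ij")
    tube = _hairpin_distance(Y, X, spec) <= spec.tube_width_px / 2
    coverage = tube.reshape(rows, ss, cols, ss).mean(axis=(1, 3))

    img = spec.background - spec.contrast * coverage
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma, mode="reflect", truncate=4.0)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)

    label = (f"capillary_phantom(blur={spec.blur_sigma},noise={spec.noise_sigma},"
             f"seed={spec.seed})")
    return (CalibratedImage(img, spec.pitch_um, "float", label),
            RoiMask("tube", coverage >= 0.5))


# ---------------------------------------------------------------------------
# Papilla cross-section phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PapillaPhantomSpec:
    """Concentric CLSM papilla cross-section: lumen / papilla / melanin ring.

    ``boundary_noise_px`` adds seeded zero-mean angular roughness to the
    lumen contour (low-order Fourier modes of the given RMS amplitude),
    emulating the irregular vessel outline of real cross-sections without
    changing the enclosed area to first order.
    """

    frame_px: tuple[int, int] = (201, 201)
    lumen_radius_px: float = 20.0
    papilla_outer_radius_px: float = 45.0
    ring_outer_radius_px: float = 60.0
    intensities: tuple[float, float, float, float] = (0.05, 0.40, 0.95, 0.55)
    noise_sigma: float = 0.0
    boundary_noise_px: float = 0.0
    pitch_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        r1, r2, r3 = (self.lumen_radius_px, self.papilla_outer_radius_px,
                      self.ring_outer_radius_px)
        if not (0 < r1 < r2 < r3):
            raise SpecError("need 0 < lumen < papilla_outer < ring_outer radii")
        il, ip, ir, ib = self.intensities
        if not (ir > ip > il):
            raise SpecError("need ring > papilla > lumen intensity")
        if not all(0 <= v <= 1 for v in self.intensities):
            raise SpecError("intensities must lie in [0, 1]")
        if self.noise_sigma < 0 or self.boundary_noise_px < 0:
            raise SpecError("noise amplitudes must be >= 0")
        if self.boundary_noise_px >= 0.5 * (r2 - r1):
            raise SpecError("boundary roughness would breach the papilla annulus")
        rows, cols = self.frame_px
        if 2 * r3 >= min(rows, cols):
            raise SpecError("ring does not fit inside the frame")


def make_papilla_phantom(spec: PapillaPhantomSpec
                         ) -> tuple[CalibratedImage, PapillaSegmentation]:
    """Render the concentric phantom and its exact ground-truth masks.

    Pixels are assigned to a zone by their centre distance from the frame
    centre, so the returned masks partition the intensity regions exactly
    (no anti-aliased boundary pixels): formula-level checks on the
    brightness ratio hold to machine precision at zero noise.
    """
    rows, cols = spec.frame_px
    cy, cx = (rows - 1) / 2, (cols - 1) / 2
    Y, X = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    d = np.hypot(Y - cy, X - cx)
    rng = np.random.default_rng(spec.seed)

    lumen_edge = np.full_like(d, spec.lumen_radius_px)
    if spec.boundary_noise_px > 0:
        # zero-mean angular roughness: Fourier modes k=2..6 (k=0 would
        # rescale the area, k=1 merely translates the contour)
        theta = np.arctan2(Y - cy, X - cx)
        ks = np.arange(2, 7)
        a = rng.standard_normal(ks.size)
        b = rng.standard_normal(ks.size)
        eps = sum(a[i] * np.cos(k * theta) + b[i] * np.sin(k * theta)
                  for i, k in enumerate(ks))
        rms = np.sqrt((a**2 + b**2).sum() / 2.0)
        lumen_edge = lumen_edge + eps * (spec.boundary_noise_px / rms)

    lumen = d <= lumen_edge
    papilla = (d > lumen_edge) & (d <= spec.papilla_outer_radius_px)
    ring = (d > spec.papilla_outer_radius_px) & (d <= spec.ring_outer_radius_px)

    il, ip, ir, ib = spec.intensities
    img = np.full((rows, cols), ib, dtype=float)
    img[lumen] = il
    img[papilla] = ip
    img[ring] = ir
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)

    label = f"papilla_phantom(r={spec.lumen_radius_px},noise={spec.noise_sigma},seed={spec.seed})"
    seg = PapillaSegmentation(
        papilla=RoiMask("papilla", papilla),
        ring=RoiMask("ring", ring),
        lumen=RoiMask("lumen", lumen),
    )
    return CalibratedImage(img, spec.pitch_um, "float", label), seg


# ---------------------------------------------------------------------------
# Effect models (before/after pairs)
# ---------------------------------------------------------------------------

EffectKind = Literal["occlusion_dilation", "histamine_hyporefractivity", "histamine_blur"]

_MAGNITUDE_RANGES: dict[str, tuple[float, float]] = {
    "occlusion_dilation": (1.0, 1.5),        # lumen-radius factor
    "histamine_hyporefractivity": (0.0, 1.0),  # papilla-intensity drop fraction
    "histamine_blur": (0.0, 30.0),           # post-event blur sigma (px)
}


@dataclass(frozen=True)
class EffectModel:
    """A before/after intervention applied to a phantom population.

    ``magnitude`` semantics per kind: radius multiplier (occlusion),
    fractional papilla-intensity drop (hyporefractivity), or the new blur
    sigma in px (histamine blur).
    """

    kind: EffectKind
    magnitude: float
    n_pairs: int = 12
    boundary_noise_px: float = 1.0
    population_spread: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _MAGNITUDE_RANGES:
            raise SpecError(f"unknown effect kind {self.kind!r}")
        lo, hi = _MAGNITUDE_RANGES[self.kind]
        if not (lo < self.magnitude <= hi):
            raise SpecError(
                f"magnitude {self.magnitude} outside ({lo}, {hi}] for kind {self.kind!r}")
        if self.n_pairs < 1:
            raise SpecError("n_pairs must be >= 1")


def make_effect_dataset(model: EffectModel,
                        base_spec: CapillaryPhantomSpec | PapillaPhantomSpec | None = None,
                        ) -> dict:
    """Generate paired before/after phantoms under one effect model.

    Returns ``{"pairs": [...], "model": model, "manifest": [...]}`` where
    each pair holds the two rendered images (plus ground-truth masks /
    segmentations) and the manifest records the per-pair true parameters,
    sufficient to compute every downstream metric's true value.
    """
    rng = np.random.default_rng(model.seed)
    pairs: list[dict] = []
    manifest: list[dict] = []

    if model.kind in ("occlusion_dilation", "histamine_hyporefractivity"):
        base = base_spec if base_spec is not None else PapillaPhantomSpec()
        if not isinstance(base, PapillaPhantomSpec):
            raise SpecError(f"{model.kind} needs a PapillaPhantomSpec base")
    else:
        base = base_spec if base_spec is not None else CapillaryPhantomSpec(blur_sigma=0.5)
        if not isinstance(base, CapillaryPhantomSpec):
            raise SpecError("histamine_blur needs a CapillaryPhantomSpec base")

    for i in range(model.n_pairs):
        seed_b = int(rng.integers(0, 2**31 - 1))
        seed_a = int(rng.integers(0, 2**31 - 1))
        if model.kind == "occlusion_dilation":
            # per-subject mean lumen radius; fresh boundary roughness per frame
            r_i = base.lumen_radius_px * float(
                1.0 + model.population_spread * rng.uniform(-1.0, 1.0))
            r_a = r_i * model.magnitude
            sb = replace(base, lumen_radius_px=r_i, seed=seed_b,
                         boundary_noise_px=model.boundary_noise_px)
            sa = replace(base, lumen_radius_px=r_a, seed=seed_a,
                         boundary_noise_px=model.boundary_noise_px)
            img_b, seg_b = make_papilla_phantom(sb)
            img_a, seg_a = make_papilla_phantom(sa)
            truth = {"radius_before": r_i, "radius_after": r_a,
                     "area_ratio": (r_a / r_i) ** 2}
        elif model.kind == "histamine_hyporefractivity":
            il, ip, ir, ib = base.intensities
            sb = replace(base, seed=seed_b)
            sa = replace(base, intensities=(il, ip * (1.0 - model.magnitude), ir, ib),
                         seed=seed_a)
            img_b, seg_b = make_papilla_phantom(sb)
            img_a, seg_a = make_papilla_phantom(sa)
            truth = {"papilla_before": ip,
                     "papilla_after": ip * (1.0 - model.magnitude),
                     "brightness_ratio": 1.0 - model.magnitude}
        else:  # histamine_blur
            sb = replace(base, seed=seed_b)
            sa = replace(base, blur_sigma=model.magnitude, seed=seed_a)
            img_b, seg_b = make_capillary_phantom(sb)
            img_a, seg_a = make_capillary_phantom(sa)
            truth = {"sigma_before": base.blur_sigma, "sigma_after": model.magnitude}

        pairs.append({"before": img_b, "after": img_a,
                      "before_truth": seg_b, "after_truth": seg_a})
        manifest.append({"pair": i, "seed_before": seed_b, "seed_after": seed_a,
                         **truth})

    return {"pairs": pairs, "model": model, "manifest": manifest}


# ---------------------------------------------------------------------------
# Sharpness time course
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeCourseSpec:
    """Step drop at an event time with exponential return to baseline.

    value(t) = baseline for t < event_time, and
    baseline * (1/drop_factor + (1 - 1/drop_factor) * (1 - exp(-(t - event_time)/tau)))
    afterwards, i.e. an instantaneous drop by ``drop_factor`` followed by
    recovery with time constant ``recovery_tau``.
    """

    baseline: float = 1.0
    drop_factor: float = 2.0
    recovery_tau: float = 10.0
    event_time: float = 0.0
    times: tuple[float, ...] = tuple(float(t) for t in range(-15, 45))
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.drop_factor <= 1:
            raise SpecError("drop_factor must be > 1")
        if self.recovery_tau <= 0:
            raise SpecError("recovery_tau must be > 0")
        if self.baseline <= 0:
            raise SpecError("baseline must be > 0")
        t = self.times
        if len(t) < 2 or any(b <= a for a, b in zip(t, t[1:])):
            raise SpecError("times must be strictly increasing, >= 2 points")
        if self.noise_sigma < 0:
            raise SpecError("noise_sigma must be >= 0")


def timecourse_model(spec: TimeCourseSpec, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    floor = spec.baseline / spec.drop_factor
    rec = 1.0 - np.exp(-np.maximum(t - spec.event_time, 0.0) / spec.recovery_tau)
    post = floor + (spec.baseline - floor) * rec
    return np.where(t < spec.event_time, spec.baseline, post)


def make_timecourse(spec: TimeCourseSpec) -> tuple[SharpnessSeries, SharpnessSeries]:
    """Return (noise-free ground truth, noisy observation) series."""
    t = np.asarray(spec.times)
    clean = timecourse_model(spec, t)
    rng = np.random.default_rng(spec.seed)
    noisy = clean + rng.normal(0.0, spec.noise_sigma, clean.shape)
    return (SharpnessSeries(tuple(t), tuple(clean), spec.event_time),
            SharpnessSeries(tuple(t), tuple(noisy), spec.event_time))
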