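"""Batch orchestration: study manifests → tidy metric tables → statistics,
plus the seeded synthetic validation run.

A study manifest is a CSV (or DataFrame) with columns
``image,subject,condition,timestamp,annotation,pitch_um`` — one row per
acquired frame.  :func:`run_study` computes the requested metrics per
frame (per ROI where rectangles are annotated), summarizes each condition
with box statistics, and compares conditions with Bonferroni-corrected
pairwise rank tests.  Per-record failures (missing files, absent
annotations) are collected into an error report; the run continues —
clinical batches tolerate partial annotation.

:func:`run_validation` regenerates every phantom family, pushes it
through the metrics, and checks the closed-loop recovery properties
(blur monotonicity, disk-size recovery, brightness formula, effect-size
recovery, time-course minimum, type-I error of the statistics stage).
Its report is deterministic given the seed: two runs with the same seed
produce byte-identical report bodies.
"""

from __future__ import annotations

import json
import os
from dataclasses import replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from capedema import __version__ as _pkg_version
from capedema import phantoms as ph
from capedema.clsm_morphometry import (
    PapillaSegmentation,
    VesselSegParams,
    brightness_cohort_summary,
    papilla_brightness,
    segment_vessel,
    vessel_size_change,
)
from capedema.group_stats import (
    GroupedSamples,
    box_summary,
    kruskal_wallis,
    pairwise_bonferroni,
)
from capedema.imagemodel import (
    CalibratedImage,
    DEFAULT_CONFIG,
    RoiMask,
    RoiRect,
    crop,
    load_image,
    load_rois,
    normalize_unit,
)
from capedema.nvc_sharpness import DoGParams, fit_timecourse, sharpness

MANIFEST_COLUMNS = ["image", "subject", "condition", "timestamp", "annotation", "pitch_um"]

LABEL_CODES = {1: "lumen", 2: "papilla", 3: "ring"}  # label-raster convention


class RunError(RuntimeError):
    """Zero usable records in a batch run."""


def load_manifest(path_or_df) -> pd.DataFrame:
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, dtype=str).fillna("")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    df["pitch_um"] = df["pitch_um"].astype(float)
    if (df["pitch_um"] <= 0).any():
        raise ValueError("manifest pitch_um must be > 0")
    return df


def _segmentation_from_annotation(path: str, shape: tuple[int, int]) -> PapillaSegmentation:
    """Papilla/ring/lumen masks from a label raster or a polygon JSON."""
    if path.lower().endswith((".png", ".tif", ".tiff")):
        labels = load_image(path, pitch_um=1.0).pixels.astype(int)
        masks = {name: labels == code for code, name in LABEL_CODES.items()}
    else:
        rois = load_rois(path, image_shape=shape)
        masks = {}
        for r in rois:
            if isinstance(r, RoiMask) and r.name in ("papilla", "ring", "lumen"):
                masks[r.name] = r.mask
        if set(masks) != {"papilla", "ring", "lumen"}:
            raise ValueError(
                f"annotation {path!r} must provide polygon masks named papilla, ring, lumen")
    return PapillaSegmentation(
        papilla=RoiMask("papilla", masks["papilla"]),
        ring=RoiMask("ring", masks["ring"]),
        lumen=RoiMask("lumen", masks["lumen"]),
    )


def run_study(manifest, config: dict | None = None,
              metrics: Sequence[str] = ("sharpness",)) -> dict:
    """Process a study manifest into metric rows plus group statistics.

    Returns a dict with keys ``results`` (long-format DataFrame: one row
    per image x ROI x metric), ``summaries`` (per metric, per condition
    box stats), ``comparisons`` (per metric, pairwise Bonferroni results
    across conditions, skipped with a notice for single-condition runs),
    ``percent_change`` (medians, two-condition designs only), ``errors``
    (per-record failure report) and ``params`` (full parameter echo).
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    df = load_manifest(manifest)
    dog = DoGParams(cfg["sigma_low"], cfg["sigma_high"])
    seg_params = VesselSegParams(smooth_sigma=cfg["smooth_sigma"],
                                 threshold_frac=cfg["threshold_frac"])

    rows: list[dict] = []
    errors: list[dict] = []
    for idx, rec in df.iterrows():
        try:
            img = load_image(rec["image"], float(rec["pitch_um"]))
            if cfg["normalize"]:
                img = normalize_unit(img)
            rects: list[RoiRect] = []
            if rec["annotation"] and any(m in metrics for m in ("sharpness", "vessel_size")):
                if rec["annotation"].lower().endswith((".json", ".csv")) or \
                        "papilla_brightness" not in metrics:
                    try:
                        rects = [r for r in load_rois(rec["annotation"], img.shape)
                                 if isinstance(r, RoiRect)]
                    except Exception:
                        rects = []

            for metric in metrics:
                if metric == "sharpness":
                    targets = rects or [None]
                    for roi in targets:
                        sv = sharpness(img, dog, roi)
                        rows.append(dict(image=rec["image"], subject=rec["subject"],
                                         condition=rec["condition"],
                                         roi=roi.name if roi else "frame",
                                         metric="sharpness", value=sv.value))
                elif metric == "vessel_size":
                    if not rects:
                        raise ValueError("vessel_size requires rectangle ROIs")
                    for roi in rects:
                        m = segment_vessel(crop(img, roi), seg_params)
                        rows.append(dict(image=rec["image"], subject=rec["subject"],
                                         condition=rec["condition"], roi=roi.name,
                                         metric="vessel_size_px", value=m.size_px))
                        rows.append(dict(image=rec["image"], subject=rec["subject"],
                                         condition=rec["condition"], roi=roi.name,
                                         metric="vessel_size_um", value=m.size_um))
                elif metric == "papilla_brightness":
                    if not rec["annotation"]:
                        raise ValueError("papilla_brightness requires a mask annotation")
                    seg = _segmentation_from_annotation(rec["annotation"], img.shape)
                    pb = papilla_brightness(img, seg)
                    rows.append(dict(image=rec["image"], subject=rec["subject"],
                                     condition=rec["condition"], roi="capillary",
                                     metric="papilla_brightness", value=pb.value))
                else:
                    raise ValueError(f"unknown metric {metric!r}")
        except Exception as exc:
            errors.append(dict(record=int(idx), image=rec["image"], error=str(exc)))

    if not rows:
        raise RunError(f"no usable records ({len(errors)} errors)")
    results = pd.DataFrame(rows)

    summaries: dict = {}
    comparisons: dict = {}
    pct_change: dict = {}
    for metric, sub in results.groupby("metric"):
        by_cond = {c: list(g["value"]) for c, g in sub.groupby("condition", sort=False)}
        summaries[metric] = {c: vars(box_summary(v)) for c, v in by_cond.items()}
        usable = {c: v for c, v in by_cond.items() if len(v) >= 2}
        if len(usable) >= 2:
            comp = pairwise_bonferroni(GroupedSamples(usable))
            comparisons[metric] = comp
        else:
            comparisons[metric] = "skipped: fewer than 2 conditions with n >= 2"
        if len(by_cond) == 2:
            (ca, va), (cb, vb) = by_cond.items()
            if "before" in by_cond and ca != "before":
                (ca, va), (cb, vb) = (cb, vb), (ca, va)
            mb, ma = float(np.median(va)), float(np.median(vb))
            if mb != 0:
                pct_change[metric] = {"from": ca, "to": cb,
                                      "percent_change_of_medians": 100.0 * (ma - mb) / mb}

    return {
        "results": results,
        "summaries": summaries,
        "comparisons": comparisons,
        "percent_change": pct_change,
        "errors": errors,
        "params": {"config": cfg, "metrics": list(metrics), "version": _pkg_version},
    }


# ---------------------------------------------------------------------------
# Synthetic validation run
# ---------------------------------------------------------------------------

BLUR_SERIES = (0.5, 3.8, 7.2, 11.0, 14.0, 17.0)


def run_validation(seed: int = 1,
                   out_dir: str | os.PathLike | None = None,
                   quick: bool = False,
                   image_hook: Callable[[np.ndarray], np.ndarray] | None = None,
                   ) -> dict:
    """Closed-loop validation on seeded phantoms; see module docstring.

    ``image_hook``, applied to every capillary-phantom raster before the
    metrics, exists as a negative-control handle: corrupting the images
    must make the relevant properties fail.  ``quick`` shrinks the type-I
    simulation for smoke tests.
    """
    rng = np.random.default_rng(seed)
    report: dict = {"seed": int(seed), "version": _pkg_version, "properties": {}}

    def record(name: str, passed: bool, **info) -> None:
        report["properties"][name] = {"pass": bool(passed),
                                      **{k: _jsonable(v) for k, v in info.items()}}

    def hooked(img: CalibratedImage) -> CalibratedImage:
        if image_hook is None:
            return img
        return CalibratedImage(np.clip(image_hook(img.pixels), 0, None),
                               img.pitch_um, "float", img.origin_label + "|hooked")

    # -- blur monotonicity of the sharpness score -------------------------
    vals = []
    for s in BLUR_SERIES:
        img, _ = ph.make_capillary_phantom(ph.CapillaryPhantomSpec(blur_sigma=s))
        vals.append(sharpness(hooked(img)).value)
    mono = all(b < a for a, b in zip(vals, vals[1:]))
    washout = vals[-1] < 0.25 * vals[0]
    record("blur_monotonicity", mono and washout,
           blur_sigmas=BLUR_SERIES, sharpness=vals,
           ratio_last_to_first=vals[-1] / vals[0])

    # -- null and linearity ----------------------------------------------
    const = CalibratedImage(np.full((64, 64), 0.5), 1.0)
    s0 = sharpness(const).value
    img, _ = ph.make_capillary_phantom(ph.CapillaryPhantomSpec())
    s1 = sharpness(hooked(img)).value
    s2 = sharpness(CalibratedImage(2.0 * hooked(img).pixels, 1.0)).value
    lin_err = abs(s2 - 2 * s1) / (2 * s1)
    record("null_and_linearity", s0 < 1e-12 and lin_err < 1e-9,
           constant_sharpness=s0, linearity_rel_err=lin_err)

    # -- vessel-size recovery on noiseless disks --------------------------
    radii = (10, 15, 20, 25, 30)
    sizes, errs = [], []
    for r in radii:
        spec = ph.PapillaPhantomSpec(lumen_radius_px=float(r),
                                     papilla_outer_radius_px=r + 25.0,
                                     ring_outer_radius_px=r + 40.0)
        pimg, _ = ph.make_papilla_phantom(spec)
        m = segment_vessel(pimg, VesselSegParams(smooth_sigma=0.5))
        sizes.append(m.size_px)
        errs.append(abs(m.size_px / (r * np.sqrt(np.pi)) - 1.0))
    record("vessel_size_recovery",
           max(errs) < 0.05 and all(b > a for a, b in zip(sizes, sizes[1:])),
           radii=radii, sizes_px=sizes, max_rel_err=max(errs))

    # -- papilla-brightness closed form -----------------------------------
    pimg, seg = ph.make_papilla_phantom(
        ph.PapillaPhantomSpec(intensities=(0.0, 0.25, 1.0, 0.5)))
    v1 = papilla_brightness(pimg, seg).value
    v2 = papilla_brightness(
        CalibratedImage(2.0 * pimg.pixels, 1.0), seg).value
    record("papilla_brightness_formula",
           abs(v1 - 25.0) < 1e-6 and abs(v2 - v1) < 1e-9,
           value=v1, gain_doubled_value=v2)

    # -- hyporefractivity recovery ----------------------------------------
    ds = ph.make_effect_dataset(
        ph.EffectModel("histamine_hyporefractivity", 0.20, n_pairs=12,
                       seed=int(rng.integers(2**31 - 1))),
        ph.PapillaPhantomSpec(noise_sigma=0.02))
    meas, labels = [], []
    for pair in ds["pairs"]:
        meas.append(papilla_brightness(pair["before"], pair["before_truth"]))
        labels.append("before")
        meas.append(papilla_brightness(pair["after"], pair["after_truth"]))
        labels.append("after")
    summ = brightness_cohort_summary(meas, labels)
    comp = pairwise_bonferroni(GroupedSamples({
        "before": [m.value for m, l in zip(meas, labels) if l == "before"],
        "after": [m.value for m, l in zip(meas, labels) if l == "after"]}))
    hypo_change = summ["percent_change"]
    record("hyporefractivity_recovery",
           abs(hypo_change + 20.0) <= 3.0 and comp.pairwise[0][2] < 0.05,
           percent_change=hypo_change, adjusted_p=comp.pairwise[0][2])

    # -- occlusion (dilation) recovery ------------------------------------
    ds = ph.make_effect_dataset(
        ph.EffectModel("occlusion_dilation", 1.10, n_pairs=20,
                       seed=int(rng.integers(2**31 - 1))))
    p = VesselSegParams(smooth_sigma=2.0)
    before = [segment_vessel(pair["before"], p) for pair in ds["pairs"]]
    after = [segment_vessel(pair["after"], p) for pair in ds["pairs"]]
    occ_change = vessel_size_change(before, after)
    record("occlusion_recovery", abs(occ_change - 10.0) <= 3.0,
           percent_change=occ_change)

    # -- time-course fit ---------------------------------------------------
    tc_spec = ph.TimeCourseSpec(seed=int(rng.integers(2**31 - 1)))
    _, noisy = ph.make_timecourse(tc_spec)
    # smoothing by the discrepancy principle: expected residual = n * sigma^2
    fit = fit_timecourse(noisy, smoothing_factor=len(noisy) * tc_spec.noise_sigma**2)
    dt = np.median(np.diff(tc_spec.times))
    tmin_off = abs(fit.t_min - tc_spec.event_time) / dt
    t_check = tc_spec.event_time + 4 * tc_spec.recovery_tau
    recovered = float(fit.predict(t_check)) >= 0.9 * fit.baseline
    record("timecourse_fit", tmin_off <= 2.0 and recovered,
           t_min=fit.t_min, t_min_offset_samples=tmin_off,
           fit_at_4tau=float(fit.predict(t_check)), baseline=fit.baseline)

    # -- type-I error of the statistics stage ------------------------------
    reps = 100 if quick else 1000
    srng = np.random.default_rng(seed + 202)
    rejections = 0
    for _ in range(reps):
        g = {k: srng.normal(size=20) for k in ("a", "b", "c")}
        _, pval = kruskal_wallis(GroupedSamples(g))
        rejections += pval < 0.05
    rate = rejections / reps
    from scipy.stats import binom
    lo = binom.ppf(0.005, reps, 0.05) / reps
    hi = binom.ppf(0.995, reps, 0.05) / reps
    record("stats_type1", lo <= rate <= hi,
           rejection_rate=rate, n_reps=reps, interval=(float(lo), float(hi)))

    report["all_pass"] = all(p["pass"] for p in report["properties"].values())
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "validation_report.json"), "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return report


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
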