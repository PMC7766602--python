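"""NVC image-sharpness metric and its time-course analysis.

The sharpness of a capillaroscopy frame is scored by band-pass filtering
with a difference of Gaussians (narrow minus wide, sigma_low = 0.5 px and
sigma_high = 8 px by default) and taking the mean absolute amplitude of
the filtered image.  The DoG stage passes only small, sharply bordered
objects — first-row capillaries — so the score collapses when epidermal
water accumulation blurs them.

The metric is linear in intensity scale; compare images on a declared
common scale (see :func:`capedema.imagemodel.normalize_unit`).  Time
courses of sharpness around an intervention (e.g. topical histamine) are
summarized by a least-squares cubic smoothing spline, from which the
minimum and the recovery time are read off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.interpolate import UnivariateSpline

from capedema.imagemodel import CalibratedImage, DegenerateInputError, RoiRect, crop

logger = logging.getLogger(__name__)

_TRUNCATE = 4.0  # kernel truncation radius in sigmas


class SizeError(ValueError):
    """Raster too small for the requested filter."""


class OrderingError(ValueError):
    """Time axis not strictly increasing."""


class FitError(ValueError):
    """Too few points (or otherwise unusable series) for spline fitting."""


@dataclass(frozen=True)
class DoGParams:
    """Difference-of-Gaussians band-pass parameters (pixels)."""

    sigma_low: float = 0.5
    sigma_high: float = 8.0

    def __post_init__(self) -> None:
        if not (0 < self.sigma_low < self.sigma_high):
            raise ValueError(
                f"need 0 < sigma_low < sigma_high, got {self.sigma_low}, {self.sigma_high}")


@dataclass(frozen=True)
class SharpnessValue:
    """Mean |DoG| amplitude of one image region."""

    value: float
    params: DoGParams
    roi_name: str = ""

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("sharpness is non-negative by construction")


@dataclass(frozen=True)
class SharpnessSeries:
    """Sharpness sampled over time (seconds or frame index)."""

    times: tuple[float, ...]
    values: tuple[float, ...]
    event_time: float | None = None

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.times)
        v = tuple(float(x) for x in self.values)
        if len(t) != len(v):
            raise ValueError("times and values must have equal length")
        if len(t) == 0:
            raise ValueError("empty series")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise OrderingError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class TimeCourseFit:
    """Cubic smoothing-spline summary of a sharpness time course.

    ``t_min`` is the argmin of the fitted curve over the observed span;
    ``recovery_time`` is the first time after ``t_min`` at which the fit
    re-attains ``recovery_fraction`` of the pre-event baseline (``None``
    if it never does within the span, or no event time was given).
    """

    tck: tuple
    smoothing_factor: float
    rmse: float
    t_min: float
    recovery_time: float | None
    baseline: float | None
    recovery_fraction: float
    flat: bool

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        from scipy.interpolate import splev
        return splev(t, self.tck)


# ---------------------------------------------------------------------------
# Filtering and the sharpness score
# ---------------------------------------------------------------------------

def _min_support(params: DoGParams) -> int:
    # only the narrow kernel bounds the admissible frame: the wide blur is
    # well defined on smaller frames via repeated reflection
    r = int(_TRUNCATE * params.sigma_low + 0.5)
    return 2 * r + 1

def dog_filter(image: CalibratedImage | np.ndarray,
               params: DoGParams = DoGParams()) -> np.ndarray:
    """Difference-of-Gaussians band-pass: G(sigma_low)*I - G(sigma_high)*I.

    Gaussian kernels are sampled, normalized and truncated at 4 sigma;
    boundaries are handled by reflection, which keeps constant rasters
    exactly constant (hence DoG exactly zero).  The output is signed.
    """
    px = image.pixels if isinstance(image, CalibratedImage) else np.asarray(image, float)
    need = _min_support(params)
    if min(px.shape) < need:
        raise SizeError(
            f"raster {px.shape} smaller than the narrow-kernel support ({need} px)")
    lo = ndimage.gaussian_filter(px, params.sigma_low, mode="reflect", truncate=_TRUNCATE)
    hi = ndimage.gaussian_filter(px, params.sigma_high, mode="reflect", truncate=_TRUNCATE)
    return lo - hi


def sharpness(image: CalibratedImage,
              params: DoGParams = DoGParams(),
              roi: RoiRect | None = None) -> SharpnessValue:
    """Mean absolute DoG amplitude of ``image`` (cropped to ``roi`` first).

    The score is 0 exactly for constant rasters and scales linearly with
    intensity: sharpness(a*I) = a*sharpness(I) for a >= 0.
    """
    if roi is not None:
        image = crop(image, roi)
    amp = np.abs(dog_filter(image, params))
    return SharpnessValue(float(amp.mean()), params, roi.name if roi else "")


# ---------------------------------------------------------------------------
# Relative sharpness and time-course fitting
# ---------------------------------------------------------------------------

def relative_sharpness(series: SharpnessSeries,
                       baseline_window: tuple[float, float] | None = None,
                       ) -> list[tuple[float, float]]:
    """Divide each point by the mean baseline sharpness.

    The baseline is the mean over ``baseline_window`` (closed interval) if
    given, else over all points before ``series.event_time``.  Baseline
    points map to ~1; a post-event drop by a factor f maps to ~1/f.
    """
    t = np.asarray(series.times)
    v = np.asarray(series.values)
    if baseline_window is not None:
        lo, hi = baseline_window
        sel = (t >= lo) & (t <= hi)
    elif series.event_time is not None:
        sel = t < series.event_time
    else:
        raise ValueError("need a baseline_window or an event_time on the series")
    if not sel.any():
        raise DegenerateInputError("baseline window contains no points")
    base = v[sel].mean()
    if base <= 0:
        raise DegenerateInputError("baseline mean is not positive")
    return [(float(ti), float(vi / base)) for ti, vi in zip(t, v)]


def _cv_smoothing(t: np.ndarray, v: np.ndarray) -> float:
    """Pick the spline smoothing factor by k-fold cross-validation.

    Candidate factors span from near-interpolation to near-regression on a
    log grid scaled by n*var(v); the factor minimizing out-of-fold squared
    error is returned.
    """
    import warnings

    n = len(t)
    scale = n * max(v.var(), 1e-30)
    grid = scale * np.logspace(-4, 1, 16)
    k = min(5, n - 3)
    folds = [np.arange(i, n, k) for i in range(k)]
    best, best_err = grid[-1], np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # fitpack maxit chatter
        for s in grid:
            err = 0.0
            ok = True
            for hold in folds:
                keep = np.setdiff1d(np.arange(n), hold)
                if len(keep) < 4:
                    ok = False
                    break
                try:
                    sp = UnivariateSpline(t[keep], v[keep], k=3, s=s * len(keep) / n)
                except Exception:
                    ok = False
                    break
                err += float(np.sum((sp(t[hold]) - v[hold]) ** 2))
            if ok and err < best_err:
                best, best_err = s, err
    return float(best)


def fit_timecourse(series: SharpnessSeries,
                   smoothing_factor: float | None = None,
                   recovery_fraction: float = 0.9,
                   ) -> TimeCourseFit:
    """Least-squares cubic smoothing spline through a sharpness series.

    Reports the fitted-curve minimum ``t_min`` over the span and, when the
    series carries an event time, the recovery time: the first instant
    after ``t_min`` at which the fit re-attains ``recovery_fraction`` of
    the pre-event baseline mean.  When ``smoothing_factor`` is omitted it
    is chosen by cross-validation.  Flat series are fitted and flagged
    rather than rejected — clinical series may be short or uneventful.
    """
    if len(series) < 4:
        raise FitError(f"need >= 4 points for a cubic smoothing spline, got {len(series)}")
    if smoothing_factor is not None and smoothing_factor < 0:
        raise FitError("smoothing_factor must be >= 0")
    t = np.asarray(series.times)
    v = np.asarray(series.values)

    flat = np.ptp(v) <= 1e-12 * max(1.0, abs(v.mean()))
    s = 0.0 if flat else (
        smoothing_factor if smoothing_factor is not None else _cv_smoothing(t, v))
    spline = UnivariateSpline(t, v, k=3, s=s)
    tck = tuple(spline._eval_args)  # full (t, c, k) triple for splev
    dense_t = np.linspace(t[0], t[-1], max(2000, 20 * len(t)))
    fit_vals = spline(dense_t)
    rmse = float(np.sqrt(np.mean((spline(t) - v) ** 2)))

    if flat:
        t_min = float(t[0])
    else:
        t_min = float(dense_t[int(np.argmin(fit_vals))])

    baseline = None
    recovery = None
    if series.event_time is not None:
        pre = v[t < series.event_time]
        if pre.size:
            baseline = float(pre.mean())
            target = recovery_fraction * baseline
            after = dense_t > t_min
            hit = after & (fit_vals >= target)
            if hit.any():
                recovery = float(dense_t[int(np.argmax(hit))])

    return TimeCourseFit(
        tck=tck,
        smoothing_factor=float(s),
        rmse=rmse,
        t_min=t_min,
        recovery_time=recovery,
        baseline=baseline,
        recovery_fraction=recovery_fraction,
        flat=bool(flat),
    )
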