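"""Intensity-based kinetic measurements.

Covers illumination flattening against a blank Gaussian-beam image, the
tubulin-mass profile over the convex hull of a network, the TPX2
binding-rate estimate from per-pixel kymograph slopes, and the
single-molecule intensity from Heaviside step fits to photobleaching
traces.  The binding rate in molecules µm⁻¹ s⁻¹ is
slope (au/s) / (single-molecule intensity (au) × pixel size (µm)); a
constant background offset does not affect the slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import morphology

from .imaging import ImageStack, KymographTruth, PhotobleachTrace

__all__ = [
    "SlopeFit",
    "StepFit",
    "IntensityProfile",
    "correct_illumination",
    "network_hull_mask",
    "tubulin_intensity_profile",
    "estimate_binding_rate",
    "fit_step_amplitude",
]


@dataclass
class SlopeFit:
    pixel: int
    slope_au_per_s: float
    window: tuple[int, int]  # fit frames [start, stop)
    rate: float  # molecules µm⁻¹ s⁻¹
    r2: float


@dataclass
class StepFit:
    trace: int
    amplitude: float
    step_frame: int
    residual: float
    r2: float
    flagged: bool = False


@dataclass
class IntensityProfile:
    bin_centers: np.ndarray  # normalized distance
    mean_intensity: np.ndarray  # normalized (hull mean = 1)
    sd: np.ndarray
    n_pixels: np.ndarray


def correct_illumination(
    image: np.ndarray,
    blank: np.ndarray,
    filter_size: int = 110,
    filter_sigma: float = 30.0,
    eps_frac: float = 1e-3,
) -> np.ndarray:
    """Flatten uneven Gaussian-beam illumination using a blank image.

    The blank is smoothed with a wide Gaussian (kernel ~filter_size px,
    sigma filter_sigma px) and the specimen image divided by it; the
    result is rescaled by the blank's mean so intensities keep their
    scale.  Pixels where the filtered blank falls below eps·max are
    masked (set to 0) with a warning.
    """
    image = np.asarray(image, dtype=float)
    blank = np.asarray(blank, dtype=float)
    if blank.shape != image.shape[-2:]:
        raise ValueError("blank must match the image field of view")
    truncate = filter_size / (2.0 * filter_sigma)
    fb = ndimage.gaussian_filter(blank, filter_sigma, truncate=truncate)
    eps = eps_frac * fb.max()
    low = fb < eps
    if low.any():
        warnings.warn(f"{int(low.sum())} blank pixels below threshold; masked")
    safe = np.where(low, np.inf, fb)
    out = image / safe * fb.mean()
    return out


def network_hull_mask(
    image: np.ndarray, threshold_sd: float = 3.0, close_px: int = 5
) -> np.ndarray:
    """Convex hull of the thresholded, morphologically closed MT signal."""
    med = np.median(image)
    sd = 1.4826 * np.median(np.abs(image - med)) or image.std() or 1.0
    mask = image > med + threshold_sd * sd
    mask = morphology.binary_closing(mask, morphology.disk(close_px))
    if not mask.any():
        raise ValueError("no signal above threshold; cannot build hull")
    return morphology.convex_hull_image(mask)


def tubulin_intensity_profile(
    image: np.ndarray,
    hull: np.ndarray,
    origin: tuple[float, float],
    bins: int = 10,
) -> IntensityProfile:
    """Radial tubulin-mass profile inside the network hull.

    Background (mean outside the hull) is subtracted, intensities are
    normalized by the mean inside the hull, distances from the origin by
    the largest in-hull distance.
    """
    image = np.asarray(image, dtype=float)
    hull = np.asarray(hull, dtype=bool)
    if hull.sum() < 10:
        raise ValueError("hull has fewer than 10 interior pixels")
    background = image[~hull].mean() if (~hull).any() else 0.0
    sub = image - background
    inside_mean = sub[hull].mean()
    if inside_mean == 0:
        raise ValueError("zero mean intensity inside hull")
    yy, xx = np.nonzero(hull)
    d = np.hypot(xx - origin[0], yy - origin[1])
    dmax = d.max() or 1.0
    dn = d / dmax
    vals = sub[yy, xx] / inside_mean
    edges = np.linspace(0.0, 1.0, bins + 1)
    which = np.clip(np.digitize(dn, edges) - 1, 0, bins - 1)
    mean = np.zeros(bins)
    sd = np.zeros(bins)
    n = np.zeros(bins, dtype=int)
    for b in range(bins):
        sel = which == b
        n[b] = sel.sum()
        if n[b]:
            mean[b] = vals[sel].mean()
            sd[b] = vals[sel].std()
    return IntensityProfile(0.5 * (edges[:-1] + edges[1:]), mean, sd, n)


def estimate_binding_rate(
    kymograph: KymographTruth | np.ndarray,
    single_intensity: float,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    arrival_frames: np.ndarray | None = None,
    min_window: int = 5,
    background_sd_factor: float = 3.0,
) -> tuple[list[SlopeFit], float, float]:
    """Per-pixel linear slope fits of TPX2 accumulation.

    For each lattice pixel the trace from lattice arrival to the end is
    fit with a straight line; the slope (au/s) is converted to
    molecules µm⁻¹ s⁻¹.  Arrival frames come from the kymograph truth or
    are detected as the first frame exceeding background + 3 sd.
    Returns (fits, ensemble mean, ensemble sd).
    """
    if single_intensity <= 0:
        raise ValueError("single_intensity must be > 0")
    if isinstance(kymograph, KymographTruth):
        data = kymograph.data
        pixel_size = kymograph.pixel_size
        frame_interval = kymograph.frame_interval
        if arrival_frames is None:
            arrival_frames = kymograph.arrival_frame
    else:
        data = np.asarray(kymograph, dtype=float)
        if pixel_size is None or frame_interval is None:
            raise ValueError("pixel_size and frame_interval required for raw arrays")
    n_pixels, n_frames = data.shape
    if arrival_frames is None:
        arrival_frames = np.empty(n_pixels, dtype=int)
        for p in range(n_pixels):
            base = data[p, : max(3, n_frames // 10)]
            thr = base.mean() + background_sd_factor * (base.std() or 1.0)
            above = np.nonzero(data[p] > thr)[0]
            arrival_frames[p] = above[0] if above.size else n_frames
    fits: list[SlopeFit] = []
    for p in range(n_pixels):
        a = int(arrival_frames[p])
        if n_frames - a < min_window:
            continue
        t = np.arange(a, n_frames) * frame_interval
        y = data[p, a:]
        slope, intercept = np.polyfit(t, y, 1)
        pred = slope * t + intercept
        ss_res = float(((y - pred) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum()) or 1.0
        fits.append(
            SlopeFit(
                pixel=p,
                slope_au_per_s=float(slope),
                window=(a, n_frames),
                rate=float(slope / (single_intensity * pixel_size)),
                r2=1.0 - ss_res / ss_tot,
            )
        )
    rates = np.array([f.rate for f in fits])
    if rates.size == 0:
        return fits, float("nan"), float("nan")
    return fits, float(rates.mean()), float(rates.std(ddof=1) if rates.size > 1 else 0.0)


def fit_step_amplitude(
    traces: list[PhotobleachTrace] | list[np.ndarray],
    min_variance_explained: float = 0.5,
) -> tuple[list[StepFit], float, float]:
    """Least-squares Heaviside fit of single-molecule bleaching steps.

    The step frame is found by grid search; pre/post means are the
    closed-form least-squares levels and the amplitude their difference.
    Fits explaining less than half the variance are flagged and excluded
    from the ensemble mean/sd.
    """
    fits: list[StepFit] = []
    for i, tr in enumerate(traces):
        y = tr.intensity if isinstance(tr, PhotobleachTrace) else np.asarray(tr, float)
        n = len(y)
        if n < 10:
            raise ValueError("trace must have at least 10 frames")
        best = None
        tot = float(((y - y.mean()) ** 2).sum()) or 1.0
        cums = np.concatenate([[0.0], np.cumsum(y)])
        cums2 = np.concatenate([[0.0], np.cumsum(y**2)])
        for s in range(1, n):
            pre = cums[s] / s
            post = (cums[n] - cums[s]) / (n - s)
            sse = (
                cums2[s] - s * pre**2 + (cums2[n] - cums2[s]) - (n - s) * post**2
            )
            if best is None or sse < best[0]:
                best = (sse, s, pre, post)
        sse, s, pre, post = best
        r2 = 1.0 - sse / tot
        # a trace that a straight line explains at least as well has no step
        t = np.arange(n, dtype=float)
        coef = np.polyfit(t, y, 1)
        sse_line = float(((y - np.polyval(coef, t)) ** 2).sum())
        fits.append(
            StepFit(
                trace=i,
                amplitude=float(pre - post),
                step_frame=int(s),
                residual=float(sse),
                r2=float(r2),
                flagged=(r2 < min_variance_explained) or (sse >= sse_line),
            )
        )
    amps = np.array([f.amplitude for f in fits if not f.flagged])
    if amps.size == 0:
        return fits, float("nan"), float("nan")
    return fits, float(amps.mean()), float(amps.std(ddof=1) if amps.size > 1 else 0.0)
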