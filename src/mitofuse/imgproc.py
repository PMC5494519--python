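"""Shared image operations: despeckle, series-level Otsu, noise-ratio rule.

These are the three primitives the photoactivation analyses are built on:

* :func:`despeckle` — the 3x3 median filter applied to every frame before
  segmentation (removes single-pixel shot-noise outliers).
* :func:`otsu_threshold_series` — one threshold per channel per *series*,
  from the histogram pooled over the selected frames, maximizing
  between-class variance.  A single threshold per series keeps masks
  comparable across time, which the pixel-count decay readout requires.
* :func:`noise_ratio_threshold` — the smallest gray level at which at most
  0.1% of in-cell pre-activation pixels are suprathreshold.  Before the
  pulse the PA-GFP channel contains only noise, so any suprathreshold
  pre-activation pixel is a false positive; this pins the false-positive
  rate of the spreading mask at 1/1000.

Threshold conventions (documented, deliberate): Otsu masks use the strict
split ``pixel > threshold``; the noise-ratio rule counts ``pixel >=
threshold`` as suprathreshold (its boundary cases are defined that way).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .series import ImageSeries


def despeckle(frame: np.ndarray) -> np.ndarray:
    """3x3 median filter with edge replication (ImageJ "Despeckle")."""
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError(f"despeckle expects a 2-D image, got ndim={frame.ndim}")
    return ndimage.median_filter(frame, size=3, mode="nearest")


def _otsu_from_hist(hist: np.ndarray) -> int:
    """Exhaustive Otsu on an integer-level histogram.

    Candidate threshold t splits levels into {<= t} and {> t}; returns the t
    maximizing the between-class variance, ties broken toward the lowest t.
    """
    hist = np.asarray(hist, dtype=np.float64)
    total = hist.sum()
    if total <= 0 or np.count_nonzero(hist) < 2:
        raise ValueError("Otsu needs at least two distinct gray levels")
    levels = np.arange(hist.size, dtype=np.float64)
    p = hist / total
    omega = np.cumsum(p)                # weight of class {<= t}
    mu = np.cumsum(p * levels)          # first moment of class {<= t}
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    # argmax returns the first (lowest) maximizer
    return int(np.argmax(sigma_b[:-1]))


def otsu_threshold_values(values: np.ndarray, bit_depth: int = 8) -> int:
    """Otsu threshold of a pooled sample of integer gray values.

    For bit depths above 8 the histogram is first binned to 1,024 coarse
    bins for speed; the exact gray level is then recovered by exhaustive
    search restricted to the winning coarse bin's neighbourhood.
    """
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValueError("empty sample")
    n_levels = 2 ** bit_depth
    if n_levels <= 256:
        hist = np.bincount(values.astype(np.int64), minlength=n_levels)
        return _otsu_from_hist(hist)
    # coarse pass
    n_bins = 1024
    factor = n_levels // n_bins
    coarse = np.bincount(values.astype(np.int64) // factor, minlength=n_bins)
    t_coarse = _otsu_from_hist(coarse)
    # exact refinement over the levels spanned by the winning bin and its
    # neighbours, evaluated on the full-resolution histogram
    hist = np.bincount(values.astype(np.int64), minlength=n_levels).astype(np.float64)
    total = hist.sum()
    levels = np.arange(n_levels, dtype=np.float64)
    omega = np.cumsum(hist) / total
    mu = np.cumsum(hist * levels) / total
    mu_total = mu[-1]
    lo = max(0, (t_coarse - 1) * factor)
    hi = min(n_levels - 1, (t_coarse + 2) * factor)
    cand = np.arange(lo, hi)
    with np.errstate(divide="ignore", invalid="ignore"):
        sb = (mu_total * omega[cand] - mu[cand]) ** 2 / (
            omega[cand] * (1.0 - omega[cand])
        )
    sb[~np.isfinite(sb)] = -np.inf
    return int(cand[np.argmax(sb)])


def otsu_threshold_series(
    series: ImageSeries, channel: int, frames=None
) -> int:
    """Single Otsu threshold for one channel over a set of frames.

    The histogram is pooled over ``frames`` (default: the post-activation
    frames), restricted to ``cell_roi`` if the series has one.  Pooling makes
    the threshold invariant to frame order and gives every frame of the
    series the same mask rule.
    """
    if frames is None:
        frames = series.post_frames
    frames = list(frames)
    if not frames:
        raise ValueError("no frames selected")
    cell = series.cell_mask()
    vals = series.pixels[frames][:, channel][:, cell]
    return otsu_threshold_values(vals, bit_depth=series.bit_depth)


def otsu_threshold_image(image: np.ndarray, bit_depth: int = 8) -> int:
    """Otsu threshold of a single image (used for colocalization masks)."""
    return otsu_threshold_values(np.asarray(image), bit_depth=bit_depth)


def noise_ratio_threshold(
    series: ImageSeries, channel: int, max_fraction: float = 0.001
) -> int:
    """Smallest threshold leaving <= ``max_fraction`` suprathreshold pixels
    in the pre-activation frames of ``channel`` (in-cell pixels only).

    "Suprathreshold" means ``pixel >= threshold``.  With the default 0.1%
    this is the empirical 99.9th-percentile rank statistic of the
    pre-activation noise, plus one gray level.
    """
    if series.t_act == 0:
        raise ValueError("no pre-activation frames; noise threshold undefined")
    cell = series.cell_mask()
    vals = series.pixels[: series.t_act, channel][:, cell].ravel()
    n = vals.size
    allowed = int(np.floor(max_fraction * n))
    if allowed >= n:
        return 0
    # count(>= t) <= allowed  <=>  t > (allowed+1)-th largest value
    kth = np.partition(vals, n - allowed - 1)[n - allowed - 1]
    return int(kth) + 1
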