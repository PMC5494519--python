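"""Frame-differencing motility index and mask colocalization.

The motility index grades organelle movement without tracking: the two
channels are summed, successive summed frames are subtracted, and both the
difference and the summed series are thresholded at the constant 32 (8-bit
scale).  The index is the median suprathreshold pixel count of the
difference series normalized by that of the summed series — 0 for a frozen
scene, ~1 when every object pixel is displaced or re-intensified each
frame.

Colocalization is Manders-style on binary Otsu masks: the percentage of
mask-A pixels that also fall in mask B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgproc import otsu_threshold_image
from .series import CH_GFP, CH_RED, ImageSeries

#: the constant threshold of the motility procedure, on the 8-bit scale
MOTILITY_THRESHOLD = 32


@dataclass
class MotilityResult:
    diff_counts: np.ndarray   # per-interval suprathreshold counts, difference series
    sum_counts: np.ndarray    # per-frame suprathreshold counts, summed series
    index: float              # median(diff) / median(sum)
    mean_intensity_above: float  # QC: mean of suprathreshold summed pixels


@dataclass
class ColocResult:
    percent_A_in_B: float
    threshold_A: int
    threshold_B: int
    n_A: int
    n_overlap: int


def _summed_8bit(series: ImageSeries) -> np.ndarray:
    """GFP + DsRed on an 8-bit working scale.

    16-bit input is linearly rescaled (max-normalized per series) to 8 bits
    before summing, since the constant threshold is defined on 8-bit data;
    the sum is clipped to 255.
    """
    post = list(series.post_frames)
    g = series.pixels[post][:, CH_GFP].astype(np.float64)
    r = series.pixels[post][:, CH_RED].astype(np.float64)
    if series.bit_depth > 8:
        peak = max(g.max(), r.max())
        if peak > 0:
            g = g * (255.0 / peak)
            r = r * (255.0 / peak)
    return np.clip(g + r, 0, 255)


def motility_index(series: ImageSeries, threshold: int = MOTILITY_THRESHOLD) -> MotilityResult:
    """Motility index over the post-activation frames.

    Requires >= 2 post-activation frames.  Raises when the summed series
    never exceeds the threshold (no cell signal: the index is undefined).
    """
    post = list(series.post_frames)
    if len(post) < 2:
        raise ValueError("need >= 2 post-activation frames")
    summed = _summed_8bit(series)
    cell = series.cell_mask()
    above_sum = (summed > threshold) & cell
    sum_counts = above_sum.sum(axis=(1, 2)).astype(np.int64)
    diff = np.abs(np.diff(summed, axis=0))
    diff_counts = ((diff > threshold) & cell).sum(axis=(1, 2)).astype(np.int64)
    med_sum = float(np.median(sum_counts))
    if med_sum == 0:
        raise ValueError("summed series entirely below threshold; index undefined")
    vals = summed[above_sum]
    return MotilityResult(
        diff_counts=diff_counts,
        sum_counts=sum_counts,
        index=float(np.median(diff_counts)) / med_sum,
        mean_intensity_above=float(vals.mean()) if vals.size else 0.0,
    )


def coloc_percent(
    img_a: np.ndarray, img_b: np.ndarray, bit_depth: int = 8
) -> ColocResult:
    """Percentage of Otsu-mask-A pixels that co-occur with Otsu mask B.

    Object-pixel co-occurrence on binary masks (Manders-style, unweighted).
    Raises when mask A is empty (fraction undefined).
    """
    img_a = np.asarray(img_a)
    img_b = np.asarray(img_b)
    if img_a.shape != img_b.shape or img_a.ndim != 2:
        raise ValueError("coloc_percent expects two same-shape 2-D images")
    thr_a = otsu_threshold_image(img_a, bit_depth=bit_depth)
    thr_b = otsu_threshold_image(img_b, bit_depth=bit_depth)
    mask_a = img_a > thr_a
    mask_b = img_b > thr_b
    n_a = int(mask_a.sum())
    if n_a == 0:
        raise ValueError("mask A empty; colocalization undefined")
    n_ab = int((mask_a & mask_b).sum())
    return ColocResult(
        percent_A_in_B=100.0 * n_ab / n_a,
        threshold_A=thr_a,
        threshold_B=thr_b,
        n_A=n_a,
        n_overlap=n_ab,
    )
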