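"""Matrix-continuity readouts: RPA ratio decay and PA-GFP spreading.

Activated PA-GFP is a soluble matrix protein: it diffuses out of the region
of photoactivation (RPA) only through lumenally continuous mitochondria.
Two readouts quantify that continuity:

* :func:`rpa_decay` — the time course of the ratio F(mtPA-GFP)/F(mtDsRed)
  averaged over the RPA, normalized to the first post-activation frame.
  DsRed in the denominator cancels focus drift and z-motion.  The summary
  statistic is the decay of the normalized ratio at 500 s,
  ``decay_500s = 1 - R(500 s)``: larger decay = more connected network.
* :func:`spreading_curve` — the count of suprathreshold PA-GFP pixels
  *outside* the activation squares per frame, with the threshold set by the
  0.1% noise-to-signal rule on the pre-activation frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgproc import noise_ratio_threshold
from .series import CH_GFP, CH_RED, ImageSeries


@dataclass
class RpaTimecourse:
    """Normalized RPA fluorescence-ratio time course.

    ``ratio[0] == 1`` by construction; ``decay_500s = 1 - ratio(500 s)``
    (linear interpolation between bracketing frames).  ``at_500s`` is False
    when the recording is shorter than 500 s and the decay was taken at the
    last frame instead.
    """

    time_s: np.ndarray
    ratio: np.ndarray
    decay_500s: float
    at_500s: bool
    per_roi_ratio: np.ndarray  # (n_rois, T_post), normalized


@dataclass
class SpreadCurve:
    time_s: np.ndarray
    outside_pixels: np.ndarray
    threshold: int


def _dsred_floor(series: ImageSeries) -> float:
    """Background + 3 sigma of the pre-activation noise, estimated from the
    pre-activation GFP channel (pure noise before the pulse)."""
    if series.t_act == 0:
        return 0.0
    cell = series.cell_mask()
    noise = series.pixels[: series.t_act, CH_GFP][:, cell].astype(np.float64)
    return float(noise.mean() + 3.0 * noise.std())


def rpa_decay(
    series: ImageSeries,
    at_time_s: float = 500.0,
    dsred_floor: float | None = None,
) -> RpaTimecourse:
    """RPA ratio time course and its decay at ``at_time_s`` (default 500 s).

    Per activation ROI and post-activation frame the ratio of ROI-mean GFP
    to ROI-mean DsRed is computed and normalized to the first
    post-activation frame; multiple ROIs are averaged per cell.  Raises if
    the DsRed ROI mean falls below ``dsred_floor`` (default: background +
    3 sigma of pre-activation noise) — the ratio is undefined on a
    bleached-out ROI.
    """
    if not series.act_rois:
        raise ValueError("series has no activation ROIs")
    if dsred_floor is None:
        dsred_floor = _dsred_floor(series)
    post = list(series.post_frames)
    g = series.pixels[:, CH_GFP].astype(np.float64)
    r = series.pixels[:, CH_RED].astype(np.float64)
    per_roi = np.empty((len(series.act_rois), len(post)), dtype=np.float64)
    for k, (r0, c0, hh, ww) in enumerate(series.act_rois):
        sl = (slice(r0, r0 + hh), slice(c0, c0 + ww))
        for i, t in enumerate(post):
            red_mean = r[t][sl].mean()
            if red_mean <= dsred_floor:
                raise ValueError(
                    f"DsRed ROI mean {red_mean:.2f} at frame {t} below floor "
                    f"{dsred_floor:.2f}; ratio undefined (bleached-out ROI)"
                )
            per_roi[k, i] = g[t][sl].mean() / red_mean
        if per_roi[k, 0] <= 0:
            raise ValueError(
                f"ROI {k}: no activated PA-GFP at the normalization frame"
            )
        per_roi[k] /= per_roi[k, 0]
    ratio = per_roi.mean(axis=0)
    time_s = np.asarray(series.times_s(post), dtype=np.float64)
    if time_s[-1] >= at_time_s:
        r_at = float(np.interp(at_time_s, time_s, ratio))
        at_flag = True
    else:
        r_at = float(ratio[-1])
        at_flag = False
    return RpaTimecourse(
        time_s=time_s,
        ratio=ratio,
        decay_500s=1.0 - r_at,
        at_500s=at_flag,
        per_roi_ratio=per_roi,
    )


def spreading_curve(series: ImageSeries) -> SpreadCurve:
    """Suprathreshold PA-GFP pixels outside the activation squares per frame.

    The threshold comes from the 0.1% noise-to-signal rule on the
    pre-activation GFP frames; the activation-square pixels are subtracted
    (masked out) before counting.  Counts are restricted to the cell ROI.
    """
    thr = noise_ratio_threshold(series, CH_GFP)
    post = list(series.post_frames)
    outside = series.cell_mask() & ~series.roi_mask()
    g = series.pixels[:, CH_GFP]
    counts = np.array([int(((g[t] >= thr) & outside).sum()) for t in post])
    return SpreadCurve(
        time_s=np.asarray(series.times_s(post), dtype=np.float64),
        outside_pixels=counts,
        threshold=thr,
    )


def predicted_dilution_decay(run, roi_index: int = 0) -> float:
    """Closed-form decay expected from the simulator's content ledger.

    For a static network the normalized RPA ratio relaxes from the
    just-activated state to the fully equilibrated one; the predicted decay
    is ``1 - (ratio at the final frame) / (ratio at activation)``, computed
    directly from the fluorophore amounts of the ROI-resident segments —
    independent of rendering and of the image-based estimator.
    """
    from .sim import _in_any_roi  # local import to avoid cycle

    params = run.params
    roi = params.act_rois[roi_index]

    def roi_ratio(state) -> float:
        bright = red = length = 0.0
        for s in state:
            if _in_any_roi(s.centroid_um, (roi,)):
                bright += s.pagfp_bright
                red += s.dsred_amount
                length += s.length_um
        if red <= 0:
            raise ValueError("no DsRed in ROI; ledger ratio undefined")
        return bright / red

    r0 = roi_ratio(run.states[params.t_act])
    r_inf = roi_ratio(run.states[-1])
    return 1.0 - r_inf / r0
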