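"""Fusion-activity readouts from photoactivation series.

Two complementary measures of mitochondrial fusion:

1. **GFP-only pixel loss** (:func:`gfp_only_decay`).  Simultaneous
   photoactivation/photobleaching leaves a population of "green-only"
   mitochondria (above the PA-GFP threshold, below the DsRed threshold).
   Every fusion of a green-only mitochondrion with an unbleached red one
   mixes matrix content, so the green-only pixel count decays with fusion
   activity.  The count time course is fit by a single exponential
   ``y = a * exp(-b * x)`` (x in seconds); the decay constant ``b`` — or the
   half-time ``ln(2)/b`` — is the readout.  Slower half-time = less fusion.

2. **Object-level event detection** (:func:`detect_fusion_events`).  A
   fusion event appears as an abrupt, complementary inter-mitochondrial
   transfer of the two fluorophores between contacting objects: the donor's
   mean GFP drops while its DsRed rises, and the acceptor shows the opposite
   signs (or the two objects merge into one while the same precondition
   holds).  Events are classified transient (the pair separates again within
   the recording; "kiss-and-run") or complete, and by contact geometry
   (end-to-end / end-to-side / side-to-side).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from skimage.measure import label as sk_label
from skimage.morphology import skeletonize

from .imgproc import despeckle, otsu_threshold_series, otsu_threshold_values
from .series import CH_GFP, CH_RED, ImageSeries

# --------------------------------------------------------------------------
# Exponential decay fit
# --------------------------------------------------------------------------


@dataclass
class DecayFit:
    """Result of the single-exponential fit ``y = a * exp(-b * x)``.

    ``half_time_s`` is ``ln(2)/b`` for ``b > 0`` and ``+inf`` (flagged by
    ``decaying = False``) otherwise.
    """

    a: float
    b: float
    half_time_s: float
    r2: float
    counts: np.ndarray
    times_s: np.ndarray
    converged: bool

    @property
    def decaying(self) -> bool:
        return math.isfinite(self.half_time_s)


def fit_exponential_decay(x, y) -> DecayFit:
    """Unweighted least-squares fit of ``y = a * exp(-b * x)``.

    Initialized from a log-linear regression on the positive counts; falls
    back to the log-linear estimate (``converged = False``) if the nonlinear
    fit does not converge.  Zero counts are allowed in the objective.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
        a0, b0 = float(np.exp(intercept)), float(-slope)
    else:
        a0, b0 = float(max(y.max(initial=0.0), 1.0)), 0.0

    def model(t, a, b):
        return a * np.exp(-b * t)

    converged = True
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # singular covariance on perfect fits
            (a, b), _ = curve_fit(model, x, y, p0=[a0, b0], maxfev=20000)
    except RuntimeError:
        a, b, converged = a0, b0, False
    resid = y - model(x, a, b)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    half = math.log(2.0) / b if b > 1e-12 else math.inf
    return DecayFit(
        a=float(a),
        b=float(b),
        half_time_s=half,
        r2=r2,
        counts=y,
        times_s=x,
        converged=converged,
    )


def gfp_only_counts(series: ImageSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame green-only pixel counts over the post-activation window.

    Every post-activation frame is despeckled; one Otsu threshold per
    channel is set on the pooled despeckled series (in-cell pixels);
    green-only = GFP mask AND NOT DsRed mask.  Returns ``(times_s, counts)``.
    """
    post = list(series.post_frames)
    cell = series.cell_mask()
    dg = np.stack([despeckle(series.pixels[t, CH_GFP]) for t in post])
    dr = np.stack([despeckle(series.pixels[t, CH_RED]) for t in post])
    thr_g = otsu_threshold_values(dg[:, cell], bit_depth=series.bit_depth)
    thr_r = otsu_threshold_values(dr[:, cell], bit_depth=series.bit_depth)
    green_only = (dg > thr_g) & ~(dr > thr_r) & cell
    counts = green_only.sum(axis=(1, 2)).astype(np.float64)
    return series.times_s(post), counts


def gfp_only_decay(series: ImageSeries) -> DecayFit:
    """Exponential fit of the GFP-only pixel-loss time course.

    Requires at least 10 post-activation frames.  Raises if the green-only
    count is zero everywhere (no activated signal to track).
    """
    if len(series.post_frames) < 10:
        raise ValueError("need >= 10 post-activation frames for the decay fit")
    x, counts = gfp_only_counts(series)
    if counts.sum() == 0:
        raise ValueError("no GFP-only signal above threshold")
    return fit_exponential_decay(x, counts)


# --------------------------------------------------------------------------
# Object-level fusion events
# --------------------------------------------------------------------------


@dataclass
class FusionEvent:
    """One fusion event, detected or ground truth.

    ``frame`` is the absolute frame index at which the exchanged content is
    first visible; ``time_s`` is seconds since activation.  ``duration_s``
    is set only for transient events (fusion -> fission interval).
    ``location_px`` is the contact point, (row, col).
    """

    frame: int
    time_s: float
    id_a: int
    id_b: int
    type: str = "complete"  # "transient" | "complete"
    duration_s: float | None = None
    orientation: str = "side_to_side"
    location_px: tuple[float, float] | None = None


def rate_per_min(n_events: float, window_s: float) -> float:
    """Convert an event count over a recording window to events/minute."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    return n_events / (window_s / 60.0)


@dataclass
class FusionSummary:
    n_events: int
    events_per_run: float
    events_per_min: float
    mean_duration_s: float
    fraction_transient: float
    orientation_counts: dict = field(default_factory=dict)


def summarize_fusion(events: list[FusionEvent], window_s: float = 480.0) -> FusionSummary:
    """Count/rate/duration/type summary of one recording window.

    ``window_s`` defaults to the 8-minute recording window; an empty event
    list yields an all-zero summary.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    n = len(events)
    transient = [e for e in events if e.type == "transient"]
    orient: dict[str, int] = {}
    for e in events:
        orient[e.orientation] = orient.get(e.orientation, 0) + 1
    mean_dur = (
        float(np.mean([e.duration_s for e in transient])) if transient else 0.0
    )
    return FusionSummary(
        n_events=n,
        events_per_run=float(n),
        events_per_min=rate_per_min(n, window_s),
        mean_duration_s=mean_dur,
        fraction_transient=(len(transient) / n) if n else 0.0,
        orientation_counts=orient,
    )


# -- tracking internals ----------------------------------------------------

_ADJ_OFFSETS = [
    (dr, dc)
    for dr in range(-2, 3)
    for dc in range(-2, 3)
    if (dr, dc) != (0, 0)
]


def _adjacent_pairs(tid_img: np.ndarray) -> set[tuple[int, int]]:
    """Track-id pairs whose 1-px-dilated masks intersect (within 2 px)."""
    pairs: set[tuple[int, int]] = set()
    h, w = tid_img.shape
    for dr, dc in _ADJ_OFFSETS:
        a = tid_img[max(0, dr) : h + min(0, dr), max(0, dc) : w + min(0, dc)]
        b = tid_img[max(0, -dr) : h + min(0, -dr), max(0, -dc) : w + min(0, -dc)]
        sel = (a >= 0) & (b >= 0) & (a != b)
        if sel.any():
            for x, y in zip(a[sel].ravel(), b[sel].ravel()):
                pairs.add((min(int(x), int(y)), max(int(x), int(y))))
    return pairs


def _skeleton_endpoints(mask: np.ndarray) -> np.ndarray:
    """(N, 2) coordinates of skeleton endpoints (<= 1 skeleton neighbour)."""
    skel = skeletonize(mask)
    if not skel.any():
        return np.argwhere(mask)[:1]
    nbrs = ndimage.convolve(skel.astype(np.int8), np.ones((3, 3), np.int8), mode="constant")
    ends = skel & (nbrs <= 2)  # self + at most one neighbour
    if not ends.any():
        ends = skel
    return np.argwhere(ends)


def _contact_pixels(
    mask_a: np.ndarray, mask_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest pixel pair between two masks (contact locus on each object)."""
    ca, cb = np.argwhere(mask_a), np.argwhere(mask_b)
    d, idx = cKDTree(ca).query(cb)
    j = int(np.argmin(d))
    return ca[idx[j]], cb[j]


def _classify_orientation(
    mask_a: np.ndarray, mask_b: np.ndarray, radius_px: float
) -> tuple[str, tuple[float, float]]:
    """End/side classification: each object's contact locus is compared with
    that object's own skeleton endpoints."""
    pa, pb = _contact_pixels(mask_a, mask_b)
    hits = 0
    for m, p in ((mask_a, pa), (mask_b, pb)):
        ends = _skeleton_endpoints(m)
        if ends.size and np.min(np.hypot(ends[:, 0] - p[0], ends[:, 1] - p[1])) <= radius_px:
            hits += 1
    name = {2: "end_to_end", 1: "end_to_side", 0: "side_to_side"}[hits]
    contact = (float(pa[0] + pb[0]) / 2.0, float(pa[1] + pb[1]) / 2.0)
    return name, contact


def detect_fusion_events(
    series: ImageSeries,
    delta_frac: float = 0.2,
    min_delta: float = 5.0,
    endpoint_radius_px: float = 3.0,
    min_overlap_px: int = 2,
) -> list[FusionEvent]:
    """Detect fusion events by complementary two-channel exchange.

    Post-activation frames are segmented with the union of the per-channel
    series Otsu masks, labeled, and tracked frame-to-frame by maximal mask
    overlap (a merged object inherits the larger parent's track id; a split
    re-assigns by overlap).  An event is emitted when contacting (or
    merging) tracks show an abrupt complementary exchange: donor mean GFP
    down and mean DsRed up by at least the per-track/channel threshold
    ``delta`` within one frame interval, acceptor the opposite.  ``delta``
    is ``delta_frac`` of the track's intensity range, floored at
    ``min_delta`` gray levels (scaled up for 16-bit data) so flat noisy
    tracks cannot trigger.

    Orientation is classified from the contact point and the skeleton
    endpoints of the two pre-fusion masks: within ``endpoint_radius_px`` of
    an endpoint of both objects -> end_to_end, of exactly one ->
    end_to_side, of neither -> side_to_side.
    """
    post = list(series.post_frames)
    if len(post) < 2:
        return []

    def _thr(ch: int) -> int:
        try:
            return otsu_threshold_series(series, ch, post)
        except ValueError:
            # single-valued channel: no separable classes, empty mask
            return int(series.pixels[post, ch].max(initial=0))

    thr_g = _thr(CH_GFP)
    thr_r = _thr(CH_RED)
    if series.bit_depth > 8:
        min_delta *= 2 ** (series.bit_depth - 8)
    g = series.pixels[:, CH_GFP].astype(np.float64)
    r = series.pixels[:, CH_RED].astype(np.float64)
    cell = series.cell_mask()
    h, w = series.frame_shape
    n_post = len(post)

    tid_imgs = np.full((n_post, h, w), -1, dtype=np.int32)
    next_tid = 0
    mean_g: dict[int, dict[int, float]] = defaultdict(dict)
    mean_r: dict[int, dict[int, float]] = defaultdict(dict)
    areas: dict[int, dict[int, int]] = defaultdict(dict)
    merges: list[tuple[int, int, list[int]]] = []  # (fi, kept, lost)
    splits: dict[int, list[int]] = defaultdict(list)  # tid -> frame idx of split
    adjacency: list[set[tuple[int, int]]] = []

    for fi, t in enumerate(post):
        mask = ((g[t] > thr_g) | (r[t] > thr_r)) & cell
        lab, nlab = sk_label(mask, connectivity=2, return_num=True)
        tid_img = np.full((h, w), -1, dtype=np.int32)
        if fi == 0 or nlab == 0:
            for l in range(1, nlab + 1):
                tid_img[lab == l] = next_tid
                next_tid += 1
        else:
            prev = tid_imgs[fi - 1]
            sel = lab > 0
            overlap: dict[tuple[int, int], int] = defaultdict(int)
            for l_val, p_val in zip(lab[sel].ravel(), prev[sel].ravel()):
                if p_val >= 0:
                    overlap[(int(l_val), int(p_val))] += 1
            parents_of: dict[int, dict[int, int]] = defaultdict(dict)
            children_of: dict[int, dict[int, int]] = defaultdict(dict)
            for (l_val, p_val), cnt in overlap.items():
                if cnt >= min_overlap_px:
                    parents_of[l_val][p_val] = cnt
                    children_of[p_val][l_val] = cnt
            label_order = sorted(
                range(1, nlab + 1),
                key=lambda l: -sum(parents_of.get(l, {}).values()),
            )
            used: set[int] = set()
            assigned: dict[int, int] = {}
            for l in label_order:
                eligible = [
                    p
                    for p, cnt in parents_of.get(l, {}).items()
                    if p not in used
                    and l == max(children_of[p], key=children_of[p].get)
                ]
                if eligible:
                    # merged object inherits the larger parent's id
                    kept = max(eligible, key=lambda p: areas[p].get(fi - 1, 0))
                    assigned[l] = kept
                    used.update(eligible)
                    lost = [p for p in eligible if p != kept]
                    if lost:
                        merges.append((fi, kept, lost))
                else:
                    assigned[l] = next_tid
                    next_tid += 1
                    # a parent whose winner went elsewhere lost this child: split
                    cands = [p for p in parents_of.get(l, {}) if p in used]
                    for p in cands:
                        splits[p].append(fi)
            for l, tid in assigned.items():
                tid_img[lab == l] = tid
        tid_imgs[fi] = tid_img
        present = np.unique(tid_img)
        present = present[present >= 0]
        for tid in present:
            m = tid_img == tid
            areas[int(tid)][fi] = int(m.sum())
            mean_g[int(tid)][fi] = float(g[t][m].mean())
            mean_r[int(tid)][fi] = float(r[t][m].mean())
        adjacency.append(_adjacent_pairs(tid_img))

    all_tids = set(mean_g)
    if len(all_tids) < 2:
        return []

    def delta_thr(track_means: dict[int, float], extra: float) -> float:
        vals = list(track_means.values()) + [extra]
        return max(delta_frac * (max(vals) - min(vals)), min_delta)

    def complementary(p: int, q: int, fi: int, fp_p: np.ndarray, fp_q: np.ndarray):
        """Test exchange between footprints fp_p/fp_q from frame fi-1 to fi."""
        tp, tc = post[fi - 1], post[fi]
        vals = {}
        for name, fp in (("p", fp_p), ("q", fp_q)):
            vals[name] = (
                float(g[tp][fp].mean()),
                float(r[tp][fp].mean()),
                float(g[tc][fp].mean()),
                float(r[tc][fp].mean()),
            )
        dg_p = vals["p"][2] - vals["p"][0]
        dr_p = vals["p"][3] - vals["p"][1]
        dg_q = vals["q"][2] - vals["q"][0]
        dr_q = vals["q"][3] - vals["q"][1]
        tg_p = delta_thr(mean_g[p], vals["p"][2])
        tr_p = delta_thr(mean_r[p], vals["p"][3])
        tg_q = delta_thr(mean_g[q], vals["q"][2])
        tr_q = delta_thr(mean_r[q], vals["q"][3])
        donor_p = dg_p <= -tg_p and dr_p >= tr_p and dg_q >= tg_q and dr_q <= -tr_q
        donor_q = dg_q <= -tg_q and dr_q >= tr_q and dg_p >= tg_p and dr_p <= -tr_p
        return donor_p or donor_q

    events: list[FusionEvent] = []
    seen: set[tuple[int, int, int]] = set()  # (fi, a, b) de-dup

    def emit(fi: int, p: int, q: int, merged_tid: int | None) -> None:
        key = (fi, min(p, q), max(p, q))
        if key in seen:
            return
        seen.add(key)
        fp_p = tid_imgs[fi - 1] == p
        fp_q = tid_imgs[fi - 1] == q
        orientation, contact = _classify_orientation(fp_p, fp_q, endpoint_radius_px)
        ev = FusionEvent(
            frame=post[fi],
            time_s=float(series.times_s([post[fi]])[0]),
            id_a=p,
            id_b=q,
            orientation=orientation,
            location_px=contact,
        )
        # transient if the pair separates again within the recording
        sep_fi = None
        if merged_tid is not None:
            later = [s for s in splits.get(merged_tid, []) if s > fi]
            sep_fi = min(later) if later else None
        else:
            for fj in range(fi + 1, n_post):
                a_here = fj in areas.get(p, {})
                b_here = fj in areas.get(q, {})
                if not (a_here and b_here):
                    break
                if (min(p, q), max(p, q)) not in adjacency[fj]:
                    sep_fi = fj
                    break
        if sep_fi is not None:
            ev.type = "transient"
            ev.duration_s = (sep_fi - fi) * series.frame_interval_s
        events.append(ev)

    # path 1: label merges with complementary pre-merge exchange
    merged_pairs_by_frame: dict[int, set[tuple[int, int]]] = defaultdict(set)
    for fi, kept, lost in merges:
        for q in lost:
            merged_pairs_by_frame[fi].add((min(kept, q), max(kept, q)))
            fp_p = tid_imgs[fi - 1] == kept
            fp_q = tid_imgs[fi - 1] == q
            if fp_p.any() and fp_q.any() and complementary(kept, q, fi, fp_p, fp_q):
                emit(fi, kept, q, merged_tid=kept)

    # path 2: contacting tracks that exchange without merging
    for fi in range(1, n_post):
        for a, b in adjacency[fi - 1]:
            if (a, b) in merged_pairs_by_frame.get(fi, set()):
                continue
            if fi not in areas.get(a, {}) or fi not in areas.get(b, {}):
                continue
            fp_a = tid_imgs[fi - 1] == a
            fp_b = tid_imgs[fi - 1] == b
            if complementary(a, b, fi, fp_a, fp_b):
                emit(fi, a, b, merged_tid=None)

    events.sort(key=lambda e: e.frame)
    return events
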