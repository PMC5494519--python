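"""Ground-truthed synthetic photoactivation experiments.

Mitochondria are modeled as mobile line segments ("capsules") in a square
2-D field, each carrying three matrix pools: mtDsRed, dark (unactivated)
mtPA-GFP and bright (activated) mtPA-GFP.  Segments joined by fusion form
connected components; matrix content equilibrates across a component
proportionally to segment length (PA-GFP and DsRed are soluble matrix
proteins that diffuse much faster than the 4-s frame interval, so mixing is
instantaneous at frame resolution, applied one frame after the topology or
activation change that caused it).

Per-frame dynamics (one seeded generator, fixed draw order):

1. matrix mixing within each component (equilibrates the previous frame's
   fusions/activation),
2. rigid Brownian motion of each component (per-axis variance ``2 D dt``),
3. fission: each junction breaks independently with ``1 - exp(-k_fiss dt)``,
4. fusion: contacting segment pairs from different components fuse with
   ``1 - exp(-k_fuse dt)`` (ascending id order, one fusion per segment per
   frame),
5. at ``t_act``: segments whose centroid lies inside an activation ROI have
   all dark PA-GFP switched bright and their DsRed multiplied by
   ``bleach_survival`` (the activation pulse photobleaches DsRed).

The junction graph is a forest (fusion only joins distinct components), so
every fission splits a component.  A fusion followed by fission of the same
junction within the recording is a transient ("kiss-and-run") event with
the fused interval as its duration; otherwise it is complete.

Rendering draws each segment as a constant-width capsule with per-pixel
intensity proportional to fluorophore amount per unit length, then applies
Gaussian PSF blur, Poisson shot noise and a constant background, and
quantizes to the requested bit depth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import ndimage

from .fusion import FusionEvent
from .series import CH_GFP, CH_RED, ImageSeries, write_series

#: activation ROI in physical coordinates: (x0_um, y0_um, side_um)
UmRoi = tuple[float, float, float]


@dataclass
class SimParams:
    """Simulation parameters.

    Defaults emulate the live-imaging conditions of the assay: a 512x512
    field at 0.1 um/pixel (51.2 um), 0.25 frames/s (4-s interval), one
    centred 5x5 um (25 um^2) photoactivation square, and an 8-minute
    (120-frame) post-activation window.  The activation pulse bleaches 80%
    of the DsRed in the ROI (``bleach_survival = 0.2``); the true bleach
    depth is instrument-dependent and is a parameter, not a claim.
    """

    n_segments: int = 40
    field_um: float = 51.2
    pixel_um: float = 0.1
    frame_interval_s: float = 4.0
    n_pre_frames: int = 5
    n_post_frames: int = 120
    seg_len_um_mean: float = 1.6
    seg_len_um_sd: float = 0.5
    seg_width_um: float = 0.3
    diffusion_um2_s: float = 0.01
    k_fuse_per_contact_s: float = 0.01
    k_fiss_per_junction_s: float = 0.0
    contact_dist_um: float = 0.3
    bleach_survival: float = 0.2
    act_rois: tuple[UmRoi, ...] | None = None  # default: one centred 5 um square
    psf_sigma_um: float = 0.15
    photons_per_unit: float = 5000.0
    background: float = 8.0
    bit_depth: int = 8
    density_per_um: float = 1.0  # initial fluorophore amount per um of length
    seed: int = 0

    def __post_init__(self) -> None:
        if self.act_rois is None:
            half = self.field_um / 2.0
            self.act_rois = ((half - 2.5, half - 2.5, 5.0),)
        self.act_rois = tuple(tuple(float(v) for v in r) for r in self.act_rois)

    def validate(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        for name in ("field_um", "pixel_um", "frame_interval_s", "seg_width_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "diffusion_um2_s",
            "k_fuse_per_contact_s",
            "k_fiss_per_junction_s",
            "contact_dist_um",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.bleach_survival <= 1.0:
            raise ValueError("bleach_survival must be in [0, 1]")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        for x0, y0, side in self.act_rois:
            if side <= 0 or x0 < 0 or y0 < 0 or x0 + side > self.field_um or y0 + side > self.field_um:
                raise ValueError(f"activation ROI {(x0, y0, side)} outside field")

    @property
    def t_act(self) -> int:
        return self.n_pre_frames

    @property
    def n_frames(self) -> int:
        return self.n_pre_frames + self.n_post_frames

    @property
    def field_px(self) -> int:
        return int(round(self.field_um / self.pixel_um))

    def rois_px(self) -> list[tuple[int, int, int, int]]:
        """Activation ROIs converted to (row0, col0, h, w) pixel rectangles."""
        out = []
        for x0, y0, side in self.act_rois:
            r0 = int(round(y0 / self.pixel_um))
            c0 = int(round(x0 / self.pixel_um))
            s = int(round(side / self.pixel_um))
            out.append((r0, c0, s, s))
        return out


@dataclass
class Segment:
    """One mitochondrial segment with its matrix-fluorophore pools (a.u.)."""

    id: int
    centroid_um: tuple[float, float]  # (x, y)
    angle_rad: float
    length_um: float
    component_id: int
    dsred_amount: float
    pagfp_dark: float
    pagfp_bright: float = 0.0

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        h = 0.5 * self.length_um * np.array(
            [math.cos(self.angle_rad), math.sin(self.angle_rad)]
        )
        c = np.asarray(self.centroid_um)
        return c - h, c + h

    def copy(self) -> "Segment":
        return dataclasses.replace(self)


@dataclass
class SimRun:
    """Bundle of parameters, state trajectory, ground truth and rendering."""

    params: SimParams
    states: list[list[Segment]]
    truth_events: list[FusionEvent]
    fission_records: list[tuple[int, int, int]]  # (frame, id_a, id_b)
    series: ImageSeries | None = None


# -- geometry --------------------------------------------------------------


def _seg_seg_closest(p1, p2, q1, q2) -> tuple[float, float, float]:
    """Distance and closest-point parameters (s, t) between two segments."""
    d1 = p2 - p1
    d2 = q2 - q1
    r = p1 - q1
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    if a <= 1e-12 and e <= 1e-12:
        return float(np.linalg.norm(r)), 0.0, 0.0
    if a <= 1e-12:
        s, t = 0.0, float(np.clip(f / e, 0.0, 1.0))
    else:
        c = float(d1 @ r)
        if e <= 1e-12:
            t, s = 0.0, float(np.clip(-c / a, 0.0, 1.0))
        else:
            b = float(d1 @ d2)
            denom = a * e - b * b
            s = float(np.clip((b * f - c * e) / denom, 0.0, 1.0)) if denom > 1e-12 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, float(np.clip(-c / a, 0.0, 1.0))
            elif t > 1.0:
                t, s = 1.0, float(np.clip((b - c) / a, 0.0, 1.0))
    cp1 = p1 + s * d1
    cp2 = q1 + t * d2
    return float(np.linalg.norm(cp1 - cp2)), s, t


def _truth_orientation(si: Segment, sj: Segment, s: float, t: float) -> str:
    """End/side classification from the closest-point parameters."""
    near_i = min(s, 1.0 - s) * si.length_um <= si.length_um * 0.25 + 1e-9
    near_j = min(t, 1.0 - t) * sj.length_um <= sj.length_um * 0.25 + 1e-9
    if near_i and near_j:
        return "end_to_end"
    if near_i or near_j:
        return "end_to_side"
    return "side_to_side"


def _contact_candidates(
    segs: dict[int, "Segment"], ids: list[int], params: "SimParams"
) -> list[tuple[int, int, float, float]]:
    """All segment pairs whose capsule boundaries come within
    ``contact_dist_um``, in ascending (id_i, id_j) order, with the
    closest-point parameters of each pair (vectorized scan)."""
    from scipy.spatial import cKDTree

    n = len(ids)
    if n < 2:
        return []
    p1 = np.empty((n, 2))
    p2 = np.empty((n, 2))
    cent = np.empty((n, 2))
    half_len = np.empty(n)
    for k, i in enumerate(ids):
        a, b = segs[i].endpoints()
        p1[k], p2[k] = a, b
        cent[k] = segs[i].centroid_um
        half_len[k] = 0.5 * segs[i].length_um
    reach = params.contact_dist_um + params.seg_width_um
    pairs = cKDTree(cent).query_pairs(
        2.0 * half_len.max() + reach, output_type="ndarray"
    )
    if pairs.size == 0:
        return []
    ia, ib = pairs[:, 0], pairs[:, 1]
    # per-pair tight prefilter on centroid distance
    cd = np.linalg.norm(cent[ia] - cent[ib], axis=1)
    keep = cd <= half_len[ia] + half_len[ib] + reach
    ia, ib = ia[keep], ib[keep]
    if ia.size == 0:
        return []
    d1 = p2[ia] - p1[ia]
    d2 = p2[ib] - p1[ib]
    r = p1[ia] - p1[ib]
    a = np.maximum((d1 * d1).sum(1), 1e-12)
    e = np.maximum((d2 * d2).sum(1), 1e-12)
    f = (d2 * r).sum(1)
    c = (d1 * r).sum(1)
    b = (d1 * d2).sum(1)
    denom = a * e - b * b
    s = np.where(denom > 1e-12, np.clip((b * f - c * e) / np.maximum(denom, 1e-12), 0.0, 1.0), 0.0)
    tpar = (b * s + f) / e
    s = np.where(tpar < 0.0, np.clip(-c / a, 0.0, 1.0), s)
    s = np.where(tpar > 1.0, np.clip((b - c) / a, 0.0, 1.0), s)
    tpar = np.clip(tpar, 0.0, 1.0)
    diff = (p1[ia] + s[:, None] * d1) - (p1[ib] + tpar[:, None] * d2)
    gap = np.linalg.norm(diff, axis=1) - params.seg_width_um
    hit = gap <= params.contact_dist_um
    out = []
    for k in np.nonzero(hit)[0]:
        i, j = ids[ia[k]], ids[ib[k]]
        si, ti = float(s[k]), float(tpar[k])
        if i > j:
            i, j = j, i
            si, ti = ti, si
        out.append((i, j, si, ti))
    out.sort(key=lambda x: (x[0], x[1]))
    return out


def _in_any_roi(centroid, rois: tuple[UmRoi, ...]) -> bool:
    x, y = centroid
    return any(x0 <= x < x0 + s and y0 <= y < y0 + s for x0, y0, s in rois)


# -- dynamics --------------------------------------------------------------


def _mix(segs: dict[int, Segment], graph: nx.Graph) -> None:
    """Equilibrate each fluorophore pool within every connected component,
    proportionally to segment length (conserves component totals)."""
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        members = [segs[i] for i in sorted(comp)]
        total_len = sum(m.length_um for m in members)
        for attr in ("dsred_amount", "pagfp_dark", "pagfp_bright"):
            total = sum(getattr(m, attr) for m in members)
            for m in members:
                setattr(m, attr, total * m.length_um / total_len)


def _components(graph: nx.Graph) -> list[set[int]]:
    return sorted(nx.connected_components(graph), key=min)


def simulate(
    params: SimParams,
    render_series: bool = True,
    init_segments: list[Segment] | None = None,
) -> SimRun:
    """Run one synthetic photoactivation experiment.

    Reproducible given ``params.seed``: dynamics and rendering use two
    independent streams derived from it.  Set ``render_series=False`` to
    skip image rendering (state trajectory and ground truth only).
    ``init_segments`` overrides the random initial placement (e.g. a pair
    held in permanent contact for hazard calibration).
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    dt = params.frame_interval_s
    p_fuse = 1.0 - math.exp(-params.k_fuse_per_contact_s * dt)
    p_fiss = 1.0 - math.exp(-params.k_fiss_per_junction_s * dt)

    segs: dict[int, Segment] = {}
    if init_segments is not None:
        if len(init_segments) != params.n_segments:
            raise ValueError("init_segments length must equal n_segments")
        for s in init_segments:
            segs[s.id] = s.copy()
    else:
        margin = min(params.seg_len_um_mean, params.field_um / 4.0)
        for i in range(params.n_segments):
            x = rng.uniform(margin, params.field_um - margin)
            y = rng.uniform(margin, params.field_um - margin)
            angle = rng.uniform(0.0, 2.0 * math.pi)
            length = float(
                np.clip(
                    rng.normal(params.seg_len_um_mean, params.seg_len_um_sd),
                    0.4,
                    3.0 * params.seg_len_um_mean,
                )
            )
            amt = params.density_per_um * length
            segs[i] = Segment(
                id=i,
                centroid_um=(x, y),
                angle_rad=angle,
                length_um=length,
                component_id=i,
                dsred_amount=amt,
                pagfp_dark=amt,
            )
    graph = nx.Graph()
    graph.add_nodes_from(segs)

    states: list[list[Segment]] = []
    raw_fusions: list[tuple[int, int, int, str, tuple[float, float]]] = []
    raw_fissions: list[tuple[int, int, int]] = []
    sd_step = math.sqrt(2.0 * params.diffusion_um2_s * dt)

    for t in range(params.n_frames):
        if t > 0:
            _mix(segs, graph)
            # rigid Brownian motion per component (ascending min-id order),
            # bounced off the field boundary (the cell confines mitochondria)
            for comp in _components(graph):
                if sd_step <= 0:
                    continue
                delta = rng.normal(0.0, sd_step, size=2)
                xs = [segs[i].centroid_um[0] for i in comp]
                ys = [segs[i].centroid_um[1] for i in comp]
                lo = 0.3
                hi = params.field_um - 0.3
                if min(xs) + delta[0] < lo or max(xs) + delta[0] > hi:
                    delta[0] = -delta[0]
                if min(ys) + delta[1] < lo or max(ys) + delta[1] > hi:
                    delta[1] = -delta[1]
                for i in comp:
                    s = segs[i]
                    s.centroid_um = (
                        s.centroid_um[0] + delta[0],
                        s.centroid_um[1] + delta[1],
                    )
            # fission: each junction breaks independently
            if p_fiss > 0:
                for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
                    if rng.random() < p_fiss:
                        graph.remove_edge(a, b)
                        raw_fissions.append((t, a, b))
            # fusion: contacting pairs from different components
            if p_fuse > 0:
                comp_of = {}
                comps_now = _components(graph)
                for ci, comp in enumerate(comps_now):
                    for i in comp:
                        comp_of[i] = ci
                parent = {ci: ci for ci in range(len(comps_now))}  # union-find over component labels

                def find(c):
                    while parent[c] != c:
                        parent[c] = parent[parent[c]]
                        c = parent[c]
                    return c

                fused_this_frame: set[int] = set()
                ids = sorted(segs)
                contacts = _contact_candidates(segs, ids, params)
                for i, j, s_par, t_par in contacts:
                        if i in fused_this_frame or j in fused_this_frame:
                            continue
                        if find(comp_of[i]) == find(comp_of[j]):
                            continue
                        si, sj = segs[i], segs[j]
                        if rng.random() < p_fuse:
                            graph.add_edge(i, j)
                            parent[find(comp_of[i])] = find(comp_of[j])
                            fused_this_frame.update((i, j))
                            p1, p2 = si.endpoints()
                            q1, q2 = sj.endpoints()
                            cp = 0.5 * ((p1 + s_par * (p2 - p1)) + (q1 + t_par * (q2 - q1)))
                            raw_fusions.append(
                                (t, i, j, _truth_orientation(si, sj, s_par, t_par), (cp[0], cp[1]))
                            )
        if t == params.t_act:
            for s in segs.values():
                if _in_any_roi(s.centroid_um, params.act_rois):
                    s.pagfp_bright += s.pagfp_dark
                    s.pagfp_dark = 0.0
                    s.dsred_amount *= params.bleach_survival
        comp_label = {}
        for comp in _components(graph):
            root = min(comp)
            for i in comp:
                comp_label[i] = root
        snapshot = []
        for i in sorted(segs):
            s = segs[i].copy()
            s.component_id = comp_label[i]
            snapshot.append(s)
        states.append(snapshot)

    truth_events = _pair_truth_events(raw_fusions, raw_fissions, params)
    series = render(states, params) if render_series else None
    return SimRun(
        params=params,
        states=states,
        truth_events=truth_events,
        fission_records=raw_fissions,
        series=series,
    )


def _pair_truth_events(raw_fusions, raw_fissions, params: SimParams) -> list[FusionEvent]:
    """Type each fusion transient/complete by matching later fissions of the
    same junction; content mixes one frame after the junction forms, so the
    ground-truth event frame is ``fusion frame + 1``."""
    dt = params.frame_interval_s
    events: list[FusionEvent] = []
    open_by_pair: dict[tuple[int, int], FusionEvent] = {}
    fiss_iter = sorted(raw_fissions)
    fus_iter = sorted(raw_fusions)
    timeline: list[tuple[int, str, tuple]] = [
        (t, "fusion", rec) for rec in fus_iter for t in [rec[0]]
    ] + [(t, "fission", rec) for rec in fiss_iter for t in [rec[0]]]
    timeline.sort(key=lambda x: (x[0], x[1] == "fusion"))  # fission before fusion in a frame
    for t, kind, rec in timeline:
        if kind == "fusion":
            _, a, b, orientation, loc_um = rec
            key = (min(a, b), max(a, b))
            ev = FusionEvent(
                frame=t + 1,
                time_s=(t + 1 - params.t_act) * dt,
                id_a=a,
                id_b=b,
                type="complete",
                orientation=orientation,
                location_px=(loc_um[1] / params.pixel_um, loc_um[0] / params.pixel_um),
            )
            open_by_pair[key] = ev
            events.append(ev)
        else:
            _, a, b = rec
            key = (min(a, b), max(a, b))
            ev = open_by_pair.pop(key, None)
            if ev is not None:
                ev.type = "transient"
                ev.duration_s = (t - (ev.frame - 1)) * dt
    return events


# -- rendering -------------------------------------------------------------


def _draw_capsule(img: np.ndarray, seg: Segment, amount: float, params: SimParams) -> None:
    if amount <= 0:
        return
    px = params.pixel_um
    p1, p2 = seg.endpoints()
    # pixel-centre coordinates: pixel (r, c) centre is ((c+.5) px, (r+.5) px)
    a = p1 / px - 0.5
    b = p2 / px - 0.5
    half_w = 0.5 * params.seg_width_um / px
    r_lo = int(np.floor(min(a[1], b[1]) - half_w - 1))
    r_hi = int(np.ceil(max(a[1], b[1]) + half_w + 1))
    c_lo = int(np.floor(min(a[0], b[0]) - half_w - 1))
    c_hi = int(np.ceil(max(a[0], b[0]) + half_w + 1))
    h, w = img.shape
    r_lo, r_hi = max(r_lo, 0), min(r_hi, h - 1)
    c_lo, c_hi = max(c_lo, 0), min(c_hi, w - 1)
    if r_lo > r_hi or c_lo > c_hi:
        return
    rr, cc = np.mgrid[r_lo : r_hi + 1, c_lo : c_hi + 1]
    # distance from pixel centres (x=c, y=r) to the axis segment
    d = np.stack([cc - a[0], rr - a[1]], axis=-1).astype(np.float64)
    ab = np.array([b[0] - a[0], b[1] - a[1]])
    denom = float(ab @ ab)
    tpar = (d @ ab) / denom if denom > 1e-12 else np.zeros(d.shape[:2])
    tpar = np.clip(tpar, 0.0, 1.0)
    closest = tpar[..., None] * ab
    dist = np.linalg.norm(d - closest, axis=-1)
    mask = dist <= half_w
    if not mask.any():
        # sub-pixel capsule: deposit everything in the nearest pixel
        rc = int(round((a[1] + b[1]) / 2)), int(round((a[0] + b[0]) / 2))
        if 0 <= rc[0] < h and 0 <= rc[1] < w:
            img[rc] += amount
        return
    img[r_lo : r_hi + 1, c_lo : c_hi + 1][mask] += amount / mask.sum()


def render(
    states: list[list[Segment]],
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> ImageSeries:
    """Render a state trajectory to a two-channel image series.

    Channel 0 (GFP) shows ``pagfp_bright``; channel 1 (DsRed) shows
    ``dsred_amount``.  A non-finite ``photons_per_unit`` disables shot noise
    (the rendered expectation is used directly).
    """
    if not states:
        raise ValueError("states must be nonempty")
    if params.bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    n = params.field_px
    sigma_px = params.psf_sigma_um / params.pixel_um
    maxval = 2 ** params.bit_depth - 1
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    out = np.zeros((len(states), 2, n, n), dtype=dtype)
    noisy = math.isfinite(params.photons_per_unit)
    for t, segs in enumerate(states):
        for ch, attr in ((CH_GFP, "pagfp_bright"), (CH_RED, "dsred_amount")):
            img = np.zeros((n, n), dtype=np.float64)
            for seg in segs:
                _draw_capsule(img, seg, getattr(seg, attr), params)
            if sigma_px > 0:
                img = ndimage.gaussian_filter(img, sigma_px)
            if noisy:
                img = rng.poisson(img * params.photons_per_unit).astype(np.float64)
            img += params.background
            out[t, ch] = np.clip(np.rint(img), 0, maxval).astype(dtype)
    return ImageSeries(
        pixels=out,
        pixel_um=params.pixel_um,
        frame_interval_s=params.frame_interval_s,
        t_act=params.t_act,
        act_rois=params.rois_px(),
        bit_depth=params.bit_depth,
    )


# -- scripted scenes for detector validation --------------------------------


def staged_fusion_run(
    n_pairs: int = 10,
    transient_pairs: tuple[int, ...] = (),
    transient_duration_frames: int = 8,
    event_spacing_frames: int = 6,
    field_um: float = 25.6,
    n_pre_frames: int = 3,
    seed: int = 0,
    params: SimParams | None = None,
) -> SimRun:
    """Scripted scene: ``n_pairs`` donor/acceptor pairs fusing at chosen,
    well-separated frames.

    Each pair holds one activated segment (bright PA-GFP, bleached DsRed)
    and one resting segment (dark PA-GFP, full DsRed), arranged end-to-end.
    At its assigned frame the donor closes the gap and the pair's matrix
    content equilibrates (the ground-truth fusion).  Pairs listed in
    ``transient_pairs`` separate again after ``transient_duration_frames``
    (contents stay mixed — fission does not unmix).  Event frames are spaced
    ``event_spacing_frames`` apart, satisfying the "well-separated events"
    regime used to grade the detector.  Ground truth (frames, partners,
    types, durations, end_to_end orientation, contact locations) is exact
    by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    event_frames = [
        n_pre_frames + 3 + k * event_spacing_frames for k in range(n_pairs)
    ]
    n_post = (event_frames[-1] - n_pre_frames) + transient_duration_frames + 6
    if params is None:
        params = SimParams(
            n_segments=2 * n_pairs,
            field_um=field_um,
            n_pre_frames=n_pre_frames,
            n_post_frames=n_post,
            diffusion_um2_s=0.0,
            k_fuse_per_contact_s=0.0,
            k_fiss_per_junction_s=0.0,
            act_rois=((0.0, 0.0, min(5.0, field_um),),),
            seed=seed,
        )
    params.validate()
    grid = int(math.ceil(math.sqrt(n_pairs)))
    cell = field_um / grid
    density = params.density_per_um
    seg_len = 1.4
    gap = 0.6
    pairs: list[tuple[Segment, Segment]] = []
    for k in range(n_pairs):
        gx, gy = k % grid, k // grid
        cx = (gx + 0.5) * cell + rng.uniform(-0.05, 0.05) * cell
        cy = (gy + 0.5) * cell + rng.uniform(-0.05, 0.05) * cell
        offset = (seg_len + gap) / 2.0
        donor = Segment(
            id=2 * k,
            centroid_um=(cx - offset, cy),
            angle_rad=0.0,
            length_um=seg_len,
            component_id=2 * k,
            dsred_amount=params.bleach_survival * density * seg_len,
            pagfp_dark=0.0,
            pagfp_bright=density * seg_len,
        )
        acceptor = Segment(
            id=2 * k + 1,
            centroid_um=(cx + offset, cy),
            angle_rad=0.0,
            length_um=seg_len,
            component_id=2 * k + 1,
            dsred_amount=density * seg_len,
            pagfp_dark=density * seg_len,
            pagfp_bright=0.0,
        )
        pairs.append((donor, acceptor))

    approach = gap - 0.05  # close the gap to slight overlap at fusion
    states: list[list[Segment]] = []
    truth: list[FusionEvent] = []
    fissions: list[tuple[int, int, int]] = []
    n_frames = params.n_frames
    for t in range(n_frames):
        frame_segs: list[Segment] = []
        for k, (donor, acceptor) in enumerate(pairs):
            f_k = event_frames[k]
            d = donor.copy()
            a = acceptor.copy()
            fused_now = t >= f_k
            separated = (
                k in transient_pairs and t >= f_k + transient_duration_frames
            )
            if fused_now:
                # mixed content (length-proportional equilibration)
                total_len = d.length_um + a.length_um
                for attr in ("dsred_amount", "pagfp_dark", "pagfp_bright"):
                    tot = getattr(donor, attr) + getattr(acceptor, attr)
                    setattr(d, attr, tot * d.length_um / total_len)
                    setattr(a, attr, tot * a.length_um / total_len)
            if fused_now and not separated:
                d.centroid_um = (d.centroid_um[0] + approach, d.centroid_um[1])
                d.component_id = a.component_id = min(d.id, a.id)
            frame_segs.extend((d, a))
            if t == f_k:
                tip = (donor.centroid_um[0] + seg_len / 2 + gap / 2, donor.centroid_um[1])
                ev = FusionEvent(
                    frame=f_k,
                    time_s=(f_k - params.t_act) * params.frame_interval_s,
                    id_a=d.id,
                    id_b=a.id,
                    type="transient" if k in transient_pairs else "complete",
                    duration_s=(
                        transient_duration_frames * params.frame_interval_s
                        if k in transient_pairs
                        else None
                    ),
                    orientation="end_to_end",
                    location_px=(tip[1] / params.pixel_um, tip[0] / params.pixel_um),
                )
                truth.append(ev)
            if k in transient_pairs and t == f_k + transient_duration_frames:
                fissions.append((t, d.id, a.id))
        states.append(frame_segs)
    series = render(states, params)
    return SimRun(
        params=params,
        states=states,
        truth_events=truth,
        fission_records=fissions,
        series=series,
    )


# -- outputs ---------------------------------------------------------------


def write_run(run: SimRun, out_dir: str | Path, stem: str = "sim") -> dict[str, Path]:
    """Write a run as TIFF + JSON sidecar + ground-truth event CSV."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if run.series is not None:
        paths["tiff"] = write_series(run.series, out_dir / f"{stem}.tif")
        paths["sidecar"] = (out_dir / f"{stem}.json")
    rows = [
        {
            "frame": e.frame,
            "time_s": e.time_s,
            "id_a": e.id_a,
            "id_b": e.id_b,
            "type": e.type,
            "duration_s": e.duration_s,
            "orientation": e.orientation,
        }
        for e in run.truth_events
    ]
    truth_path = out_dir / f"{stem}_truth_events.csv"
    pd.DataFrame(rows, columns=["frame", "time_s", "id_a", "id_b", "type", "duration_s", "orientation"]).to_csv(
        truth_path, index=False
    )
    paths["truth"] = truth_path
    params_path = out_dir / f"{stem}_params.json"
    params_path.write_text(json.dumps(dataclasses.asdict(run.params), indent=1))
    paths["params"] = params_path
    return paths


def expected_fusion_events(params: SimParams, n_trial_frames: int | None = None) -> float:
    """Closed-form expected fusion-event count for a pair held in permanent
    contact, from the per-frame hazards (deterministic Markov recursion).

    Mirrors the per-frame trial order of :func:`simulate`: a fused pair
    first attempts fission, then an unfused pair attempts fusion, on each of
    the ``n_frames - 1`` dynamic frames.
    """
    dt = params.frame_interval_s
    p_fuse = 1.0 - math.exp(-params.k_fuse_per_contact_s * dt)
    p_fiss = 1.0 - math.exp(-params.k_fiss_per_junction_s * dt)
    if n_trial_frames is None:
        n_trial_frames = params.n_frames - 1
    p_fused = 0.0
    expected = 0.0
    for _ in range(n_trial_frames):
        p_unfused = (1.0 - p_fused) + p_fused * p_fiss
        expected += p_unfused * p_fuse
        p_fused = p_unfused * p_fuse + (p_fused * (1.0 - p_fiss))
    return expected
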