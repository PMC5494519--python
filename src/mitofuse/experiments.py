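"""Canonical in-silico validation experiments.

These are the package's reference study conditions: each function returns
the parameter set (or scene) for one of the simulator-based validation
experiments that the test-suite and the reproduction script both run.  The
conditions are fixed here, in one place, so every entry point measures the
same thing.

All experiments use a 16-um field at 0.1 um/pixel, the 4-s frame interval
of the assay, and three 5x5-um (25 um^2) activation squares.  The dense
variant (120 segments of ~0.8 um) emulates a perinuclear network patch:
roughly 30 activated objects, enough for the pixel-count decay to be
quasi-continuous.

Two motility regimes are used deliberately:

* ``halftime_sweep_params`` — a low-motility network (D = 0.0005 um^2/s, no
  fission).  Used for the specificity control (no fusion -> no decay) and
  the rate-response of the fitted half-time, where partner exchange by
  transport would confound the per-contact fusion rate.
* ``correlation_sweep_params`` — a churning network (D = 0.002 um^2/s,
  fission at 0.008 /s per junction, i.e. fused-state lifetimes of ~125 s,
  the scale of observed transient-fusion durations).  Used to relate the
  ground-truth event count to the fitted decay, where partner renewal makes
  successive events transfer fresh content, as in a living cell.
"""

from __future__ import annotations

import math

import numpy as np

from .sim import Segment, SimParams

#: three 25-um^2 activation squares in the 16-um field
ACT_ROIS_16UM = ((1.5, 1.5, 5.0), (9.5, 2.5, 5.0), (5.0, 9.5, 5.0))

#: fusion rates (1/s per contacting pair) for the half-time rate response
HALFTIME_SWEEP_RATES = (0.0, 0.0006, 0.0025, 0.01)

#: 20x span of fusion rates for the event-count correlation
CORRELATION_RATE_RANGE = (0.0005, 0.01)


def _dense_network(k_fuse: float, seed: int, **overrides) -> SimParams:
    kw = dict(
        n_segments=120,
        field_um=16.0,
        seg_len_um_mean=0.8,
        seg_len_um_sd=0.25,
        n_pre_frames=5,
        n_post_frames=120,
        act_rois=ACT_ROIS_16UM,
        k_fuse_per_contact_s=k_fuse,
        seed=seed,
    )
    kw.update(overrides)
    return SimParams(**kw)


def halftime_sweep_params(k_fuse: float, seed: int) -> SimParams:
    """Low-motility network for the fitted-half-time rate response."""
    return _dense_network(
        k_fuse, seed, diffusion_um2_s=0.0005, k_fiss_per_junction_s=0.0
    )


def correlation_sweep_params(k_fuse: float, seed: int) -> SimParams:
    """Churning network for the event-count vs 1/half-time correlation."""
    return _dense_network(
        k_fuse, seed, diffusion_um2_s=0.002, k_fiss_per_junction_s=0.008
    )


def correlation_rates(n_levels: int = 13) -> np.ndarray:
    lo, hi = CORRELATION_RATE_RANGE
    return np.geomspace(lo, hi, n_levels)


def held_pair_params(
    k_fuse: float = 0.08, k_fiss: float = 0.15, n_frames: int = 50, seed: int = 0
) -> tuple[SimParams, list[Segment]]:
    """Two static overlapping segments in permanent contact.

    The per-frame fusion/fission hazards of this scene have an exact
    closed-form expected event count (:func:`mitofuse.sim.expected_fusion_events`).
    """
    params = SimParams(
        n_segments=2,
        field_um=8.0,
        n_pre_frames=1,
        n_post_frames=n_frames,
        k_fuse_per_contact_s=k_fuse,
        k_fiss_per_junction_s=k_fiss,
        diffusion_um2_s=0.0,
        act_rois=((1.0, 1.0, 5.0),),
        seed=seed,
    )
    init = [
        Segment(0, (4.0, 4.0), 0.0, 1.6, 0, 1.6, 1.6),
        Segment(1, (4.0, 4.2), 0.0, 1.6, 1, 1.6, 1.6),
    ]
    return params, init


def grid_segments(params: SimParams, seed: int, jitter_um: float = 0.25) -> list[Segment]:
    """Segments on a jittered grid covering the whole field.

    Guarantees activation-square occupancy (unlike uniform placement, which
    can leave a square empty), so it is the initial condition of choice for
    the matrix-continuity experiments.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    n = params.n_segments
    grid = int(math.ceil(math.sqrt(n)))
    cell = params.field_um / grid
    segs: list[Segment] = []
    for i in range(n):
        gx, gy = i % grid, i // grid
        x = (gx + 0.5) * cell + rng.uniform(-jitter_um, jitter_um)
        y = (gy + 0.5) * cell + rng.uniform(-jitter_um, jitter_um)
        angle = rng.uniform(0.0, 2 * math.pi)
        length = float(
            np.clip(
                rng.normal(params.seg_len_um_mean, params.seg_len_um_sd),
                0.4,
                3.0 * params.seg_len_um_mean,
            )
        )
        amt = params.density_per_um * length
        segs.append(Segment(i, (x, y), angle, length, i, amt, amt))
    return segs


def continuity_params(connected: bool, seed: int) -> SimParams:
    """Noiseless static network for the dilution-decay check.

    ``connected=True`` lets every pair fuse during the pre-activation
    window (unbounded contact distance, fast fusion), producing a single
    lumenally continuous component by activation time; ``connected=False``
    keeps every segment isolated.  Shot noise is off and the fluorophore
    density is high so quantization is negligible against the diluted
    signal.
    """
    return SimParams(
        n_segments=40,
        field_um=16.0,
        seg_len_um_mean=0.9,
        seg_len_um_sd=0.3,
        n_pre_frames=10,
        n_post_frames=130,
        diffusion_um2_s=0.0,
        k_fuse_per_contact_s=5.0 if connected else 0.0,
        contact_dist_um=50.0 if connected else 0.3,
        act_rois=((5.5, 5.5, 5.0),),
        psf_sigma_um=0.05,
        photons_per_unit=float("inf"),
        background=0.0,
        bit_depth=16,
        density_per_um=3000.0,
        seed=seed,
    )


def motility_params(diffusion_um2_s: float, seed: int, static_noiseless: bool = False) -> SimParams:
    """Non-fusing scene for the frame-differencing motility index."""
    kw = dict(
        n_segments=30,
        field_um=12.8,
        n_pre_frames=2,
        n_post_frames=40,
        k_fuse_per_contact_s=0.0,
        diffusion_um2_s=diffusion_um2_s,
        act_rois=((3.9, 3.9, 5.0),),
        seed=seed,
    )
    if static_noiseless:
        kw.update(photons_per_unit=float("inf"), density_per_um=5000.0, n_post_frames=10)
    return SimParams(**kw)
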