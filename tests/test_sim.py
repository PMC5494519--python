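"""Simulator invariants: conservation, hazards, activation, rendering."""

import dataclasses

import numpy as np
import pytest

from mitofuse.experiments import held_pair_params
from mitofuse.sim import (
    SimParams,
    Segment,
    expected_fusion_events,
    render,
    simulate,
    staged_fusion_run,
)


def small_params(**overrides):
    kw = dict(
        n_segments=25,
        field_um=12.8,
        n_pre_frames=3,
        n_post_frames=30,
        k_fuse_per_contact_s=0.02,
        k_fiss_per_junction_s=0.01,
        diffusion_um2_s=0.01,
        act_rois=((3.9, 3.9, 5.0),),
        seed=7,
    )
    kw.update(overrides)
    return SimParams(**kw)


def test_param_validation():
    with pytest.raises(ValueError):
        SimParams(n_segments=0).validate()
    with pytest.raises(ValueError):
        SimParams(bleach_survival=1.5).validate()
    with pytest.raises(ValueError):
        SimParams(act_rois=((50.0, 50.0, 5.0),), field_um=16.0).validate()
    with pytest.raises(ValueError):
        simulate(SimParams(n_segments=0))


def test_zero_fusion_rate_yields_no_events():
    run = simulate(small_params(k_fuse_per_contact_s=0.0), render_series=False)
    assert run.truth_events == []


def test_dsred_conserved_except_single_bleach_step():
    params = small_params()
    run = simulate(params, render_series=False)
    totals = [sum(s.dsred_amount for s in st) for st in run.states]
    pre = totals[: params.t_act]
    post = totals[params.t_act :]
    assert np.allclose(pre, pre[0], rtol=1e-12)
    assert np.allclose(post, post[0], rtol=1e-12)
    assert post[0] < pre[0]  # the bleach step removed DsRed


def test_pagfp_total_conserved_throughout():
    run = simulate(small_params(), render_series=False)
    totals = [sum(s.pagfp_dark + s.pagfp_bright for s in st) for st in run.states]
    assert np.allclose(totals, totals[0], rtol=1e-12)


def test_component_totals_conserved_across_mixing():
    """Mixing redistributes within a component but conserves its totals."""
    params = small_params(seed=11)
    run = simulate(params, render_series=False)
    for t in range(1, len(run.states)):
        if t == params.t_act:
            continue  # bleach intentionally changes DsRed
        prev = {s.id: s for s in run.states[t - 1]}
        # group the current frame's segments by their *previous* component:
        # motion/fission/fusion steps never transfer content, so per-previous-
        # component sums must match (mixing happened inside those components)
        by_comp_prev: dict[int, float] = {}
        by_comp_now: dict[int, float] = {}
        for s in run.states[t]:
            c = prev[s.id].component_id
            by_comp_now[c] = by_comp_now.get(c, 0.0) + s.dsred_amount
            by_comp_prev[c] = by_comp_prev.get(c, 0.0) + prev[s.id].dsred_amount
        for c in by_comp_prev:
            assert by_comp_now[c] == pytest.approx(by_comp_prev[c], rel=1e-9)


def test_identical_seed_gives_identical_run():
    p = small_params(seed=21)
    a = simulate(p)
    b = simulate(dataclasses.replace(p, seed=21))
    assert np.array_equal(a.series.pixels, b.series.pixels)
    for sa, sb in zip(a.states[-1], b.states[-1]):
        assert sa == sb
    assert len(a.truth_events) == len(b.truth_events)


def test_activation_is_local_until_mixing():
    params = small_params(seed=13)
    run = simulate(params, render_series=False)
    rois = params.act_rois
    from mitofuse.sim import _in_any_roi

    state = run.states[params.t_act]
    activated = {s.id for s in state if s.pagfp_bright > 0}
    for s in state:
        if s.id in activated:
            assert _in_any_roi(s.centroid_um, rois)
    # pre-activation frames carry no bright PA-GFP at all
    for st in run.states[: params.t_act]:
        assert all(s.pagfp_bright == 0.0 for s in st)
    # afterwards, bright PA-GFP may appear only on segments that shared a
    # component with an already-contaminated segment (mixing lineage)
    allowed = set(activated)
    for st in run.states[params.t_act :]:
        comps: dict[int, set[int]] = {}
        for s in st:
            comps.setdefault(s.component_id, set()).add(s.id)
        for members in comps.values():
            if members & allowed:
                allowed |= members
        for s in st:
            if s.pagfp_bright > 1e-12:
                assert s.id in allowed


def test_held_pair_transient_typing():
    """A fused pair that fissions later is typed transient with the fused
    interval as duration."""
    params, init = held_pair_params(k_fuse=5.0, k_fiss=0.05, n_frames=40, seed=3)
    run = simulate(params, render_series=False, init_segments=init)
    assert run.truth_events, "pair in permanent contact must fuse"
    first = run.truth_events[0]
    if run.fission_records:
        assert first.type == "transient"
        assert first.duration_s is not None and first.duration_s > 0
        assert first.duration_s % params.frame_interval_s == 0


def test_hazard_matches_markov_recursion_oracle():
    params, init = held_pair_params(k_fuse=0.08, k_fiss=0.15, n_frames=50)
    expected = expected_fusion_events(params)
    counts = []
    for seed in range(100):
        run = simulate(
            dataclasses.replace(params, seed=seed),
            render_series=False,
            init_segments=init,
        )
        counts.append(len(run.truth_events))
    counts = np.asarray(counts, float)
    se = counts.std(ddof=1) / np.sqrt(len(counts))
    assert abs(counts.mean() - expected) <= 3.0 * se


def test_expected_events_closed_form_without_fission():
    # with no fission the pair can fuse at most once:
    # E[events] = 1 - (1 - p)^n with p = 1 - exp(-k dt)
    params, _ = held_pair_params(k_fuse=0.25, k_fiss=0.0, n_frames=50)
    p = 1.0 - np.exp(-0.25 * params.frame_interval_s)
    n = params.n_frames - 1
    assert expected_fusion_events(params) == pytest.approx(1 - (1 - p) ** n, rel=1e-12)


# -- rendering -------------------------------------------------------------


def test_render_dark_channel_is_pure_background():
    params = small_params(
        n_segments=3,
        n_pre_frames=1,
        n_post_frames=1,
        k_fuse_per_contact_s=0.0,
        act_rois=((11.0, 11.0, 1.0),),  # activates nothing
        photons_per_unit=float("inf"),
        background=6.0,
    )
    run = simulate(params)
    gfp = run.series.pixels[0, 0]
    assert np.all(gfp == 6)  # no bright PA-GFP anywhere before activation


def test_render_integrated_intensity_proportional_to_amount():
    params = SimParams(
        n_segments=1,
        field_um=6.4,
        n_pre_frames=0,
        n_post_frames=1,
        psf_sigma_um=0.0,
        photons_per_unit=float("inf"),
        background=0.0,
        bit_depth=16,
        density_per_um=500.0,
        act_rois=((0.0, 0.0, 1.0),),
        seed=1,
    )
    seg = Segment(0, (3.2, 3.2), 0.5, 1.5, 0, dsred_amount=750.0, pagfp_dark=0.0)
    img = render([[seg]], params).pixels[0, 1].astype(float)
    assert img.sum() == pytest.approx(750.0, rel=0.01)  # quantization only


def test_render_rejects_bad_inputs():
    params = small_params()
    with pytest.raises(ValueError):
        render([], params)
    with pytest.raises(ValueError):
        render([[]], dataclasses.replace(params, bit_depth=12))


def test_render_deterministic_for_fixed_seed():
    params = small_params(n_pre_frames=1, n_post_frames=3)
    states = simulate(params, render_series=False).states
    a = render(states, params)
    b = render(states, params)
    assert np.array_equal(a.pixels, b.pixels)


# -- staged scenes ---------------------------------------------------------


def test_staged_run_ground_truth_layout():
    run = staged_fusion_run(n_pairs=4, transient_pairs=(1,), seed=5)
    frames = [e.frame for e in run.truth_events]
    assert len(frames) == 4
    assert min(np.diff(frames)) >= 5  # well-separated events
    types = [e.type for e in run.truth_events]
    assert types.count("transient") == 1
    tr = next(e for e in run.truth_events if e.type == "transient")
    assert tr.duration_s == 8 * run.params.frame_interval_s
    assert all(e.orientation == "end_to_end" for e in run.truth_events)


def test_staged_run_mixes_content_at_event_frame():
    run = staged_fusion_run(n_pairs=1, seed=2)
    ev = run.truth_events[0]
    before = {s.id: s for s in run.states[ev.frame - 1]}
    after = {s.id: s for s in run.states[ev.frame]}
    assert before[ev.id_b].pagfp_bright == 0.0
    assert after[ev.id_b].pagfp_bright > 0.0
    assert after[ev.id_a].dsred_amount > before[ev.id_a].dsred_amount
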