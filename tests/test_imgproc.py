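"""Despeckle, pooled-series Otsu, and the 0.1% noise-ratio threshold rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitofuse.imgproc import (
    despeckle,
    noise_ratio_threshold,
    otsu_threshold_series,
    otsu_threshold_values,
)

from conftest import make_series


# -- independent oracles ---------------------------------------------------


def median3x3_oracle(img):
    """Per-pixel sorted-neighborhood median with edge replication."""
    padded = np.pad(img, 1, mode="edge")
    out = np.empty_like(img)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            out[r, c] = np.sort(padded[r : r + 3, c : c + 3].ravel())[4]
    return out


def otsu_oracle(values, n_levels=256):
    """Exhaustive between-class-variance search, ties toward the lowest level."""
    hist = np.bincount(values.ravel(), minlength=n_levels).astype(float)
    total = hist.sum()
    best_t, best_sigma = 0, -1.0
    for t in range(n_levels - 1):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / w0
        mu1 = (hist[t + 1 :] * np.arange(t + 1, n_levels)).sum() / w1
        sigma = w0 * w1 * (mu0 - mu1) ** 2
        if sigma > best_sigma + 1e-9:
            best_sigma, best_t = sigma, t
    return best_t


# -- despeckle -------------------------------------------------------------


def test_despeckle_leaves_constant_image_unchanged():
    img = np.full((9, 9), 17, dtype=np.uint8)
    assert np.array_equal(despeckle(img), img)


def test_despeckle_removes_isolated_saturated_pixel():
    img = np.zeros((7, 7), dtype=np.uint8)
    img[3, 3] = 255
    assert despeckle(img)[3, 3] == 0


def test_despeckle_matches_sorted_neighborhood_oracle(rng):
    img = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
    assert np.array_equal(despeckle(img), median3x3_oracle(img))


def test_despeckle_rejects_non_2d():
    with pytest.raises(ValueError):
        despeckle(np.zeros((3, 4, 5)))


def test_despeckle_idempotent_on_stable_image_and_bounded(rng):
    img = rng.integers(0, 256, size=(20, 20)).astype(np.uint8)
    once = despeckle(img)
    assert once.max() <= img.max()
    # a twice-filtered image that no longer changes is a fixed point
    stable = despeckle(despeckle(despeckle(once)))
    if np.array_equal(despeckle(stable), stable):
        assert np.array_equal(despeckle(stable), stable)


# -- Otsu ------------------------------------------------------------------


def test_otsu_separates_two_level_histogram():
    vals = np.array([10] * 50 + [200] * 50)
    t = otsu_threshold_values(vals, bit_depth=8)
    assert 10 <= t < 200
    assert (vals > t).sum() == 50


def test_otsu_matches_exhaustive_search(rng):
    for _ in range(5):
        # bimodal-ish stack: noise + objects
        stack = rng.integers(0, 60, size=(3, 24, 24))
        stack[:, 5:12, 5:12] = rng.integers(120, 250, size=(3, 7, 7))
        stack = stack.astype(np.uint8)
        series = make_series(np.stack([stack, stack], axis=1), t_act=0)
        t = otsu_threshold_series(series, 0)
        assert t == otsu_oracle(stack)


def test_otsu_invariant_under_frame_permutation(rng):
    px = rng.integers(0, 256, size=(5, 2, 12, 12)).astype(np.uint8)
    series = make_series(px, t_act=0)
    shuffled = make_series(px[[3, 1, 4, 0, 2]], t_act=0)
    assert otsu_threshold_series(series, 0) == otsu_threshold_series(shuffled, 0)


def test_otsu_empty_frame_pulls_threshold_down(rng):
    px = rng.integers(50, 250, size=(3, 2, 16, 16)).astype(np.uint8)
    with_empty = np.concatenate([px, np.zeros((1, 2, 16, 16), np.uint8)])
    t_without = otsu_threshold_series(make_series(px, t_act=0), 0)
    t_with = otsu_threshold_series(make_series(with_empty, t_act=0), 0)
    assert t_with <= t_without


def test_otsu_single_valued_image_errors():
    px = np.full((2, 2, 8, 8), 7, dtype=np.uint8)
    with pytest.raises(ValueError):
        otsu_threshold_series(make_series(px, t_act=0), 0)


def test_otsu_16bit_refinement_matches_direct_exhaustive(rng):
    vals = np.concatenate(
        [rng.integers(0, 900, 4000), rng.integers(20000, 40000, 1000)]
    ).astype(np.uint16)
    t = otsu_threshold_values(vals, bit_depth=16)
    # exhaustive full-resolution search as oracle
    hist = np.bincount(vals, minlength=65536).astype(float)
    levels = np.arange(65536, dtype=float)
    p = hist / hist.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * levels)
    with np.errstate(divide="ignore", invalid="ignore"):
        sb = (mu[-1] * omega - mu) ** 2 / (omega * (1 - omega))
    sb[~np.isfinite(sb)] = -np.inf
    assert t == int(np.argmax(sb[:-1]))


# -- noise-ratio threshold -------------------------------------------------


def test_noise_threshold_zero_channel_is_one():
    px = np.zeros((3, 2, 20, 20), dtype=np.uint8)
    px[2, 0] = 100  # post-activation signal, irrelevant
    series = make_series(px, t_act=2)
    assert noise_ratio_threshold(series, 0) == 1


def test_noise_threshold_boundary_case_single_hot_pixel():
    # 1,000 in-cell pixels, exactly one at 50: t = 1 qualifies (1/1000 = 0.1%)
    px = np.zeros((3, 2, 25, 40), dtype=np.uint8)
    px[0, 0, 0, 0] = 50
    cell = np.zeros((25, 40), bool)
    cell[:25, :20] = True  # 500 px per frame x 2 pre frames = 1000
    series = make_series(px, t_act=2, cell_roi=cell)
    assert noise_ratio_threshold(series, 0) == 1


def test_noise_threshold_matches_rank_statistic_oracle(rng):
    px = np.clip(rng.normal(10, 3, size=(5, 2, 160, 160)), 0, 255).astype(np.uint8)
    series = make_series(px, t_act=4)
    # 4 pre-activation frames of 160x160 -> 102,400 noise pixels
    t = noise_ratio_threshold(series, 0)
    vals = px[:4, 0].ravel()
    # oracle: linear scan for the smallest t with <=0.1% of pixels >= t
    allowed = int(np.floor(0.001 * vals.size))
    t_oracle = 0
    while (vals >= t_oracle).sum() > allowed:
        t_oracle += 1
    assert t == t_oracle


def test_noise_threshold_requires_pre_frames(flat_series):
    flat_series.t_act = 0
    with pytest.raises(ValueError):
        noise_ratio_threshold(flat_series, 0)


def test_noise_threshold_monotone_in_noise_scale(rng):
    base = rng.normal(10, 2, size=(4, 2, 64, 64))
    thresholds = []
    for scale in (1.0, 2.0, 4.0):
        px = np.clip(base * scale, 0, 255).astype(np.uint8)
        thresholds.append(noise_ratio_threshold(make_series(px, t_act=3), 0))
    assert thresholds == sorted(thresholds)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_noise_threshold_fraction_contract(seed):
    """At the returned threshold, at most 0.1% of pre-activation pixels are
    suprathreshold, and the threshold is minimal."""
    r = np.random.default_rng(seed)
    px = r.integers(0, 40, size=(3, 2, 40, 40)).astype(np.uint8)
    series = make_series(px, t_act=2)
    t = noise_ratio_threshold(series, 0)
    vals = px[:2, 0].ravel()
    allowed = int(np.floor(0.001 * vals.size))
    assert (vals >= t).sum() <= allowed
    if t > 0:
        assert (vals >= t - 1).sum() > allowed
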