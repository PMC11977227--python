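"""Concealment operators: oracles, idempotence, locality, seeded noise."""

import numpy as np
import pytest

import pulseveil as pv
from pulseveil.errors import ConfigError, DimensionError, StateError
from pulseveil.filters import (FilterConfig, FilterState, METHODS, add_noise,
                               apply_filter, bilateral_blur, gaussian_blur,
                               gaussian_kernel_1d, median_blur, modify_video,
                               moving_average_gain, ta_cumulative_step,
                               ta_sliding_step)
from pulseveil.roi import ROIMask, SyntheticLandmarkProvider


def full_mask(h=8, w=8):
    return ROIMask(np.ones((h, w)), "full_frame")


def gray(v, h=8, w=8):
    return np.full((h, w, 3), v, dtype=np.uint8)


# --- configuration validation -------------------------------------------------

@pytest.mark.parametrize("kwargs", [
    {"method": "XX"},
    {"method": "MB", "kernel_size": 4},
    {"method": "GB", "kernel_size": 0},
    {"method": "BB", "sigma_space": -1.0},
    {"method": "TA-S", "window_frames": 0},
    {"method": "SPN", "noise_params": {"amount": 1.5}},
])
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ConfigError):
        FilterConfig(**kwargs)


# --- blurs --------------------------------------------------------------------

@pytest.mark.parametrize("method", ["MB", "GB", "BB", "TA-C", "TA-S"])
def test_smoothing_methods_leave_constant_frames_unchanged(method):
    cfg = FilterConfig(method=method)
    state = FilterState.for_config(cfg)
    frame = gray(123)
    for _ in range(3):
        out, state = apply_filter(frame, full_mask(), cfg, state)
        assert np.array_equal(out, frame)


def test_median_blur_removes_isolated_spike():
    frame = gray(0, 9, 9)
    frame[4, 4] = 255
    out = median_blur(frame, full_mask(9, 9), FilterConfig(method="MB", kernel_size=5))
    assert out[4, 4, 0] == 0  # median of 25 values with one 255 is 0


def test_gaussian_kernel_normalized_and_symmetric():
    for k in (3, 5, 7):
        w = gaussian_kernel_1d(k)
        assert abs(w.sum() - 1.0) < 1e-12
        assert np.allclose(w, w[::-1])


def test_gaussian_blur_preserves_linear_ramp_interior():
    """A symmetric normalized kernel reproduces a linear signal exactly."""
    ramp = np.tile(np.arange(20, 120, 5, dtype=np.uint8)[None, :, None], (20, 1, 3))
    out = gaussian_blur(ramp, full_mask(20, 20), FilterConfig(method="GB", kernel_size=5))
    interior = (slice(3, -3), slice(3, -3))
    assert np.max(np.abs(out[interior].astype(int) - ramp[interior].astype(int))) <= 1


def test_gaussian_blur_matches_direct_convolution_oracle(rng):
    frame = rng.integers(0, 256, (12, 12, 3), dtype=np.uint8)
    cfg = FilterConfig(method="GB", kernel_size=5)
    out = gaussian_blur(frame, full_mask(12, 12), cfg)
    w1 = gaussian_kernel_1d(5)
    kernel = np.outer(w1, w1)
    pad = np.pad(frame.astype(float), ((2, 2), (2, 2), (0, 0)), mode="reflect")
    expected = np.empty_like(frame, dtype=float)
    for i in range(12):
        for j in range(12):
            patch = pad[i:i + 5, j:j + 5]
            expected[i, j] = (patch * kernel[..., None]).sum(axis=(0, 1))
    assert np.array_equal(out, np.clip(np.floor(expected + 0.5), 0, 255).astype(np.uint8))


def test_bilateral_preserves_step_edge_better_than_gaussian():
    frame = np.zeros((10, 10, 3), dtype=np.uint8)
    frame[:, 5:] = 200
    cfg = FilterConfig(method="BB", sigma_space=75.0, sigma_range=10.0)
    bb = bilateral_blur(frame, full_mask(10, 10), cfg)
    gb = gaussian_blur(frame, full_mask(10, 10), FilterConfig(method="GB", kernel_size=5))
    # pixel adjacent to the edge: bilateral stays near its side's level
    assert abs(int(bb[5, 4, 0]) - 0) < abs(int(gb[5, 4, 0]) - 0)
    assert abs(int(bb[5, 5, 0]) - 200) < abs(int(gb[5, 5, 0]) - 200)


# --- temporal averaging -------------------------------------------------------

def test_ta_cumulative_alternating_sequence():
    """Pixels alternating 0,255: output at t is round(running mean)."""
    cfg = FilterConfig(method="TA-C")
    state = FilterState.for_config(cfg)
    seen = []
    for t in range(4):
        frame = gray(255 if t % 2 else 0)
        out, state = ta_cumulative_step(frame, full_mask(), state)
        seen.append(out[0, 0, 0])
    # means: 0, 127.5, 85, 127.5 → rounded half-away-from-zero
    assert seen == [0, 128, 85, 128]


def test_ta_cumulative_matches_bruteforce_mean(rng):
    frames = rng.integers(0, 256, (30, 6, 6, 3), dtype=np.uint8)
    state = FilterState()
    for t in range(30):
        out, state = ta_cumulative_step(frames[t], full_mask(6, 6), state)
        expected = np.floor(frames[: t + 1].astype(float).mean(axis=0) + 0.5)
        assert np.array_equal(out, expected.astype(np.uint8))


def test_ta_cumulative_shape_change_is_state_error():
    state = FilterState()
    ta_cumulative_step(gray(0, 4, 4), full_mask(4, 4), state)
    with pytest.raises(StateError):
        ta_cumulative_step(gray(0, 5, 5), full_mask(5, 5), state)


def test_ta_sliding_window_one_is_identity(rng):
    cfg = FilterConfig(method="TA-S", window_frames=1)
    state = FilterState()
    for _ in range(5):
        frame = rng.integers(0, 256, (6, 6, 3), dtype=np.uint8)
        out, state = ta_sliding_step(frame, full_mask(6, 6), state, cfg)
        assert np.array_equal(out, frame)


def test_ta_sliding_warmup_then_window_mean(rng):
    f = 4
    cfg = FilterConfig(method="TA-S", window_frames=f)
    state = FilterState()
    frames = rng.integers(0, 256, (10, 5, 5, 3), dtype=np.uint8)
    for t in range(10):
        out, state = ta_sliding_step(frames[t], full_mask(5, 5), state, cfg)
        lo = max(0, t - f + 1)
        expected = np.floor(frames[lo:t + 1].astype(float).mean(axis=0) + 0.5)
        assert np.array_equal(out, expected.astype(np.uint8))


@pytest.mark.parametrize("fr,w,r,expected", [
    (1.5, 20, 25, 0.1568),
    (1.2, 20, 25, 0.0417),
    (1.0, 10, 25, 0.7588),
    (0.9, 15, 20, 0.4034),
])
def test_ta_sliding_gain_matches_dirichlet_formula(fr, w, r, expected):
    """Measured amplitude ratio on a sinusoidal pixel equals the closed form."""
    assert moving_average_gain(fr, w, r) == pytest.approx(expected, abs=5e-4)
    n = int(r * 12) + w
    t = np.arange(n) / r
    amp = 100.0
    cfg = FilterConfig(method="TA-S", window_frames=w)
    state = FilterState()
    outs = []
    for v in 127.0 + amp * np.sin(2 * np.pi * fr * t):
        frame = np.full((2, 2, 3), np.clip(np.floor(v + 0.5), 0, 255), dtype=np.uint8)
        out, state = ta_sliding_step(frame, full_mask(2, 2), state, cfg)
        outs.append(float(out[0, 0, 0]))
    y = np.array(outs[w:]) - np.mean(outs[w:])
    tt = t[w:]
    # amplitude via quadrature projection (phase-insensitive)
    c = 2 * np.mean(y * np.cos(2 * np.pi * fr * tt))
    s = 2 * np.mean(y * np.sin(2 * np.pi * fr * tt))
    measured = np.hypot(c, s) / amp
    assert measured == pytest.approx(moving_average_gain(fr, w, r), abs=0.01)


# --- noise --------------------------------------------------------------------

@pytest.mark.parametrize("method", ["AGN", "AGN-L", "SPN", "PoN", "PeN", "SN"])
def test_noise_is_seed_deterministic(method, rng):
    frame = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
    cfg = FilterConfig(method=method, seed=11)
    runs = []
    for _ in range(2):
        state = FilterState.for_config(cfg)
        out1, state = add_noise(frame, full_mask(16, 16), cfg, state)
        out2, state = add_noise(frame, full_mask(16, 16), cfg, state)
        runs.append((out1, out2))
    assert np.array_equal(runs[0][0], runs[1][0])
    assert np.array_equal(runs[0][1], runs[1][1])
    assert not np.array_equal(runs[0][0], runs[0][1])  # rng advances across frames


def test_spn_fraction_and_values():
    frame = np.full((400, 400, 3), 128, dtype=np.uint8)
    cfg = FilterConfig(method="SPN", seed=3)
    out, _ = add_noise(frame, full_mask(400, 400), cfg, FilterState.for_config(cfg))
    changed = np.any(out != frame, axis=2)
    assert changed.mean() == pytest.approx(0.05, abs=0.01)
    assert set(np.unique(out[changed])) <= {0, 255}


def test_pen_sets_pixels_to_zero_only():
    frame = np.full((200, 200, 3), 128, dtype=np.uint8)
    cfg = FilterConfig(method="PeN", seed=3)
    out, _ = add_noise(frame, full_mask(200, 200), cfg, FilterState.for_config(cfg))
    changed = np.any(out != frame, axis=2)
    assert changed.mean() == pytest.approx(0.05, abs=0.01)
    assert np.all(out[changed] == 0)


def test_agn_unit_variance_calibration():
    frame = np.full((400, 400, 3), 128, dtype=np.uint8)
    cfg = FilterConfig(method="AGN", seed=3)
    out, _ = add_noise(frame, full_mask(400, 400), cfg, FilterState.for_config(cfg))
    v = ((out.astype(float) - frame.astype(float)) / 255.0).var()
    assert v == pytest.approx(0.01, rel=0.10)


def test_speckle_scales_with_intensity():
    """SN noise std is proportional to the local intensity."""
    frame = np.full((200, 200, 3), 64, dtype=np.uint8)
    frame[:, 100:] = 192
    cfg = FilterConfig(method="SN", seed=5)
    out, _ = add_noise(frame, full_mask(200, 200), cfg, FilterState.for_config(cfg))
    d = (out.astype(float) - frame.astype(float)) / 255.0
    lo, hi = d[:, :100].std(), d[:, 100:].std()
    assert hi / lo == pytest.approx(3.0, rel=0.15)  # 192/64


def test_poisson_noise_mean_preserving():
    frame = np.full((300, 300, 3), 100, dtype=np.uint8)
    cfg = FilterConfig(method="PoN", seed=5)
    out, _ = add_noise(frame, full_mask(300, 300), cfg, FilterState.for_config(cfg))
    assert out.astype(float).mean() == pytest.approx(100, abs=0.5)
    assert out.std() > 0


# --- overlay & pipeline -------------------------------------------------------

def test_overlay_matches_per_pixel_oracle(rng):
    a = rng.integers(0, 256, (10, 10, 3), dtype=np.uint8)
    b = rng.integers(0, 256, (10, 10, 3), dtype=np.uint8)
    m = rng.random((10, 10)) < 0.5
    out = pv.overlay_roi(a, b, ROIMask(m, "full_frame"))
    for i in range(10):
        for j in range(10):
            assert np.array_equal(out[i, j], b[i, j] if m[i, j] else a[i, j])
    assert np.array_equal(pv.overlay_roi(a, b, ROIMask(np.zeros((10, 10)), "x")), a)
    assert np.array_equal(pv.overlay_roi(a, b, ROIMask(np.ones((10, 10)), "x")), b)


def test_overlay_shape_mismatch():
    with pytest.raises(DimensionError):
        pv.overlay_roi(gray(0, 4, 4), gray(0, 5, 5), ROIMask(np.ones((4, 4)), "x"))


def test_ne_is_bit_identical(tiny_scene):
    out = modify_video(tiny_scene.video, "full_frame", FilterConfig(method="NE"))
    assert np.array_equal(out.frames, tiny_scene.video.frames)
    assert pv.frame_mse(tiny_scene.video, out) == 0.0


@pytest.mark.parametrize("method", [m for m in METHODS if m != "NE"])
def test_roi_locality_all_methods(method, tiny_scene):
    """Outside-mask pixels are bit-identical to the input, every frame."""
    provider = SyntheticLandmarkProvider(tiny_scene.landmarks)
    cfg = FilterConfig(method=method, seed=4)
    out = modify_video(tiny_scene.video, "facial_skin", cfg, provider)
    assert out.frames.dtype == np.uint8
    for t in range(len(tiny_scene.video)):
        mask = pv.facial_skin_mask(tiny_scene.landmarks[t], tiny_scene.video.shape).mask
        assert np.array_equal(out.frames[t][~mask], tiny_scene.video.frames[t][~mask]), method


def test_modify_video_needs_provider_for_skin_roi(tiny_scene):
    with pytest.raises(ConfigError):
        modify_video(tiny_scene.video, "facial_skin", FilterConfig(method="MB"))
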