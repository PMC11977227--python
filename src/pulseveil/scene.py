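"""Synthetic pulse-modulated facial scenes with exact ground truth.

Every other module is testable against this generator: it renders an
ellipsoidal "skin" region whose RGB intensities are modulated by a known
pulse waveform (green strongest, mimicking hemoglobin absorption), darker
static "eye" and "mouth" rectangles that carry no pulse, optional Gaussian
sensor noise, optional rigid linear drift, a matching landmark set per frame
(outer face ring, eye/mouth corners, and ≥100 forehead/cheek/nose grid
points), and a co-registered ground-truth PPG sampled at 60 Hz from the very
same waveform formula. Everything is deterministic given the seed.

Two structural features make the scene a fair test bed for the estimators:
a static fixed-pattern texture that dithers 8-bit rounding (without it, a
uniform patch quantizes coherently and sub-step pulse amplitudes vanish
entirely), and a common-mode illumination flicker along the base-color axis
(the in-band disturbance the projection-based methods are designed to
reject; without it the pulse is the dominant data direction and LGI's
projection would remove exactly the signal of interest). See
docs/methods.md for the rationale and parameter choices.

The pulse is additive in intensity — a linear small-signal model of
blood-volume absorption: skin(t) = base_color + (a_R, a_G, a_B)·w(t) + noise.
Default amplitudes (0.45, 1.5, 0.9) put the green pulse a few PSD noise
standard deviations above the floor at the default sensor noise, so clean
recovery is easy and concealment is measurable.

What this scene does NOT emulate: facial texture, specular highlights,
illumination changes, non-rigid motion (talking, rotation). Passing tests on
synthetic scenes validates the signal path, not robustness to those real-data
phenomena.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, EmptyInputError, PulseveilError
from .io_media import PPGRecord, VideoSequence
from .roi import LandmarkSet
from .rppg import BAND_HZ

_BACKGROUND = (40, 40, 45)
_DARK_FACTOR = 0.3  # eye/mouth brightness relative to base skin color


@dataclass
class SceneConfig:
    """Parameters of a synthetic scene; defaults give a 72-bpm face at 25 fps."""

    width: int = 128
    height: int = 128
    frame_rate: float = 25.0
    duration: float = 10.0
    hr_bpm: float = 72.0
    pulse_waveform: str = "sinusoid"  # or "sinusoid+harmonic"
    channel_amplitudes: tuple[float, float, float] = (0.45, 1.5, 0.9)
    base_color: tuple[float, float, float] = (180.0, 120.0, 100.0)
    sensor_noise_sigma: float = 0.5
    texture_amplitude: float = 0.5
    illumination_rel_sigma: float = 0.007
    illumination_tones: int = 24
    motion: tuple[float, float] = (0.0, 0.0)  # linear drift, px/s
    ppg_rate: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        f = self.hr_bpm / 60.0
        if not BAND_HZ[0] < f < BAND_HZ[1]:
            raise ConfigError(
                f"hr_bpm={self.hr_bpm} outside the physiological band "
                f"({BAND_HZ[0]*60:.0f}-{BAND_HZ[1]*60:.0f} bpm, exclusive)")
        if self.pulse_waveform not in ("sinusoid", "sinusoid+harmonic"):
            raise ConfigError(f"unknown pulse_waveform {self.pulse_waveform!r}")
        if any(a < 0 for a in self.channel_amplitudes):
            raise ConfigError("channel amplitudes must be ≥0")
        wmax = 1.3 if self.pulse_waveform == "sinusoid+harmonic" else 1.0
        for base, amp in zip(self.base_color, self.channel_amplitudes):
            headroom = (amp * wmax + 4.0 * self.sensor_noise_sigma
                        + self.texture_amplitude
                        + 4.0 * base * self.illumination_rel_sigma)
            if base - headroom < 0 or base + headroom > 255:
                raise ConfigError(
                    f"base color {base} ± amplitude {amp} (+noise) exceeds [0,255]")


@dataclass
class SyntheticScene:
    """A rendered scene: video, ground-truth PPG, per-frame landmarks, true HR."""

    video: VideoSequence
    ppg: PPGRecord
    landmarks: list[LandmarkSet]
    truth_bpm: float
    config: SceneConfig = field(repr=False, default=None)


def _waveform(cfg: SceneConfig, t: np.ndarray) -> np.ndarray:
    """Unit-amplitude pulse waveform evaluated at times t (seconds)."""
    f = cfg.hr_bpm / 60.0
    w = np.sin(2 * np.pi * f * t)
    if cfg.pulse_waveform == "sinusoid+harmonic":
        w = w + 0.3 * np.sin(4 * np.pi * f * t)
    return w


def ppg_waveform(cfg: SceneConfig) -> PPGRecord:
    """The ground-truth PPG: the pulse waveform sampled at cfg.ppg_rate."""
    n = int(round(cfg.duration * cfg.ppg_rate))
    if n < 1:
        raise EmptyInputError("duration too short for a single PPG sample")
    t = np.arange(n) / cfg.ppg_rate
    return PPGRecord(_waveform(cfg, t), cfg.ppg_rate)


class _Geometry:
    """Scene geometry in pixel coordinates, given a face-center offset."""

    def __init__(self, cfg: SceneConfig, dx: float = 0.0, dy: float = 0.0):
        w, h = cfg.width, cfg.height
        self.cx, self.cy = w / 2 + dx, h / 2 + dy
        self.rx, self.ry = 0.35 * w, 0.42 * h
        # eye/mouth rectangles as (cx, cy, half_w, half_h)
        self.left_eye = (self.cx - 0.14 * w, self.cy - 0.14 * h, 0.047 * w, 0.023 * h)
        self.right_eye = (self.cx + 0.14 * w, self.cy - 0.14 * h, 0.047 * w, 0.023 * h)
        self.mouth = (self.cx, self.cy + 0.22 * h, 0.094 * w, 0.031 * h)
        self.shape = (h, w)

    def ellipse_mask(self) -> np.ndarray:
        h, w = self.shape
        ys, xs = np.mgrid[0:h, 0:w]
        return (((xs + 0.5 - self.cx) / self.rx) ** 2
                + ((ys + 0.5 - self.cy) / self.ry) ** 2) <= 1.0

    def rect_mask(self, rect) -> np.ndarray:
        cx, cy, hw, hh = rect
        h, w = self.shape
        ys, xs = np.mgrid[0:h, 0:w]
        return (np.abs(xs + 0.5 - cx) <= hw) & (np.abs(ys + 0.5 - cy) <= hh)

    def inside_ellipse(self, pts: np.ndarray, margin: float = 1.0) -> np.ndarray:
        return (((pts[:, 0] - self.cx) / self.rx) ** 2
                + ((pts[:, 1] - self.cy) / self.ry) ** 2) <= margin

    def landmark_set(self, cfg: SceneConfig) -> LandmarkSet:
        w, h = cfg.width, cfg.height
        cx, cy = self.cx, self.cy

        def grid(x0, x1, y0, y1, nx, ny):
            gx, gy = np.meshgrid(np.linspace(x0, x1, nx), np.linspace(y0, y1, ny))
            return np.stack([gx.ravel(), gy.ravel()], axis=1)

        theta = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        outer = np.stack([cx + self.rx * np.cos(theta), cy + self.ry * np.sin(theta)], axis=1)

        def rect_corners(rect):
            rcx, rcy, hw, hh = rect
            return np.array([[rcx - hw, rcy - hh], [rcx + hw, rcy - hh],
                             [rcx + hw, rcy + hh], [rcx - hw, rcy + hh]])

        forehead = grid(cx - 0.19 * w, cx + 0.19 * w, cy - 0.34 * h, cy - 0.23 * h, 8, 6)
        left_cheek = grid(cx - 0.23 * w, cx - 0.08 * w, cy, cy + 0.14 * h, 5, 5)
        right_cheek = grid(cx + 0.08 * w, cx + 0.23 * w, cy, cy + 0.14 * h, 5, 5)
        nose = grid(cx - 0.04 * w, cx + 0.04 * w, cy - 0.08 * h, cy + 0.06 * h, 3, 4)

        blocks = [("outer_face", outer), ("left_eye", rect_corners(self.left_eye)),
                  ("right_eye", rect_corners(self.right_eye)),
                  ("mouth", rect_corners(self.mouth)), ("forehead", forehead),
                  ("left_cheek", left_cheek), ("right_cheek", right_cheek), ("nose", nose)]
        points, groups, start = [], {}, 0
        for name, pts in blocks:
            points.append(pts)
            groups[name] = list(range(start, start + len(pts)))
            start += len(pts)
        return LandmarkSet(np.concatenate(points), groups)


def _illumination(cfg: SceneConfig, t: np.ndarray) -> np.ndarray:
    """Common-mode relative illumination fluctuation shared by all skin pixels.

    A sum of sinusoids with seeded random frequencies in 2.6-3.8 Hz (think
    aliased mains flicker and fast ambient fluctuations) and random phases —
    the intensity disturbance that the projection-based rPPG methods
    (LGI, POS, CHROM) are built to reject. It sits inside the passband, so it
    reaches the BVP extractors, and its total variance exceeds the pulse's,
    so the dominant data direction is the illumination axis (the base color)
    rather than the pulse; its band lies above common resting/active heart
    rates, so it does not crowd the pulse peak itself.
    """
    if cfg.illumination_rel_sigma <= 0 or cfg.illumination_tones < 1:
        return np.zeros_like(t)
    rng = np.random.default_rng([cfg.seed, 1])
    k = cfg.illumination_tones
    # equispaced tones, random phases: a flat comb avoids the rogue spectral
    # peaks that randomly clustered tones would produce
    freqs = np.linspace(2.6, 3.8, k)
    phases = rng.uniform(0, 2 * np.pi, size=k)
    amp = cfg.illumination_rel_sigma * np.sqrt(2.0 / k)
    return (amp * np.sin(2 * np.pi * freqs[:, None] * t[None, :]
                         + phases[:, None])).sum(axis=0)


def render_scene(cfg: SceneConfig) -> SyntheticScene:
    """Render the full scene: video + ground-truth PPG + per-frame landmarks."""
    n_frames = int(round(cfg.duration * cfg.frame_rate))
    if n_frames < 1:
        raise EmptyInputError("duration too short for a single frame")
    rng_texture = np.random.default_rng([cfg.seed, 0])
    rng = np.random.default_rng([cfg.seed, 2])
    frame_times = np.arange(n_frames) / cfg.frame_rate
    w_t = _waveform(cfg, frame_times)
    flick_t = _illumination(cfg, frame_times)
    amps = np.asarray(cfg.channel_amplitudes)
    base = np.asarray(cfg.base_color)
    # static fixed-pattern texture: dithers 8-bit rounding so patch averages
    # resolve sub-quantization pulse amplitudes, as real skin texture does
    texture = rng_texture.uniform(-cfg.texture_amplitude, cfg.texture_amplitude,
                                  size=(cfg.height, cfg.width, 3))

    static_motion = cfg.motion == (0.0, 0.0)
    geo0 = _Geometry(cfg)
    frames = np.empty((n_frames, cfg.height, cfg.width, 3), dtype=np.uint8)
    landmarks: list[LandmarkSet] = []
    background = np.tile(np.array(_BACKGROUND, dtype=np.float64),
                         (cfg.height, cfg.width, 1))
    geo, skin, dark, pulse_px = None, None, None, None
    for t in range(n_frames):
        if geo is None or not static_motion:
            dx, dy = cfg.motion[0] * frame_times[t], cfg.motion[1] * frame_times[t]
            geo = _Geometry(cfg, dx, dy)
            skin = geo.ellipse_mask()
            dark = (geo.rect_mask(geo.left_eye) | geo.rect_mask(geo.right_eye)
                    | geo.rect_mask(geo.mouth)) & skin
            pulse_px = skin & ~dark
            lm = geo.landmark_set(cfg)
            if not geo.inside_ellipse(
                    np.concatenate([lm.group_points(g) for g in
                                    ("forehead", "left_cheek", "right_cheek", "nose")])).all():
                raise PulseveilError("internal: skin landmarks left the ellipse")
        else:
            lm = landmarks[0]
        img = background.copy()
        img[skin] = base
        img[dark] = base * _DARK_FACTOR
        vals = base * (1.0 + flick_t[t]) + amps * w_t[t]
        img[pulse_px] = vals + texture[pulse_px]
        if cfg.sensor_noise_sigma > 0:
            img[pulse_px] += rng.normal(0.0, cfg.sensor_noise_sigma,
                                        size=(int(pulse_px.sum()), 3))
        frames[t] = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
        landmarks.append(lm)
    video = VideoSequence(frames, cfg.frame_rate)
    return SyntheticScene(video=video, ppg=ppg_waveform(cfg), landmarks=landmarks,
                          truth_bpm=cfg.hr_bpm, config=cfg)


def scene_landmarks(scene: SyntheticScene, t: int) -> LandmarkSet:
    """The exact landmark set of frame t; IndexError outside the frame range."""
    if not 0 <= t < len(scene.landmarks):
        raise IndexError(f"frame index {t} out of range [0, {len(scene.landmarks)})")
    return scene.landmarks[t]
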