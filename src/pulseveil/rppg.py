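"""Heart-rate estimation from facial video (remote photoplethysmography).

Pipeline: average the R, G, B channels over square skin patches centered on
up to 100 equispaced landmarks (forehead, cheeks, nose) → slice the trace
into overlapping 8-s windows at a 1-s stride → per window, linearly detrend
and zero-phase bandpass (sixth-order Butterworth, 0.65–4.0 Hz, i.e.
39–240 bpm) → extract a blood-volume-pulse (BVP) signal with one of five
classical methods → read heart rate off the Welch power-spectrum peak.

The five BVP extractors:

* GREEN — the green channel as-is; hemoglobin absorption makes green the
  most pulse-informative channel.
* ICA — blind source separation of the three channels (FastICA, seeded);
  the pulse-carrying component is selected deterministically by in-band
  spectral energy (ICA's output order is arbitrary, so "which component"
  must be pinned down by a rule; see bvp_ica).
* CHROM — two chrominance combinations of mean-normalized channels,
  X = 3Rn − 2Gn and Y = 1.5Rn + Gn − 1.5Bn, mixed as X − (σX/σY)·Y to
  cancel intensity variation.
* POS — projection of mean-normalized channels onto the plane orthogonal to
  the skin-tone axis, rows (0, 1, −1) and (−2, 1, 1), recombined with the
  adaptive ratio σ(S1)/σ(S2).
* LGI — project out the dominant left-singular direction of the 3×L window
  (the common intensity/motion mode) and keep the second row.

The same window/bandpass/spectral-peak path applied to a contact PPG record
yields the ground-truth heart-rate series, so video and reference estimates
share every processing convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal
from sklearn.decomposition import FastICA

from .errors import (ConfigError, DecompositionError, InsufficientDataError,
                     NormalizationError, SamplingError, UndefinedPeakError)
from .io_media import PPGRecord, VideoSequence
from .roi import LandmarkSet

BAND_HZ = (0.65, 4.0)          # physiological heart-rate band, 39-240 bpm
BUTTER_ORDER = 6
BPM_GRID_STEP = 0.25           # target PSD resolution in bpm
BVP_METHODS = ("GREEN", "ICA", "CHROM", "POS", "LGI")


@dataclass
class RGBTrace:
    """Per-frame mean R/G/B intensities (8-bit counts) at the video rate."""

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.r, self.g, self.b = (np.asarray(c, dtype=float) for c in (self.r, self.g, self.b))
        if not (len(self.r) == len(self.g) == len(self.b)):
            raise ValueError("channel lengths differ")
        if not self.rate > 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return len(self.r)

    def as_matrix(self) -> np.ndarray:
        """3×L matrix with rows R, G, B."""
        return np.stack([self.r, self.g, self.b])


@dataclass
class SignalWindow:
    """A 3×L (or 1×L) slice of a trace, with its start time and rate.

    ``raw_means`` holds the per-row means of the window *before* any
    detrending — CHROM/POS normalize by them, since the means of a
    bandpassed (zero-mean) signal carry no information.
    """

    samples: np.ndarray
    start_time: float
    rate: float
    raw_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))

    @property
    def length(self) -> int:
        return self.samples.shape[1]


@dataclass
class BVPEstimate:
    """A single-window blood-volume-pulse signal and the method that made it."""

    signal: np.ndarray
    method: str
    rate: float


@dataclass
class BPMSeries:
    """Per-window heart-rate estimates with window start times (seconds)."""

    times: np.ndarray
    bpm: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bpm = np.asarray(self.bpm, dtype=float)
        if self.times.shape != self.bpm.shape:
            raise ValueError("times and bpm lengths differ")

    def __len__(self) -> int:
        return len(self.bpm)


def sample_rgb_trace(video: VideoSequence, landmarks_per_frame: Sequence[LandmarkSet],
                     n_points: int = 100, patch_side: int = 9) -> RGBTrace:
    """Average each channel over square skin patches around sampled landmarks.

    Up to ``n_points`` equispaced points are drawn from the concatenated
    forehead, left_cheek, right_cheek and nose groups; each contributes a
    patch_side×patch_side patch clipped to the frame. The union of patch
    pixels is averaged per channel per frame.
    """
    if len(landmarks_per_frame) != len(video):
        raise SamplingError(
            f"{len(landmarks_per_frame)} landmark sets for {len(video)} frames")
    h, w = video.shape
    half = patch_side // 2
    means = np.empty((len(video), 3))
    prev_key: tuple | None = None
    rows = cols = None
    for t, frame in enumerate(video):
        lms = landmarks_per_frame[t]
        pts = np.concatenate([
            lms.group_points(g) for g in ("forehead", "left_cheek", "right_cheek", "nose")
        ])
        if pts.shape[0] == 0:
            raise SamplingError(f"frame {t}: no forehead/cheek/nose landmarks")
        if pts.shape[0] > n_points:
            idx = np.linspace(0, pts.shape[0] - 1, n_points).round().astype(int)
            pts = pts[idx]
        key = (t > 0 and np.array_equal(pts, prev_key))
        if not key:  # recompute pixel index set only when landmarks move
            cx = np.floor(pts[:, 0]).astype(int)
            cy = np.floor(pts[:, 1]).astype(int)
            offs = np.arange(-half, half + 1)
            ys = np.clip(cy[:, None, None] + offs[None, :, None], 0, h - 1)
            xs = np.clip(cx[:, None, None] + offs[None, None, :], 0, w - 1)
            flat = (ys * w + xs).ravel()
            flat = np.unique(flat)
            rows, cols = flat // w, flat % w
            prev_key = pts
        if rows.size == 0:
            raise SamplingError(f"frame {t}: empty patch union")
        means[t] = frame[rows, cols].mean(axis=0)
    return RGBTrace(means[:, 0], means[:, 1], means[:, 2], video.frame_rate)


def make_windows(trace: RGBTrace | np.ndarray, rate: float | None = None,
                 window_seconds: float = 8.0, stride_seconds: float = 1.0) -> list[SignalWindow]:
    """Slice a trace into the maximal set of full overlapping windows.

    Accepts an RGBTrace or a bare (rows, L) array with an explicit rate.
    A trailing partial window is dropped; a trace shorter than one window
    raises InsufficientDataError.
    """
    if isinstance(trace, RGBTrace):
        mat, rate = trace.as_matrix(), trace.rate
    else:
        mat = np.atleast_2d(np.asarray(trace, dtype=float))
        if rate is None:
            raise ConfigError("rate required for a bare array")
    L = int(round(window_seconds * rate))
    stride = max(1, int(round(stride_seconds * rate)))
    n = mat.shape[1]
    if n < L:
        raise InsufficientDataError(
            f"trace of {n / rate:.2f} s is shorter than one {window_seconds} s window")
    windows = []
    for start in range(0, n - L + 1, stride):
        windows.append(SignalWindow(mat[:, start:start + L], start / rate, rate))
    return windows


def preprocess_window(w: SignalWindow, band: tuple[float, float] = BAND_HZ,
                      order: int = BUTTER_ORDER) -> SignalWindow:
    """Linear detrend + zero-phase Butterworth bandpass, per row, zero-mean out."""
    if w.rate <= 2 * band[1]:
        raise ConfigError(
            f"rate {w.rate} Hz too low for a {band[1]} Hz band edge (Nyquist)")
    if w.length <= 3 * order:
        raise InsufficientDataError(f"window of {w.length} samples too short to filter")
    raw_means = w.samples.mean(axis=1)
    x = signal.detrend(w.samples, axis=1, type="linear")
    sos = signal.butter(order, band, btype="bandpass", fs=w.rate, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=1)
    y = y - y.mean(axis=1, keepdims=True)
    return SignalWindow(y, w.start_time, w.rate, raw_means=raw_means)


def _require_rgb(w: SignalWindow) -> None:
    if w.samples.shape[0] != 3:
        raise ConfigError(f"expected a 3-row RGB window, got {w.samples.shape[0]} rows")


def bvp_green(w: SignalWindow) -> BVPEstimate:
    """The green channel is the BVP estimate."""
    _require_rgb(w)
    g = w.samples[1] - w.samples[1].mean()
    return BVPEstimate(g, "GREEN", w.rate)


def _inband_peakedness(x: np.ndarray, rate: float) -> float:
    """Tallest in-band PSD bin as a fraction of total power.

    High for a narrowband (pulse-like) component, low both for broadband
    noise and for multi-tone disturbances such as illumination flicker.
    """
    f, p = signal.welch(x, fs=rate, nperseg=min(len(x), 256))
    total = p.sum()
    if total <= 0:
        return 0.0
    sel = (f >= BAND_HZ[0]) & (f <= BAND_HZ[1])
    if not np.any(sel):
        return 0.0
    return float(p[sel].max() / total)


def bvp_ica(w: SignalWindow, seed: int = 0) -> BVPEstimate:
    """Blind source separation of the three channels.

    FastICA (deflation, seeded) recovers three components; they are ranked by
    in-band spectral peakedness (tallest heart-rate-band PSD bin over total
    power) and the top-ranked — most periodic — component is returned.
    Ranking makes the classical "pulse component of ICA" deterministic:
    FastICA's own output order and signs are arbitrary.
    """
    _require_rgb(w)
    x = w.samples - w.samples.mean(axis=1, keepdims=True)
    if np.linalg.matrix_rank(np.cov(x), tol=1e-12) < 1 or np.allclose(x, 0):
        raise DecompositionError("window is constant; nothing to decompose")
    ica = FastICA(n_components=3, algorithm="deflation", whiten="unit-variance",
                  random_state=seed, max_iter=500, tol=1e-4)
    try:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comps = ica.fit_transform(x.T).T  # (3, L)
    except Exception as exc:
        raise DecompositionError(f"FastICA failed: {exc}") from exc
    scores = [_inband_peakedness(c, w.rate) for c in comps]
    best = comps[int(np.argmax(scores))]
    return BVPEstimate(best - best.mean(), "ICA", w.rate)


def _mean_normalized(w: SignalWindow) -> np.ndarray:
    """Bandpassed rows divided by the raw per-channel window means."""
    _require_rgb(w)
    means = w.raw_means if w.raw_means is not None else w.samples.mean(axis=1)
    if np.any(np.abs(means) < 1e-12):
        raise NormalizationError("zero channel mean; cannot normalize")
    return w.samples / means[:, None]


def bvp_chrom(w: SignalWindow) -> BVPEstimate:
    """Chrominance method: X − (σX/σY)·Y on mean-normalized channels."""
    rn, gn, bn = _mean_normalized(w)
    x = 3 * rn - 2 * gn
    y = 1.5 * rn + gn - 1.5 * bn
    sy = y.std()
    alpha = x.std() / sy if sy > 0 else 0.0
    s = x - alpha * y
    return BVPEstimate(s - s.mean(), "CHROM", w.rate)


def bvp_pos(w: SignalWindow) -> BVPEstimate:
    """Plane-orthogonal-to-skin projection of mean-normalized channels."""
    cn = _mean_normalized(w)
    p = np.array([[0.0, 1.0, -1.0], [-2.0, 1.0, 1.0]])
    s = p @ cn
    s2_std = s[1].std()
    h = s[0] + (s[0].std() / s2_std) * s[1] if s2_std > 0 else s[0]
    return BVPEstimate(h - h.mean(), "POS", w.rate)


def bvp_lgi(w: SignalWindow) -> BVPEstimate:
    """Local group invariance: project out the dominant singular direction.

    With U from the SVD of the 3×L window, P = I − u1·u1ᵀ removes the common
    intensity/motion mode; the second row of P·X is the BVP estimate.
    """
    _require_rgb(w)
    x = w.samples
    try:
        u, _, _ = np.linalg.svd(x, full_matrices=True)
    except np.linalg.LinAlgError as exc:
        raise DecompositionError(f"SVD failed: {exc}") from exc
    u1 = u[:, :1]
    proj = (np.eye(3) - u1 @ u1.T) @ x
    s = proj[1]
    return BVPEstimate(s - s.mean(), "LGI", w.rate)


_BVP_DISPATCH = {
    "GREEN": lambda w, seed: bvp_green(w),
    "ICA": lambda w, seed: bvp_ica(w, seed),
    "CHROM": lambda w, seed: bvp_chrom(w),
    "POS": lambda w, seed: bvp_pos(w),
    "LGI": lambda w, seed: bvp_lgi(w),
}


def bpm_from_bvp(b: BVPEstimate | np.ndarray, rate: float | None = None) -> float:
    """Heart rate (bpm) from the Welch power-spectrum peak in 0.65–4.0 Hz.

    Welch: Hann taper, segments of min(L, 256) samples, 50% overlap,
    zero-padded so the frequency grid is at most 0.25 bpm.
    """
    if isinstance(b, BVPEstimate):
        x, rate = np.asarray(b.signal, dtype=float), b.rate
    else:
        x = np.asarray(b, dtype=float)
        if rate is None:
            raise ConfigError("rate required for a bare array")
    if not np.any(x):
        raise UndefinedPeakError("all-zero signal has no spectral peak")
    nperseg = min(len(x), 256)
    df_target = BPM_GRID_STEP / 60.0
    nfft = max(4096, int(2 ** np.ceil(np.log2(rate / df_target))))
    f, p = signal.welch(x, fs=rate, window="hann", nperseg=nperseg,
                        noverlap=nperseg // 2, nfft=nfft)
    sel = (f >= BAND_HZ[0]) & (f <= BAND_HZ[1])
    if not np.any(sel) or not np.any(p[sel] > 0):
        raise UndefinedPeakError("no spectral power inside the heart-rate band")
    return 60.0 * float(f[sel][np.argmax(p[sel])])


def estimate_bpm_series(video: VideoSequence, landmarks_per_frame: Sequence[LandmarkSet],
                        method: str, seed: int = 0, window_seconds: float = 8.0,
                        stride_seconds: float = 1.0, n_points: int = 100,
                        patch_side: int = 9) -> BPMSeries:
    """End-to-end heart-rate series from a facial video with one BVP method."""
    if method not in BVP_METHODS:
        raise ConfigError(f"unknown BVP method {method!r}; choose from {BVP_METHODS}")
    trace = sample_rgb_trace(video, landmarks_per_frame, n_points=n_points,
                             patch_side=patch_side)
    windows = make_windows(trace, window_seconds=window_seconds,
                           stride_seconds=stride_seconds)
    times, bpms = [], []
    for i, w in enumerate(windows):
        try:
            pre = preprocess_window(w)
            bvp = _BVP_DISPATCH[method](pre, seed)
            bpms.append(bpm_from_bvp(bvp))
        except Exception as exc:
            raise type(exc)(f"window {i} (t={w.start_time:.1f}s): {exc}") from exc
        times.append(w.start_time)
    return BPMSeries(np.array(times), np.array(bpms))


def ppg_bpm_series(ppg: PPGRecord, window_seconds: float = 8.0,
                   stride_seconds: float = 1.0) -> BPMSeries:
    """Ground-truth heart-rate series from a contact PPG record.

    Identical windowing, bandpass and spectral-peak conventions as the video
    path, so the two series differ only through the signals themselves.
    """
    windows = make_windows(ppg.samples[None, :], rate=ppg.sample_rate,
                           window_seconds=window_seconds, stride_seconds=stride_seconds)
    times, bpms = [], []
    for w in windows:
        pre = preprocess_window(w)
        bpms.append(bpm_from_bvp(pre.samples[0], rate=w.rate))
        times.append(ppg.start_offset + w.start_time)
    return BPMSeries(np.array(times), np.array(bpms))
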