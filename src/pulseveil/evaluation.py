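"""Concealment scoring: heart-rate error, frame information loss, overall score.

Four metrics grade a modification method:

* |Δbpm| — mean absolute difference between ground-truth and estimated
  per-window heart rates; large is good for concealment.
* MSE — mean squared per-pixel intensity difference between original and
  modified frames, averaged over frames (and over the three channels);
  small is good for visual utility.
* OS — overall score, (|Δbpm|_n + (1 − MSE_n)) / 2, where both terms are
  min-max normalized across the set of methods under comparison and
  1 − MSE_n is the data-retention factor. OS ∈ [0, 1]; the ideal method
  maximizes heart-rate error while minimizing pixel damage.
* fps — throughput of the mask→filter→overlay path; purely descriptive,
  it depends on the hardware and frame size.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DimensionError, EmptyInputError, InsufficientDataError
from .filters import FilterConfig, FilterState, apply_filter, modify_video
from .io_media import PPGRecord, VideoSequence
from .roi import LandmarkProvider, detect_landmarks, make_mask
from .rppg import BVP_METHODS, BPMSeries, estimate_bpm_series, ppg_bpm_series

_TIME_TOL = 1e-6


def delta_bpm(gt: BPMSeries, est: BPMSeries) -> float:
    """Mean absolute per-window heart-rate difference, (1/n)·Σ|h_i − ĥ_i|."""
    if len(gt) != len(est):
        raise AlignmentError(f"series lengths differ: {len(gt)} vs {len(est)}")
    if len(gt) == 0:
        raise AlignmentError("empty series")
    if np.max(np.abs(gt.times - est.times)) > _TIME_TOL:
        raise AlignmentError("window start times differ")
    return float(np.mean(np.abs(gt.bpm - est.bpm)))


def frame_mse(original: VideoSequence, modified: VideoSequence,
              per_channel_sum: bool = False) -> float:
    """Mean squared pixel difference, averaged over frames.

    Per frame the squared differences are summed over all pixels and the
    three channels and divided by m·n·3 (set ``per_channel_sum`` to divide by
    m·n only, i.e. sum the channel contributions).
    """
    if original.frames.shape != modified.frames.shape:
        raise DimensionError(
            f"video shapes differ: {original.frames.shape} vs {modified.frames.shape}")
    diff = original.frames.astype(np.float64) - modified.frames.astype(np.float64)
    per_frame = (diff**2).mean(axis=(1, 2, 3))
    if per_channel_sum:
        per_frame = per_frame * 3.0
    return float(per_frame.mean())


def normalize_minmax(values: Sequence[float]) -> np.ndarray:
    """(v − min)/(max − min); a constant list maps to all zeros."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("min-max normalization needs ≥2 values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def overall_score(delta_bpms: Sequence[float], mses: Sequence[float]) -> np.ndarray:
    """OS per method: (Δbpm_n + (1 − MSE_n)) / 2, normalized across methods.

    ``delta_bpms`` should already be averaged across rPPG techniques when
    several were measured.
    """
    d = np.asarray(delta_bpms, dtype=float)
    m = np.asarray(mses, dtype=float)
    if d.shape != m.shape:
        raise AlignmentError(f"method sets differ in length: {d.shape} vs {m.shape}")
    return (normalize_minmax(d) + (1.0 - normalize_minmax(m))) / 2.0


def measure_fps(cfg: FilterConfig, video: VideoSequence, roi_kind: str = "full_frame",
                provider: LandmarkProvider | None = None) -> float:
    """Throughput of the mask→filter→overlay path in frames per second.

    fps = 1 / mean(T_frame). Hardware- and frame-size-dependent; report it
    as descriptive metadata, never compare across machines.
    """
    if len(video) == 0:
        raise EmptyInputError("empty video")
    state = FilterState.for_config(cfg)
    start = time.perf_counter()
    for t, frame in enumerate(video):
        landmarks = detect_landmarks(frame, provider, t) if roi_kind != "full_frame" else None
        mask = make_mask(roi_kind, frame, landmarks)
        _, state = apply_filter(frame, mask, cfg, state)
    elapsed = time.perf_counter() - start
    return len(video) / max(elapsed, 1e-12)


@dataclass
class EvalReport:
    """Tidy per-(method, technique) metric table plus per-method summary.

    ``rows``: columns method, technique, delta_bpm, mse.
    ``summary``: columns method, delta_bpm (technique average), mse,
    delta_bpm_norm, mse_norm, retention, os, and fps when measured.
    """

    rows: pd.DataFrame
    summary: pd.DataFrame

    def to_csv(self, path) -> None:
        self.rows.merge(self.summary.drop(columns=["delta_bpm"]), on="method").to_csv(
            path, index=False)

    def to_json(self, path) -> None:
        import json
        payload = {"rows": self.rows.to_dict(orient="records"),
                   "summary": self.summary.to_dict(orient="records")}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def evaluate_run(original: VideoSequence, cfgs: Sequence[FilterConfig], roi_kind: str,
                 rppg_methods: Sequence[str], gt: PPGRecord,
                 provider: LandmarkProvider | None = None,
                 landmarks_per_frame=None, seed: int = 0,
                 measure_throughput: bool = False, **estimate_kwargs) -> EvalReport:
    """Score a set of modification methods end to end on one video.

    For each FilterConfig: modify the video, estimate a heart-rate series per
    rPPG technique, compare against the ground-truth PPG series; measure the
    frame MSE; finally min-max normalize across the method set and compute OS.
    ``landmarks_per_frame`` feeds the rPPG sampler (ground-truth landmarks for
    synthetic scenes); ``provider`` feeds ROI masking.
    """
    for m in rppg_methods:
        if m not in BVP_METHODS:
            raise AlignmentError(f"unknown rPPG technique {m!r}")
    if landmarks_per_frame is None and provider is not None:
        landmarks_per_frame = [detect_landmarks(f, provider, t)
                               for t, f in enumerate(original)]
    gt_series = ppg_bpm_series(gt)
    records, per_method = [], []
    for cfg in cfgs:
        try:
            modified = modify_video(original, roi_kind, cfg, provider)
            mse = frame_mse(original, modified)
            deltas = []
            for technique in rppg_methods:
                est = estimate_bpm_series(modified, landmarks_per_frame, technique,
                                          seed=seed, **estimate_kwargs)
                n = min(len(gt_series), len(est))
                d = delta_bpm(BPMSeries(gt_series.times[:n], gt_series.bpm[:n]),
                              BPMSeries(est.times[:n], est.bpm[:n]))
                deltas.append(d)
                records.append({"method": cfg.method, "technique": technique,
                                "delta_bpm": d, "mse": mse})
        except Exception as exc:
            raise type(exc)(f"method {cfg.method!r}: {exc}") from exc
        entry = {"method": cfg.method, "delta_bpm": float(np.mean(deltas)), "mse": mse}
        if measure_throughput:
            entry["fps"] = measure_fps(cfg, original, roi_kind, provider)
        per_method.append(entry)
    summary = pd.DataFrame(per_method)
    summary["delta_bpm_norm"] = normalize_minmax(summary["delta_bpm"])
    summary["mse_norm"] = normalize_minmax(summary["mse"])
    summary["retention"] = 1.0 - summary["mse_norm"]
    summary["os"] = (summary["delta_bpm_norm"] + summary["retention"]) / 2.0
    return EvalReport(rows=pd.DataFrame(records), summary=summary)
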