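"""Parameter-sweep harness: metric suite over a grid of filter parameters.

Mirrors the ablation style of kernel-size sweeps for the blurring methods and
window-length sweeps for sliding temporal averaging: each grid point runs the
full modify → estimate → score loop and contributes tidy long-format rows
(parameter, value, method, technique, delta_bpm, mse, os).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .evaluation import delta_bpm, frame_mse, normalize_minmax
from .filters import FilterConfig, modify_video
from .io_media import PPGRecord, VideoSequence, read_ppg, read_video
from .roi import LandmarkSet, SyntheticLandmarkProvider
from .rppg import BPMSeries, estimate_bpm_series, ppg_bpm_series

SWEEPABLE = ("kernel_size", "window_frames")


def sweep_metrics(video: VideoSequence, landmark_sets: Sequence[LandmarkSet],
                  gt: PPGRecord, parameter: str, values: Sequence[int], method: str,
                  techniques: Sequence[str], roi_kind: str = "facial_skin",
                  seed: int = 0, **estimate_kwargs) -> pd.DataFrame:
    """Run the metric suite at every grid point; returns a tidy DataFrame.

    OS is min-max normalized across the grid points (technique-averaged
    delta_bpm vs MSE), so it compares parameter values against each other.
    """
    if parameter not in SWEEPABLE:
        raise ConfigError(f"cannot sweep {parameter!r}; choose from {SWEEPABLE}")
    if not values:
        raise ConfigError("empty sweep grid")
    provider = SyntheticLandmarkProvider(landmark_sets)
    gt_series = ppg_bpm_series(gt)
    rows, mses, mean_deltas = [], [], []
    for value in values:
        cfg = FilterConfig(method=method, seed=seed, **{parameter: value})
        modified = modify_video(video, roi_kind, cfg, provider)
        mse = frame_mse(video, modified)
        deltas = {}
        for tech in techniques:
            est = estimate_bpm_series(modified, landmark_sets, tech, seed=seed,
                                      **estimate_kwargs)
            n = min(len(gt_series), len(est))
            deltas[tech] = delta_bpm(BPMSeries(gt_series.times[:n], gt_series.bpm[:n]),
                                     BPMSeries(est.times[:n], est.bpm[:n]))
        mses.append(mse)
        mean_deltas.append(float(np.mean(list(deltas.values()))))
        for tech, d in deltas.items():
            rows.append({"parameter": parameter, "value": value, "method": method,
                         "technique": tech, "delta_bpm": d, "mse": mse})
    df = pd.DataFrame(rows)
    if len(values) >= 2:
        os_by_value = dict(zip(values, (normalize_minmax(mean_deltas)
                                        + 1.0 - normalize_minmax(mses)) / 2.0))
        df["os"] = df["value"].map(os_by_value)
    else:
        df["os"] = np.nan
    return df


def run_sweep(scene_dir: Path, parameter: str, values: Sequence[int], method: str,
              techniques: Sequence[str], roi_kind: str = "facial_skin",
              seed: int = 0) -> pd.DataFrame:
    """Load a `pulseveil synth` scene directory and sweep over it."""
    scene_dir = Path(scene_dir)
    video = read_video(scene_dir / "video")
    gt = read_ppg(scene_dir / "ppg.csv")
    lm_path = scene_dir / "video" / "landmarks.json"
    if not lm_path.exists():
        lm_path = scene_dir / "landmarks.json"
    data = json.loads(lm_path.read_text())
    sets = [LandmarkSet(np.array(d["points"]), d["groups"]) for d in data]
    return sweep_metrics(video, sets, gt, parameter, values, method,
                         techniques, roi_kind, seed)
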