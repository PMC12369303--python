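"""File round-trips for the package's data objects.

Conventions: numeric payloads as ``.npy`` (traces) or multi-page TIFF
(M-mode matrices, frame stacks) with a YAML sidecar carrying acquisition
metadata and ground truth; tables as TSV with units in the column names.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from ctquant.synth.neural import NeuralTrace, StimulusEpoch
from ctquant.synth.oct import OctMmode
from ctquant.synth.video import FrameStack

__all__ = [
    "save_trace", "load_trace",
    "save_mmode", "load_mmode",
    "save_frames", "load_frames",
]


def save_trace(trace: NeuralTrace, path: str | Path) -> None:
    """Write ``<path>.npy`` (µV samples) and ``<path>.yaml`` (metadata)."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), trace.samples)
    meta = {
        "sampling_rate_hz": float(trace.sampling_rate),
        "epochs": [
            {"kind": e.kind, "t_start_s": e.t_start, "t_end_s": e.t_end,
             "params": dict(e.params)}
            for e in trace.epochs
        ],
        "truth_spike_times_s": (
            None if trace.truth_spike_times is None else [float(t) for t in trace.truth_spike_times]
        ),
        "truth_discharge_duration_s": trace.truth_discharge_duration,
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def load_trace(path: str | Path) -> NeuralTrace:
    path = Path(path)
    samples = np.load(path.with_suffix(".npy"))
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    epochs = [
        StimulusEpoch(e["kind"], e["t_start_s"], e["t_end_s"], e.get("params", {}))
        for e in meta["epochs"]
    ]
    truth = meta.get("truth_spike_times_s")
    return NeuralTrace(
        samples=samples,
        sampling_rate=meta["sampling_rate_hz"],
        epochs=epochs,
        truth_spike_times=None if truth is None else np.asarray(truth),
        truth_discharge_duration=meta.get("truth_discharge_duration_s"),
    )


def save_mmode(trial: OctMmode, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path.with_suffix(".tif"), trial.intensity)
    meta = {
        "aline_rate_hz": float(trial.aline_rate),
        "depth_resolution_um": float(trial.depth_resolution),
        "condition": trial.condition,
        "location": list(trial.location),
        "trial_id": int(trial.trial_id),
        "truth_event_time_s": trial.truth_event_time,
        "truth_displacement_um": trial.truth_displacement,
        "artefact": trial.artefact,
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def load_mmode(path: str | Path) -> OctMmode:
    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    return OctMmode(
        intensity=tifffile.imread(path.with_suffix(".tif")),
        aline_rate=meta["aline_rate_hz"],
        depth_resolution=meta["depth_resolution_um"],
        condition=meta["condition"],
        location=tuple(meta["location"]),
        trial_id=meta["trial_id"],
        truth_event_time=meta.get("truth_event_time_s"),
        truth_displacement=meta.get("truth_displacement_um"),
        artefact=meta.get("artefact"),
    )


def save_frames(stack: FrameStack, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(
        path.with_suffix(".tif"),
        (stack.frames * 65535).astype(np.uint16),
        photometric="minisblack",
    )
    meta = {
        "fps": float(stack.fps),
        "calibration_px_per_cm": float(stack.calibration),
        "truth_trajectory_xy_px": stack.truth_trajectory.tolist(),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def load_frames(path: str | Path) -> FrameStack:
    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    frames = tifffile.imread(path.with_suffix(".tif")).astype(float) / 65535.0
    return FrameStack(
        frames=frames,
        fps=meta["fps"],
        calibration=meta["calibration_px_per_cm"],
        truth_trajectory=np.asarray(meta["truth_trajectory_xy_px"]),
    )
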