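"""Synthetic video of a dark instrument tip moving over light skin.

Emulates the hair-deflection videography: a lighter, gently textured skin
background with a dark elongated instrument (forceps/hook) whose apex
follows a known per-frame trajectory, optionally with a dark hair strand.
Defaults follow the study acquisition: 60 frames/s and a pixel calibration
of 465 px/cm (frame sizes are configurable; analyses are resolution
independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.draw import line as draw_line

__all__ = ["TipScenario", "FrameStack", "gen_tip_video"]


@dataclass
class TipScenario:
    """Ground-truth tip trajectory and imaging geometry."""

    trajectory: np.ndarray  # (n_frames, 2) of (x, y) px
    fps: float = 60.0
    calibration: float = 465.0  # px/cm
    frame_shape: tuple[int, int] = (240, 320)  # (H, W)
    apex_angle_deg: float = 25.0
    tool_length: float = 140.0
    tool_angle_deg: float = 135.0  # apex-to-base direction, image coords
    hair: bool = False
    noise_sd: float = 0.01
    supersample: int = 4  # area-coverage anti-aliasing of the instrument

    def __post_init__(self) -> None:
        self.trajectory = np.asarray(self.trajectory, dtype=float)
        if self.calibration <= 0:
            raise ValueError("calibration must be positive")
        H, W = self.frame_shape
        x, y = self.trajectory[:, 0], self.trajectory[:, 1]
        if np.any(x < 0) or np.any(x >= W) or np.any(y < 0) or np.any(y >= H):
            raise ValueError("trajectory exits the frame")

    @classmethod
    def constant_velocity(
        cls,
        speed_cm_s: float = 0.8,
        n_frames: int = 40,
        start_xy: tuple[float, float] = (60.0, 150.0),
        direction_deg: float = 0.0,
        **kwargs,
    ) -> "TipScenario":
        """Straight-line motion at a constant speed (cm/s)."""
        fps = kwargs.get("fps", 60.0)
        calibration = kwargs.get("calibration", 465.0)
        step = speed_cm_s * calibration / fps  # px/frame
        th = np.deg2rad(direction_deg)
        t = np.arange(n_frames)
        traj = np.stack(
            [start_xy[0] + step * t * np.cos(th), start_xy[1] + step * t * np.sin(th)],
            axis=1,
        )
        return cls(trajectory=traj, **kwargs)

    @property
    def speed_profile_cm_s(self) -> np.ndarray:
        steps = np.linalg.norm(np.diff(self.trajectory, axis=0), axis=1)
        return steps * self.fps / self.calibration


@dataclass
class FrameStack:
    frames: np.ndarray  # (n_frames, H, W) float in [0, 1]
    fps: float
    calibration: float
    truth_trajectory: np.ndarray  # (n_frames, 2) of (x, y)

    def __len__(self) -> int:
        return len(self.frames)


def _background(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Light skin-like background with low-contrast smooth texture."""
    tex = rng.normal(0.0, 1.0, size=shape)
    tex = ndimage.gaussian_filter(tex, 2.0, mode="reflect")
    tex = tex / max(tex.std(), 1e-9) * 0.05
    return np.clip(0.75 + tex, 0.0, 1.0)


def _wedge_coverage(
    shape: tuple[int, int],
    apex_xy: tuple[float, float],
    angle_deg: float,
    half_angle_deg: float,
    length: float,
    supersample: int,
) -> np.ndarray:
    """Per-pixel area coverage of the wedge, in [0, 1] (anti-aliased)."""
    s = max(1, int(supersample))
    th = np.deg2rad(angle_deg)
    ha = np.deg2rad(half_angle_deg)
    ax, ay = apex_xy
    pts_x = np.array([ax, ax + length * np.cos(th - ha), ax + length * np.cos(th + ha)])
    pts_y = np.array([ay, ay + length * np.sin(th - ha), ay + length * np.sin(th + ha)])
    big = np.zeros((shape[0] * s, shape[1] * s))
    # pixel centers at integer coordinates: supersampled center of (r, c)
    # lies at (r*s + (s-1)/2, c*s + (s-1)/2)
    rr, cc = draw_polygon(pts_y * s + (s - 1) / 2, pts_x * s + (s - 1) / 2, shape=big.shape)
    big[rr, cc] = 1.0
    return big.reshape(shape[0], s, shape[1], s).mean(axis=(1, 3))


def gen_tip_video(scenario: TipScenario, seed: int | np.random.Generator = 0) -> FrameStack:
    """Render the scenario; ground-truth trajectory is retained."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bg = _background(scenario.frame_shape, rng)
    frames = np.empty((len(scenario.trajectory),) + scenario.frame_shape)
    for i, (x, y) in enumerate(scenario.trajectory):
        frame = bg.copy()
        cov = _wedge_coverage(
            scenario.frame_shape, (x, y), scenario.tool_angle_deg,
            scenario.apex_angle_deg / 2.0, scenario.tool_length,
            scenario.supersample,
        )
        frame = frame * (1.0 - cov) + 0.08 * cov
        if scenario.hair:
            H, W = scenario.frame_shape
            rr, cc = draw_line(int(0.8 * H), 0, int(0.2 * H), W - 1)
            frame[rr, cc] = np.minimum(frame[rr, cc], 0.35)
        if scenario.noise_sd > 0:
            frame = frame + rng.normal(0.0, scenario.noise_sd, size=frame.shape)
        frames[i] = np.clip(frame, 0.0, 1.0)
    return FrameStack(
        frames=frames,
        fps=scenario.fps,
        calibration=scenario.calibration,
        truth_trajectory=scenario.trajectory.copy(),
    )
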