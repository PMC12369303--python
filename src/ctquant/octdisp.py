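"""Skin-surface tracking and micro-displacement estimation from OCT M-mode.

Processing chain per trial: segment the air/skin boundary on every A-line
(threshold crossing with sub-sample linear interpolation, median smoothing),
locate the stimulus event on the tracked surface, average the surface depth
in windows before and after the event and subtract. Displacements are
reported as magnitudes (depth increases away from the probe; indentation and
hair release both appear as positive displacements). Trials with artefacts
are rejected before the ten highest displacements per condition enter the
pairwise Tukey HSD comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import median_filter

from ctquant.synth.oct import OctMmode

__all__ = [
    "SurfaceTrack",
    "DisplacementMeasure",
    "ConditionComparison",
    "RejectionCriteria",
    "segment_surface",
    "detect_event",
    "displacement_windows",
    "displacement_idle",
    "reject_trials",
    "select_top",
    "compare_conditions",
]


@dataclass
class SurfaceTrack:
    """Tracked surface depth per A-line (µm), with validity flags."""

    depth_um: np.ndarray
    valid: np.ndarray  # bool per A-line
    aline_rate: float
    threshold_k: float
    smooth_ms: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.depth_um)) / self.aline_rate

    @property
    def invalid_fraction(self) -> float:
        return float(1.0 - np.mean(self.valid))


@dataclass
class DisplacementMeasure:
    condition: str
    location: tuple[int, int]
    trial_id: int
    displacement_um: float | None
    windows: tuple[tuple[float, float], tuple[float, float]] | None = None
    rejected: bool = False
    reason: str | None = None
    truth_um: float | None = None


@dataclass
class ConditionComparison:
    """Per-condition summaries plus Tukey HSD pairwise results."""

    summary: pd.DataFrame  # index condition: n, mean_um, ci_low, ci_high
    pairwise: pd.DataFrame  # condition_a, condition_b, p_adj, significant
    alpha: float = 0.05


def segment_surface(
    trial: OctMmode,
    threshold_k: float = 5.0,
    smooth_ms: float = 1.0,
    background_rows: int = 8,
) -> SurfaceTrack:
    """Track the first supra-threshold depth sample per A-line.

    The detection threshold is background mean + ``threshold_k`` x background
    SD, estimated from the shallow (probe-side) rows; on effectively
    noiseless data it falls back to the half-contrast level. The crossing is
    refined to sub-sample precision by linear interpolation between the two
    bracketing samples, then median-filtered over ``smooth_ms``. A-lines
    with no crossing are flagged invalid (beam occlusion).
    """
    img = np.asarray(trial.intensity, dtype=float)
    n_depth, n_t = img.shape
    bg = img[:background_rows]
    bg_mean, bg_sd = float(bg.mean()), float(bg.std())
    contrast = float(img.max()) - bg_mean
    threshold = bg_mean + threshold_k * bg_sd
    if contrast <= 0:
        return SurfaceTrack(
            np.full(n_t, np.nan), np.zeros(n_t, bool),
            trial.aline_rate, threshold_k, smooth_ms,
        )
    if threshold < bg_mean + 0.1 * contrast or threshold > bg_mean + 0.9 * contrast:
        threshold = bg_mean + 0.5 * contrast

    above = img >= threshold
    has_crossing = above.any(axis=0)
    idx = above.argmax(axis=0)
    valid = has_crossing & (idx > 0)

    cols = np.arange(n_t)
    i = np.where(valid, idx, 1)
    i_prev = i - 1
    v_prev = img[i_prev, cols]
    v_cur = img[i, cols]
    denom = v_cur - v_prev
    frac = np.where(np.abs(denom) > 1e-12, (threshold - v_prev) / np.maximum(np.abs(denom), 1e-12) * np.sign(denom), 0.5)
    depth = (i_prev + frac) * trial.depth_resolution
    depth[~valid] = np.nan

    win = max(1, int(round(smooth_ms * 1e-3 * trial.aline_rate)))
    if win > 1 and valid.any():
        filled = depth.copy()
        if (~valid).any():
            good = np.flatnonzero(valid)
            filled[~valid] = np.interp(np.flatnonzero(~valid), good, depth[good])
        smoothed = median_filter(filled, size=win, mode="reflect")
        depth = np.where(valid, smoothed, np.nan)
    return SurfaceTrack(depth, valid, trial.aline_rate, threshold_k, smooth_ms)


def detect_event(track: SurfaceTrack, kind: str = "contact", min_step_um: float = 0.5) -> float:
    """Event time from the extremal derivative of the tracked surface.

    ``contact`` selects the largest positive depth step (skin pushed away
    from the probe by indentation); ``release`` selects the largest step by
    magnitude (the surface returning to rest after hair release). A track
    without a step above ``min_step_um`` raises.
    """
    if kind not in ("contact", "release"):
        raise ValueError("kind must be 'contact' or 'release'")
    d = np.asarray(track.depth_um, dtype=float)
    if len(d) < track.aline_rate:
        raise ValueError("need at least 1 s of tracked data")
    dd = np.diff(d)
    dd = np.where(np.isfinite(dd), dd, 0.0)
    i = int(np.argmax(dd)) if kind == "contact" else int(np.argmax(np.abs(dd)))
    step = dd[i] if kind == "contact" else abs(dd[i])
    if step < min_step_um:
        raise ValueError("no event: surface track is flat")
    return float((i + 0.5) / track.aline_rate)


def _window_mean(track: SurfaceTrack, t0: float, t1: float, min_valid: float = 0.5) -> float:
    i0, i1 = int(round(t0 * track.aline_rate)), int(round(t1 * track.aline_rate))
    if i0 < 0 or i1 > len(track.depth_um) or i1 <= i0:
        raise ValueError("window out of range")
    seg = track.depth_um[i0:i1]
    ok = np.isfinite(seg)
    if np.mean(ok) < min_valid:
        raise ValueError("insufficient valid samples in window")
    return float(np.mean(seg[ok]))


def displacement_windows(
    track: SurfaceTrack,
    event: float,
    window_ms: float = 200.0,
    guard_ms: float = 20.0,
) -> tuple[float, tuple[tuple[float, float], tuple[float, float]]]:
    """|mean(pre-window) - mean(post-window)| around the event, µm.

    Two ``window_ms`` windows are placed before and after the event, each
    separated from it by a ``guard_ms`` gap that excludes the transition.
    """
    w, g = window_ms * 1e-3, guard_ms * 1e-3
    pre = (event - g - w, event - g)
    post = (event + g, event + g + w)
    m_pre = _window_mean(track, *pre)
    m_post = _window_mean(track, *post)
    return abs(m_pre - m_post), (pre, post)


def displacement_idle(
    track: SurfaceTrack,
    window_ms: float = 500.0,
    start: float = 0.0,
) -> tuple[float, tuple[tuple[float, float], tuple[float, float]]]:
    """|difference of two consecutive window means| at rest, µm.

    The longer default window (500 ms) averages out biological motion.
    """
    w = window_ms * 1e-3
    w1 = (start, start + w)
    w2 = (start + w, start + 2 * w)
    return abs(_window_mean(track, *w1) - _window_mean(track, *w2)), (w1, w2)


@dataclass(frozen=True)
class RejectionCriteria:
    """Artefact-rejection thresholds.

    * ``max_invalid_fraction`` — beam-crossing occlusion: fraction of
      A-lines with no detectable surface.
    * ``max_heartbeat_um`` — amplitude of the strongest 0.8-2 Hz component
      of the linearly detrended early track (heartbeat).
    * ``max_drift_um_per_s`` — linear drift of the early track (gross
      participant motion); set above the idle condition's physiological
      drift so resting trials are not self-rejected.
    """

    max_invalid_fraction: float = 0.05
    max_heartbeat_um: float = 3.0
    max_drift_um_per_s: float = 10.0
    assess_window_s: float = 1.2


def _assess_artefacts(track: SurfaceTrack, criteria: RejectionCriteria) -> str | None:
    if track.invalid_fraction > criteria.max_invalid_fraction:
        return "beam-crossing"
    n = int(criteria.assess_window_s * track.aline_rate)
    seg = track.depth_um[:n]
    ok = np.isfinite(seg)
    if ok.sum() < 10:
        return "beam-crossing"
    t = np.arange(n)[ok] / track.aline_rate
    y = seg[ok]
    slope, intercept = np.polyfit(t, y, 1)
    if abs(slope) > criteria.max_drift_um_per_s:
        return "motion"
    resid = y - (slope * t + intercept)
    freqs = np.fft.rfftfreq(len(resid), d=1.0 / track.aline_rate)
    amp = 2.0 * np.abs(np.fft.rfft(resid)) / len(resid)
    band = (freqs >= 0.8) & (freqs <= 2.0)
    if band.any() and amp[band].max() > criteria.max_heartbeat_um:
        return "heartbeat"
    return None


def reject_trials(
    trials: list[tuple[OctMmode, SurfaceTrack]],
    criteria: RejectionCriteria | None = None,
) -> tuple[list[tuple[OctMmode, SurfaceTrack]], float, list[str | None]]:
    """Apply artefact criteria; return kept trials, rejection fraction, reasons."""
    criteria = criteria or RejectionCriteria()
    reasons = [_assess_artefacts(track, criteria) for _, track in trials]
    kept = [pair for pair, r in zip(trials, reasons) if r is None]
    frac = 1.0 - len(kept) / len(trials) if trials else 0.0
    return kept, frac, reasons


def select_top(
    measures: list[DisplacementMeasure],
    k: int = 10,
) -> tuple[list[DisplacementMeasure], bool]:
    """The k largest displacements of one condition, post-rejection.

    Ties at the boundary are broken by (location, trial id) for
    determinism. Returns all survivors plus a shortfall flag when fewer
    than k are available.
    """
    if not measures:
        raise ValueError("no measures to select from")
    usable = [m for m in measures if not m.rejected and m.displacement_um is not None]
    ordered = sorted(usable, key=lambda m: (-m.displacement_um, m.location, m.trial_id))
    return ordered[:k], len(usable) < k


def compare_conditions(
    selected: dict[str, np.ndarray | list[float]],
    alpha: float = 0.05,
) -> ConditionComparison:
    """One-way Tukey HSD across conditions with t-based 95% CIs per group."""
    names = list(selected)
    groups = [np.asarray(selected[c], dtype=float) for c in names]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 conditions with >= 2 values each")
    if all(np.var(g) == 0 for g in groups):
        raise ValueError("degenerate: zero within-group variance in every group")

    res = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            p = float(res.pvalue[i, j])
            rows.append(
                {
                    "condition_a": names[i],
                    "condition_b": names[j],
                    "p_adj": p,
                    "significant": p < alpha,
                }
            )
    pairwise = pd.DataFrame(rows)

    summ = []
    for name, g in zip(names, groups):
        n = len(g)
        m = float(np.mean(g))
        se = float(np.std(g, ddof=1) / np.sqrt(n))
        tcrit = stats.t.ppf(0.975, n - 1)
        summ.append({"condition": name, "n": n, "mean_um": m,
                     "ci_low": m - tcrit * se, "ci_high": m + tcrit * se})
    summary = pd.DataFrame(summ).set_index("condition")
    return ConditionComparison(summary=summary, pairwise=pairwise, alpha=alpha)
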