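"""Spike detection, instantaneous-frequency metrics, unit classification,
monofilament threshold estimation and after-discharge quantification.

The metric conventions follow single-unit microneurography practice:

* instantaneous frequency (IF) = reciprocal of an inter-spike interval;
* ``mean_if`` = arithmetic mean of the reciprocal ISIs between the first and
  last spike of the analysis window (the alternative ``(N-1)/span``
  convention is available via ``mean_if_mode="span"``);
* ``peak_if`` = maximum reciprocal ISI;
* both are undefined (``None``) for fewer than two spikes — a minimum of two
  spikes is required before a response is quantified.

Fibre classes follow the conduction-velocity / spike-polarity convention:
C fibres conduct below 2 m/s and deflect downward, A-beta fibres above
30 m/s and deflect upward; a response delay of hundreds of milliseconds is
an accepted C-fibre marker when no electrical conduction estimate exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from ctquant.synth.neural import NeuralTrace

__all__ = [
    "SpikeTrain",
    "SpikeMetrics",
    "UnitRecord",
    "AfterDischarge",
    "SEMMES_WEINSTEIN_MN",
    "detect_spikes",
    "spike_metrics",
    "conduction_velocity",
    "classify_fibre",
    "estimate_mech_threshold",
    "classify_unit",
    "classify_adaptation",
    "detect_after_discharge",
]

#: Standard Semmes-Weinstein monofilament buckling forces (mN).
SEMMES_WEINSTEIN_MN = (
    0.08, 0.2, 0.4, 0.7, 1.6, 4.0, 6.0, 10.0, 15.0, 26.0,
    60.0, 100.0, 180.0, 300.0, 600.0, 1000.0, 1800.0, 3000.0,
)


@dataclass
class SpikeTrain:
    spike_times: np.ndarray  # s, strictly increasing
    polarity: str = "unknown"  # "up" | "down" | "unknown"
    template: np.ndarray | None = None
    template_fallback: bool = False  # no brush epoch available for templating

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")
        self.spike_times = t

    def __len__(self) -> int:
        return len(self.spike_times)


@dataclass(frozen=True)
class SpikeMetrics:
    count: int
    mean_if: float | None  # spikes/s; None when count < 2
    peak_if: float | None
    window: tuple[float, float]


@dataclass
class UnitRecord:
    fibre_class: str  # "C" | "A_beta" | "other"
    mech_threshold: float | None  # mN; None when unresponsive
    adaptation: str = "unknown"  # "RA" | "SA" | "unknown"
    conduction_velocity: float | None = None  # m/s
    unit_type: str = "other"  # "CT" | "HFA" | "other"
    metrics: dict[str, SpikeMetrics] = field(default_factory=dict)


@dataclass(frozen=True)
class AfterDischarge:
    duration: float  # s; 0 when no post-stimulus spikes
    mean_if: float | None
    peak_if: float | None
    gap_rule: float


def _candidate_events(samples: np.ndarray, threshold: float, refractory_n: int) -> np.ndarray:
    """Indices of |v| peaks above threshold, separated by the refractory gap."""
    peaks, _ = find_peaks(np.abs(samples), height=threshold, distance=max(1, refractory_n))
    return peaks


def _waveform_at(samples: np.ndarray, idx: int, half: int) -> np.ndarray | None:
    i0, i1 = idx - half, idx + half
    if i0 < 0 or i1 > len(samples):
        return None
    return samples[i0:i1]


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def detect_spikes(
    trace: NeuralTrace,
    threshold: float | None = None,
    refractory: float = 0.002,
    match_threshold: float = 0.8,
    waveform_ms: float = 3.0,
) -> SpikeTrain:
    """Threshold-crossing spike detection with template-matching confirmation.

    Candidate events are voltage-magnitude peaks above ``threshold``
    (either polarity) separated by at least the refractory period. The
    matching template is the mean candidate waveform within brush epochs —
    the stimulus during which spike morphology is verified — and candidates
    are retained iff their normalized cross-correlation with the template
    reaches ``match_threshold``. Spike time is the peak sample time.

    When ``threshold`` is None it defaults to 5 robust noise SDs
    (median absolute deviation estimate).
    """
    fs = trace.sampling_rate
    samples = np.asarray(trace.samples, dtype=float)
    half = max(2, int(round(waveform_ms * 1e-3 * fs / 2)))
    if len(samples) < 2 * half:
        raise ValueError("trace shorter than one spike waveform")
    if threshold is None:
        noise_sd = 1.4826 * np.median(np.abs(samples - np.median(samples)))
        threshold = 5.0 * max(noise_sd, 1e-12)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")

    refractory_n = int(round(refractory * fs))
    peaks = _candidate_events(samples, threshold, refractory_n)
    waveforms = {int(i): _waveform_at(samples, int(i), half) for i in peaks}
    peaks = [i for i in peaks if waveforms[int(i)] is not None]
    if not peaks:
        return SpikeTrain(np.empty(0))

    brush_windows = [(e.t_start, e.t_end + 0.5) for e in trace.epochs if e.kind == "brush"]
    in_brush = [
        i for i in peaks if any(t0 <= i / fs <= t1 for t0, t1 in brush_windows)
    ]
    fallback = not in_brush
    if fallback:
        # no brush epoch (or none produced candidates): highest-amplitude candidate
        ref = max(peaks, key=lambda i: abs(samples[i]))
        template = waveforms[int(ref)].copy()
    else:
        template = np.mean([waveforms[int(i)] for i in in_brush], axis=0)

    accepted = [i for i in peaks if _ncc(waveforms[int(i)], template) >= match_threshold]
    times = np.asarray(sorted(i / fs for i in accepted))

    lead = template[np.argmax(np.abs(template[: len(template) // 2]))]
    polarity = "down" if lead < 0 else "up"
    return SpikeTrain(times, polarity=polarity, template=template, template_fallback=fallback)


def instantaneous_frequencies(spike_times: np.ndarray) -> np.ndarray:
    """Reciprocal successive inter-spike intervals, spikes/s."""
    t = np.asarray(spike_times, dtype=float)
    return 1.0 / np.diff(t) if t.size >= 2 else np.empty(0)


def spike_metrics(
    train: SpikeTrain | np.ndarray,
    window: tuple[float, float],
    mean_if_mode: str = "reciprocal",
) -> SpikeMetrics:
    """Spike count, mean IF and peak IF within an analysis window.

    ``mean_if_mode="reciprocal"`` (default) averages the reciprocal ISIs;
    ``"span"`` uses (count - 1) / (t_last - t_first).
    """
    t0, t1 = window
    if t0 >= t1:
        raise ValueError("window requires t0 < t1")
    times = train.spike_times if isinstance(train, SpikeTrain) else np.asarray(train, dtype=float)
    times = times[(times >= t0) & (times <= t1)]
    count = int(times.size)
    if count < 2:
        return SpikeMetrics(count=count, mean_if=None, peak_if=None, window=window)
    ifs = instantaneous_frequencies(times)
    if mean_if_mode == "reciprocal":
        mean_if = float(np.mean(ifs))
    elif mean_if_mode == "span":
        mean_if = (count - 1) / (times[-1] - times[0])
    else:
        raise ValueError(f"unknown mean_if_mode {mean_if_mode!r}")
    return SpikeMetrics(count=count, mean_if=mean_if, peak_if=float(np.max(ifs)), window=window)


def conduction_velocity(distance: float, latency: float) -> float:
    """Conduction velocity (m/s) from electrical-stimulation distance/latency."""
    if distance <= 0 or latency <= 0:
        raise ValueError("distance and latency must be > 0")
    return distance / latency


def classify_fibre(
    polarity: str,
    conduction_velocity: float | None = None,
    response_delay: float | None = None,
) -> str:
    """C / A_beta / other from spike polarity plus CV or response delay.

    C: downward-deflecting spikes with CV < 2 m/s, or with a response delay
    of at least 100 ms when no CV was recorded. A_beta: upward-deflecting
    with CV > 30 m/s. Everything else: "other".
    """
    if conduction_velocity is None and response_delay is None:
        raise ValueError("need conduction_velocity or response_delay")
    if polarity == "down":
        if conduction_velocity is not None and conduction_velocity < 2.0:
            return "C"
        if conduction_velocity is None and response_delay is not None and response_delay >= 0.1:
            return "C"
    if polarity == "up" and conduction_velocity is not None and conduction_velocity > 30.0:
        return "A_beta"
    return "other"


def estimate_mech_threshold(
    responses: Mapping[float, Sequence[bool]],
) -> tuple[float | None, dict]:
    """Monofilament threshold by the 50%-of-occasions criterion.

    ``responses`` maps tested force (mN, from the standard Semmes-Weinstein
    set) to the per-trial spike-response outcomes. The threshold is the
    lowest tested force whose response proportion is >= 0.5, confirmed on
    re-test (>= 2 trials at that force); a qualifying force tested only once
    is returned with a ``low_confidence`` flag. Returns ``(None, flags)``
    with ``flags["unresponsive"]`` when no force qualifies.
    """
    if not responses:
        raise ValueError("empty response map")
    for force in responses:
        if not any(np.isclose(force, f, rtol=1e-3) for f in SEMMES_WEINSTEIN_MN):
            raise ValueError(
                f"{force} mN is not in the standard monofilament force set"
            )
    flags: dict = {"unresponsive": False, "low_confidence": False}
    for force in sorted(responses):
        trials = list(responses[force])
        if not trials:
            continue
        if np.mean(trials) >= 0.5:
            flags["low_confidence"] = len(trials) < 2
            return float(force), flags
    flags["unresponsive"] = True
    return None, flags


def classify_unit(record: UnitRecord, hair_deflection_responsive: bool = False) -> str:
    """CT / HFA / other classification of a characterized unit.

    CT: C fibre, mechanical threshold <= 4 mN, responsive to soft brushing.
    HFA: A-beta rapidly-adapting LTMR responsive to hair deflection.
    """
    brush = record.metrics.get("brush")
    brush_responsive = brush is not None and brush.count >= 2
    if (
        record.fibre_class == "C"
        and record.mech_threshold is not None
        and record.mech_threshold <= 4.0
        and brush_responsive
    ):
        return "CT"
    if (
        record.fibre_class == "A_beta"
        and record.adaptation == "RA"
        and hair_deflection_responsive
    ):
        return "HFA"
    return "other"


def classify_adaptation(
    train: SpikeTrain | np.ndarray,
    hold_window: tuple[float, float],
    onset_s: float = 0.5,
    drop_fraction: float = 0.1,
) -> str:
    """RA / SA from firing during a sustained (100 mN) indentation hold.

    Rapidly adapting: the firing rate over the remainder of the hold drops
    below ``drop_fraction`` of the onset rate (first ``onset_s`` of the
    hold). Returns "unknown" when there is no onset response.
    """
    t0, t1 = hold_window
    if t1 - t0 <= onset_s:
        raise ValueError("hold window must exceed the onset interval")
    times = train.spike_times if isinstance(train, SpikeTrain) else np.asarray(train, dtype=float)
    onset_rate = np.sum((times >= t0) & (times < t0 + onset_s)) / onset_s
    late_rate = np.sum((times >= t0 + onset_s) & (times <= t1)) / (t1 - t0 - onset_s)
    if onset_rate == 0:
        return "unknown"
    return "RA" if late_rate < drop_fraction * onset_rate else "SA"


def detect_after_discharge(
    train: SpikeTrain | np.ndarray,
    stimulus_end: float,
    gap_rule: float = 2.0,
) -> AfterDischarge:
    """Quantify continued firing after a stimulus (hair pluck) ends.

    Post-stimulus spikes are scanned in order; the discharge terminates at
    the last spike before the first inter-spike gap exceeding ``gap_rule``
    (or at the last spike overall). Duration is that spike's time minus
    ``stimulus_end``; IF metrics are computed over the discharge interval.
    """
    times = train.spike_times if isinstance(train, SpikeTrain) else np.asarray(train, dtype=float)
    post = times[times > stimulus_end]
    if post.size == 0:
        return AfterDischarge(0.0, None, None, gap_rule)
    gaps = np.diff(post)
    big = np.nonzero(gaps > gap_rule)[0]
    last = post[big[0]] if big.size else post[-1]
    # also terminate before the first spike if the onset gap exceeds the rule
    if post[0] - stimulus_end > gap_rule:
        return AfterDischarge(0.0, None, None, gap_rule)
    m = spike_metrics(post, (stimulus_end, last + 1e-9))
    return AfterDischarge(float(last - stimulus_end), m.mean_if, m.peak_if, gap_rule)
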