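"""Synthetic extracellular voltage traces with known spike-time ground truth.

Emulates single-unit microneurography of low-threshold mechanoreceptors in
hairy skin: stimulus-locked firing modelled as a gamma renewal process,
stereotyped biphasic spike waveforms whose leading-phase polarity encodes the
fibre class (downward for unmyelinated C fibres, upward for myelinated
A-beta fibres), conduction latency, and additive Gaussian noise.

The key calibration is the renewal-rate correction: the downstream metric of
interest is the *mean instantaneous frequency*, i.e. the mean of reciprocal
inter-spike intervals. For a gamma renewal process with shape ``k`` and ISI
scale ``theta``, ``E[1/ISI] = 1/(theta * (k - 1))``, so a target mean IF of
``f`` requires ``theta = 1 / (f * (k - 1))`` (event rate ``(k-1)/k * f``).
A Poisson process (k = 1) is excluded: its mean reciprocal ISI diverges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "StimulusEpoch",
    "UnitSpec",
    "NeuralTrace",
    "gen_neural_trace",
    "gen_discharge_spikes",
    "CT_PRESET",
    "HFA_PRESET",
    "CT_THRESHOLD_FORCES",
    "CT_THRESHOLD_WEIGHTS",
]

STIMULUS_KINDS = ("brush", "hair_deflection", "air_puff", "monofilament", "pluck", "idle")

#: Default gamma ISI shape; regular enough that mean(1/ISI) is finite and
#: close to the nominal rate.
ISI_SHAPE = 4.0

#: Electrode-to-receptive-field conduction distance (m) used to convert a
#: unit's conduction velocity into a response latency.
CONDUCTION_DISTANCE_M = 0.3


@dataclass(frozen=True)
class StimulusEpoch:
    """A stimulation interval within a recording.

    ``params`` carries the stimulus-specific quantities: ``force`` in mN for
    monofilament indentation, ``velocity`` in cm/s for brushing or hair
    deflection.
    """

    kind: str
    t_start: float
    t_end: float
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in STIMULUS_KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if not self.t_start < self.t_end:
            raise ValueError("epoch requires t_start < t_end")
        if self.kind == "monofilament":
            force = self.params.get("force")
            if force is None or force <= 0:
                raise ValueError("monofilament epoch requires force > 0 mN")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def _check_epochs(epochs: Sequence[StimulusEpoch]) -> None:
    ordered = sorted(epochs, key=lambda e: e.t_start)
    for a, b in zip(ordered, ordered[1:]):
        if b.t_start < a.t_end:
            raise ValueError(f"overlapping epochs: {a} / {b}")


@dataclass(frozen=True)
class UnitSpec:
    """Generating parameters of one simulated afferent unit.

    ``rate_presets`` maps stimulus kind to ``(mean_if, isi_shape)``: the
    target mean instantaneous frequency in spikes/s during that stimulus and
    the gamma ISI shape. ``after_discharge`` is ``(duration_mean_s,
    duration_sd_s, initial_rate)``; ``None`` disables after-discharge
    (the A-beta hair-follicle-afferent behaviour).
    """

    fibre_class: str  # "C" | "A_beta"
    true_threshold: float  # mN
    conduction_velocity: float  # m/s
    rate_presets: Mapping[str, tuple[float, float]]
    after_discharge: tuple[float, float, float] | None = None
    adaptation: str = "unknown"  # "RA" | "SA" | "unknown"; RA units fire only at indentation onset

    def __post_init__(self) -> None:
        if self.fibre_class not in ("C", "A_beta"):
            raise ValueError("fibre_class must be 'C' or 'A_beta'")
        if self.fibre_class == "C" and not self.conduction_velocity < 2.0:
            raise ValueError("C units require conduction velocity < 2 m/s")
        if self.fibre_class == "A_beta" and not self.conduction_velocity > 30.0:
            raise ValueError("A_beta units require conduction velocity > 30 m/s")
        for kind, (rate, shape) in self.rate_presets.items():
            if rate < 0 or shape <= 1:
                raise ValueError(f"invalid rate preset for {kind!r}: mean IF >= 0 and shape > 1 required")

    @property
    def polarity(self) -> str:
        return "down" if self.fibre_class == "C" else "up"

    @property
    def response_latency(self) -> float:
        """Conduction delay (s) between stimulus and recorded spikes."""
        return CONDUCTION_DISTANCE_M / self.conduction_velocity


@dataclass
class NeuralTrace:
    """Sampled voltage trace with stimulus epochs and optional ground truth."""

    samples: np.ndarray  # µV
    sampling_rate: float  # Hz
    epochs: list[StimulusEpoch]
    truth_spike_times: np.ndarray | None = None  # s, strictly increasing
    truth_template: np.ndarray | None = None
    truth_discharge_duration: float | None = None  # s after pluck epoch end

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    def __post_init__(self) -> None:
        if self.truth_spike_times is not None:
            t = np.asarray(self.truth_spike_times, dtype=float)
            if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > self.duration):
                raise ValueError("truth spike times must be strictly increasing within [0, duration]")
            self.truth_spike_times = t


# ---------------------------------------------------------------------------
# Population presets calibrated to the recorded CT / HFA populations:
# CT brushing mean IF 21 spikes/s (SD 6), hair deflection 12 (SD 5),
# after-discharge duration 7.1 s (SD 3.2) at ~5 spikes/s;
# HFA brushing 31 (SD 15), deflection 12 (SD 7), no after-discharge.
# ---------------------------------------------------------------------------

CT_PRESET = UnitSpec(
    fibre_class="C",
    true_threshold=0.7,
    conduction_velocity=1.09,
    rate_presets={
        "brush": (21.0, ISI_SHAPE),
        "hair_deflection": (12.0, ISI_SHAPE),
        "air_puff": (10.0, ISI_SHAPE),
        "monofilament": (15.0, ISI_SHAPE),
        "pluck": (15.0, ISI_SHAPE),
    },
    after_discharge=(7.1, 3.2, 10.0),
    adaptation="SA",
)

HFA_PRESET = UnitSpec(
    fibre_class="A_beta",
    true_threshold=0.4,
    conduction_velocity=34.9,
    rate_presets={
        "brush": (31.0, ISI_SHAPE),
        "hair_deflection": (12.0, ISI_SHAPE),
        "air_puff": (26.0, ISI_SHAPE),
        "monofilament": (30.0, ISI_SHAPE),
        "pluck": (30.0, ISI_SHAPE),
    },
    after_discharge=None,
    adaptation="RA",
)

#: Categorical preset over standard monofilament forces for CT mechanical
#: thresholds; reproduces the recorded population summary
#: (mean 0.92 mN, SD 0.87 mN, min 0.4, max 4.0).
CT_THRESHOLD_FORCES = np.array([0.4, 0.7, 1.6, 4.0])
CT_THRESHOLD_WEIGHTS = np.array([3.0, 10.0, 1.0, 1.0]) / 15.0


def _gamma_renewal_times(
    rng: np.random.Generator,
    t0: float,
    t1: float,
    mean_if: float,
    shape: float,
) -> np.ndarray:
    """Spike times of a stationary gamma renewal process on [t0, t1).

    ``mean_if`` is the target mean reciprocal ISI, corrected for the gamma
    shape (see module docstring).
    """
    if mean_if <= 0:
        return np.empty(0)
    theta = 1.0 / (mean_if * (shape - 1.0))
    mean_isi = shape * theta
    n_guess = max(8, int((t1 - t0) / mean_isi * 2 + 20))
    times: list[float] = []
    t = t0
    while True:
        isis = rng.gamma(shape, theta, size=n_guess)
        for isi in isis:
            t += isi
            if t >= t1:
                return np.asarray(times)
            times.append(t)


def gen_discharge_spikes(
    rng: np.random.Generator,
    t_end_stimulus: float,
    duration_mean: float,
    duration_sd: float,
    initial_rate: float = 10.0,
    shape: float = ISI_SHAPE,
    floor_rate: float = 2.5,
) -> tuple[np.ndarray, float]:
    """After-discharge spike times following a pluck, plus the drawn duration.

    The duration is drawn from Normal(mean, sd) with non-positive draws
    resampled. Firing is an inhomogeneous renewal process whose rate decays
    linearly from ``initial_rate`` towards ``floor_rate`` at the drawn
    duration; the final spike sits exactly at the drawn duration, which
    defines the ground-truth discharge length (time of the last spike).
    """
    d = rng.normal(duration_mean, duration_sd)
    while d <= 0:
        d = rng.normal(duration_mean, duration_sd)
    times: list[float] = []
    t = 0.0
    while True:
        rate = max(floor_rate, initial_rate * (1.0 - t / d))
        theta = 1.0 / (rate * (shape - 1.0))
        t += rng.gamma(shape, theta)
        if t >= d:
            break
        times.append(t)
    times.append(d)
    return t_end_stimulus + np.asarray(times), float(d)


def spike_waveform(
    sampling_rate: float = 20_000.0,
    width_ms: float = 3.0,
    polarity: str = "down",
    amplitude: float = 100.0,
) -> np.ndarray:
    """Stereotyped biphasic action-potential template (µV).

    A Gabor-like single cycle: the leading phase carries the polarity
    convention (downward-leading for C units, upward for A-beta).
    """
    n = int(round(width_ms * 1e-3 * sampling_rate))
    t = np.linspace(-1.0, 1.0, n)
    # dominant leading phase, weaker trailing phase of opposite sign: the
    # global extremum is unique, so peak alignment is unambiguous
    w = -np.exp(-(((t + 0.25) / 0.18) ** 2)) + 0.45 * np.exp(-(((t - 0.3) / 0.28) ** 2))
    w = w / np.max(np.abs(w)) * amplitude
    if polarity == "up":
        w = -w
    return w


def gen_neural_trace(
    spec: UnitSpec,
    epochs: Sequence[StimulusEpoch],
    noise_sd: float = 5.0,
    seed: int | np.random.Generator = 0,
    duration: float | None = None,
    sampling_rate: float = 20_000.0,
    spike_amplitude: float = 100.0,
) -> NeuralTrace:
    """Render a voltage trace for one unit under a stimulus protocol.

    Spiking is ~0 outside epochs; within an epoch it is a gamma renewal
    process targeting the preset mean IF for that stimulus kind, delayed by
    the unit's conduction latency. A ``pluck`` epoch is followed by
    after-discharge when the spec defines one. Each spike inserts the
    unit's biphasic waveform; Gaussian noise of ``noise_sd`` µV is added.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    _check_epochs(epochs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    latency = spec.response_latency
    discharge_duration: float | None = None
    spike_times: list[np.ndarray] = []
    for epoch in epochs:
        if epoch.kind == "idle":
            continue
        mean_if, shape = spec.rate_presets.get(epoch.kind, (0.0, ISI_SHAPE))
        t0, t1 = epoch.t_start + latency, epoch.t_end + latency
        if spec.adaptation == "RA" and epoch.kind == "monofilament":
            t1 = min(t1, t0 + 0.2)  # rapidly adapting: onset burst only
        spike_times.append(_gamma_renewal_times(rng, t0, t1, mean_if, shape))
        if epoch.kind == "pluck" and spec.after_discharge is not None:
            d_mean, d_sd, r0 = spec.after_discharge
            ad_times, discharge_duration = gen_discharge_spikes(
                rng, epoch.t_end + latency, d_mean, d_sd, initial_rate=r0
            )
            spike_times.append(ad_times)
    all_times = np.sort(np.concatenate(spike_times)) if spike_times else np.empty(0)

    if duration is None:
        tail = 1.0 if all_times.size == 0 else max(1.0, all_times[-1] - (epochs[-1].t_end if epochs else 0.0) + 0.5)
        end = max([e.t_end for e in epochs], default=1.0)
        duration = end + tail
    n = int(round(duration * sampling_rate))

    # enforce strictly increasing, inside the trace, separated by >=2 samples
    min_gap = 2.0 / sampling_rate
    kept: list[float] = []
    for t in all_times:
        if t <= 0 or t >= duration - 0.005:
            continue
        if kept and t - kept[-1] < min_gap:
            continue
        kept.append(float(t))
    truth = np.asarray(kept)

    template = spike_waveform(sampling_rate, polarity=spec.polarity, amplitude=spike_amplitude)
    samples = np.zeros(n)
    half = len(template) // 2
    peak_offset = int(np.argmax(np.abs(template)))
    for t in truth:
        i_peak = int(round(t * sampling_rate))
        i0 = i_peak - peak_offset
        i1 = i0 + len(template)
        if i0 < 0 or i1 > n:
            continue
        samples[i0:i1] += template
    if noise_sd > 0:
        samples += rng.normal(0.0, noise_sd, size=n)

    return NeuralTrace(
        samples=samples,
        sampling_rate=sampling_rate,
        epochs=list(epochs),
        truth_spike_times=truth,
        truth_template=template,
        truth_discharge_duration=discharge_duration,
    )
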