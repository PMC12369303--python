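"""End-to-end study pipelines: synthetic generation -> quantification ->
statistics -> report tables.

Two orchestrators mirror the study's two quantification arms:

* :func:`run_microneuro_pipeline` — simulate a roster of CT / HFA units,
  run spike detection and instantaneous-frequency metrics per stimulus
  trial, average within unit, classify every unit, quantify after-discharge
  following hair plucking, and summarize across units including the
  brushing vs. hair-deflection comparison (Mann-Whitney and paired t).
* :func:`run_oct_pipeline` — generate the full OCT M-mode protocol,
  segment the skin surface, detect stimulus events, estimate per-trial
  displacement by the condition-appropriate windowing rule, reject artefact
  trials, select the ten highest displacements per condition and compare
  conditions with Tukey HSD.

All randomness flows from one top-level seed through `numpy` child
generators, so re-running with the same configuration reproduces every
output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ctquant import octdisp
from ctquant.spikes import (
    SpikeMetrics,
    UnitRecord,
    classify_adaptation,
    classify_fibre,
    classify_unit,
    detect_after_discharge,
    detect_spikes,
    estimate_mech_threshold,
    spike_metrics,
)
from ctquant.stats import compare_groups
from ctquant.synth.neural import (
    CT_PRESET,
    CT_THRESHOLD_FORCES,
    CT_THRESHOLD_WEIGHTS,
    HFA_PRESET,
    StimulusEpoch,
    UnitSpec,
    gen_neural_trace,
)
from ctquant.synth.oct import OctProtocol, gen_oct_protocol

__all__ = [
    "MicroneuroConfig",
    "OctConfig",
    "GroupStats",
    "draw_unit_specs",
    "simulate_monofilament_responses",
    "run_microneuro_pipeline",
    "run_oct_pipeline",
    "calibrated_oct_protocol",
    "simulate_after_discharge_durations",
    "simulate_ct_population_mean_if",
    "simulate_threshold_population",
]


@dataclass(frozen=True)
class MicroneuroConfig:
    """Roster and protocol for the simulated microneurography study.

    Per-unit mean-IF targets are drawn from the population presets
    (CT brushing 21 +/- 6 spikes/s, hair deflection 12 +/- 5; HFA brushing
    31 +/- 15, deflection 12 +/- 7); CT mechanical thresholds come from the
    categorical monofilament preset (mean 0.92 mN).
    """

    n_ct: int = 15
    n_hfa: int = 3
    trials_per_stimulus: int = 4
    stimuli: tuple[str, ...] = ("brush", "hair_deflection")
    include_pluck: bool = True
    noise_sd: float = 5.0  # µV; spike amplitude is 100 µV
    epoch: tuple[float, float] = (0.5, 2.5)
    rate_sd: dict = field(
        default_factory=lambda: {
            ("C", "brush"): 6.0,
            ("C", "hair_deflection"): 5.0,
            ("A_beta", "brush"): 15.0,
            ("A_beta", "hair_deflection"): 7.0,
        }
    )


@dataclass
class GroupStats:
    """Across-unit summaries per stimulus plus two-group comparisons."""

    per_stimulus: pd.DataFrame  # index stimulus: n, mean_if_mean, mean_if_sd, peak_if_mean, peak_if_sd
    comparisons: dict  # e.g. {"mean_if": {"mann_whitney": (U, p), "paired_t": (t, p)}}


def draw_unit_specs(
    config: MicroneuroConfig, rng: np.random.Generator
) -> list[UnitSpec]:
    """Unit roster with per-unit rate targets drawn around the presets."""
    specs: list[UnitSpec] = []
    for base, n in ((CT_PRESET, config.n_ct), (HFA_PRESET, config.n_hfa)):
        for _ in range(n):
            presets = dict(base.rate_presets)
            for kind in config.stimuli:
                mean, shape = presets[kind]
                sd = config.rate_sd.get((base.fibre_class, kind), 0.0)
                presets[kind] = (float(max(3.0, rng.normal(mean, sd))), shape)
            if base.fibre_class == "C":
                thr = float(rng.choice(CT_THRESHOLD_FORCES, p=CT_THRESHOLD_WEIGHTS))
            else:
                thr = base.true_threshold
            specs.append(replace(base, rate_presets=presets, true_threshold=thr))
    return specs


def simulate_monofilament_responses(
    true_threshold: float,
    rng: np.random.Generator,
    trials_per_force: int = 3,
    lapse: float = 0.02,
    forces: tuple[float, ...] = (4.0, 1.6, 0.7, 0.4, 0.2, 0.08),
) -> dict[float, list[bool]]:
    """Descending-staircase monofilament testing of one unit.

    The unit responds to a force at or above its true threshold with
    probability ``1 - lapse`` and below threshold with probability
    ``lapse``. Testing descends from the strongest force and stops after
    the first force with no responses, mirroring the threshold procedure
    (decrease until no response, then confirm).
    """
    responses: dict[float, list[bool]] = {}
    for force in sorted(forces, reverse=True):
        p = 1.0 - lapse if force >= true_threshold - 1e-9 else lapse
        trials = (rng.random(trials_per_force) < p).tolist()
        responses[force] = [bool(t) for t in trials]
        if not any(trials):
            break
    return responses


def _unit_metrics(
    spec: UnitSpec,
    kind: str,
    config: MicroneuroConfig,
    rng: np.random.Generator,
) -> SpikeMetrics:
    """Mean response over repeat trials of one stimulus for one unit."""
    t0, t1 = config.epoch
    window = (t0, t1 + spec.response_latency + 0.1)
    counts, mean_ifs, peak_ifs = [], [], []
    for _ in range(config.trials_per_stimulus):
        epoch = StimulusEpoch(kind, t0, t1)
        trace = gen_neural_trace(
            spec, [epoch], noise_sd=config.noise_sd, seed=rng, duration=t1 + 1.0
        )
        train = detect_spikes(trace)
        m = spike_metrics(train, window)
        counts.append(m.count)
        if m.mean_if is not None:
            mean_ifs.append(m.mean_if)
            peak_ifs.append(m.peak_if)
    return SpikeMetrics(
        count=int(round(np.mean(counts))),
        mean_if=float(np.mean(mean_ifs)) if mean_ifs else None,
        peak_if=float(np.mean(peak_ifs)) if peak_ifs else None,
        window=window,
    )


def run_microneuro_pipeline(
    config: MicroneuroConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroupStats | None]:
    """Simulate, quantify and classify a unit roster; summarize across units.

    Returns a one-row-per-unit table (classification, threshold, per-stimulus
    metrics, after-discharge) and group statistics (None for an empty
    roster).
    """
    config = config or MicroneuroConfig()
    rng = np.random.default_rng(seed)
    specs = draw_unit_specs(config, rng)
    rows = []
    for i, spec in enumerate(specs):
        row: dict = {"unit": i, "fibre_class_true": spec.fibre_class}
        record = UnitRecord(fibre_class="other", mech_threshold=None)

        # electrical classification: polarity from detected spikes, CV as measured
        t0, t1 = config.epoch
        brush_trace = gen_neural_trace(
            spec, [StimulusEpoch("brush", t0, t1)], noise_sd=config.noise_sd,
            seed=rng, duration=t1 + 1.0,
        )
        brush_train = detect_spikes(brush_trace)
        record.conduction_velocity = spec.conduction_velocity
        record.fibre_class = classify_fibre(
            brush_train.polarity, conduction_velocity=spec.conduction_velocity
        )

        # adaptation from a 100 mN hold
        hold = StimulusEpoch("monofilament", 0.5, 1.5, {"force": 100.0})
        hold_trace = gen_neural_trace(spec, [hold], noise_sd=config.noise_sd, seed=rng, duration=2.0)
        lat = spec.response_latency
        record.adaptation = classify_adaptation(
            detect_spikes(hold_trace), (0.5 + lat, 1.5 + lat)
        )

        # mechanical threshold by the 50%-criterion staircase
        responses = simulate_monofilament_responses(spec.true_threshold, rng)
        record.mech_threshold, thr_flags = estimate_mech_threshold(responses)

        # per-stimulus metrics, averaged over repeat trials
        for kind in config.stimuli:
            record.metrics[kind] = _unit_metrics(spec, kind, config, rng)
            row[f"{kind}_mean_if"] = record.metrics[kind].mean_if
            row[f"{kind}_peak_if"] = record.metrics[kind].peak_if
            row[f"{kind}_count"] = record.metrics[kind].count

        deflection = record.metrics.get("hair_deflection")
        deflection_responsive = deflection is not None and deflection.count >= 2
        record.unit_type = classify_unit(record, deflection_responsive)

        # after-discharge following hair plucking
        if config.include_pluck:
            pluck = StimulusEpoch("pluck", 0.5, 1.5)
            pluck_trace = gen_neural_trace(spec, [pluck], noise_sd=config.noise_sd, seed=rng)
            ad = detect_after_discharge(
                detect_spikes(pluck_trace), stimulus_end=1.5 + lat
            )
            row["after_discharge_s"] = ad.duration
            row["after_discharge_mean_if"] = ad.mean_if if ad.mean_if is not None else 0.0

        row.update(
            fibre_class=record.fibre_class,
            mech_threshold_mN=record.mech_threshold,
            adaptation=record.adaptation,
            unit_type=record.unit_type,
            threshold_unresponsive=thr_flags["unresponsive"],
        )
        rows.append(row)

    table = pd.DataFrame(rows)
    if table.empty:
        return table, None

    per_stim = []
    for kind in config.stimuli:
        vals = table[f"{kind}_mean_if"].dropna()
        peaks = table[f"{kind}_peak_if"].dropna()
        per_stim.append(
            {
                "stimulus": kind,
                "n": int(len(vals)),
                "mean_if_mean": float(vals.mean()),
                "mean_if_sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "peak_if_mean": float(peaks.mean()),
                "peak_if_sd": float(peaks.std(ddof=1)) if len(peaks) > 1 else np.nan,
            }
        )
    per_stimulus = pd.DataFrame(per_stim).set_index("stimulus")

    comparisons: dict = {}
    if {"brush", "hair_deflection"} <= set(config.stimuli):
        ct = table[table.unit_type == "CT"]
        paired = ct.dropna(subset=["brush_mean_if", "hair_deflection_mean_if"])
        if len(paired) >= 2:
            a = paired["brush_mean_if"].to_numpy()
            b = paired["hair_deflection_mean_if"].to_numpy()
            comparisons["mean_if"] = {
                "mann_whitney": compare_groups(a, b, "mann_whitney")[:2],
                "paired_t": compare_groups(a, b, "paired_t")[:2],
            }
    return table, GroupStats(per_stimulus=per_stimulus, comparisons=comparisons)


# ---------------------------------------------------------------------------
# Population-recovery simulations
# ---------------------------------------------------------------------------


def simulate_after_discharge_durations(
    n_trials: int = 500,
    seed: int = 0,
    duration_mean: float = 7.1,
    duration_sd: float = 3.2,
    gap_rule: float = 2.0,
) -> np.ndarray:
    """Detected after-discharge durations over simulated pluck trials.

    Spike-level simulation: each trial draws a discharge duration from
    Normal(mean, sd) (non-positive draws resampled), generates the
    decaying-rate discharge train after a pluck ending at t = 1 s, and runs
    the gap-rule detector.
    """
    from ctquant.synth.neural import gen_discharge_spikes

    rng = np.random.default_rng(seed)
    stimulus_end = 1.0
    out = np.empty(n_trials)
    for i in range(n_trials):
        times, _truth = gen_discharge_spikes(
            rng, stimulus_end, duration_mean, duration_sd
        )
        ad = detect_after_discharge(times, stimulus_end, gap_rule=gap_rule)
        out[i] = ad.duration
    return out


def simulate_ct_population_mean_if(
    kind: str = "brush",
    n_units: int = 60,
    trials_per_unit: int = 4,
    seed: int = 0,
) -> float:
    """Across-unit mean of per-unit mean IF for one stimulus, full pipeline.

    Per-unit rate targets are drawn from the CT preset for the stimulus
    (brush 21 +/- 6 spikes/s, hair deflection 12 +/- 5); each unit is
    quantified by spike detection + IF metrics over repeat trials.
    """
    config = MicroneuroConfig(
        n_ct=1, n_hfa=0, trials_per_stimulus=trials_per_unit, stimuli=(kind,)
    )
    rng = np.random.default_rng(seed)
    unit_means = []
    for _ in range(n_units):
        spec = draw_unit_specs(config, rng)[0]
        m = _unit_metrics(spec, kind, config, rng)
        if m.mean_if is not None:
            unit_means.append(m.mean_if)
    return float(np.mean(unit_means))


def simulate_threshold_population(
    n_units: int = 400,
    trials_per_force: int = 3,
    seed: int = 0,
) -> float:
    """Mean staircase-estimated monofilament threshold over simulated CTs.

    True thresholds are drawn from the categorical CT preset (mean 0.92 mN)
    over the standard monofilament forces; each unit is tested by the
    descending staircase with the 50%-of-occasions criterion.
    """
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_units):
        true_thr = float(rng.choice(CT_THRESHOLD_FORCES, p=CT_THRESHOLD_WEIGHTS))
        responses = simulate_monofilament_responses(
            true_thr, rng, trials_per_force=trials_per_force
        )
        est, flags = estimate_mech_threshold(responses)
        if est is not None:
            estimates.append(est)
    return float(np.mean(estimates))


# ---------------------------------------------------------------------------
# OCT arm
# ---------------------------------------------------------------------------


def calibrated_oct_protocol(
    artefact_fraction: float = 0.23,
    noise_sd: float = 0.05,
    aline_rate: float = 1000.0,
    n_depth: int = 128,
) -> OctProtocol:
    """The full synthetic protocol calibrated to the study conditions.

    Ground-truth displacements and spreads carry the reported per-condition
    group statistics; the A-line rate and depth-axis length are reduced from
    the acquisition values to keep full-protocol runs light (the windowed
    estimators are rate independent).
    """
    return OctProtocol(
        artefact_fraction=artefact_fraction,
        noise_sd=noise_sd,
        aline_rate=aline_rate,
        n_depth=n_depth,
    )


@dataclass(frozen=True)
class OctConfig:
    protocol: OctProtocol = field(default_factory=calibrated_oct_protocol)
    criteria: octdisp.RejectionCriteria = field(default_factory=octdisp.RejectionCriteria)
    top_k: int = 10
    smooth_ms: float = 5.0
    structure_seed: int = 20210901


def measure_trial(trial, smooth_ms: float = 5.0) -> octdisp.DisplacementMeasure:
    """Condition-appropriate displacement for one segmented trial."""
    track = octdisp.segment_surface(trial, smooth_ms=smooth_ms)
    base = dict(
        condition=trial.condition,
        location=trial.location,
        trial_id=trial.trial_id,
        truth_um=trial.truth_displacement,
    )
    try:
        if trial.condition == "idle":
            disp, windows = octdisp.displacement_idle(track)
        else:
            kind = "contact" if trial.condition.startswith("mono") else "release"
            event = octdisp.detect_event(track, kind)
            disp, windows = octdisp.displacement_windows(track, event)
    except ValueError as err:
        return octdisp.DisplacementMeasure(
            displacement_um=None, rejected=True, reason=str(err), **base
        )
    return octdisp.DisplacementMeasure(displacement_um=disp, windows=windows, **base)


def run_oct_pipeline(
    config: OctConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, octdisp.ConditionComparison | None, float]:
    """Full OCT arm: generate -> segment -> reject -> measure -> top-10 -> Tukey.

    Returns the per-trial displacement table, the condition comparison
    (None with a shortfall when fewer than two conditions are usable) and
    the artefact-rejection fraction.
    """
    config = config or OctConfig()
    rng = np.random.default_rng(seed)

    pairs = []
    for trial in gen_oct_protocol(config.protocol, seed=rng, structure_seed=config.structure_seed):
        track = octdisp.segment_surface(trial, smooth_ms=config.smooth_ms)
        pairs.append((trial, track))
    kept, reject_frac, reasons = octdisp.reject_trials(pairs, config.criteria)

    measures: list[octdisp.DisplacementMeasure] = []
    for (trial, _), reason in zip(pairs, reasons):
        if reason is not None:
            measures.append(
                octdisp.DisplacementMeasure(
                    condition=trial.condition,
                    location=trial.location,
                    trial_id=trial.trial_id,
                    displacement_um=None,
                    rejected=True,
                    reason=reason,
                    truth_um=trial.truth_displacement,
                )
            )
        else:
            measures.append(measure_trial(trial, config.smooth_ms))

    table = pd.DataFrame(
        {
            "condition": [m.condition for m in measures],
            "location": [str(m.location) for m in measures],
            "trial_id": [m.trial_id for m in measures],
            "displacement_um": [m.displacement_um for m in measures],
            "truth_um": [m.truth_um for m in measures],
            "rejected": [m.rejected for m in measures],
            "reason": [m.reason for m in measures],
        }
    )

    selected: dict[str, np.ndarray] = {}
    for condition in config.protocol.conditions:
        cond = [m for m in measures if m.condition == condition]
        if not cond:
            continue
        top, _short = octdisp.select_top(cond, k=config.top_k)
        if len(top) >= 2:
            selected[condition] = np.array([m.displacement_um for m in top])

    comparison = (
        octdisp.compare_conditions(selected) if len(selected) >= 2 else None
    )
    return table, comparison, reject_frac
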