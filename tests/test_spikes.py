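"""Spike metrics, detection, classification and after-discharge rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctquant.spikes import (
    SpikeTrain,
    classify_adaptation,
    classify_fibre,
    classify_unit,
    conduction_velocity,
    detect_after_discharge,
    detect_spikes,
    estimate_mech_threshold,
    spike_metrics,
    SpikeMetrics,
    UnitRecord,
)
from ctquant.synth.neural import CT_PRESET, StimulusEpoch, gen_neural_trace


class TestSpikeMetrics:
    @pytest.mark.parametrize(
        "times, count, mean_if, peak_if",
        [
            ([1.0, 1.1, 1.2, 1.3], 4, 10.0, 10.0),  # regular train
            ([0.0, 0.5, 0.6], 3, 6.0, 10.0),  # IFs {2, 10}
            ([2.0], 1, None, None),  # single spike: undefined by the 2-spike rule
            ([], 0, None, None),
        ],
    )
    def test_window_metrics(self, times, count, mean_if, peak_if):
        m = spike_metrics(np.asarray(times), (0.0, 5.0))
        assert m.count == count
        if mean_if is None:
            assert m.mean_if is None and m.peak_if is None
        else:
            assert m.mean_if == pytest.approx(mean_if)
            assert m.peak_if == pytest.approx(peak_if)

    def test_span_mode(self):
        m = spike_metrics(np.array([0.0, 0.5, 0.6]), (0.0, 1.0), mean_if_mode="span")
        assert m.mean_if == pytest.approx(2 / 0.6)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            spike_metrics(np.array([1.0]), (2.0, 1.0))

    @given(
        isis=st.lists(st.floats(0.01, 2.0), min_size=1, max_size=30),
        t0=st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_mean_if_at_least_span_rate(self, isis, t0):
        """Jensen: mean(1/ISI) >= (N-1)/span, equality iff all ISIs equal."""
        times = t0 + np.concatenate([[0.0], np.cumsum(isis)])
        m = spike_metrics(times, (times[0] - 0.1, times[-1] + 0.1))
        span_rate = (m.count - 1) / (times[-1] - times[0])
        assert m.mean_if >= span_rate - 1e-9
        if np.allclose(isis, isis[0]):
            assert m.mean_if == pytest.approx(span_rate)

    @given(delta=st.floats(0.005, 1.0), n=st.integers(2, 40))
    @settings(max_examples=60, deadline=None)
    def test_regular_train_exactness(self, delta, n):
        """Regular ISIs Delta: mean IF = peak IF = 1/Delta exactly."""
        times = np.arange(n) * delta
        m = spike_metrics(times, (-0.1, times[-1] + 0.1))
        assert m.mean_if == pytest.approx(1.0 / delta, rel=1e-9)
        assert m.peak_if == pytest.approx(1.0 / delta, rel=1e-9)

    def test_peak_at_least_mean(self):
        t = np.cumsum(np.random.default_rng(0).uniform(0.01, 0.2, 20))
        m = spike_metrics(t, (0.0, t[-1] + 1))
        assert m.peak_if >= m.mean_if


class TestDetectSpikes:
    def test_recovers_truth_under_noise(self):
        """SNR 8: every truth spike detected within 0.5 ms, no extras."""
        trace = gen_neural_trace(
            CT_PRESET, [StimulusEpoch("brush", 0.5, 2.5)],
            noise_sd=12.5, seed=21, duration=3.5,
        )
        train = detect_spikes(trace)
        truth = trace.truth_spike_times
        d = np.abs(train.spike_times[:, None] - truth[None, :])
        assert len(train) == len(truth)
        assert np.all(d.min(axis=1) < 5e-4)

    def test_pure_noise_yields_no_detections(self, rng):
        from ctquant.synth.neural import NeuralTrace

        trace = NeuralTrace(
            samples=rng.normal(0, 5.0, 40_000), sampling_rate=20_000.0, epochs=[]
        )
        train = detect_spikes(trace, threshold=25.0)
        assert len(train) == 0

    def test_template_rejects_foreign_artefact(self):
        """A high-amplitude square artefact fails the correlation gate."""
        trace = gen_neural_trace(
            CT_PRESET, [StimulusEpoch("brush", 0.5, 2.5)],
            noise_sd=0.0, seed=2, duration=3.5,
        )
        n_true = len(trace.truth_spike_times)
        i = int(3.2 * trace.sampling_rate)
        trace.samples[i : i + 20] = 150.0  # square pulse, not spike-shaped
        train = detect_spikes(trace)
        assert len(train) == n_true
        assert np.all(np.abs(train.spike_times - 3.2) > 1e-3)

    def test_too_short_trace_raises(self):
        from ctquant.synth.neural import NeuralTrace

        trace = NeuralTrace(samples=np.zeros(10), sampling_rate=20_000.0, epochs=[])
        with pytest.raises(ValueError):
            detect_spikes(trace)


class TestConductionVelocityAndFibre:
    @pytest.mark.parametrize(
        "distance, latency, expected",
        [(0.060, 0.055, 1.0909), (0.35, 0.010, 35.0)],
    )
    def test_velocity_arithmetic(self, distance, latency, expected):
        assert conduction_velocity(distance, latency) == pytest.approx(expected, abs=1e-3)

    def test_nonpositive_inputs_rejected(self):
        for d, l in [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)]:
            with pytest.raises(ValueError):
                conduction_velocity(d, l)

    @pytest.mark.parametrize(
        "polarity, cv, delay, expected",
        [
            ("down", 1.09, None, "C"),
            ("up", 34.9, None, "A_beta"),
            ("up", 10.0, None, "other"),  # between the class ranges
            ("down", None, 0.3, "C"),  # delayed response marks a C fibre
            ("down", None, 0.02, "other"),
            ("up", None, 0.3, "other"),
        ],
    )
    def test_classification_rules(self, polarity, cv, delay, expected):
        assert classify_fibre(polarity, cv, delay) == expected

    def test_requires_some_evidence(self):
        with pytest.raises(ValueError):
            classify_fibre("down")


class TestMechThreshold:
    def test_fifty_percent_rule_with_confirmation(self):
        responses = {
            4.0: [True, True],
            0.7: [True, True],
            0.4: [True, False, True],
            0.2: [False, False],
        }
        thr, flags = estimate_mech_threshold(responses)
        assert thr == 0.4
        assert not flags["low_confidence"] and not flags["unresponsive"]

    def test_unresponsive_flag(self):
        thr, flags = estimate_mech_threshold({4.0: [False], 60.0: [False, False]})
        assert thr is None and flags["unresponsive"]

    def test_single_trial_low_confidence(self):
        thr, flags = estimate_mech_threshold({0.4: [True]})
        assert thr == 0.4 and flags["low_confidence"]

    def test_nonstandard_force_rejected(self):
        with pytest.raises(ValueError):
            estimate_mech_threshold({0.5: [True, True]})

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            estimate_mech_threshold({})


class TestClassifyUnit:
    def _record(self, fibre, thr, adaptation="unknown", brush_count=10):
        rec = UnitRecord(fibre_class=fibre, mech_threshold=thr, adaptation=adaptation)
        rec.metrics["brush"] = SpikeMetrics(brush_count, 20.0, 40.0, (0.0, 2.0))
        return rec

    def test_ct_requires_c_low_threshold_brush(self):
        assert classify_unit(self._record("C", 0.4)) == "CT"
        assert classify_unit(self._record("C", 6.0)) == "other"  # threshold > 4 mN
        assert classify_unit(self._record("C", 0.4, brush_count=1)) == "other"

    def test_threshold_boundary_inclusive(self):
        assert classify_unit(self._record("C", 4.0)) == "CT"

    def test_hfa_requires_ra_and_deflection(self):
        rec = self._record("A_beta", 0.4, adaptation="RA")
        assert classify_unit(rec, hair_deflection_responsive=True) == "HFA"
        assert classify_unit(rec, hair_deflection_responsive=False) == "other"
        sa = self._record("A_beta", 0.4, adaptation="SA")
        assert classify_unit(sa, hair_deflection_responsive=True) == "other"

    def test_pure_function(self):
        rec = self._record("C", 0.4)
        assert classify_unit(rec) == classify_unit(rec) == "CT"


class TestAdaptation:
    def test_onset_only_firing_is_ra(self):
        times = np.linspace(0.51, 0.68, 8)
        assert classify_adaptation(times, (0.5, 1.5)) == "RA"

    def test_sustained_firing_is_sa(self):
        times = np.arange(0.5, 1.5, 0.05)
        assert classify_adaptation(times, (0.5, 1.5)) == "SA"

    def test_silent_hold_is_unknown(self):
        assert classify_adaptation(np.array([]), (0.5, 1.5)) == "unknown"


class TestAfterDischarge:
    def test_gap_rule_excludes_stray_spike(self):
        """Spikes to +2.0 s then a stray at +30 s: duration stops at 1.9 s."""
        times = np.concatenate([np.arange(0.1, 2.0, 0.1), [30.0]]) + 5.0
        ad = detect_after_discharge(times, stimulus_end=5.0, gap_rule=2.0)
        assert ad.duration == pytest.approx(1.9, abs=1e-9)

    def test_no_post_stimulus_spikes(self):
        ad = detect_after_discharge(np.array([0.1, 0.2]), stimulus_end=1.0)
        assert ad.duration == 0.0 and ad.mean_if is None

    def test_late_onset_counts_as_no_discharge(self):
        ad = detect_after_discharge(np.array([10.0, 10.1]), stimulus_end=1.0, gap_rule=2.0)
        assert ad.duration == 0.0

    def test_duration_matches_generator_truth(self):
        from ctquant.synth.neural import gen_discharge_spikes

        rng = np.random.default_rng(9)
        times, d = gen_discharge_spikes(rng, 1.0, 7.1, 3.2)
        ad = detect_after_discharge(times, stimulus_end=1.0, gap_rule=2.0)
        assert ad.duration == pytest.approx(d, abs=1e-9)
        assert ad.mean_if is not None and ad.peak_if >= ad.mean_if
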