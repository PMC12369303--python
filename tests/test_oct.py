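"""OCT M-mode generation, surface tracking, displacement and Tukey HSD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctquant import octdisp
from ctquant.octdisp import (
    DisplacementMeasure,
    RejectionCriteria,
    compare_conditions,
    detect_event,
    displacement_idle,
    displacement_windows,
    reject_trials,
    segment_surface,
    select_top,
)
from ctquant.synth.oct import (
    CONDITION_DISPLACEMENT_UM,
    OctProtocol,
    gen_oct_protocol,
    gen_oct_trial,
)

NOISELESS = OctProtocol(noise_sd=0.0)


def _track(trial, smooth_ms=1.0):
    return segment_surface(trial, smooth_ms=smooth_ms)


class TestProtocolBookkeeping:
    def test_default_counts(self):
        assert NOISELESS.trials_per_condition == 45  # 3x3 grid x 5 replicates
        trials = list(gen_oct_protocol(NOISELESS, seed=0))
        assert len(trials) == 45 * 6
        counts = pd.Series([t.condition for t in trials]).value_counts()
        assert (counts == 45).all()

    def test_minimal_grid(self):
        p = OctProtocol(grid=(1, 1), trials_per_location=1, aline_rate=500.0, n_depth=64)
        trials = list(gen_oct_protocol(p, seed=0))
        assert len(trials) == len(p.conditions)

    def test_ground_truth_invariant_to_noise_seed(self):
        p = OctProtocol(noise_sd=0.05, aline_rate=500.0, n_depth=64, grid=(1, 1), trials_per_location=2)
        a = list(gen_oct_protocol(p, seed=1))
        b = list(gen_oct_protocol(p, seed=2))
        assert [t.truth_displacement for t in a] == [t.truth_displacement for t in b]
        assert not np.array_equal(a[0].intensity, b[0].intensity)

    def test_fixed_seed_bit_identical(self):
        p = OctProtocol(noise_sd=0.05, aline_rate=500.0, n_depth=64, grid=(1, 1), trials_per_location=1)
        a = list(gen_oct_protocol(p, seed=3))
        b = list(gen_oct_protocol(p, seed=3))
        for x, y in zip(a, b):
            assert np.array_equal(x.intensity, y.intensity)

    def test_artefact_fraction(self):
        p = OctProtocol(artefact_fraction=0.23, aline_rate=200.0, n_depth=32)
        trials = list(gen_oct_protocol(p, seed=0))
        frac = np.mean([t.artefact is not None for t in trials])
        assert frac == pytest.approx(0.23, abs=0.005)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            gen_oct_trial(NOISELESS, "mono_9.9")
        with pytest.raises(ValueError):
            gen_oct_trial(NOISELESS, "idle", location=(7, 7))


class TestSegmentSurface:
    def test_constant_surface_recovered_exactly(self):
        trial = gen_oct_trial(NOISELESS, "idle", seed=0, displacement_um=0.0)
        track = _track(trial)
        assert np.all(track.valid)
        assert np.allclose(track.depth_um, 300.0, atol=1e-4)

    def test_step_recovered_within_smoothing_window(self):
        trial = gen_oct_trial(NOISELESS, "mono_4.0", seed=0)  # 60.93 µm step
        track = _track(trial)
        t = track.times
        hold = (t > 1.52) & (t < 1.95)
        pre = t < 1.48
        assert np.allclose(track.depth_um[pre], 300.0, atol=1e-3)
        assert np.allclose(track.depth_um[hold], 300.0 + 60.93, atol=1e-3)

    def test_occlusion_flags_invalid(self):
        trial = gen_oct_trial(NOISELESS, "idle", seed=0, artefact="occlusion")
        track = _track(trial)
        assert 0.15 < track.invalid_fraction < 0.25  # 0.6 s of 3 s occluded
        assert np.all(np.isnan(track.depth_um[~track.valid]))

    def test_offset_invariance(self):
        """Adding a constant depth offset shifts the track, not the estimate."""
        p = OctProtocol(noise_sd=0.0, base_depth_um=300.0)
        p2 = OctProtocol(noise_sd=0.0, base_depth_um=420.0)
        d1, _ = displacement_windows(_track(gen_oct_trial(p, "mono_0.7", seed=0)), 1.5)
        d2, _ = displacement_windows(_track(gen_oct_trial(p2, "mono_0.7", seed=0)), 1.5)
        assert d1 == pytest.approx(d2, abs=1e-6)


class TestDetectEvent:
    def test_step_time_recovered(self):
        trial = gen_oct_trial(NOISELESS, "mono_0.4", seed=0)
        assert detect_event(_track(trial), "contact") == pytest.approx(1.5, abs=1e-3)

    def test_release_time_recovered(self):
        trial = gen_oct_trial(NOISELESS, "hair_release", seed=0)
        assert detect_event(_track(trial), "release") == pytest.approx(1.5, abs=1e-3)

    def test_flat_track_raises(self):
        trial = gen_oct_trial(NOISELESS, "idle", seed=0, displacement_um=0.0)
        with pytest.raises(ValueError):
            detect_event(_track(trial), "contact")

    def test_larger_of_two_steps_selected(self):
        from ctquant.octdisp import SurfaceTrack

        depth = np.full(3000, 100.0)
        depth[1000:] += 5.0
        depth[2000:] += 20.0  # the larger step, at t = 2.0 s
        track = SurfaceTrack(depth, np.ones(3000, bool), 1000.0, 5.0, 1.0)
        assert detect_event(track, "contact") == pytest.approx(2.0, abs=1e-3)


class TestDisplacement:
    @pytest.mark.parametrize(
        "condition, expected",
        [("mono_0.4", 17.09), ("mono_0.7", 25.28), ("mono_4.0", 60.93), ("mono_6.0", 79.18)],
    )
    def test_noiseless_step_exact(self, condition, expected):
        """Windowed estimator recovers the generating amplitude to <0.01 µm."""
        trial = gen_oct_trial(NOISELESS, condition, seed=0)
        track = _track(trial)
        event = detect_event(track, "contact")
        disp, (pre, post) = displacement_windows(track, event)
        assert disp == pytest.approx(expected, abs=0.01)
        assert pre[1] <= event <= post[0]

    def test_hair_release_exact(self):
        trial = gen_oct_trial(NOISELESS, "hair_release", seed=0)
        track = _track(trial)
        disp, _ = displacement_windows(track, detect_event(track, "release"))
        assert disp == pytest.approx(8.14, abs=0.01)

    def test_idle_drift_exact(self):
        trial = gen_oct_trial(NOISELESS, "idle", seed=0)
        disp, _ = displacement_idle(_track(trial))
        assert disp == pytest.approx(2.04, abs=0.01)

    def test_zero_step_gives_zero(self):
        trial = gen_oct_trial(NOISELESS, "idle", seed=0, displacement_um=0.0)
        disp, _ = displacement_idle(_track(trial))
        assert disp == pytest.approx(0.0, abs=1e-6)

    def test_noisy_step_within_standard_error(self):
        p = OctProtocol(noise_sd=0.05)
        trial = gen_oct_trial(p, "mono_4.0", seed=5)
        track = _track(trial, smooth_ms=1.0)
        disp, _ = displacement_windows(track, 1.5)
        assert disp == pytest.approx(60.93, abs=0.2)

    def test_heartbeat_bounded_by_amplitude(self):
        """Sinusoidal surface motion cannot move window means more than its amplitude."""
        from ctquant.octdisp import SurfaceTrack

        t = np.arange(3000) / 1000.0
        depth = 300.0 + 5.0 * np.sin(2 * np.pi * 1.2 * t)
        track = SurfaceTrack(depth, np.ones(3000, bool), 1000.0, 5.0, 1.0)
        disp, _ = displacement_idle(track)
        assert 0.0 < disp < 5.0

    def test_window_out_of_range(self):
        trial = gen_oct_trial(NOISELESS, "idle", seed=0)
        with pytest.raises(ValueError):
            displacement_windows(_track(trial), 0.05)  # pre-window before t=0


class TestRejectTrials:
    def _pairs(self, protocol, seed=0):
        return [(t, segment_surface(t, smooth_ms=5.0)) for t in gen_oct_protocol(protocol, seed=seed)]

    def test_clean_protocol_keeps_everything(self):
        p = OctProtocol(noise_sd=0.02, aline_rate=500.0, n_depth=128, grid=(1, 3), trials_per_location=2)
        kept, frac, reasons = reject_trials(self._pairs(p))
        assert frac == 0.0 and all(r is None for r in reasons)

    def test_rejection_fraction_tracks_artefact_fraction(self):
        p = OctProtocol(artefact_fraction=0.23, noise_sd=0.02, aline_rate=500.0, n_depth=128)
        kept, frac, reasons = reject_trials(self._pairs(p))
        assert frac == pytest.approx(0.23, abs=0.03)

    def test_occluded_trial_rejected_with_reason(self):
        trial = gen_oct_trial(NOISELESS, "idle", seed=0, artefact="occlusion")
        _, frac, reasons = reject_trials([(trial, _track(trial))])
        assert frac == 1.0 and reasons[0] == "beam-crossing"

    def test_heartbeat_and_motion_reasons(self):
        hb = gen_oct_trial(NOISELESS, "idle", seed=0, artefact="heartbeat")
        mo = gen_oct_trial(NOISELESS, "idle", seed=0, artefact="motion")
        _, _, reasons = reject_trials([(hb, _track(hb)), (mo, _track(mo))])
        assert reasons == ["heartbeat", "motion"]

    def test_idle_drift_not_self_rejected(self):
        """The physiological idle drift stays below the motion criterion."""
        trial = gen_oct_trial(NOISELESS, "idle", seed=0)  # 2.04 µm per 500 ms
        _, frac, _ = reject_trials([(trial, _track(trial))])
        assert frac == 0.0


class TestSelectTop:
    def _measures(self, values):
        return [
            DisplacementMeasure("idle", (0, i % 3), i, float(v))
            for i, v in enumerate(values)
        ]

    def test_largest_k_selected(self):
        vals = np.arange(45, dtype=float)
        top, short = select_top(self._measures(vals), k=10)
        assert not short
        assert sorted(m.displacement_um for m in top) == list(range(35, 45))

    def test_shortfall_warning(self):
        top, short = select_top(self._measures([1.0] * 8), k=10)
        assert short and len(top) == 8

    def test_deterministic_tie_break(self):
        measures = self._measures([5.0] * 20)
        a, _ = select_top(measures, k=10)
        b, _ = select_top(list(measures), k=10)
        assert [(m.location, m.trial_id) for m in a] == [(m.location, m.trial_id) for m in b]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_top([], k=10)

    @given(
        values=st.lists(st.floats(0.0, 100.0), min_size=1, max_size=60),
        k=st.integers(1, 15),
    )
    @settings(max_examples=80, deadline=None)
    def test_selection_invariants(self, values, k):
        """Output subset of input, size <= k, min(selected) >= max(rest)."""
        measures = self._measures(values)
        top, _ = select_top(measures, k=k)
        assert len(top) <= k
        chosen = [m.displacement_um for m in top]
        rest = sorted(values, reverse=True)[len(chosen):]
        if chosen and rest:
            assert min(chosen) >= max(rest) - 1e-9


class TestCompareConditions:
    def test_separated_groups_significant(self, rng):
        groups = {
            "a": np.array([1.0, 1.0, 1.0]) + rng.normal(0, 1e-3, 3),
            "b": np.array([100.0, 100.0, 100.0]) + rng.normal(0, 1e-3, 3),
        }
        comp = compare_conditions(groups)
        assert bool(comp.pairwise.significant.iloc[0])
        # CI contains the mean
        for cond in comp.summary.index:
            row = comp.summary.loc[cond]
            assert row.ci_low <= row.mean_um <= row.ci_high

    def test_pvalues_in_unit_interval(self, rng):
        groups = {c: rng.normal(10, 2, 8) for c in "abcd"}
        comp = compare_conditions(groups)
        assert ((comp.pairwise.p_adj >= 0) & (comp.pairwise.p_adj <= 1)).all()

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions({"a": [1.0, 1.0], "b": [2.0, 2.0]})

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions({"a": [1.0, 2.0]})

    def test_agrees_with_permutation_oracle(self, rng):
        """Adjusted p of the extreme pair matches a label-permutation null."""
        groups = [rng.normal(0, 1, 3), rng.normal(1.0, 1, 3), rng.normal(2.4, 1, 3)]
        comp = compare_conditions({"a": groups[0], "b": groups[1], "c": groups[2]})
        p_tukey = comp.pairwise.loc[
            (comp.pairwise.condition_a == "a") & (comp.pairwise.condition_b == "c"),
            "p_adj",
        ].iloc[0]

        # permutation null of the maximum studentized pairwise difference
        pooled = np.concatenate(groups)
        n = 3

        def max_q(arrs):
            s2 = np.mean([np.var(g, ddof=1) for g in arrs])
            se = np.sqrt(s2 / n)
            ms = [np.mean(g) for g in arrs]
            return max(abs(a - b) for a in ms for b in ms) / max(se, 1e-12)

        q_obs_pair = abs(groups[0].mean() - groups[2].mean()) / np.sqrt(
            np.mean([np.var(g, ddof=1) for g in groups]) / n
        )
        count = 0
        n_perm = 3000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            arrs = [perm[:3], perm[3:6], perm[6:]]
            if max_q(arrs) >= q_obs_pair - 1e-12:
                count += 1
        p_perm = count / n_perm
        assert p_tukey == pytest.approx(p_perm, abs=0.08)
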