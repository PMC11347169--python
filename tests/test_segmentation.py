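import numpy as np
import pytest

from flowstretch.calibration import GEOMETRIES
from flowstretch.errors import DegenerateDataError, ValidationError
from flowstretch.segmentation import (
    NoiseProfile,
    characterize_noise,
    compute_threshold_rate,
    detect_pauses,
    segment_trace,
    smooth_fft,
    trace_statistics,
    two_pass_segment,
)
from flowstretch.simulate import (
    PRESETS,
    per_trace_seed,
    render_plan,
    simulate_baseline,
    simulate_trace,
)
from conftest import make_plan


class TestSmoothFFT:
    def test_constant_unchanged(self, leading_geom):
        tr = simulate_baseline(0.0, 100.0, seed=0)
        sm = smooth_fft(tr, 0.2)
        np.testing.assert_allclose(sm.position_bp, tr.position_bp, atol=1e-9)

    def test_high_frequency_attenuated(self):
        tr = simulate_baseline(0.0, 200.0, seed=0)
        tr.position_bp = 100.0 * np.sin(2 * np.pi * 0.8 * tr.time_s)
        sm = smooth_fft(tr, 0.2)
        assert np.max(np.abs(sm.position_bp)) < 10.0  # >= 10x attenuation

    def test_dc_offset_preserved(self):
        tr = simulate_baseline(50.0, 100.0, seed=1)
        tr.position_bp = tr.position_bp + 500.0
        sm = smooth_fft(tr, 0.2)
        assert np.mean(sm.position_bp) == pytest.approx(np.mean(tr.position_bp))

    def test_cutoff_at_or_above_nyquist_rejected(self):
        tr = simulate_baseline(10.0, 50.0, seed=2)
        with pytest.raises(ValidationError):
            smooth_fft(tr, 1.0)


class TestCharacterizeNoise:
    def test_resolution_floor_for_sub200_noise(self):
        baselines = [simulate_baseline(150.0, 300.0, seed=i) for i in range(5)]
        prof = characterize_noise(baselines)
        assert prof.resolution_bp == 200.0
        assert prof.noise_sd_bp == pytest.approx(150.0, rel=0.15)

    def test_constant_baseline(self):
        prof = characterize_noise([simulate_baseline(0.0, 120.0, seed=0)])
        assert prof.noise_sd_bp == 0.0
        assert prof.resolution_bp == 200.0

    def test_rounding_rule_above_floor(self):
        baselines = [simulate_baseline(195.0, 600.0, seed=i) for i in range(3)]
        # scale up to an SD of ~240 to exercise the rounding branch
        for b in baselines:
            b.position_bp = b.position_bp * (240.0 / 195.0)
        prof = characterize_noise(baselines)
        assert prof.resolution_bp in (300.0, 400.0)
        assert prof.resolution_bp == np.ceil(prof.noise_sd_bp / 100) * 100

    def test_short_or_empty_inputs(self):
        with pytest.raises(ValidationError):
            characterize_noise([])
        with pytest.raises(ValidationError):
            characterize_noise([simulate_baseline(100.0, 30.0, seed=0)])


class TestThresholdRule:
    @pytest.mark.parametrize(
        "mean,expected", [(1.1, 0.1), (5.3, 0.5), (240.0, 20.0), (4.6, 0.5)]
    )
    def test_one_tenth_rounded_to_one_sig_fig(self, mean, expected):
        assert compute_threshold_rate(mean) == pytest.approx(expected)

    def test_non_positive_rejected(self):
        with pytest.raises(ValidationError):
            compute_threshold_rate(0.0)


class TestDetectPauses:
    def test_flat_run_between_ramps(self, rng):
        ramp = np.arange(30) * 100.0
        flat = np.full(10, 3000.0) + rng.normal(0, 5, 10)
        y = np.concatenate([ramp, flat, 3100.0 + np.arange(30) * 100.0])
        pauses = detect_pauses(y, noise_sd_bp=10.0)
        assert len(pauses) == 1
        t0, t1 = pauses[0]
        assert t1 - t0 == pytest.approx(5.0, abs=1.0)

    def test_five_samples_is_not_a_pause(self, rng):
        ramp = np.arange(30) * 100.0
        flat = np.full(5, 3000.0)
        y = np.concatenate([ramp, flat, 3100.0 + np.arange(30) * 100.0])
        assert detect_pauses(y, noise_sd_bp=10.0) == []

    def test_entire_flat_trace_is_one_run(self, rng):
        y = rng.normal(0, 10.0, 200)
        pauses = detect_pauses(y, noise_sd_bp=10.0)
        assert len(pauses) == 1
        assert pauses[0][1] - pauses[0][0] > 80.0


class TestSegmentTrace:
    def test_noise_free_reproduces_truth(self, noise_free_trace, sv40_profile,
                                         leading_geom):
        segs = segment_trace(noise_free_trace.trace, sv40_profile, 0.5, leading_geom)
        kinds = [s.kind for s in segs]
        assert kinds == ["baseline", "event", "pause", "event", "baseline"]
        for seg, iv in zip(segs, noise_free_trace.truth):
            assert seg.t_start_s == pytest.approx(iv.t_start_s, abs=0.51)
            assert seg.t_end_s == pytest.approx(iv.t_end_s, abs=0.51)
        ev = [s for s in segs if s.kind == "event"]
        assert ev[0].delta_bp == pytest.approx(400.0, abs=5)
        assert ev[1].delta_bp == pytest.approx(300.0, abs=5)
        assert ev[0].rate_bp_s == pytest.approx(5.0, rel=0.02)

    def test_sub_resolution_event_is_baseline(self, sv40_profile, leading_geom):
        plan = make_plan(
            ("baseline", 60.0, 0.0), ("event", 30.0, 5.0), ("baseline", 60.0, 0.0)
        )  # 150 bp < 200 bp resolution
        sim = render_plan(plan, leading_geom, 0.0, 0)
        segs = segment_trace(sim.trace, sv40_profile, 0.5, leading_geom)
        assert all(s.kind != "event" for s in segs)

    def test_segments_tile_trace_exactly(self, sv40_ensemble, sv40_profile,
                                         leading_geom):
        for sim in sv40_ensemble[:20]:
            segs = segment_trace(sim.trace, sv40_profile, 0.5, leading_geom)
            assert segs[0].t_start_s == 0.0
            for a, b in zip(segs[:-1], segs[1:]):
                assert b.t_start_s == pytest.approx(a.t_end_s)
            total = sum(s.duration_s for s in segs)
            assert total == pytest.approx(sim.trace.n_samples / 2.0)

    def test_event_recall_and_pause_accuracy_at_preset_noise(
        self, sv40_ensemble, sv40_profile, leading_geom
    ):
        hits = misses = 0
        pause_errs = []
        for sim in sv40_ensemble:
            segs = segment_trace(sim.trace, sv40_profile, 0.5, leading_geom)
            det = [s for s in segs if s.kind == "event"]
            for iv in sim.truth:
                if iv.kind == "event" and iv.delta_bp >= 200.0:
                    matched = any(
                        min(s.t_end_s, iv.t_end_s) - max(s.t_start_s, iv.t_start_s)
                        > 0.5 * iv.duration_s
                        for s in det
                    )
                    hits += matched
                    misses += not matched
                if iv.kind == "pause":
                    mid = 0.5 * (iv.t_start_s + iv.t_end_s)
                    for s in segs:
                        if s.kind == "pause" and s.t_start_s <= mid <= s.t_end_s:
                            pause_errs.append(
                                abs(s.duration_s - iv.duration_s) / iv.duration_s
                            )
                            break
        assert hits / (hits + misses) >= 0.9
        assert np.median(pause_errs) <= 0.10

    def test_reanneal_labelled_on_shortening_substrate(self):
        geom = GEOMETRIES["unwinding_shortening"]
        plan = make_plan(
            ("baseline", 60.0, 0.0),
            ("event", 300.0, 1.1),
            ("reanneal", 66.0, -5.0),
            ("baseline", 60.0, 0.0),
        )
        sim = render_plan(plan, geom, 0.0, 0)
        segs = segment_trace(sim.trace, NoiseProfile(0.0, 200.0), 0.1, geom)
        assert [s.kind for s in segs].count("reanneal") == 1
        re = next(s for s in segs if s.kind == "reanneal")
        assert re.delta_bp < -200

    def test_short_trace_rejected(self, sv40_profile, leading_geom):
        sim = simulate_trace(PRESETS["sv40_ssb"], 0)
        sim.trace.time_s = sim.trace.time_s[:4]
        sim.trace.position_bp = sim.trace.position_bp[:4]
        with pytest.raises(ValidationError):
            segment_trace(sim.trace, sv40_profile, 0.5, leading_geom)


class TestTwoPass:
    def test_sv40_threshold_is_half_bp_per_s(self, sv40_ensemble, sv40_profile,
                                             leading_geom):
        traces = [s.trace for s in sv40_ensemble]
        result = two_pass_segment(traces, sv40_profile, leading_geom)
        assert result.threshold_bp_s == pytest.approx(0.5)

    def test_threshold_is_a_fixed_point(self, sv40_ensemble, sv40_profile,
                                        leading_geom):
        from flowstretch.kinetics import fit_rate_gaussian

        traces = [s.trace for s in sv40_ensemble]
        result = two_pass_segment(traces, sv40_profile, leading_geom)
        rates = [
            s.rate_bp_s
            for segs in result.segments_by_trace
            for s in segs
            if s.kind == "event"
        ]
        again = compute_threshold_rate(fit_rate_gaussian(rates).mean)
        assert again == result.threshold_bp_s

    def test_pure_baselines_raise(self, sv40_profile, leading_geom):
        traces = [simulate_baseline(150.0, 200.0, seed=i) for i in range(10)]
        with pytest.raises(DegenerateDataError):
            two_pass_segment(traces, sv40_profile, leading_geom)


class TestTraceStatistics:
    def test_single_event_single_equals_multi(self, leading_geom):
        plan = make_plan(
            ("baseline", 60.0, 0.0), ("event", 80.0, 5.0), ("baseline", 60.0, 0.0)
        )
        sim = render_plan(plan, leading_geom, 0.0, 0)
        segs = segment_trace(sim.trace, NoiseProfile(0.0, 200.0), 0.5, leading_geom)
        st = trace_statistics(segs)
        assert st.n_events == 1
        assert not st.restarted
        assert st.single_steps[0].processivity_bp == pytest.approx(400.0, abs=5)
        assert st.multi_step_processivity_bp == pytest.approx(
            st.single_steps[0].processivity_bp, abs=2
        )
        assert st.multi_step_lifetime_s == pytest.approx(
            st.single_steps[0].lifetime_s, abs=1
        )

    def test_pause_included_in_multi_step_lifetime(self, noise_free_trace,
                                                   leading_geom):
        segs = segment_trace(
            noise_free_trace.trace, NoiseProfile(0.0, 200.0), 0.5, leading_geom
        )
        st = trace_statistics(segs)
        assert st.n_events == 2
        assert st.restarted
        # events 400 + 300 bp with a 100 s interior pause
        assert st.multi_step_processivity_bp == pytest.approx(700.0, abs=10)
        assert st.multi_step_lifetime_s == pytest.approx(240.0, abs=1.5)
        assert len(st.restart_pauses_s) == st.n_events - 1
        assert st.restart_pauses_s[0] == pytest.approx(100.0, abs=1.5)

    def test_pause_only_trace_has_empty_stats(self, sv40_profile, leading_geom):
        tr = simulate_baseline(150.0, 200.0, seed=4)
        segs = segment_trace(tr, sv40_profile, 0.5, leading_geom)
        st = trace_statistics(segs)
        assert st.n_events == 0
        assert not st.restarted
        assert st.restart_pauses_s == []

    def test_multi_at_least_max_single_up_to_noise(
        self, sv40_ensemble, sv40_profile, leading_geom
    ):
        for sim in sv40_ensemble[:30]:
            st = trace_statistics(
                segment_trace(sim.trace, sv40_profile, 0.5, leading_geom)
            )
            if st.n_events:
                biggest = max(s.processivity_bp for s in st.single_steps)
                assert st.multi_step_processivity_bp >= biggest - 3 * 150.0
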