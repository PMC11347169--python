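import numpy as np
import pytest

from flowstretch.calibration import GEOMETRIES
from flowstretch.errors import ValidationError
from flowstretch.simulate import (
    PRESETS,
    KineticPreset,
    RateModel,
    draw_plan,
    render_plan,
    simulate_baseline,
    simulate_ensemble,
    simulate_mst,
    simulate_trace,
)
from conftest import make_plan


class TestTraceGeneration:
    def test_noise_free_single_event_is_piecewise_linear(self, leading_geom):
        plan = make_plan(("event", 80.0, 5.0))
        sim = render_plan(plan, leading_geom, 0.0, 0)
        y = leading_geom.direction_sign * sim.trace.position_bp
        slopes = np.diff(y) / np.diff(sim.trace.time_s)
        assert np.allclose(slopes, 5.0, atol=1e-9)

    def test_seeded_reproducibility_is_bitwise(self):
        a = simulate_trace(PRESETS["sv40_ssb"], 99)
        b = simulate_trace(PRESETS["sv40_ssb"], 99)
        np.testing.assert_array_equal(a.trace.position_bp, b.trace.position_bp)
        assert [iv.delta_bp for iv in a.truth] == [iv.delta_bp for iv in b.truth]

    def test_sampling_interval_exact(self):
        sim = simulate_trace(PRESETS["pol_delta_pe"], 3)
        assert np.allclose(np.diff(sim.trace.time_s), 0.5, atol=1e-12)

    def test_truth_tiles_trace(self):
        for seed in range(10):
            sim = simulate_trace(PRESETS["sv40_ssb"], seed)
            truth = sim.truth
            assert truth[0].t_start_s == 0.0
            for a, b in zip(truth[:-1], truth[1:]):
                assert b.t_start_s == pytest.approx(a.t_end_s)
            duration = (sim.trace.n_samples - 1) / sim.trace.acquisition_hz
            assert truth[-1].t_end_s == pytest.approx(duration)

    def test_cumulative_activity_bounded_by_template(self):
        preset = PRESETS["sv40_ssb"]
        for seed in range(20):
            sim = simulate_trace(preset, seed)
            total = sum(iv.delta_bp for iv in sim.truth if iv.kind == "event")
            assert total <= preset.template + 1e-9

    def test_generative_law_of_large_numbers(self):
        # per-event lengths ~ Exp(0.3 kb); restart fraction ~ p_restart
        rng = np.random.default_rng(7)
        preset = PRESETS["sv40_ssb"]
        lengths, restarts = [], 0
        n = 1000
        for _ in range(n):
            plan = draw_plan(preset, rng)
            ev = [iv.delta_bp for iv in plan if iv.kind == "event"]
            lengths += ev
            restarts += len(ev) >= 2
        mean = np.mean(lengths)
        se = np.std(lengths) / np.sqrt(len(lengths))
        assert abs(mean - preset.proc_mean_bp) < 3 * se + 5
        frac = restarts / n
        assert abs(frac - preset.p_restart) < 3 * np.sqrt(0.4 * 0.6 / n)

    def test_multi_step_identity(self):
        # total activity mean = proc_mean / (1 - p_restart)
        rng = np.random.default_rng(11)
        preset = PRESETS["sv40_ssb"]
        totals = [
            sum(iv.delta_bp for iv in draw_plan(preset, rng) if iv.kind == "event")
            for _ in range(2000)
        ]
        expected = preset.multi_step_mean_bp
        se = np.std(totals) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - expected) < 3 * se

    def test_reanneal_returns_to_baseline(self):
        sim = simulate_trace(PRESETS["ltag_alone"], 5)
        kinds = [iv.kind for iv in sim.truth]
        if "reanneal" in kinds:
            net = sum(iv.delta_bp for iv in sim.truth)
            assert net == pytest.approx(0.0, abs=1e-6)


class TestEnsemble:
    def test_ensemble_shape_and_reproducibility(self):
        a = simulate_ensemble(PRESETS["pol_delta_pe"], 12, seed=5)
        b = simulate_ensemble(PRESETS["pol_delta_pe"], 12, seed=5)
        assert len(a) == 12
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.trace.position_bp, s2.trace.position_bp)
        # element-wise distinct traces
        assert not np.array_equal(a[0].trace.position_bp[:50],
                                  a[1].trace.position_bp[:50])

    def test_zero_traces_rejected(self):
        with pytest.raises(ValidationError):
            simulate_ensemble(PRESETS["pol_delta_pe"], 0, seed=1)

    def test_truth_rate_mean_matches_preset(self):
        sims = simulate_ensemble(PRESETS["pol_delta_pe"], 151, seed=3)
        rates = [iv.rate_bp_s for s in sims for iv in s.truth if iv.kind == "event"]
        se = np.std(rates) / np.sqrt(len(rates))
        assert abs(np.mean(rates) - 240.0) < 4 * se


class TestBaseline:
    def test_sd_recovered(self):
        tr = simulate_baseline(150.0, 500.0, seed=2)
        assert np.std(tr.position_bp) == pytest.approx(150.0, rel=0.10)

    def test_zero_noise_constant(self):
        tr = simulate_baseline(0.0, 100.0, seed=2)
        assert np.ptp(tr.position_bp) == 0.0

    def test_independent_seeds_uncorrelated(self):
        a = simulate_baseline(150.0, 500.0, seed=10)
        b = simulate_baseline(150.0, 500.0, seed=11)
        r = np.corrcoef(a.position_bp, b.position_bp)[0, 1]
        assert abs(r) < 0.2

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            simulate_baseline(150.0, 2.0, seed=0)


class TestPresetValidation:
    def test_invalid_fields_name_the_field(self):
        with pytest.raises(ValidationError, match="p_restart"):
            KineticPreset("x", RateModel("normal", 5, 1), 300, p_restart=1.5)
        with pytest.raises(ValidationError, match="proc_mean_bp"):
            KineticPreset("x", RateModel("normal", 5, 1), -1)
        with pytest.raises(ValidationError, match="noise_sd_bp"):
            KineticPreset("x", RateModel("normal", 5, 1), 300, noise_sd_bp=250)
        with pytest.raises(ValidationError, match="pause_mean_s"):
            KineticPreset("x", RateModel("normal", 5, 1), 300,
                          p_restart=0.3, pause_mean_s=1.0)

    def test_default_presets_valid_and_consistent(self):
        assert PRESETS["ltag_rpa"].multi_step_mean_bp == pytest.approx(800.0)
        assert PRESETS["sv40_ssb"].multi_step_mean_bp == pytest.approx(500.0)
        assert PRESETS["sv40_fpc_mcm10"].multi_step_mean_bp == pytest.approx(1100.0)
        # heavy-tailed FPC rate model: arithmetic mean far above the peak
        fpc = PRESETS["sv40_fpc"].rate_model
        assert fpc.arithmetic_mean == pytest.approx(23.0, rel=0.01)
        assert fpc.mean_bp_s == pytest.approx(3.8)


class TestMSTSimulation:
    def test_monotone_fraction_bound(self):
        curve = simulate_mst(6.7)
        assert np.all(np.diff(curve.titrant_nM) < 0)
        assert np.all(np.diff(curve.signal) < 0)  # noise-free, decreasing titrant

    def test_huge_kd_means_unbound(self):
        curve = simulate_mst(1e9)
        assert np.all(curve.signal < 0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            simulate_mst(6.7, n_points=3)
        with pytest.raises(ValidationError):
            simulate_mst(6.7, dilution_factor=1.0)
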