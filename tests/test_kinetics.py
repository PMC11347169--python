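import numpy as np
import pytest

from flowstretch.errors import DegenerateDataError, FitError, ValidationError
from flowstretch.kinetics import (
    arithmetic_rate,
    compare_conditions,
    fit_exponential,
    fit_rate_gaussian,
    summarize_condition,
)
from flowstretch.segmentation import SingleStep, TraceStats


def make_stats(rng, n_traces, proc_mean, rate_mean, p_restart, pause_mean=182.0):
    """Synthetic per-trace statistics drawn from the generative model."""
    out = []
    for _ in range(n_traces):
        k = 1 + rng.geometric(1.0 - p_restart) - 1 if p_restart else 1
        steps = []
        for _ in range(max(k, 1)):
            proc = rng.exponential(proc_mean)
            rate = max(rng.normal(rate_mean, 0.3 * rate_mean), 0.1)
            steps.append(SingleStep(proc, proc / rate, rate))
        pauses = list(3.0 + rng.exponential(pause_mean - 3.0, size=len(steps) - 1))
        out.append(
            TraceStats(
                single_steps=steps,
                multi_step_processivity_bp=sum(s.processivity_bp for s in steps),
                multi_step_lifetime_s=sum(s.lifetime_s for s in steps) + sum(pauses),
                restart_pauses_s=pauses,
                n_events=len(steps),
                restarted=len(steps) >= 2,
            )
        )
    return out


class TestGaussianFit:
    def test_recovers_primer_extension_rate_distribution(self, rng):
        rates = rng.normal(240.0, 72.0, 151)
        fit = fit_rate_gaussian(rates)
        assert fit.mean == pytest.approx(240.0, rel=0.10)
        assert fit.sem > 0

    def test_symmetric_peaked_set_equals_arithmetic_mean(self):
        # noise-free, symmetric about 5: the fitted mean is the sample mean
        half = np.exp(np.linspace(0, 1.2, 400)) - 1.0
        rates = np.concatenate([5.0 - half, 5.0 + half])
        fit = fit_rate_gaussian(rates)
        assert np.mean(rates) == pytest.approx(5.0)
        assert fit.mean == pytest.approx(5.0, abs=0.1)

    def test_errors(self):
        with pytest.raises(ValidationError):
            fit_rate_gaussian([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateDataError):
            fit_rate_gaussian(np.full(20, 5.0))


class TestExponentialFit:
    def test_recovers_processivity_with_first_bin_exclusion(self, rng):
        values = rng.exponential(400.0, 151)
        fit = fit_exponential(values, cutoff=200.0, bin_width=200.0)
        assert fit.mean == pytest.approx(400.0, rel=0.15)
        assert all(c < 200.0 for c in fit.excluded_bins)

    def test_memorylessness_truncated_mle(self, rng):
        # mean(x - c | x >= c) = mu for any cutoff of an exponential
        values = rng.exponential(400.0, 20000)
        for cutoff in (0.0, 200.0, 600.0):
            tail = values[values >= cutoff]
            assert np.mean(tail) - cutoff == pytest.approx(400.0, rel=0.05)

    def test_lsq_and_mle_agree_at_large_n(self, rng):
        values = rng.exponential(500.0, 400)
        fit = fit_exponential(values, cutoff=200.0, bin_width=200.0)
        assert fit.lsq_mean == pytest.approx(fit.mle_mean, rel=0.15)

    def test_errors(self, rng):
        with pytest.raises(ValidationError):
            fit_exponential([1.0] * 5, cutoff=0.0)
        with pytest.raises(FitError):
            fit_exponential(rng.uniform(0, 100, 50), cutoff=5000.0)


class TestArithmeticRate:
    def test_hand_computed(self):
        mean, se = arithmetic_rate([2.0, 4.0, 6.0])
        assert mean == pytest.approx(4.0)
        assert se == pytest.approx(2.0 / np.sqrt(3))

    def test_heavy_tail_exceeds_gaussian_peak(self, rng):
        # mixture mirroring the FPC rate distribution: narrow peak + tail
        peak = rng.normal(3.8, 1.0, 85)
        tail = 3.8 + rng.exponential(64.0, 36)
        rates = np.concatenate([peak, tail])
        amean, _ = arithmetic_rate(rates)
        gfit = fit_rate_gaussian(rates, bin_width=1.0)
        assert amean > 3.0 * gfit.mean

    def test_single_value_rejected(self):
        with pytest.raises(ValidationError):
            arithmetic_rate([5.0])


class TestSummarize:
    def test_recovers_sv40_statistics(self, rng):
        stats = make_stats(rng, 150, proc_mean=300.0, rate_mean=5.3, p_restart=0.4)
        summary = summarize_condition(stats, "sv40")
        assert summary.gaussian_rate.mean == pytest.approx(5.3, rel=0.15)
        assert summary.multi_processivity.mean == pytest.approx(500.0, rel=0.2)
        assert summary.restart_fraction == pytest.approx(0.4, abs=0.12)
        assert summary.restart_pause.mean == pytest.approx(179.0, rel=0.25)

    def test_single_event_traces_have_single_equals_multi(self, rng):
        stats = make_stats(rng, 120, proc_mean=400.0, rate_mean=240.0, p_restart=0.0)
        summary = summarize_condition(stats, "pe")
        assert summary.single_processivity.mean == pytest.approx(
            summary.multi_processivity.mean, rel=0.05
        )

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValidationError):
            summarize_condition([TraceStats()], "empty")


class TestCompare:
    def test_fold_change_of_multi_step(self, rng):
        base = summarize_condition(
            make_stats(rng, 200, 300.0, 5.3, 0.4), "sv40"
        )
        boosted = summarize_condition(
            make_stats(rng, 200, 550.0, 3.8, 0.5), "sv40_fpc_mcm10"
        )
        table = compare_conditions([base, boosted], reference="sv40")
        fold = table.loc["sv40_fpc_mcm10", "multi_proc_bp_fold"]
        assert fold == pytest.approx(2.2, rel=0.25)

    def test_self_comparison_is_unity(self, rng):
        s = summarize_condition(make_stats(rng, 100, 300.0, 5.3, 0.4), "a")
        table = compare_conditions([s], reference="a")
        for col in table.columns:
            if col.endswith("_fold"):
                assert table.loc["a", col] == pytest.approx(1.0)

    def test_missing_reference_and_empty(self, rng):
        s = summarize_condition(make_stats(rng, 50, 300.0, 5.3, 0.4), "a")
        with pytest.raises(ValidationError):
            compare_conditions([s], reference="b")
        with pytest.raises(ValidationError):
            compare_conditions([], reference="a")
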