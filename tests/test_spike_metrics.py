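"""Spike detection, binning, percent inhibition and desensitization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from receptorquant.errors import EpochError, ZeroBaselineError
from receptorquant.spike_metrics import (
    FiringAnalyzer,
    SpikeExperiment,
    bin_rates,
    detect_spikes,
    percent_desensitization,
    percent_inhibition,
)
from receptorquant.synthetic import (
    firing_params_from_targets,
    make_spike_experiment,
    render_trace,
)


class TestDetectSpikes:
    def test_injected_spikes_recovered_exactly(self):
        """20 spikes at 8x the noise SD are all found at a 4-SD threshold,
        each within one sample of its injected time.  The trace is kept
        short enough that the Gaussian tail bound predicts well under one
        false threshold crossing."""
        times = np.round(np.linspace(0.02, 0.48, 20), 4)
        exp = SpikeExperiment(
            spike_times=times, agonist_onset_s=0.49, agonist_end_s=0.5
        )
        trace = render_trace(
            exp, duration_s=0.5, noise_sd=1.0, spike_amplitude_sd_units=8.0, rng_seed=0
        )
        detected = detect_spikes(
            trace, 10_000.0, threshold_sd=4.0, polarity="negative"
        )
        assert detected.size == 20
        assert np.abs(detected - times).max() <= 1.01 / 10_000.0

    def test_pure_noise_at_8sd_threshold_detects_nothing(self, rng):
        """P(|z| > 8) ~ 1e-15 per sample: 10 s of 10-kHz noise crosses an
        8-SD threshold with probability ~1e-10."""
        trace = rng.normal(0.0, 1.0, 100_000)
        assert detect_spikes(trace, 10_000.0, threshold_sd=8.0).size == 0

    def test_flat_trace_returns_empty_with_warning(self):
        with pytest.warns(UserWarning, match="flat trace"):
            out = detect_spikes(np.zeros(1000), 10_000.0)
        assert out.size == 0

    def test_refractory_suppresses_close_events(self, rng):
        trace = rng.normal(0.0, 1.0, 10_000)
        trace[5000] = -30.0
        trace[5005] = -25.0  # 0.5 ms later: inside the 2-ms refractory
        detected = detect_spikes(trace, 10_000.0, threshold_sd=5.0, smooth_ms=0.0)
        assert np.sum((detected > 0.49) & (detected < 0.51)) == 1


class TestBinRates:
    def test_simple_assignment(self):
        counts, edges = bin_rates(np.array([1.0, 16.0, 31.0]), 15.0, t_end=45.0)
        np.testing.assert_array_equal(counts, [1, 1, 1])
        assert edges[0] == 0.0 and edges[-1] == 45.0

    def test_spike_on_edge_falls_in_later_bin(self):
        counts, _ = bin_rates(np.array([15.0]), 15.0, t_end=30.0)
        np.testing.assert_array_equal(counts, [0, 1])

    def test_counts_conserved(self, rng):
        t = np.sort(rng.uniform(0, 300, 450))
        counts, _ = bin_rates(t, 15.0, t_end=300.0)
        assert counts.sum() == t.size

    def test_poisson_process_mean_count_matches_expectation(self):
        """Homogeneous 1.5-Hz firing for 300 s: 22.5 expected per 15-s bin."""
        means = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = rng.poisson(1.5 * 300)
            t = np.sort(rng.uniform(0, 300, n))
            counts, _ = bin_rates(t, 15.0, t_end=300.0)
            means.append(counts.mean())
        # SE of the grand mean ~ sqrt(22.5/2000) ~ 0.1
        assert np.mean(means) == pytest.approx(22.5, abs=0.5)


def _experiment(baseline_rate=2.0, early_rate=1.0, late_rate=None, seed=0):
    """Deterministic regular-firing experiment with programmed epoch rates."""
    parts = [np.arange(0.0, 120.0, 1.0 / baseline_rate)]
    if early_rate > 0:
        parts.append(120.0 + np.arange(60.0, 120.0, 1.0 / early_rate))
    if late_rate:
        parts.append(120.0 + np.arange(270.0, 300.0, 1.0 / late_rate))
    times = np.unique(np.concatenate(parts))
    return SpikeExperiment(
        spike_times=times, agonist_onset_s=120.0, agonist_end_s=420.0
    )


class TestPercentInhibition:
    def test_complete_suppression_is_100(self):
        exp = _experiment(baseline_rate=1.5, early_rate=0.0)
        assert percent_inhibition(exp) == 100.0

    def test_half_suppression_is_50(self):
        exp = _experiment(baseline_rate=2.0, early_rate=1.0)
        assert percent_inhibition(exp) == pytest.approx(50.0)

    def test_zero_baseline_excluded(self):
        exp = SpikeExperiment(
            spike_times=np.array([125.0, 126.0]),
            agonist_onset_s=120.0,
            agonist_end_s=420.0,
        )
        with pytest.raises(ZeroBaselineError):
            percent_inhibition(exp)

    def test_short_baseline_rejected(self):
        exp = SpikeExperiment(
            spike_times=np.arange(0.0, 30.0, 0.5),
            agonist_onset_s=30.0,
            agonist_end_s=330.0,
        )
        with pytest.raises(EpochError, match="baseline"):
            percent_inhibition(exp)

    def test_rebound_clamps_to_zero_and_flags(self):
        exp = _experiment(baseline_rate=1.0, early_rate=3.0)
        res = FiringAnalyzer().analyze(exp)
        assert res.percent_inhibition == 0.0
        assert res.rebound

    def test_invariant_under_common_time_rescaling(self):
        exp = _experiment(baseline_rate=2.0, early_rate=1.0)
        c = 2.0
        scaled = SpikeExperiment(
            spike_times=exp.spike_times * c,
            agonist_onset_s=exp.agonist_onset_s * c,
            agonist_end_s=exp.agonist_end_s * c,
        )
        analyzer = FiringAnalyzer(
            early_window_s=(60.0 * c, 120.0 * c), min_baseline_s=60.0 * c
        )
        assert analyzer.percent_inhibition(scaled) == pytest.approx(
            percent_inhibition(exp)
        )

    def test_programmed_80pct_drop_recovered_over_seeds(self):
        """Inhomogeneous Poisson with a programmed 80% rate drop: the mean
        estimate over 200 seeds is within 2 points of truth."""
        estimates = []
        for seed in range(200):
            params = firing_params_from_targets(80.0, 0.0, rng_seed=seed)
            exp, truth = make_spike_experiment(params)
            estimates.append(percent_inhibition(exp))
        assert truth.percent_inhibition == pytest.approx(80.0)
        assert np.mean(estimates) == pytest.approx(80.0, abs=2.0)


class TestPercentDesensitization:
    def test_no_recovery_means_zero(self):
        exp = _experiment(baseline_rate=2.0, early_rate=0.0, late_rate=None)
        assert percent_desensitization(exp) == 0.0

    def test_full_recovery_equals_early_inhibition(self):
        exp = _experiment(baseline_rate=2.0, early_rate=0.0, late_rate=2.0)
        assert percent_desensitization(exp) == pytest.approx(
            percent_inhibition(exp), abs=1e-9
        )

    def test_partial_recovery_worked_example(self):
        # early 100% inhibition, late rate at 80% of baseline -> 80 points
        exp = _experiment(baseline_rate=2.0, early_rate=0.0, late_rate=1.6)
        assert percent_desensitization(exp) == pytest.approx(80.0)

    def test_agonist_epoch_shorter_than_5min_rejected(self):
        times = np.concatenate(
            [np.arange(0.0, 120.0, 0.5), 120.0 + np.arange(60.0, 120.0, 1.0)]
        )
        exp = SpikeExperiment(
            spike_times=times, agonist_onset_s=120.0, agonist_end_s=120.0 + 200.0
        )
        with pytest.raises(EpochError, match="too short"):
            percent_desensitization(exp)

    def test_exponential_recovery_matches_analytic_rate_integral(self):
        """Full suppression then exponential recovery (tau = 90 s): the
        desensitization estimate over many seeds matches the closed-form
        window-averaged rate integral."""
        params0 = firing_params_from_targets(
            100.0, 80.0, desens_tau_s=90.0, rng_seed=0
        )
        truth = make_spike_experiment(params0)[1]
        estimates = []
        for seed in range(100):
            params = firing_params_from_targets(
                100.0, 80.0, desens_tau_s=90.0, rng_seed=seed
            )
            exp, _ = make_spike_experiment(params)
            estimates.append(percent_desensitization(exp))
        assert np.mean(estimates) == pytest.approx(
            truth.percent_desensitization, abs=3.0
        )

    def test_normalized_variant_rescales_by_maximal_inhibition(self):
        exp = _experiment(baseline_rate=2.0, early_rate=1.0, late_rate=1.8)
        raw = percent_desensitization(exp)
        norm = percent_desensitization(exp, normalize_desensitization=True)
        early = percent_inhibition(exp)
        assert norm == pytest.approx(100.0 * raw / early)


class TestGridRecovery:
    def test_pipeline_recovers_programmed_grid(self):
        """3x3 grid of programmed (inhibition, desensitization): per-cell
        mean estimates over ~22 seeds each (200 runs total) recover the
        analytic truth with MAE < 5 points."""
        analyzer = FiringAnalyzer()
        errors = []
        for inh in (50.0, 80.0, 100.0):
            for des in (0.0, 40.0, 80.0):
                est_i, est_d = [], []
                truth = None
                for k in range(22):
                    seed = int(1000 * inh + 10 * des + k)
                    params = firing_params_from_targets(inh, des, rng_seed=seed)
                    exp, truth = make_spike_experiment(params)
                    est_i.append(analyzer.percent_inhibition(exp))
                    est_d.append(analyzer.percent_desensitization(exp))
                errors.append(abs(np.mean(est_i) - truth.percent_inhibition))
                errors.append(abs(np.mean(est_d) - truth.percent_desensitization))
        assert np.mean(errors) < 5.0


@given(st.integers(0, 10_000))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_binned_counts_always_conserve_spikes(seed):
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, 100, rng.integers(0, 200)))
    t = np.unique(t)
    counts, edges = bin_rates(t, rng.uniform(1, 30), t_end=100.0)
    assert counts.sum() == t.size
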