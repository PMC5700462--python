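"""Trace idealization: mixture model selection, HMM decoding, dwell recovery."""

import warnings

import numpy as np
import pytest

from smfet import (
    KineticModel,
    fit_amplitude_histogram,
    idealize_trace,
    render_trace,
    simulate_control_trace,
    simulate_state_path,
)
from smfet.idealization import InsufficientDataError, NoDynamicsError
from smfet.models import Trace
from conftest import per_sample_labels


def decoded_labels(path, dt, n):
    lab = per_sample_labels(path, dt, clamp=False)
    return lab[:n]


class TestModelSelection:
    def test_three_level_trace_selects_k3(self, wtc_rendered):
        _, trace = wtc_rendered
        fit = fit_amplitude_histogram(trace)
        assert fit.k == 3
        assert list(fit.labels) == ["low", "intermediate", "high"]

    def test_two_level_control_selects_k2(self):
        trace = simulate_control_trace("two_level", seed=31, duration_ms=600.0)
        assert fit_amplitude_histogram(trace).k == 2

    def test_pure_noise_selects_k1(self):
        rng = np.random.default_rng(32)
        trace = Trace(dt=1 / 28.8, values=rng.normal(0.0, 0.5, 20_000))
        assert fit_amplitude_histogram(trace).k == 1

    def test_selection_degrades_with_noise(self, wtc_model):
        """Once noise exceeds half the level spacing, fewer peaks are resolved."""
        path = simulate_state_path(wtc_model, 200, seed=33)
        for noise, expect_full in [(0.5, True), (3.0, False)]:
            model = KineticModel(
                states=wtc_model.states, levels=wtc_model.levels,
                P=wtc_model.P, tau=wtc_model.tau, noise_sd=noise,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                trace = render_trace(path, model, seed=34)
            k = fit_amplitude_histogram(trace).k
            assert (k == 3) if expect_full else (k < 3)

    def test_baseline_recentering_and_signs(self, wtc_rendered):
        """Middle (hairpin) component sits at 0; low is negative, high positive."""
        _, trace = wtc_rendered
        fit = fit_amplitude_histogram(trace)
        assert fit.means[fit.baseline_index] == 0.0
        assert fit.means[0] < 0 < fit.means[2]
        assert np.all(np.diff(fit.means) > 0)
        assert fit.weights.sum() == pytest.approx(1.0)

    def test_short_trace_rejected(self):
        trace = Trace(dt=1 / 28.8, values=np.zeros(50))
        with pytest.raises(InsufficientDataError):
            fit_amplitude_histogram(trace)


class TestIdealization:
    def test_noiseless_roundtrip_is_exact(self, wtc_model):
        model = KineticModel(
            states=wtc_model.states, levels=wtc_model.levels,
            P=wtc_model.P, tau=wtc_model.tau, noise_sd=0.0,
        )
        path = simulate_state_path(model, 150, seed=35)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            trace = render_trace(path, model, seed=36)
        fit = fit_amplitude_histogram(trace)
        recovered = idealize_trace(trace, fit, min_dwell_samples=1)
        assert recovered.states == list(path.states)
        # durations agree with the sampled (grid-quantized) truth to < 1 sample
        true_counts = np.diff(
            np.round(np.concatenate([[0], np.cumsum(path.durations)]) / trace.dt)
        )
        true_counts[true_counts < 1] = 1
        assert np.max(np.abs(recovered.durations / trace.dt - true_counts)) < 1

    def test_noisy_roundtrip_per_sample_accuracy(self, wtc_rendered):
        """At noise sd 0.5 nA (levels ~3 nA apart) >99% of samples are recovered."""
        path, trace = wtc_rendered
        fit = fit_amplitude_histogram(trace)
        recovered = idealize_trace(trace, fit)
        true = per_sample_labels(path, trace.dt)
        dec = decoded_labels(recovered, trace.dt, true.size)
        assert (true == dec).mean() > 0.99

    def test_noisy_roundtrip_dwell_recovery(self, wtc_rendered):
        """>= 95% of true dwells lasting >= 5 samples appear in the decoded path."""
        path, trace = wtc_rendered
        fit = fit_amplitude_histogram(trace)
        recovered = idealize_trace(trace, fit)
        true = per_sample_labels(path, trace.dt)
        dec = decoded_labels(recovered, trace.dt, true.size)
        edges = np.concatenate(
            [[0], np.flatnonzero(true[1:] != true[:-1]) + 1, [true.size]]
        )
        long_dwells = hits = 0
        for s, e in zip(edges[:-1], edges[1:]):
            if e - s >= 5:
                long_dwells += 1
                seg = dec[s:e]
                if (seg == true[s]).mean() > 0.5:
                    hits += 1
        assert long_dwells > 100
        assert hits / long_dwells >= 0.95

    def test_downstream_occupancy_is_low_dominated(self, wtc_rendered):
        """With a well-matched target the duplex (low) state dominates."""
        from smfet import occupancy

        _, trace = wtc_rendered
        fit = fit_amplitude_histogram(trace)
        occ = occupancy(idealize_trace(trace, fit))
        assert occ.percent["low"] == max(occ.percent.values())

    def test_single_level_fit_refused(self):
        trace = simulate_control_trace("blank", seed=37, duration_ms=600.0)
        fit = fit_amplitude_histogram(trace)
        assert fit.k == 1
        with pytest.raises(NoDynamicsError):
            idealize_trace(trace, fit)

    def test_min_dwell_merging(self):
        """Dwells shorter than the floor are merged into the longer neighbour."""
        from smfet.idealization import _merge_short_dwells
        from smfet.models import StatePath

        path = StatePath(
            states=["low", "high", "low", "intermediate"],
            durations=np.array([5.0, 0.02, 3.0, 4.0]),
        )
        merged = _merge_short_dwells(path, min_duration=0.07)
        assert merged.states == ["low", "intermediate"]
        assert merged.durations[0] == pytest.approx(8.02)
        assert merged.total_duration == pytest.approx(path.total_duration)
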