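"""Generator statistics: semi-Markov paths, rendered traces, controls, curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smfet import (
    KineticModel,
    ParameterError,
    fit_amplitude_histogram,
    occupancy,
    render_trace,
    simulate_control_trace,
    simulate_melting_curve,
    simulate_state_path,
    stationary_occupancy,
    validate_hairpin_stem,
)
from conftest import STATIONARY_ORACLE


class TestStatePath:
    def test_exit_destination_frequencies_match_P(self, models):
        """Empirical destination fractions converge to P within 3 binomial SE."""
        for label, model in models.items():
            path = simulate_state_path(model, 20_000, seed=11)
            states = np.asarray(path.states)
            for i, s in enumerate(model.states):
                mask = states[:-1] == s
                n = mask.sum()
                dest = states[1:][mask]
                for j, t in enumerate(model.states):
                    p = model.P[i, j]
                    if p == 0:
                        assert not np.any(dest == t)
                        continue
                    se = np.sqrt(p * (1 - p) / n)
                    assert abs((dest == t).mean() - p) < 3 * se, (label, s, t)

    def test_forced_alternation(self):
        model = KineticModel(
            states=("low", "intermediate"),
            levels=np.array([-3.0, 0.0]),
            P=np.array([[0.0, 1.0], [1.0, 0.0]]),
            tau=np.array([[0.0, 5.0], [2.0, 0.0]]),
        )
        path = simulate_state_path(model, 50, seed=0)
        assert all(a != b for a, b in zip(path.states, path.states[1:]))
        assert set(path.states) == {"low", "intermediate"}

    def test_direction_resolved_dwell_means(self, wtc_model):
        """Sample mean dwell per direction converges to tau[i][j] (<5% rel. error)."""
        path = simulate_state_path(wtc_model, 200_000, seed=12)
        states = np.asarray(path.states)
        durs = path.durations
        for i, s in enumerate(wtc_model.states):
            for j, t in enumerate(wtc_model.states):
                if wtc_model.P[i, j] == 0:
                    continue
                mask = (states[:-1] == s) & (states[1:] == t)
                assert mask.sum() >= 5_000
                rel = abs(durs[:-1][mask].mean() - wtc_model.tau[i, j]) / wtc_model.tau[i, j]
                assert rel < 0.05, (s, t, rel)

    @pytest.mark.parametrize("label", list(STATIONARY_ORACLE))
    def test_long_run_occupancy_matches_closed_form(self, models, label):
        """Time fractions at 50k exits match the frozen stationary oracle (<1 pp)."""
        model = models[label]
        occ = occupancy(simulate_state_path(model, 50_000, seed=13))
        for s, expected in zip(model.states, STATIONARY_ORACLE[label]):
            assert occ.percent[s] == pytest.approx(expected, abs=1.0)
        # and the package's closed form agrees with the independent solve
        closed = stationary_occupancy(model)
        for s, expected in zip(model.states, STATIONARY_ORACLE[label]):
            assert 100 * closed[s] == pytest.approx(expected, abs=0.01)

    def test_seed_reproducibility(self, wtc_model):
        a = simulate_state_path(wtc_model, 500, seed=42)
        b = simulate_state_path(wtc_model, 500, seed=42)
        assert a.states == b.states
        assert np.array_equal(a.durations, b.durations)

    def test_invalid_model_rejected(self):
        with pytest.raises(ParameterError):
            KineticModel(
                P=np.array([[0, 0.5, 0.4], [1, 0, 0], [0.5, 0.5, 0]]),  # row 0 sums to 0.9
                tau=np.ones((3, 3)),
            )
        model = KineticModel(
            P=np.array([[0, 0.8, 0.2], [0.5, 0, 0.5], [0.5, 0.5, 0]]),
            tau=np.ones((3, 3)),
        )
        with pytest.raises(ParameterError):
            simulate_state_path(model, 0, seed=0)

    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(1, 60))
    @settings(max_examples=25, deadline=None)
    def test_path_invariants(self, seed, n):
        """Durations positive, consecutive states distinct, exactly n sojourns."""
        model = KineticModel(
            P=np.array([[0, 0.7, 0.3], [0.4, 0, 0.6], [0.9, 0.1, 0]]),
            tau=np.array([[0, 3.0, 1.0], [2.0, 0, 4.0], [0.5, 0.7, 0]]),
        )
        path = simulate_state_path(model, n, seed=seed)
        assert len(path) == n
        assert np.all(path.durations > 0)
        assert all(a != b for a, b in zip(path.states, path.states[1:]))


class TestRenderTrace:
    def test_noiseless_value_set_is_exact(self, wtc_model):
        model = KineticModel(
            states=wtc_model.states, levels=wtc_model.levels,
            P=wtc_model.P, tau=wtc_model.tau, noise_sd=0.0,
        )
        path = simulate_state_path(model, 100, seed=5)
        trace = render_trace(path, model, seed=6)
        assert set(np.unique(trace.values)) <= set(model.levels)

    def test_noiseless_nearest_level_inversion(self, wtc_model):
        """Zero-noise rendering is exactly invertible by nearest-level assignment."""
        model = KineticModel(
            states=wtc_model.states, levels=wtc_model.levels,
            P=wtc_model.P, tau=wtc_model.tau, noise_sd=0.0,
        )
        path = simulate_state_path(model, 200, seed=7)
        trace = render_trace(path, model, seed=8)
        idx = np.argmin(np.abs(trace.values[:, None] - model.levels[None, :]), axis=1)
        labels = np.asarray(model.states, dtype=object)[idx]
        from conftest import per_sample_labels

        assert np.array_equal(labels, per_sample_labels(path, trace.dt))

    def test_single_state_mean_near_level(self):
        from smfet.models import StatePath

        model = KineticModel(
            states=("low", "intermediate"),
            levels=np.array([-3.0, 0.0]),
            P=np.array([[0.0, 1.0], [1.0, 0.0]]),
            tau=np.array([[0.0, 5.0], [2.0, 0.0]]),
            noise_sd=0.5,
        )
        path = StatePath(states=["low"], durations=np.array([500.0]))
        trace = render_trace(path, model, seed=9)
        n = trace.values.size
        assert abs(trace.values.mean() - (-3.0)) < 3 * 0.5 / np.sqrt(n)

    def test_mixture_recovers_levels(self, wtc_rendered, wtc_model):
        """A 3-component amplitude fit recovers the level means within 0.1 nA."""
        _, trace = wtc_rendered
        assert trace.values.size >= 50_000
        fit = fit_amplitude_histogram(trace)
        assert fit.k == 3
        np.testing.assert_allclose(fit.means + fit.offset, wtc_model.levels, atol=0.1)

    def test_short_dwell_clamped_with_warning(self, wtc_model):
        from smfet.models import StatePath

        path = StatePath(
            states=["low", "intermediate", "low"],
            durations=np.array([5.0, 0.001, 5.0]),  # 0.001 ms << one sample
        )
        with pytest.warns(UserWarning, match="clamped"):
            trace = render_trace(path, wtc_model, seed=1)
        assert trace.values.size >= 2


class TestControls:
    def test_two_level_control_has_two_peaks(self):
        trace = simulate_control_trace("two_level", seed=21, duration_ms=800.0)
        assert fit_amplitude_histogram(trace).k == 2

    def test_blank_has_single_peak(self):
        trace = simulate_control_trace("blank", seed=22, duration_ms=800.0)
        assert fit_amplitude_histogram(trace).k == 1

    def test_blank_without_noise_is_flat_zero(self):
        trace = simulate_control_trace("blank", seed=23, noise_sd=0.0, pink_amplitude=0.0)
        assert np.all(trace.values == 0.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ParameterError, match="unknown control kind"):
            simulate_control_trace("triple", seed=0)


class TestMeltingCurveGenerator:
    def test_standard_temperature_grid(self):
        curve = simulate_melting_curve(59.6, 2.5, np.arange(15, 81, 5))
        assert curve.temperatures.size == 14

    def test_sigmoid_midpoint_and_limits(self):
        curve = simulate_melting_curve(50.0, 2.0, [0.0, 50.0, 200.0])
        assert curve.absorbance[1] == pytest.approx(0.5)
        assert curve.absorbance[0] == pytest.approx(0.0, abs=1e-6)
        assert curve.absorbance[2] == pytest.approx(1.0, abs=1e-6)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ParameterError):
            simulate_melting_curve(50.0, -1.0, [10, 20])
        with pytest.raises(ParameterError):
            simulate_melting_curve(50.0, 2.0, [20, 10])


class TestHairpinStem:
    @pytest.mark.parametrize(
        "seq,stem,expected",
        [
            ("TGAGGATGGATAGATGCTTGCCTCA", 5, True),  # the rs1007616 probe
            ("AAAAATTTTTGGGGG", 5, False),
            ("GCGCAAGCGC", 4, True),
        ],
    )
    def test_stem_complementarity(self, seq, stem, expected):
        assert validate_hairpin_stem(seq, stem) is expected

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            validate_hairpin_stem("ACGT", 0)
        with pytest.raises(ParameterError):
            validate_hairpin_stem("ACGU", 1)
        with pytest.raises(ParameterError):
            validate_hairpin_stem("ACG", 2)
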