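"""Simulator: dwell statistics, alternation, rendering, analytic p_open."""

import numpy as np
import pytest
from scipy import signal as _signal

from singlechan import (CurrentTrace, simulate_event_sequence,
                        render_current_trace, stationary_open_probability)
from singlechan.gating import (Exponential, GatingModel, GatingState, Pareto,
                               make_regime, REGIMES, EventSequence)

from conftest import five_state_model, pareto_closed_model, two_state_model


class TestDwellDistributions:
    def test_exponential_requires_positive_tau(self):
        with pytest.raises(ValueError):
            Exponential(0.0)

    def test_pareto_invariants(self):
        with pytest.raises(ValueError):
            Pareto(1.0, 1e-4)
        with pytest.raises(ValueError):
            Pareto(1.5, 1e-4, 5e-5)

    def test_truncated_pareto_mean_matches_samples(self, rng):
        d = Pareto(1.5, 1e-4, 1e-2)
        x = d.sample(rng, 200_000)
        assert np.all((x >= d.t_min) & (x <= d.t_max))
        se = x.std() / np.sqrt(x.size)
        assert abs(x.mean() - d.mean()) < 4 * se


class TestEventSimulation:
    def test_seeded_determinism(self):
        m = two_state_model()
        a = simulate_event_sequence(m, 5.0, seed=42)
        b = simulate_event_sequence(m, 5.0, seed=42)
        assert a.state_labels == b.state_labels
        np.testing.assert_array_equal(a.durations, b.durations)

    def test_alternation_and_conservation(self):
        ev = simulate_event_sequence(five_state_model(), 20.0, seed=7)
        assert np.all(ev.conducting[1:] != ev.conducting[:-1])
        assert np.isclose(ev.durations.sum(), 20.0)

    def test_exponential_open_mean_recovery(self):
        # mean open dwell converges to tau at rate tau/sqrt(n)
        m = two_state_model(tau_open=4e-3, tau_closed=1e-3)
        ev = simulate_event_sequence(m, 1000.0, seed=3)
        opens = ev.durations[ev.conducting][:-1]  # drop possibly-truncated end
        se = 4e-3 / np.sqrt(opens.size)
        assert abs(opens.mean() - 4e-3) < 3 * se

    def test_pareto_survival_slope(self):
        # density f ~ t^-alpha gives survival S(t) = (t_min/t)^(alpha-1):
        # log-log survival is linear with slope -(alpha-1) = -0.5
        m = pareto_closed_model(alpha=1.5, t_min=1e-4, t_max=10.0)
        ev = simulate_event_sequence(m, 4000.0, seed=11)
        closed = np.sort(ev.durations[~ev.conducting])
        assert closed.size > 1e5
        surv = 1.0 - np.arange(closed.size) / closed.size
        lo, hi = 2e-4, 2e-2  # fit window well inside [t_min, t_max]
        mask = (closed > lo) & (closed < hi) & (surv > 0)
        slope = np.polyfit(np.log10(closed[mask]), np.log10(surv[mask]), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.05)

    def test_rejects_bad_duration(self):
        with pytest.raises(ValueError):
            simulate_event_sequence(two_state_model(), -1.0, seed=0)


class TestStationaryOpenProbability:
    def test_two_state_analytic(self):
        assert stationary_open_probability(
            two_state_model(4e-3, 1e-3)) == pytest.approx(0.8)

    def test_symmetric_two_state(self):
        assert stationary_open_probability(
            two_state_model(3e-3, 3e-3)) == pytest.approx(0.5)

    def test_five_state_matches_long_simulation(self):
        m = five_state_model()
        p = stationary_open_probability(m)
        ev = simulate_event_sequence(m, 2000.0, seed=5)
        assert len(ev) > 2e5
        # binomial-ish SE on the time fraction via cycle counting
        n_cycles = len(ev) / 2
        se = np.sqrt(p * (1 - p) / n_cycles) * 3  # generous 3-SE band
        assert abs(ev.open_fraction - p) < max(3 * se, 0.01)

    def test_reducible_chain_rejected(self):
        states = (
            GatingState("O1", True, Exponential(1e-3)),
            GatingState("O2", True, Exponential(1e-3)),
            GatingState("C1", False, Exponential(1e-3)),
            GatingState("C2", False, Exponential(1e-3)),
        )
        # two disconnected O<->C pairs
        P = np.array([
            [0, 0, 1.0, 0],
            [0, 0, 0, 1.0],
            [1.0, 0, 0, 0],
            [0, 1.0, 0, 0],
        ])
        m = GatingModel(states=states, transition_probs=P,
                        noise_sigma=0.0, filter_cutoff=None)
        with pytest.raises(ValueError, match="reducible"):
            stationary_open_probability(m)


class TestModelValidation:
    def test_within_class_transition_rejected(self):
        states = (GatingState("O", True, Exponential(1e-3)),
                  GatingState("O2", True, Exponential(1e-3)),
                  GatingState("C", False, Exponential(1e-3)))
        P = np.array([[0.5, 0.5, 0.0], [0, 0, 1.0], [0.5, 0.5, 0]])
        with pytest.raises(ValueError, match="alternate"):
            GatingModel(states=states, transition_probs=P)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="twice"):
            two_state_model(sampling_rate=1500.0, filter_cutoff=1000.0)


class TestRendering:
    def test_square_wave_sample_midpoint_quantization(self):
        m = two_state_model(open_level=10.0, closed_level=0.0)
        ev = EventSequence(["O", "C"], np.array([True, False]),
                           np.array([0.3e-3, 0.2e-3]), total_duration=0.5e-3)
        tr = render_current_trace(ev, m, seed=0)
        np.testing.assert_array_equal(tr.samples, [10, 10, 10, 0, 0])

    def test_noise_sd_in_long_closed_segment(self):
        m = two_state_model(tau_open=1e-3, tau_closed=1.0,
                            noise_sigma=1.0, filter_cutoff=None)
        ev = EventSequence(["C"], np.array([False]), np.array([10.0]),
                           total_duration=10.0)
        tr = render_current_trace(ev, m, seed=1)
        assert tr.samples.std() == pytest.approx(1.0, rel=0.05)

    def test_noise_stream_independent_of_event_stream(self):
        # same seed renders the same noise; different seed, different noise
        m = two_state_model(noise_sigma=1.0)
        ev = simulate_event_sequence(m, 1.0, seed=9)
        a = render_current_trace(ev, m, seed=9)
        b = render_current_trace(ev, m, seed=9)
        c = render_current_trace(ev, m, seed=10)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_lowpass_attenuates_high_frequencies(self):
        m_filt = two_state_model(noise_sigma=1.0, filter_cutoff=1000.0)
        m_raw = two_state_model(noise_sigma=1.0, filter_cutoff=None)
        ev = simulate_event_sequence(m_raw, 50.0, seed=2)
        raw = render_current_trace(ev, m_raw, seed=2)
        filt = render_current_trace(ev, m_filt, seed=2)
        f, p_raw = _signal.welch(raw.samples, fs=10_000, nperseg=4096)
        _, p_filt = _signal.welch(filt.samples, fs=10_000, nperseg=4096)
        band = f > 2000
        assert (p_raw[band].mean() / p_filt[band].mean()) >= 10

    def test_empty_events_rejected(self):
        m = two_state_model()
        ev = EventSequence([], np.empty(0, bool), np.empty(0), 0.0)
        with pytest.raises(ValueError):
            render_current_trace(ev, m, seed=0)


class TestRegimes:
    @pytest.mark.parametrize("name", REGIMES)
    def test_regimes_build_and_are_valid(self, name):
        m = make_regime(name)
        assert 0.0 < stationary_open_probability(m) < 1.0

    def test_activation_raises_open_probability(self):
        assert (stationary_open_probability(make_regime("ca_high"))
                > stationary_open_probability(make_regime("control")))
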