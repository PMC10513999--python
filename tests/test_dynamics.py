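"""Glauber dynamics: conditional rule, sweeps, event-driven simulation."""

import dataclasses

import numpy as np
import pytest

import emonet as em
from emonet.dynamics import InvalidScheduleError, run_constant_field_chain
from emonet.states import exact_state_distribution, enumerate_spin_states


class TestConditionalActivation:
    def test_isolated_unbiased_node_is_fair(self):
        net = em.ComponentNetwork(("a",), np.zeros((1, 1)), np.zeros(1))
        p = em.conditional_activation_probability(net, np.array([-1.0]), 0)
        assert p == pytest.approx(0.5)

    def test_saturates_with_large_threshold(self):
        net = em.ComponentNetwork(("a",), np.zeros((1, 1)), np.array([50.0]))
        p = em.conditional_activation_probability(net, np.array([-1.0]), 0)
        assert p == pytest.approx(1.0)

    def test_closed_form_with_active_neighbor(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        net = em.ComponentNetwork(("a", "b"), w, np.zeros(2))
        p = em.conditional_activation_probability(net, np.array([-1.0, 1.0]), 0, beta=1.0)
        assert p == pytest.approx(1.0 / (1.0 + np.exp(-2.0)))

    def test_field_shifts_probability(self, small_net):
        state = np.ones(small_net.n)
        p0 = em.conditional_activation_probability(small_net, state, 2, field=0.0)
        p2 = em.conditional_activation_probability(small_net, state, 2, field=2.0)
        assert p2 > p0


class TestSweep:
    def test_deterministic_given_rng_state(self, small_net):
        cfg = em.SimulationConfig(seed=0)
        s0 = np.ones(small_net.n)
        a = em.sweep(small_net, s0, 0.0, cfg, np.random.default_rng(3))
        b = em.sweep(small_net, s0, 0.0, cfg, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)
        assert set(np.unique(a)) <= {-1.0, 1.0}

    def test_overwhelming_field_activates_everything(self, small_net):
        cfg = em.SimulationConfig(seed=0)
        s = np.full(small_net.n, -1.0)
        s = em.sweep(small_net, s, 100.0, cfg, np.random.default_rng(0))
        assert np.all(s == 1.0)


class TestScheduleField:
    def test_linear_profile_shape(self):
        sched = em.EventSchedule(
            baseline_sweeps=3, amplitude=2.0, hold_sweeps=2, fade_sweeps=4,
            post_sweeps=2,
        )
        e = sched.field_profile()
        assert e.shape == (11,)
        np.testing.assert_allclose(e[:3], 0.0)
        np.testing.assert_allclose(e[3:5], 2.0)
        np.testing.assert_allclose(e[5:9], [1.5, 1.0, 0.5, 0.0])
        np.testing.assert_allclose(e[9:], 0.0)
        assert np.all(np.diff(e[5:]) <= 0)  # non-increasing after hold

    def test_exponential_fade_is_nonincreasing_to_zero(self):
        sched = em.EventSchedule(
            baseline_sweeps=0, amplitude=1.0, hold_sweeps=1, fade_sweeps=10,
            fade_shape="exponential", post_sweeps=0,
        )
        e = sched.field_profile()
        assert np.all(np.diff(e) <= 0)
        assert e[-1] < 0.01

    def test_zero_total_sweeps_rejected(self):
        with pytest.raises(InvalidScheduleError):
            em.EventSchedule(baseline_sweeps=0, hold_sweeps=0, fade_sweeps=0,
                             post_sweeps=0)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidScheduleError):
            em.EventSchedule(baseline_sweeps=-1)


class TestSimulate:
    def test_same_seed_bit_identical(self, small_net, short_schedule):
        cfg = em.SimulationConfig(runs=4, seed=11)
        a = em.simulate(small_net, short_schedule, cfg)
        b = em.simulate(small_net, short_schedule, cfg)
        np.testing.assert_array_equal(a.states, b.states)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_different_seeds_differ(self, small_net, short_schedule):
        a = em.simulate(small_net, short_schedule, em.SimulationConfig(runs=2, seed=1))
        b = em.simulate(small_net, short_schedule, em.SimulationConfig(runs=2, seed=2))
        assert not np.array_equal(a.states, b.states)

    def test_intensity_is_fraction_of_active_components(self, small_net, short_schedule):
        ens = em.simulate(small_net, short_schedule, em.SimulationConfig(runs=3, seed=5))
        expected = (ens.states > 0).mean(axis=2)
        np.testing.assert_array_equal(ens.intensity, expected)
        # always a multiple of 1/n inside [0, 1]
        assert np.all((ens.intensity >= 0) & (ens.intensity <= 1))
        np.testing.assert_allclose(
            np.round(ens.intensity * small_net.n), ens.intensity * small_net.n
        )

    def test_strong_event_saturates_hold_phase(self, fear_net, short_schedule):
        sched = dataclasses.replace(short_schedule, amplitude=6.0)
        ens = em.simulate(fear_net, sched, em.SimulationConfig(runs=20, seed=7))
        hold = slice(sched.baseline_sweeps, sched.baseline_sweeps + sched.hold_sweeps)
        assert ens.intensity[:, hold].mean() > 0.95

    def test_hold_intensity_exceeds_baseline(self, fear_net, short_schedule):
        ens = em.simulate(fear_net, short_schedule, em.SimulationConfig(runs=50, seed=8))
        hold = slice(short_schedule.baseline_sweeps,
                     short_schedule.baseline_sweeps + short_schedule.hold_sweeps)
        assert ens.intensity[:, hold].mean() > ens.intensity[:, :short_schedule.baseline_sweeps].mean()

    def test_zero_amplitude_is_stationary(self, small_net):
        """No event: both halves agree with the exact stationary mean."""
        sched = em.EventSchedule(baseline_sweeps=300, amplitude=0.0, hold_sweeps=0,
                                 fade_sweeps=0, post_sweeps=300)
        ens = em.simulate(small_net, sched, em.SimulationConfig(runs=40, seed=13))
        exact_mean = em.exact_distribution(small_net).expected_intensity()
        halves = [ens.intensity[:, :300], ens.intensity[:, 300:]]
        run_means = [h.mean(axis=1) for h in halves]
        ses = [rm.std(ddof=1) / np.sqrt(len(rm)) for rm in run_means]
        for rm, se in zip(run_means, ses):
            assert abs(rm.mean() - exact_mean) < 3 * se
        pooled = np.hypot(*ses)
        assert abs(run_means[0].mean() - run_means[1].mean()) < 3 * pooled

    def test_amplitude_monotonically_raises_hold_intensity(self, small_net):
        sched0 = em.EventSchedule(baseline_sweeps=20, hold_sweeps=30, fade_sweeps=10,
                                  post_sweeps=10)
        hold = slice(20, 50)
        means = []
        for amp in (0.0, 0.7, 1.5, 3.0):
            sched = dataclasses.replace(sched0, amplitude=amp)
            ens = em.simulate(small_net, sched, em.SimulationConfig(runs=100, seed=21))
            means.append(ens.intensity[:, hold].mean())
        assert all(b > a - 0.02 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0]


class TestDetailedBalance:
    def test_chain_samples_boltzmann_distribution(self, small_net):
        """Long-run state frequencies match exact enumeration (TV < 0.02)."""
        states = run_constant_field_chain(
            small_net, sweeps=200_000, field=0.0,
            config=em.SimulationConfig(seed=17), burn_in=1000,
        )
        codes = ((states > 0) << np.arange(small_net.n)).sum(axis=1)
        freq = np.bincount(codes, minlength=2 ** small_net.n) / len(codes)
        exact = exact_state_distribution(small_net)
        assert 0.5 * np.abs(freq - exact).sum() < 0.02


class TestCommonCauseSimulation:
    def test_decoupled_star_relaxes_after_fade(self):
        model = em.make_common_cause_model(n=6, loading=0.0, threshold=-1.0)
        sched = em.EventSchedule(baseline_sweeps=30, amplitude=4.0, hold_sweeps=20,
                                 fade_sweeps=10, post_sweeps=60)
        ens = em.simulate_common_cause(model, sched, em.SimulationConfig(runs=30, seed=3))
        assert ens.intensity.shape[1] == sched.total_sweeps
        hold = slice(30, 50)
        assert ens.intensity[:, hold].mean() > 0.95
        assert ens.intensity[:, -20:].mean() < 0.15  # back near baseline

    def test_intensity_excludes_cause_node(self):
        model = em.make_common_cause_model(n=4, loading=0.5)
        sched = em.EventSchedule(baseline_sweeps=5, hold_sweeps=5, fade_sweeps=5,
                                 post_sweeps=5)
        ens = em.simulate_common_cause(model, sched, em.SimulationConfig(runs=2, seed=0))
        assert ens.states.shape[2] == 5  # 4 components + cause simulated
        np.testing.assert_array_equal(
            ens.intensity, (ens.states[:, :, :4] > 0).mean(axis=2)
        )


def test_intensity_of_counts_active_fraction():
    assert em.intensity_of([1, 1, 1, 1, 1, 1, 1, -1, -1, -1]) == 0.7
    assert em.intensity_of(np.full(4, -1)) == 0.0
    assert em.intensity_of(np.ones(4)) == 1.0
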