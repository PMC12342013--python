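import numpy as np
import pytest

from hemaclone import (
    EngraftmentState,
    ModelParams,
    draw_differentiation_times,
    draw_engraftment,
    expected_richness,
    logistic_mean,
    simulate_hsc,
)


class TestEngraftment:
    def test_all_ones(self):
        s = draw_engraftment(C_H=60000, H_star=1.11e7, n_engrafted=2500,
                             mode="all_ones", seed=0)
        assert s.n_clones == 2500
        assert (s.h_init == 1).all()

    def test_multinomial_single_box(self):
        s = draw_engraftment(C_H=1, H_star=100, n_engrafted=17,
                             mode="multinomial", seed=0)
        assert s.n_clones == 1
        assert s.h_init[0] == 17

    def test_multinomial_occupancy_expectation(self):
        # expected occupied boxes: C_H (1 - (1 - 1/C_H)^n)
        C_H, n = 10_000, 1_000
        rng = np.random.default_rng(42)
        occ = [draw_engraftment(C_H, n, n, "multinomial", rng).n_clones
               for _ in range(1000)]
        occ = np.asarray(occ, dtype=float)
        expect = C_H * (1 - (1 - 1 / C_H) ** n)
        se = occ.std(ddof=1) / np.sqrt(len(occ))
        assert abs(occ.mean() - expect) < 3 * se

    def test_overdraw_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            draw_engraftment(10, 5, 6)


class TestLogisticMean:
    def test_initial_and_fixed_point(self):
        p = ModelParams(r_h0=0.08, mu_h=0.02, K=2.5e5, C_h0=2500)
        assert logistic_mean(0.0, p, 7000.0) == pytest.approx(7000.0)
        # steady state K (1 - mu_h / r_h0)
        assert logistic_mean(1e7, p, 7000.0) == pytest.approx(187_500.0, rel=1e-9)
        p0 = p.replace(mu_h=0.0)
        assert logistic_mean(np.array([0.0, 50.0, 500.0]), p0, p.K) == pytest.approx(p.K)

    def test_net_decay_branch(self):
        p = ModelParams(r_h0=0.01, mu_h=0.05, K=1e4, C_h0=100)
        t = np.array([0.0, 100.0, 1000.0])
        h = logistic_mean(t, p, 500.0)
        assert h[0] == 500.0
        assert (np.diff(h) < 0).all()
        # with the density term negligible the path is nearly exponential decay
        assert h[1] == pytest.approx(500 * np.exp(-0.04 * 100), rel=0.05)

    def test_negative_time_rejected(self):
        p = ModelParams()
        with pytest.raises(ValueError):
            logistic_mean(-1.0, p, 100.0)


class TestExpectedRichness:
    def test_initial_value_and_monotone(self):
        p = ModelParams(r_h0=0.08, mu_h=0.02, K=2e4, C_h0=200, h0_0=0.0)
        t = np.linspace(0, 600, 25)
        c = expected_richness(t, p, 200.0)
        assert c[0] == pytest.approx(200.0)
        assert (np.diff(c) <= 1e-9).all()
        assert (c <= 200.0 + 1e-9).all()

    def test_no_death_preserves_richness(self):
        # with mu_h = 0, phi = 1 - psi so the denominator is identically 1
        p = ModelParams(r_h0=0.08, mu_h=0.0, K=2e4, C_h0=200, h0_0=0.0)
        c = expected_richness(np.array([0.0, 100.0, 400.0]), p, 200.0)
        assert c == pytest.approx(200.0, rel=1e-8)


class TestGillespie:
    def test_no_death_growth_bounded_by_capacity(self):
        p = ModelParams(r_h0=0.1, mu_h=0.0, alpha=0.0, K=500.0, C_h0=1, h0_0=0.0)
        init = EngraftmentState(h_init=np.array([5]), h0_init=0.0)
        traj = simulate_hsc(p, init, t_max=400.0, seed=3)
        sizes = 5 + np.cumsum(traj.event_delta)
        assert (np.diff(sizes) >= 0).all() or (traj.event_delta >= 0).all()
        assert sizes.max() <= p.K + 1

    def test_pure_death_extinction_probability(self):
        # r_h0 = 0: each unit clone goes extinct by t with prob 1 - exp(-mu t)
        p = ModelParams(r_h0=0.0, mu_h=0.05, alpha=0.0, K=1e4, C_h0=300, h0_0=0.0)
        init = EngraftmentState(h_init=np.ones(300, dtype=np.int64), h0_init=0.0)
        extinct = []
        for s in range(100):
            traj = simulate_hsc(p, init, t_max=30.0, seed=s)
            extinct.append(300 - traj.surviving_clones())
        extinct = np.asarray(extinct, dtype=float)
        p_ext = 1 - np.exp(-0.05 * 30)
        se = extinct.std(ddof=1) / np.sqrt(len(extinct))
        assert abs(extinct.mean() - 300 * p_ext) < 3 * se

    def test_bookkeeping_conservation(self, small_preset):
        params, _ = small_preset
        init = EngraftmentState(h_init=np.ones(params.C_h0, dtype=np.int64),
                                h0_init=params.h0_0)
        traj = simulate_hsc(params, init, t_max=120.0, seed=9)
        # per-clone cumulative deltas reproduce the stored final state
        sizes = traj.clone_sizes_at(traj.t_max)
        assert np.array_equal(sizes, traj.h_final)
        assert (sizes >= 0).all()
        assert traj.tagged_total_at(traj.t_max)[0] == traj.h_final.sum()
        # extinct clones stay extinct: no births after a clone hits zero
        for i in range(0, params.C_h0, 17):
            _, path = traj.clone_path(i)
            dead = np.where(path == 0)[0]
            if dead.size:
                assert (path[dead[0]:] == 0).all()


class TestDifferentiationTimes:
    def test_zero_rate(self):
        ev = draw_differentiation_times((np.array([0.0]), np.array([4.0])), 0.0,
                                        seed=0, t_max=100.0)
        assert ev.size == 0
        with pytest.raises(ValueError):
            draw_differentiation_times((np.array([0.0]), np.array([1.0])), -0.1)

    def test_poisson_moments_constant_path(self):
        # constant h = 1 over 100 d at alpha = 0.016: count ~ Poisson(1.6)
        rng = np.random.default_rng(1)
        counts = [
            draw_differentiation_times((np.array([0.0]), np.array([1.0])), 0.016,
                                       rng, t_max=100.0).size
            for _ in range(10_000)
        ]
        counts = np.asarray(counts, dtype=float)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 1.6) < 3 * se

    def test_intensity_proportional_to_population(self):
        # h doubles at t = 50: event density ratio after/before -> 2
        path = (np.array([0.0, 50.0]), np.array([1.0, 2.0]))
        rng = np.random.default_rng(2)
        before = after = 0
        for _ in range(10_000):
            ev = draw_differentiation_times(path, 0.05, rng, t_max=100.0)
            before += (ev < 50).sum()
            after += (ev >= 50).sum()
        ratio = after / before
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_events_within_horizon_and_sorted(self):
        path = (np.array([0.0, 10.0, 30.0]), np.array([2.0, 5.0, 1.0]))
        ev = draw_differentiation_times(path, 0.5, seed=3, t_max=60.0)
        assert (ev >= 0).all() and (ev <= 60.0).all()
        assert (np.diff(ev) >= 0).all()
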