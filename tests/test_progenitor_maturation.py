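import numpy as np
import pytest

from hemaclone import (
    ModelParams,
    cascade_population,
    mature_burst_kernel,
    superpose_bursts,
    terminal_population,
)
from hemaclone.progenitor_maturation import cascade_ode_solution


def rel_err(a, b, floor_scale):
    """Relative error with an absolute floor tied to the burst peak."""
    floor = 1e-9 * np.max(np.abs(b))
    return np.max(np.abs(a - b) / np.maximum(np.abs(b), max(floor, floor_scale)))


class TestCascadeClosedForm:
    def test_initial_condition(self):
        p = ModelParams(L=5)
        assert cascade_population(0.0, 2, p, origin=2) == pytest.approx(1.0)
        assert cascade_population(0.0, 3, p, origin=2) == 0.0

    def test_one_generation_example(self):
        # l = l0 + 1, r_n = 2, mu_n = 0, t = 1 -> 4 e^{-2}
        p = ModelParams(r_n=2.0, mu_n=0.0, L=5)
        assert cascade_population(1.0, 1, p, origin=0) == pytest.approx(
            4 * np.exp(-2), rel=1e-10
        )

    def test_domain_checks(self):
        p = ModelParams(L=5)
        with pytest.raises(ValueError):
            cascade_population(1.0, 5, p, origin=0)  # terminal handled separately
        with pytest.raises(ValueError):
            cascade_population(1.0, 0, p, origin=2)

    @pytest.mark.parametrize("r_n,omega,mu_n,L", [
        (2.0, 0.2, 0.0, 22),
        (1.3, 0.9, 0.1, 7),
        (4.5, 0.05, 0.0, 12),
        (1.0, 1.0, 0.1, 5),      # r_n == omega degenerate limit
        (1.0, 1.5, 0.0, 8),      # omega > r_n series branch
    ])
    def test_closed_forms_match_ode_oracle(self, r_n, omega, mu_n, L):
        p = ModelParams(r_n=r_n, omega=omega, mu_n=mu_n, L=L)
        t = np.linspace(0.02, 40.0, 50)
        ode = cascade_ode_solution(t, p, origin=0)
        for gen in range(L):
            cf = cascade_population(t, gen, p, origin=0)
            assert rel_err(cf, ode[gen], 0.0) < 1e-6
        term = terminal_population(t, p, origin=0)
        assert rel_err(term, ode[-1], 0.0) < 1e-6

    def test_terminal_two_stage_closed_form(self):
        # L = 1, mu_n = 0: n^(1)(t) = (2 r_n/(r_n - w)) (e^{-w t} - e^{-r_n t})
        p = ModelParams(L=1, r_n=3.0, omega=0.4, mu_n=0.0)
        t = np.linspace(0.0, 20.0, 64)
        expect = 2 * p.r_n / (p.r_n - p.omega) * (np.exp(-p.omega * t) - np.exp(-p.r_n * t))
        assert terminal_population(t, p, origin=0) == pytest.approx(expect, abs=1e-10)

    def test_terminal_starts_at_zero_and_nonnegative(self):
        p = ModelParams(L=22)
        t = np.linspace(0.0, 60.0, 200)
        n = terminal_population(t, p, origin=0)
        assert n[0] == 0.0
        assert (n >= 0).all()


class TestBurstKernel:
    def test_flux_conservation(self, zh33_preset):
        params, _ = zh33_preset  # mu_n = 0, L = 22
        k = mature_burst_kernel(params, origin=0)
        assert k.m_values[0] == 0.0
        assert (k.m_values >= 0).all()
        assert k.total_yield == pytest.approx(2.0 ** 22, rel=1e-3)

    def test_origin_generation_reduces_yield(self, zh33_preset):
        params, _ = zh33_preset
        k0 = mature_burst_kernel(params, origin=0)
        k2 = mature_burst_kernel(params, origin=2)
        assert k2.total_yield / k0.total_yield == pytest.approx(0.25, rel=1e-3)

    def test_progenitor_death_shrinks_yield(self):
        p = ModelParams(L=8, mu_n=0.1)
        k = mature_burst_kernel(p, origin=0)
        assert k.total_yield < 2.0 ** 8

    def test_peak_time_monotonicity(self):
        base = ModelParams(L=10, r_n=2.0)
        peak = mature_burst_kernel(base, origin=0).peak_time
        assert mature_burst_kernel(base.replace(L=16), origin=0).peak_time > peak
        assert mature_burst_kernel(base.replace(r_n=4.0), origin=0).peak_time < peak


class TestSuperposition:
    def test_no_events_is_zero(self):
        p = ModelParams(L=6)
        k = mature_burst_kernel(p, origin=0)
        grid = np.arange(0.0, 50.0)
        assert superpose_bursts(np.array([]), k, grid) == pytest.approx(0.0)

    def test_linearity(self):
        p = ModelParams(L=6)
        k = mature_burst_kernel(p, origin=0)
        grid = np.arange(0.0, 120.0, 0.5)
        a = superpose_bursts(np.array([5.0, 40.0]), k, grid)
        b = superpose_bursts(np.array([17.0]), k, grid)
        both = superpose_bursts(np.array([5.0, 17.0, 40.0]), k, grid)
        assert both == pytest.approx(a + b, rel=1e-12)
        # coincident events double the single-event response
        twice = superpose_bursts(np.array([5.0, 5.0]), k, grid)
        single = superpose_bursts(np.array([5.0]), k, grid)
        assert twice == pytest.approx(2 * single)

    def test_intermittent_vs_merged_bursts(self, zh33_preset):
        # low alpha h / mu_m: well-separated pulses; high: fluctuations shrink
        params, _ = zh33_preset
        k = mature_burst_kernel(params, origin=0)
        grid = np.arange(300.0, 6000.0, 1.0)
        from hemaclone import draw_differentiation_times

        cvs = []
        for h in (0.5, 5.0, 50.0):
            ev = draw_differentiation_times(
                (np.array([0.0]), np.array([h])), params.alpha,
                np.random.default_rng(int(h * 10)), t_max=6000.0,
            )
            m = superpose_bursts(ev, k, grid)
            cvs.append(m.std() / m.mean())
        assert cvs[0] > cvs[1] > cvs[2]


class TestStationaryLaw:
    def test_time_average_matches_little_law(self, zh33_preset):
        # constant clone of h HSCs: <m_i> = alpha h 2^L / mu_m
        params, _ = zh33_preset
        from hemaclone import draw_differentiation_times

        k = mature_burst_kernel(params, origin=0)
        h = 5.0
        ev = draw_differentiation_times((np.array([0.0]), np.array([h])),
                                        params.alpha, np.random.default_rng(0),
                                        t_max=40_000.0)
        grid = np.arange(500.0, 40_000.0, 1.0)
        m = superpose_bursts(ev, k, grid)
        expect = params.alpha * h * 2.0 ** params.L / params.mu_m
        assert m.mean() == pytest.approx(expect, rel=0.05)
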