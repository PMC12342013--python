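"""Deterministic transit-amplifying cascade and the mature-cell pool.

One HSC differentiation event injects a single generation-0 progenitor.
Each generation-``l`` progenitor divides at rate ``r_n`` into two
generation-``l+1`` cells (symmetric differentiating division) and dies at
rate ``mu_n``; after ``L`` generations the cell can only terminally
differentiate, at rate ``omega``, into a mature circulating cell which
turns over at rate ``mu_m``.  Because the cascade is linear, the response
to a stream of differentiation events is the superposition of single-event
"bursts".  Transplanted HSPC clones are founded at a generation ``l0 > 0``
and produce a single, smaller burst (effective depth ``L - l0``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import gammainc, gammaln

from .config_io import ModelParams
from .hsc_compartment import HSCTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "BurstKernel",
    "MatureTrajectory",
    "cascade_population",
    "terminal_population",
    "mature_burst_kernel",
    "superpose_bursts",
    "assemble_mature",
]


# ---------------------------------------------------------------------------
# Closed-form cascade populations
# ---------------------------------------------------------------------------


def cascade_population(t, gen: int, params: ModelParams, origin: int = 0):
    """Population n^(l)(t) of a pre-terminal generation, closed form.

    For a single founding cell at generation ``origin`` at t = 0 and shared
    rates across generations,

        n^(l)(t) = (2 r_n t)^(l - l0) / (l - l0)! * exp(-(r_n + mu_n) t).

    Valid for ``origin <= gen <= L - 1`` (the terminal generation has its
    own solution, :func:`terminal_population`).
    """
    if not (origin <= gen <= params.L - 1):
        raise ValueError(f"generation {gen} outside [origin={origin}, L-1={params.L - 1}]")
    t = np.asarray(t, dtype=float)
    g = gen - origin
    with np.errstate(divide="ignore", invalid="ignore"):
        logt = np.where(t > 0, np.log(np.maximum(t, 1e-300)), -np.inf)
        log_n = g * (np.log(2.0 * params.r_n) + logt) - gammaln(g + 1) \
            - (params.r_n + params.mu_n) * t
        out = np.where(t > 0, np.exp(log_n), 1.0 if g == 0 else 0.0)
    return out if out.shape else float(out)


def _gamma_series_sum(G: int, x: np.ndarray) -> np.ndarray:
    """sum_{k>=0} x^k / Gamma(G + k + 1), elementwise (x may be negative)."""
    out = np.zeros_like(x, dtype=float)
    term = np.full_like(x, np.exp(-gammaln(G + 1)), dtype=float)
    out += term
    for k in range(1, 1000):
        term = term * x / (G + k)
        out += term
        if np.all(np.abs(term) <= 1e-17 * np.maximum(np.abs(out), 1e-300)):
            break
    return out


def terminal_population(t, params: ModelParams, origin: int = 0):
    """Population n^(L)(t) of the terminal generation after a single burst.

    With ``G = L - origin`` effective generations and ``delta = r_n - omega``:

        n^(L)(t) = exp(-(omega + mu_n) t) (2 r_n / delta)^G P(G, delta t)

    where P is the regularized lower incomplete gamma function.  The
    ``r_n = omega`` degeneracy resolves to the Erlang form
    ``exp(-(omega + mu_n) t) (2 r_n t)^G / G!``; ``omega > r_n`` is handled
    by a stable series in ``delta t``.
    """
    if origin >= params.L:
        raise ValueError(f"origin={origin} must be < L={params.L}")
    t = np.asarray(t, dtype=float)
    G = params.L - origin
    rn, om, mn = params.r_n, params.omega, params.mu_n
    delta = rn - om
    if abs(delta) < 1e-9 * rn:
        log_n = -(om + mn) * t + G * np.log(np.maximum(2.0 * rn * t, 1e-300)) \
            - gammaln(G + 1)
        out = np.where(t > 0, np.exp(log_n), 0.0)
    elif delta > 0:
        x = delta * t
        P = gammainc(G, x)
        with np.errstate(divide="ignore"):
            logP = np.where(P > 0, np.log(np.maximum(P, 1e-300)), -np.inf)
        log_n = -(om + mn) * t + G * np.log(2.0 * rn / delta) + logP
        out = np.exp(log_n)
    else:
        # omega > r_n: n = e^{-(r_n+mu_n) t} (2 r_n t)^G sum_k (delta t)^k / (G+k)!
        x = delta * t
        s = _gamma_series_sum(G, x)
        log_pref = -(rn + mn) * t + G * np.log(np.maximum(2.0 * rn * t, 1e-300))
        out = np.where(t > 0, np.exp(log_pref) * s, 0.0)
    return out if out.shape else float(out)


def cascade_ode_solution(t_eval, params: ModelParams, origin: int = 0):
    """Numerical ODE integration of the full cascade (oracle / fallback).

    Returns an array of shape ``(L - origin + 1, len(t_eval))`` with rows
    for generations ``origin .. L`` (the last row is the terminal stage).
    Used to cross-check the closed forms and to support generation-dependent
    rates if ever needed.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    L, rn, mn, om = params.L, params.r_n, params.mu_n, params.omega
    n_stages = L - origin + 1

    def rhs(t, y):
        dy = np.empty_like(y)
        dy[0] = -(rn + mn) * y[0]
        for j in range(1, n_stages - 1):
            dy[j] = 2.0 * rn * y[j - 1] - (rn + mn) * y[j]
        if n_stages > 1:
            dy[-1] = 2.0 * rn * y[-2] - (om + mn) * y[-1]
        else:
            dy[0] = -(om + mn) * y[0]
        return dy

    y0 = np.zeros(n_stages)
    y0[0] = 1.0
    sol = solve_ivp(
        rhs, (0.0, float(t_eval.max())), y0, t_eval=t_eval,
        rtol=1e-12, atol=1e-20, method="DOP853",
    )
    if not sol.success:
        raise RuntimeError(f"cascade ODE integration failed: {sol.message}")
    return sol.y


# ---------------------------------------------------------------------------
# Burst kernel: mature-cell response to one differentiation event
# ---------------------------------------------------------------------------


@dataclass
class BurstKernel:
    """Mature-cell population m(t) following a single differentiation event.

    ``total_yield`` is the total number of mature cells ever produced,
    ``int mu_m m dt``; with ``mu_n = 0`` it equals ``2**(L - origin)``.
    The kernel is tabulated on a uniform grid and evaluates to 0 outside
    its support.
    """

    t_grid: np.ndarray
    m_values: np.ndarray
    origin: int
    total_yield: float

    def __call__(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.t_grid, self.m_values,
                         left=0.0, right=0.0)

    @property
    def dt(self) -> float:
        return float(self.t_grid[1] - self.t_grid[0])

    @property
    def peak_time(self) -> float:
        return float(self.t_grid[np.argmax(self.m_values)])


def mature_burst_kernel(
    params: ModelParams,
    origin: int = 0,
    t_max: float | None = None,
    dt: float = 1.0,
    rel_cutoff: float = 1e-9,
) -> BurstKernel:
    """Compute the burst kernel m(t) = omega int_0^t n^(L)(t') e^{-mu_m (t-t')} dt'.

    Solved as the ODE dm/dt = omega n^(L)(t) - mu_m m with the analytic
    terminal-stage forcing, which keeps the quadrature error independent of
    the tabulation grid ``dt``.  The horizon auto-extends (doubling) until
    the kernel has decayed below ``rel_cutoff`` of its maximum; the mature
    cells still alive at truncation are added to ``total_yield``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    horizon = t_max if t_max is not None else max(
        8.0 * (params.L - origin + 1) / params.r_n + 8.0 / min(params.omega, params.mu_m),
        10.0 * dt,
    )

    # integrate the yield-normalized kernel so tolerances are scale-free
    scale = 2.0 ** (params.L - origin)

    def rhs(t, y):
        return [params.omega * terminal_population(t, params, origin) / scale
                - params.mu_m * y[0],
                params.mu_m * y[0]]

    max_horizon = 1 << 14  # days; cap on auto-extension
    while True:
        grid = np.arange(0.0, horizon + 0.5 * dt, dt)
        sol = solve_ivp(rhs, (0.0, grid[-1]), [0.0, 0.0], t_eval=grid,
                        rtol=1e-10, atol=1e-14, method="DOP853")
        if not sol.success:
            raise RuntimeError(f"burst kernel integration failed: {sol.message}")
        m = sol.y[0] * scale
        if t_max is not None or m[-1] <= rel_cutoff * m.max() or horizon >= max_horizon:
            if m[-1] > rel_cutoff * max(m.max(), 1e-300) and t_max is None:
                warnings.warn(
                    f"burst kernel unresolved at t={horizon:.0f} d; "
                    f"mass deficit {m[-1] / max(m.max(), 1e-300):.2e} of peak"
                )
            break
        horizon *= 2.0
    # cells alive at truncation eventually turn over: residual yield = m(T)
    total_yield = float((sol.y[1][-1] + sol.y[0][-1]) * scale)
    trunc = m[-1] / max(m.max(), 1e-300)
    if trunc > 0:
        logger.debug("kernel truncated at %.2e of peak (origin=%d)", trunc, origin)
    return BurstKernel(t_grid=grid, m_values=np.maximum(m, 0.0), origin=origin,
                       total_yield=total_yield)


# ---------------------------------------------------------------------------
# Superposition over differentiation events
# ---------------------------------------------------------------------------


def superpose_bursts(event_times, kernel: BurstKernel, t_grid) -> np.ndarray:
    """Mature path of one clone: m_i(t) = sum_k kernel(t - T_k), T_k <= t."""
    t_grid = np.asarray(t_grid, dtype=float)
    event_times = np.asarray(event_times, dtype=float)
    late = event_times > t_grid.max() if t_grid.size else np.zeros(0, bool)
    if late.any():
        logger.info("%d differentiation events beyond the grid ignored", late.sum())
        event_times = event_times[~late]
    out = np.zeros_like(t_grid)
    if event_times.size == 0:
        return out
    # chunk events to bound memory for long event streams
    chunk = max(1, int(4e6 / max(t_grid.size, 1)))
    for lo in range(0, event_times.size, chunk):
        T = event_times[lo:lo + chunk]
        out += kernel((t_grid[None, :] - T[:, None]).ravel()).reshape(len(T), -1).sum(axis=0)
    return out


@dataclass
class MatureTrajectory:
    """Per-clone mature-cell populations on a time grid (days).

    ``origins[i]`` is -1 for HSC-derived clones and the founding progenitor
    generation for transplanted HSPC clones.  ``m_untagged`` is the
    expected mature population of the untagged pool.
    """

    t_grid: np.ndarray
    m: np.ndarray            # (n_clones, n_times)
    origins: np.ndarray      # (n_clones,)
    m_untagged: np.ndarray   # (n_times,)

    @property
    def n_clones(self) -> int:
        return self.m.shape[0]

    @property
    def total(self) -> np.ndarray:
        """M(t): tagged clones plus the untagged pool."""
        return self.m.sum(axis=0) + self.m_untagged

    @property
    def tagged_total(self) -> np.ndarray:
        return self.m.sum(axis=0)

    def to_frame(self):
        import pandas as pd

        n, nt = self.m.shape
        return pd.DataFrame({
            "time": np.tile(self.t_grid, n),
            "clone": np.repeat(np.arange(n), nt),
            "value": self.m.ravel(),
        })


def untagged_mature_path(
    trajectory: HSCTrajectory,
    params: ModelParams,
    kernel0: BurstKernel,
    t_grid: np.ndarray,
    conv_dt: float = 0.5,
) -> np.ndarray:
    """Expected untagged mature pool m_0(t) = int_0^t alpha h0(t') k(t - t') dt'."""
    t_grid = np.asarray(t_grid, dtype=float)
    if params.alpha == 0.0 or trajectory.h0_init == 0.0:
        return np.zeros_like(t_grid)
    t_hi = float(t_grid.max())
    fine = np.arange(0.0, t_hi + conv_dt, conv_dt)
    intensity = params.alpha * trajectory.untagged_at(fine)
    kern = kernel0(fine)
    conv = np.convolve(intensity, kern)[: len(fine)] * conv_dt
    return np.interp(t_grid, fine, conv)


def assemble_mature(
    trajectory: HSCTrajectory,
    params: ModelParams,
    t_grid,
    kernels: dict[int, BurstKernel] | None = None,
    hspc_clone_ids: bool = True,
) -> MatureTrajectory:
    """Assemble per-clone mature-cell paths for a whole animal.

    Tagged HSC clones superpose one burst per differentiation event (the
    event streams must already be attached to ``trajectory.diff_events``);
    each transplanted HSPC clone contributes a single burst founded at its
    generation ``l0`` at t = 0; the untagged pool enters through the
    expected-value convolution of ``alpha * h0(t)`` with the burst kernel.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("t_grid is empty")
    if float(t_grid.max()) > trajectory.t_max * (1 + 1e-12):
        raise ValueError("t_grid extends beyond the simulated horizon")

    needed = sorted({0, *params.hspc_init.keys()})
    if kernels is None:
        kernels = {}
    for l0 in needed:
        if l0 not in kernels:
            kernels[l0] = mature_burst_kernel(params, origin=l0)

    if params.alpha > 0 and trajectory.diff_events is None:
        raise ValueError(
            "trajectory.diff_events not set; call draw_all_differentiation first"
        )

    n_hsc = trajectory.n_clones
    n_hspc = int(sum(params.hspc_init.values()))
    m = np.zeros((n_hsc + n_hspc, t_grid.size))
    origins = np.empty(n_hsc + n_hspc, dtype=np.int64)
    origins[:n_hsc] = -1
    if params.alpha > 0:
        for i in range(n_hsc):
            ev = trajectory.diff_events[i]
            if ev.size:
                m[i] = superpose_bursts(ev, kernels[0], t_grid)
    row = n_hsc
    for l0 in sorted(params.hspc_init):
        count = params.hspc_init[l0]
        burst = kernels[l0](t_grid)
        for _ in range(count):
            m[row] = burst
            origins[row] = l0
            row += 1

    m_untagged = untagged_mature_path(trajectory, params, kernels[0], t_grid)
    return MatureTrajectory(t_grid=t_grid, m=m, origins=origins, m_untagged=m_untagged)
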