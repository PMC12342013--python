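"""Stochastic dynamics of tagged HSC clones plus the deterministic untagged pool.

The tagged hematopoietic stem cell (HSC) clones follow a coupled logistic
birth-death process: each cell proliferates at the density-dependent rate
``r_h(h) = r_h0 * (1 - h / K)`` (clamped at zero once the total pool ``h``
reaches the niche carrying capacity ``K``) and dies at rate ``mu_h``.  The
coupling between clones acts only through the shared total ``h(t)``, which
includes a large untagged pool treated deterministically.  Differentiation
is asymmetric (it does not deplete the HSC pool) and is generated afterwards
as an inhomogeneous Poisson process with intensity ``alpha * h_i(t)`` along
each clone's piecewise-constant trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .config_io import ModelParams

__all__ = [
    "EngraftmentState",
    "HSCTrajectory",
    "draw_engraftment",
    "logistic_mean",
    "expected_richness",
    "simulate_hsc",
    "draw_differentiation_times",
    "draw_all_differentiation",
]


# ---------------------------------------------------------------------------
# Engraftment
# ---------------------------------------------------------------------------


@dataclass
class EngraftmentState:
    """Initial condition of the HSC pool after homing and engraftment."""

    h_init: np.ndarray  # per-clone initial sizes, nonnegative integers
    h0_init: float      # untagged pool, treated deterministically

    def __post_init__(self) -> None:
        self.h_init = np.asarray(self.h_init, dtype=np.int64)
        if (self.h_init < 0).any() or self.h0_init < 0:
            raise ValueError("initial populations must be nonnegative")

    @property
    def n_clones(self) -> int:
        return len(self.h_init)

    @property
    def tagged_total(self) -> int:
        return int(self.h_init.sum())


def draw_engraftment(
    C_H: int,
    H_star: int,
    n_engrafted: int,
    mode: str = "all_ones",
    seed: int | np.random.Generator | None = None,
    h0_init: float = 0.0,
) -> EngraftmentState:
    """Draw the engrafted tagged clone sizes.

    ``multinomial`` mode throws ``n_engrafted`` cells into ``C_H`` equally
    likely barcodes (the symmetric multinomial obtained by marginalizing the
    hypergeometric engraftment draw over the injection multinomial) and drops
    empty barcodes.  ``all_ones`` is the simplification used throughout the
    model: every engrafted clone starts from a single cell.
    """
    if C_H < 1:
        raise ValueError("C_H >= 1 required")
    if n_engrafted > H_star:
        raise ValueError(f"n_engrafted={n_engrafted} exceeds H_star={H_star}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if mode == "all_ones":
        h = np.ones(n_engrafted, dtype=np.int64)
    elif mode == "multinomial":
        occ = rng.multinomial(n_engrafted, np.full(C_H, 1.0 / C_H))
        h = occ[occ > 0].astype(np.int64)
    else:
        raise ValueError(f"unknown engraftment mode {mode!r}")
    return EngraftmentState(h_init=h, h0_init=float(h0_init))


# ---------------------------------------------------------------------------
# Deterministic mean path and expected richness
# ---------------------------------------------------------------------------


def logistic_mean(t, params: ModelParams, h_total0: float) -> np.ndarray:
    """Closed-form solution of dh/dt = r_h0 (1 - h/K) h - mu_h h.

    Valid for any sign of the net rate ``r_h0 - mu_h`` (decay to zero when
    negative).  ``t`` may be a scalar or array of nonnegative days.
    """
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("t must be >= 0")
    rho = params.r_h0 - params.mu_h
    h0 = float(h_total0)
    if h0 == 0.0:
        return np.zeros_like(t)
    if abs(rho) < 1e-14:
        out = h0 / (1.0 + params.r_h0 * h0 * t / params.K)
    elif rho > 0:
        # h = h0 / (e^{-rho t} + (h0 r_h0/(K rho)) (1 - e^{-rho t})), overflow-safe
        em = np.exp(-rho * t)
        out = h0 / (em + h0 * params.r_h0 / (params.K * rho) * (1.0 - em))
    else:
        # decaying branch: e^{rho t} <= 1, no overflow
        em1 = np.expm1(rho * t)
        out = h0 * (em1 + 1.0) / (1.0 + h0 * params.r_h0 / (params.K * rho) * em1)
    return out


def _richness_denominator(t_eval: np.ndarray, params: ModelParams, h_total0: float):
    """Integrate psi and phi along the logistic mean path.

    psi(t) = exp(-int_0^t (r_h(t') - mu_h) dt'),
    phi(t) = int_0^t r_h(t') psi(t') dt',
    with r_h(t') = r_h0 (1 - hbar(t')/K) evaluated on the deterministic path.
    """
    t_eval = np.atleast_1d(np.asarray(t_eval, dtype=float))
    t_max = float(t_eval.max(initial=0.0))

    def rhs(t, y):
        psi, phi = y
        r = params.r_h0 * (1.0 - logistic_mean(t, params, h_total0) / params.K)
        return [-(r - params.mu_h) * psi, r * psi]

    if t_max == 0.0:
        psi = np.ones_like(t_eval)
        phi = np.zeros_like(t_eval)
    else:
        sol = solve_ivp(
            rhs, (0.0, t_max), [1.0, 0.0], t_eval=np.union1d(t_eval, [0.0, t_max]),
            rtol=1e-10, atol=1e-12, method="LSODA", dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(
                f"quadrature for expected richness failed (rtol=1e-10): {sol.message}"
            )
        y = sol.sol(t_eval)
        psi, phi = y[0], y[1]
    return psi, phi


def expected_richness(t, params: ModelParams, h_total0: float | None = None):
    """Expected surviving tagged clone count E[C_h(t)] = C_h(0)/(psi + phi).

    The generating-function result for the number of non-extinct lines of a
    birth-death process with time-varying birth rate taken along the
    deterministic mean path.  Nonincreasing in ``t`` and equal to ``C_h0``
    at ``t = 0``; constant when ``mu_h = 0``.
    """
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("t must be >= 0")
    if h_total0 is None:
        h_total0 = params.C_h0 + params.h0_0
    psi, phi = _richness_denominator(np.atleast_1d(t), params, h_total0)
    out = params.C_h0 / (psi + phi)
    return out.reshape(t.shape) if t.shape else float(out[0])


# ---------------------------------------------------------------------------
# Gillespie simulation
# ---------------------------------------------------------------------------


@njit(cache=True)
def _gillespie_core(h_init, h0_init, r_h0, mu_h, K, t_max, seed):  # pragma: no cover
    """Exact-jump simulation of the coupled clone birth-death process.

    Clone selection is proportional to clone size via a Fenwick (binary
    indexed) tree; the untagged pool is advanced deterministically between
    jumps (RK4 step on the logistic field with the tagged total frozen).
    Returns flat event arrays plus the untagged value after each event.
    """
    np.random.seed(seed)
    n = len(h_init)
    # Fenwick tree size: next power of two >= n+1 for simple traversal
    size = 1
    while size < n + 1:
        size *= 2
    tree = np.zeros(size + 1, dtype=np.int64)

    def _update(i, delta):
        j = i + 1
        while j <= size:
            tree[j] += delta
            j += j & (-j)

    def _find(target):
        # smallest index i with cumsum(h[0..i]) > target
        idx = 0
        bit = size
        rem = target
        while bit > 0:
            nxt = idx + bit
            if nxt <= size and tree[nxt] <= rem:
                idx = nxt
                rem -= tree[nxt]
            bit //= 2
        return idx  # 0-based clone index

    h = h_init.copy()
    for i in range(n):
        _update(i, h[i])
    tagged = h.sum()
    h0 = h0_init

    cap = 1 << 16
    ev_t = np.empty(cap, dtype=np.float64)
    ev_c = np.empty(cap, dtype=np.int64)
    ev_d = np.empty(cap, dtype=np.int8)
    ev_h0 = np.empty(cap, dtype=np.float64)
    n_ev = 0

    t = 0.0
    while True:
        total = tagged + h0
        b = r_h0 * (1.0 - total / K)
        if b < 0.0:
            b = 0.0
        rate = tagged * (b + mu_h)
        if rate <= 0.0:
            # no more tagged events; advance untagged to t_max
            dt_left = t_max - t
            nsub = int(dt_left) + 1
            hsub = dt_left / nsub
            for _ in range(nsub):
                bb = r_h0 * (1.0 - (tagged + h0) / K)
                if bb < 0.0:
                    bb = 0.0
                k1 = (bb - mu_h) * h0
                h0m = h0 + 0.5 * hsub * k1
                bb2 = r_h0 * (1.0 - (tagged + h0m) / K)
                if bb2 < 0.0:
                    bb2 = 0.0
                k2 = (bb2 - mu_h) * h0m
                h0 = h0 + hsub * k2
                if h0 < 0.0:
                    h0 = 0.0
            break
        dt = np.random.exponential(1.0 / rate)
        if t + dt > t_max:
            # advance untagged over the remaining interval and stop
            rem = t_max - t
            bb = r_h0 * (1.0 - (tagged + h0) / K)
            if bb < 0.0:
                bb = 0.0
            h0 = h0 + rem * (bb - mu_h) * h0
            if h0 < 0.0:
                h0 = 0.0
            break
        t += dt
        # midpoint step for the untagged pool over dt (dt is tiny)
        k1 = (b - mu_h) * h0
        h0m = h0 + 0.5 * dt * k1
        bm = r_h0 * (1.0 - (tagged + h0m) / K)
        if bm < 0.0:
            bm = 0.0
        h0 = h0 + dt * (bm - mu_h) * h0m
        if h0 < 0.0:
            h0 = 0.0
        # choose birth vs death, then clone proportional to size
        u = np.random.random() * (b + mu_h)
        target = np.random.randint(0, tagged)
        clone = _find(target)
        if u < b:
            delta = 1
        else:
            delta = -1
        h[clone] += delta
        tagged += delta
        _update(clone, delta)
        if n_ev == cap:
            cap *= 2
            tmp_t = np.empty(cap, dtype=np.float64)
            tmp_t[:n_ev] = ev_t
            ev_t = tmp_t
            tmp_c = np.empty(cap, dtype=np.int64)
            tmp_c[:n_ev] = ev_c
            ev_c = tmp_c
            tmp_d = np.empty(cap, dtype=np.int8)
            tmp_d[:n_ev] = ev_d
            ev_d = tmp_d
            tmp_h = np.empty(cap, dtype=np.float64)
            tmp_h[:n_ev] = ev_h0
            ev_h0 = tmp_h
        ev_t[n_ev] = t
        ev_c[n_ev] = clone
        ev_d[n_ev] = delta
        ev_h0[n_ev] = h0
        n_ev += 1
        if total > 100.0 * K:
            raise RuntimeError("propensity overflow: population exceeded 100 K")

    return ev_t[:n_ev], ev_c[:n_ev], ev_d[:n_ev], ev_h0[:n_ev], h, h0


@dataclass
class HSCTrajectory:
    """Piecewise-constant per-clone HSC paths from the Gillespie simulation.

    Event arrays are flat: event ``k`` changes clone ``event_clone[k]`` by
    ``event_delta[k]`` at ``event_times[k]``; ``h0_values[k]`` is the
    deterministic untagged pool right after the event.  ``diff_events`` is
    filled by :func:`draw_all_differentiation`.
    """

    h_init: np.ndarray
    h0_init: float
    event_times: np.ndarray
    event_clone: np.ndarray
    event_delta: np.ndarray
    h0_values: np.ndarray
    h_final: np.ndarray
    h0_final: float
    t_max: float
    diff_events: list[np.ndarray] | None = field(default=None, repr=False)

    @property
    def n_clones(self) -> int:
        return len(self.h_init)

    def clone_path(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, sizes): size ``sizes[k]`` holds on
        [times[k], times[k+1]); the last segment extends to t_max."""
        mask = self.event_clone == i
        jumps = self.event_times[mask]
        deltas = self.event_delta[mask]
        times = np.concatenate(([0.0], jumps))
        sizes = self.h_init[i] + np.concatenate(([0], np.cumsum(deltas)))
        return times, sizes

    def tagged_total_at(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        cum = np.concatenate(([0], np.cumsum(self.event_delta)))
        idx = np.searchsorted(self.event_times, t, side="right")
        return self.h_init.sum() + cum[idx]

    def untagged_at(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if len(self.event_times) == 0:
            # no jumps: interpolate between init and final
            grid = np.array([0.0, self.t_max])
            vals = np.array([self.h0_init, self.h0_final])
        else:
            grid = np.concatenate(([0.0], self.event_times, [self.t_max]))
            vals = np.concatenate(([self.h0_init], self.h0_values, [self.h0_final]))
        return np.interp(t, grid, vals)

    def total_at(self, t) -> np.ndarray:
        return self.tagged_total_at(t) + self.untagged_at(t)

    def surviving_clones(self, t: float | None = None) -> int:
        if t is None:
            return int((self.h_final > 0).sum())
        sizes = self.clone_sizes_at(t)
        return int((sizes > 0).sum())

    def clone_sizes_at(self, t: float) -> np.ndarray:
        sizes = self.h_init.astype(np.int64).copy()
        mask = self.event_times <= t
        np.add.at(sizes, self.event_clone[mask], self.event_delta[mask].astype(np.int64))
        return sizes

    def to_event_frame(self):
        """Tidy event log (time, clone, event) for debugging/export."""
        import pandas as pd

        kind = np.where(self.event_delta > 0, "birth", "death")
        return pd.DataFrame(
            {"time": self.event_times, "clone": self.event_clone, "event": kind}
        )


def simulate_hsc(
    params: ModelParams,
    init: EngraftmentState,
    t_max: float,
    seed: int = 0,
) -> HSCTrajectory:
    """Exact-jump (Gillespie) simulation of the coupled HSC clone dynamics.

    Birth propensity per clone is ``h_i * max(0, r_h0 (1 - h/K))`` with
    ``h`` the total pool including the deterministic untagged component;
    death propensity is ``h_i * mu_h``.  Differentiation does not appear
    here (asymmetric division does not deplete HSCs); see
    :func:`draw_differentiation_times`.
    """
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    ev_t, ev_c, ev_d, ev_h0, h_fin, h0_fin = _gillespie_core(
        init.h_init.astype(np.int64),
        float(init.h0_init),
        float(params.r_h0),
        float(params.mu_h),
        float(params.K),
        float(t_max),
        int(seed) & 0x7FFFFFFF,
    )
    return HSCTrajectory(
        h_init=init.h_init.copy(),
        h0_init=float(init.h0_init),
        event_times=ev_t,
        event_clone=ev_c,
        event_delta=ev_d,
        h0_values=ev_h0,
        h_final=h_fin,
        h0_final=float(h0_fin),
        t_max=float(t_max),
    )


# ---------------------------------------------------------------------------
# Differentiation event streams
# ---------------------------------------------------------------------------


def draw_differentiation_times(
    clone_path: tuple[np.ndarray, np.ndarray],
    alpha: float,
    seed: int | np.random.Generator | None = None,
    t_max: float | None = None,
) -> np.ndarray:
    """Exact sample of an inhomogeneous Poisson process with intensity
    ``alpha * h_i(t)`` on a piecewise-constant clone path.

    ``clone_path`` is ``(times, sizes)`` with ``sizes[k]`` holding on
    ``[times[k], times[k+1])``; the final segment extends to ``t_max``
    (default: last jump time).  Within each constant segment the process is
    homogeneous, so the total count is Poisson with mean
    ``alpha * sum(h_k * dt_k)`` and events fall uniformly within segments
    chosen proportionally to ``h_k * dt_k``.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    times, sizes = clone_path
    times = np.asarray(times, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if t_max is None:
        t_max = times[-1]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = np.concatenate((times, [t_max]))
    widths = np.diff(edges)
    weights = sizes * np.clip(widths, 0.0, None)
    lam = alpha * weights.sum()
    if lam == 0.0:
        return np.empty(0, dtype=float)
    n = rng.poisson(lam)
    if n == 0:
        return np.empty(0, dtype=float)
    seg = rng.choice(len(weights), size=n, p=weights / weights.sum())
    u = rng.random(n)
    events = edges[seg] + u * widths[seg]
    events.sort()
    return events


def draw_all_differentiation(
    trajectory: HSCTrajectory, alpha: float, seed: int = 0
) -> list[np.ndarray]:
    """Draw differentiation times for every clone, with per-clone RNG
    sub-streams keyed by (seed, clone index) so results do not depend on
    iteration order.  Stores and returns ``trajectory.diff_events``."""
    order = np.argsort(self_c := trajectory.event_clone, kind="stable")
    sorted_c = self_c[order]
    bounds = np.searchsorted(sorted_c, np.arange(trajectory.n_clones + 1))
    events: list[np.ndarray] = []
    for i in range(trajectory.n_clones):
        sel = order[bounds[i]:bounds[i + 1]]
        jumps = trajectory.event_times[sel]
        deltas = trajectory.event_delta[sel]
        times = np.concatenate(([0.0], jumps))
        sizes = trajectory.h_init[i] + np.concatenate(([0], np.cumsum(deltas)))
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        events.append(
            draw_differentiation_times((times, sizes), alpha, rng, t_max=trajectory.t_max)
        )
    trajectory.diff_events = events
    return events
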