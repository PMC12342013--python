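"""Staged parameter estimation for the clonal hematopoiesis model.

The estimation mirrors how one fits this model by hand, automated as
sequential grid pruning:

1. ``stage_richness`` — the post-transient sampled richness constrains the
   HSC-pool parameters (C_h(0), r_h(0), mu_h, K), with K anchored at
   ~100 C_h(0) and C_h(0) bounded below by the cumulative post-2-month
   richness of the data.
2. ``stage_hspc_burst`` — the small, transient clones of the first sample
   are attributed to transplanted HSPCs; matching their abundance modes
   constrains (r_n, L, omega, eta) and the per-generation clone counts
   C_n(l).  These parameters compensate each other strongly; the stage
   records feasible combinations rather than a unique answer.
3. ``stage_totals_lsq`` — the sample totals S(t_j) fix the HSC
   differentiation rate alpha by linear least squares (the expected total
   is linear in alpha).
4. ``stage_eta_adjust`` — per-time sampling-fraction multipliers absorb
   sample-to-sample fluctuations of the totals.
5. ``stage_emd_search`` — surviving candidates are simulated, their clone
   clouds clustered, and the Earth mover's distance to the clustered data
   selects the final estimate.

The pipeline is deterministic given (data, config, seed): every stochastic
sub-step derives its seed from the master seed and a stable hash of the
candidate's parameters, so candidate evaluation order is irrelevant.
"""

from __future__ import annotations

import itertools
import json
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelmax
from scipy.stats import gaussian_kde

from .clone_statistics import clone_summary
from .cluster_emd import earth_movers_distance, kmeans_with_elbow
from .config_io import ModelParams, SampleTable
from .hsc_compartment import logistic_mean
from .observation_sampling import SamplingSchedule, detection_probability
from .progenitor_maturation import BurstKernel, mature_burst_kernel

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FitResult",
    "StageRecord",
    "fit",
    "stage_richness",
    "stage_hspc_burst",
    "stage_totals_lsq",
    "stage_eta_adjust",
    "stage_emd_search",
    "composite_output_rate",
]


# ---------------------------------------------------------------------------
# Configuration and bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class FitConfig:
    """Grids and knobs of the staged search.

    ``initial`` anchors the grids: multiplicative factors are applied to its
    rates, as one would center a search on physiologically known magnitudes
    (e.g. eta from the drawn sample volume).  ``window`` (months) is the
    post-transient window used for richness and clone statistics.
    """

    initial: ModelParams
    C_h0_factors: tuple = (1.0, 1.4, 2.0)
    r_h0_factors: tuple = (0.5, 1.0, 2.0)
    mu_h_factors: tuple = (0.25, 1.0, 4.0)
    K_over_C_h0: tuple = (10.0, 100.0, 1000.0)
    r_n_factors: tuple = (0.5, 1.0, 2.0)
    L_offsets: tuple = (-3, 0, 3)
    omega_factors: tuple = (0.5, 1.0, 2.0)
    eta_factors: tuple = (1.0 / 3.0, 1.0, 3.0)
    top_q: int = 4
    hspc_top: int = 2
    replicates: int = 3
    k_range: tuple = (2, 13)
    window: float = 2.0
    alpha_bounds: tuple = (1e-5, 1.0)
    eta_band: tuple = (0.25, 4.0)
    emd_family_rtol: float = 0.2   # candidates within 20% of best EMD are
                                   # reported as the compensation family


@dataclass
class StageRecord:
    name: str
    candidates: list = field(default_factory=list)   # list of param dicts
    objectives: list = field(default_factory=list)
    selected: list = field(default_factory=list)     # indices into candidates
    skipped: bool = False
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "candidates": self.candidates,
            "objectives": [None if o is None else float(o) for o in self.objectives],
            "selected": [int(i) for i in self.selected],
            "skipped": self.skipped,
            "note": self.note,
        }


@dataclass
class FitResult:
    """Outcome of the staged fit, including per-stage diagnostics."""

    best_params: ModelParams
    stage_records: list[StageRecord]
    eta_multipliers: np.ndarray
    final_emd: float
    replicates: int
    seed: int
    compensation_family: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "best_params": self.best_params.to_dict(),
            "stage_records": [r.to_dict() for r in self.stage_records],
            "eta_multipliers": [float(x) for x in self.eta_multipliers],
            "final_emd": float(self.final_emd),
            "replicates": int(self.replicates),
            "seed": int(self.seed),
            "compensation_family": self.compensation_family,
        }


def composite_output_rate(params: ModelParams) -> float:
    """The identifiable composite alpha * 2^L * eta / mu_m.

    Expected sampled cells per HSC per day: differentiation rate times burst
    yield times sampling fraction over turnover.  Individual members of
    (r_n, L, omega, eta) trade off against alpha; this composite is pinned
    by the sample totals.
    """
    return params.alpha * 2.0 ** params.L * params.eta / params.mu_m


def _candidate_seed(seed: int, params: ModelParams, salt: int = 0) -> int:
    """Seed derived from the master seed and the candidate's parameters,
    independent of evaluation order."""
    key = json.dumps(params.to_dict(), sort_keys=True) + f"|{salt}"
    return (int(seed) * 2654435761 + zlib.crc32(key.encode())) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# Shared model summaries
# ---------------------------------------------------------------------------


_KERNEL_CACHE: dict[tuple, BurstKernel] = {}


def _kernel(params: ModelParams, origin: int) -> BurstKernel:
    key = (round(params.r_n, 12), round(params.mu_n, 12), round(params.omega, 12),
           int(params.L), round(params.mu_m, 12), int(origin))
    if key not in _KERNEL_CACHE:
        if len(_KERNEL_CACHE) > 512:
            _KERNEL_CACHE.clear()
        _KERNEL_CACHE[key] = mature_burst_kernel(params, origin=origin)
    return _KERNEL_CACHE[key]


def _kernels_for(params: ModelParams) -> dict[int, BurstKernel]:
    return {l0: _kernel(params, l0) for l0 in sorted({0, *params.hspc_init})}


def expected_tagged_mature(params: ModelParams, t_days: np.ndarray,
                           conv_dt: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Expected tagged mature population split into (per-unit-alpha HSC part,
    HSPC part): M*(t) = alpha * A(t) + B(t).

    A(t) is the convolution of the expected tagged HSC path with the burst
    kernel; B(t) superposes the single bursts of the transplanted HSPC
    clones.  Both are deterministic, making the totals stage a linear
    least-squares problem in alpha.
    """
    t_days = np.asarray(t_days, dtype=float)
    k0 = _kernel(params, 0)
    h_total0 = params.C_h0 + params.h0_0
    share = params.C_h0 / h_total0 if h_total0 > 0 else 0.0
    fine = np.arange(0.0, float(t_days.max()) + conv_dt, conv_dt)
    h_star = share * logistic_mean(fine, params, h_total0)
    conv = np.convolve(h_star, k0(fine))[: len(fine)] * conv_dt
    A = np.interp(t_days, fine, conv)
    B = np.zeros_like(t_days)
    for l0, count in params.hspc_init.items():
        B += count * _kernel(params, l0)(t_days)
    return A, B


def _simulate_table(params: ModelParams, times_months, seed: int) -> SampleTable:
    from .synthetic_data import generate_dataset  # deferred: module cycle

    schedule = SamplingSchedule.from_params(np.asarray(times_months, float), params)
    table, _ = generate_dataset(params, schedule, seed=seed,
                                kernels=_kernels_for(params))
    return table


# ---------------------------------------------------------------------------
# Stage 1: richness
# ---------------------------------------------------------------------------


def stage_richness(data: SampleTable, config: FitConfig,
                   seed: int = 0) -> tuple[list[ModelParams], StageRecord]:
    """Constrain (C_h0, r_h0, mu_h, K) from the post-transient richness.

    The cumulative richness after the window is a lower bound on C_h(0)
    (sampling only loses clones); K is anchored at 100 C_h(0) with a
    +-1 decade grid.  Each grid candidate is simulated once and scored on
    the post-window samples by the relative squared error of its richness
    plus that of its mean clone size (totals / richness).  The second term
    breaks the (C_h0, K) ridge along which a smaller clone count with a
    larger niche reproduces the richness with oversized clones.
    """
    post = data.times > config.window
    if post.sum() < 3:
        raise ValueError("need >= 3 post-window samples for the richness stage")
    c_bound = data.cumulative_richness(config.window)
    if c_bound == 0:
        raise ValueError("no clones detected after the window; richness grid empty")
    target = data.richness[post].astype(float)
    target_size = np.log((data.totals[post] + 1.0) / (target + 1.0))

    cands, objs = [], []
    for fc, fr, fm, fk in itertools.product(
        config.C_h0_factors, config.r_h0_factors,
        config.mu_h_factors, config.K_over_C_h0,
    ):
        C_h0 = int(round(c_bound * fc))
        p = config.initial.replace(
            C_h0=C_h0, h0_0=None,
            r_h0=config.initial.r_h0 * fr,
            mu_h=config.initial.mu_h * fm,
            K=fk * C_h0,
            eta_adjustments=None,
        )
        table = _simulate_table(p, data.times, _candidate_seed(seed, p))
        pred = table.richness[post].astype(float)
        pred_size = np.log((table.totals[post] + 1.0) / (pred + 1.0))
        rich_term = ((pred - target) / np.maximum(target, 1.0)) ** 2
        size_term = (pred_size - target_size) ** 2
        objs.append(float(rich_term.sum() + size_term.sum()))
        cands.append(p)
    order = np.argsort(objs, kind="stable")[: config.top_q]
    record = StageRecord(
        name="richness",
        candidates=[c.to_dict() for c in cands],
        objectives=objs,
        selected=list(order),
        note=f"C_h0 lower bound {c_bound} from cumulative post-{config.window}-month richness",
    )
    return [cands[i] for i in order], record


# ---------------------------------------------------------------------------
# Stage 2: HSPC transient / first-sample burst
# ---------------------------------------------------------------------------


def _transient_first_counts(data: SampleTable, window: float) -> np.ndarray:
    """First-sample counts of clones seen early (t <= window) but never after."""
    early = data.times <= window
    late = ~early
    seen_early = (data.counts[:, early] > 0).any(axis=1)
    seen_late = (data.counts[:, late] > 0).any(axis=1) if late.any() else False
    transient = seen_early & ~seen_late
    first = data.counts[transient, 0]
    return first[first > 0]


def _abundance_modes(counts: np.ndarray, max_modes: int = 5) -> np.ndarray:
    """Locations (log10(1+s)) of the local maxima of the count density."""
    x = np.log10(1.0 + counts.astype(float))
    if x.size < 5 or np.ptp(x) < 1e-9:
        return np.array([np.median(x)]) if x.size else np.empty(0)
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min() - 0.25, x.max() + 0.25, 512)
    dens = kde(grid)
    idx = argrelmax(dens)[0]
    if idx.size == 0:
        idx = np.array([int(np.argmax(dens))])
    order = np.argsort(dens[idx])[::-1][:max_modes]
    return np.sort(grid[idx[order]])


def stage_hspc_burst(data: SampleTable, candidates: list[ModelParams],
                     config: FitConfig,
                     seed: int = 0) -> tuple[list[ModelParams], StageRecord]:
    """Constrain (r_n, L, omega, eta) and the HSPC initial condition.

    With alpha = 0 the first sample is pure HSPC bursts: each transplanted
    generation l0 contributes clones of expected sampled size
    eta * m_{l0}(t_1).  Candidate (r_n, L, omega, eta) combinations are
    scored by how closely those predicted sizes land on the modes of the
    first-sample abundance distribution of the transient clones; C_n(l0) is
    estimated by assigning transient clones to the nearest predicted mode
    and correcting for detection dropout.
    """
    t1_days = float(data.times_days[0])
    first_counts = _transient_first_counts(data, config.window)
    init = config.initial
    origins = sorted(init.hspc_init) or [0, 1, 2]

    if first_counts.size < 5:
        record = StageRecord(
            name="hspc_burst", skipped=True,
            note="no small-clone transient detectable; defaults retained",
        )
        out = [c.replace(hspc_init=dict(init.hspc_init)) for c in candidates]
        return out, record

    modes = _abundance_modes(first_counts)
    combos, objs, hspc_maps = [], [], []
    for fr, dL, fo, fe in itertools.product(
        config.r_n_factors, config.L_offsets, config.omega_factors, config.eta_factors
    ):
        L = int(init.L + dL)
        if L <= max(origins):
            continue
        trial = init.replace(r_n=init.r_n * fr, L=L, omega=init.omega * fo,
                             eta=init.eta * fe, eta_adjustments=None)
        m_t1 = np.array([_kernel(trial, l0)(t1_days) for l0 in origins])
        pred = np.log10(1.0 + trial.eta * m_t1)
        # squared log-distance from each observed mode to its nearest predicted size
        obj = float(sum(np.min((pred - mu) ** 2) for mu in modes))
        # assign transient clones to nearest predicted generation
        xs = np.log10(1.0 + first_counts.astype(float))
        assign = np.argmin(np.abs(xs[:, None] - pred[None, :]), axis=1)
        cn = {}
        for g, l0 in enumerate(origins):
            n_obs = int((assign == g).sum())
            p_det = float(detection_probability(m_t1[g], trial.eta))
            cn[l0] = int(round(n_obs / max(p_det, 1e-3)))
        combos.append(trial)
        objs.append(obj)
        hspc_maps.append(cn)

    order = np.argsort(objs, kind="stable")[: config.hspc_top]
    out = []
    for cand in candidates:
        for i in order:
            t = combos[i]
            out.append(cand.replace(r_n=t.r_n, L=t.L, omega=t.omega, eta=t.eta,
                                    hspc_init=dict(hspc_maps[i])))
    record = StageRecord(
        name="hspc_burst",
        candidates=[{"r_n": c.r_n, "L": c.L, "omega": c.omega, "eta": c.eta,
                     "hspc_init": {str(k): v for k, v in h.items()}}
                    for c, h in zip(combos, hspc_maps)],
        objectives=objs,
        selected=list(order),
        note=f"{first_counts.size} transient clones; modes at log10(1+s) = "
             f"{np.round(modes, 3).tolist()}; (r_n, L, omega, eta) compensate "
             "and are kept as a family",
    )
    return out, record


# ---------------------------------------------------------------------------
# Stage 3: totals least squares for alpha
# ---------------------------------------------------------------------------


def stage_totals_lsq(data: SampleTable, candidates: list[ModelParams],
                     config: FitConfig) -> tuple[list[ModelParams], StageRecord]:
    """Fix alpha per candidate by least squares on the sample totals.

    The expected tagged total is S(t_j) = eta * (alpha A(t_j) + B(t_j)),
    linear in alpha, so the minimizer is closed-form; it is clipped to the
    configured physiologic bounds.
    """
    t_days = data.times_days
    s_hat = data.totals.astype(float)
    out, objs, cands_rec = [], [], []
    for cand in candidates:
        A, B = expected_tagged_mature(cand, t_days)
        y = s_hat / cand.eta - B
        denom = float((A * A).sum())
        if denom <= 0 or not np.isfinite(denom):
            logger.info("totals stage: discarding candidate with degenerate A(t)")
            continue
        alpha = float((A * y).sum() / denom)
        alpha = float(np.clip(alpha, *config.alpha_bounds))
        p = cand.replace(alpha=alpha)
        resid = s_hat - p.eta * (alpha * A + B)
        obj = float((resid ** 2).sum())
        if not np.isfinite(obj):
            logger.info("totals stage: non-finite objective, candidate discarded")
            continue
        out.append(p)
        objs.append(obj)
        cands_rec.append(p.to_dict())
    record = StageRecord(name="totals_lsq", candidates=cands_rec, objectives=objs,
                         selected=list(range(len(out))),
                         note="alpha by linear least squares on S(t_j)")
    if not out:
        raise RuntimeError("all candidates discarded in the totals stage")
    return out, record


# ---------------------------------------------------------------------------
# Stage 4: per-time sampling-fraction adjustment
# ---------------------------------------------------------------------------


def stage_eta_adjust(data: SampleTable, params: ModelParams,
                     band: tuple[float, float] = (0.25, 4.0)) -> np.ndarray:
    """Per-time multipliers eta(t_j)/eta matching the sample totals.

    multiplier_j = S_hat(t_j) / S_model(t_j), clipped to ``band`` and
    renormalized to geometric mean 1 (the mean fraction eta keeps its
    meaning; fold the geometric mean into eta if an absolute scale is
    needed).
    """
    t_days = data.times_days
    A, B = expected_tagged_mature(params, t_days)
    s_model = params.eta * (params.alpha * A + B)
    s_hat = data.totals.astype(float)
    mult = np.ones_like(s_model)
    ok = s_model > 0
    mult[ok] = s_hat[ok] / s_model[ok]
    if (~ok & (s_hat > 0)).any():
        logger.warning("model total is 0 where data is positive; multiplier capped")
        mult[~ok & (s_hat > 0)] = band[1]
    mult = np.clip(mult, *band)
    gm = float(np.exp(np.mean(np.log(mult))))
    return mult / gm


# ---------------------------------------------------------------------------
# Stage 5: EMD search
# ---------------------------------------------------------------------------


def stage_emd_search(data: SampleTable, candidates: list[ModelParams],
                     config: FitConfig, seed: int = 0,
                     prior_records: list[StageRecord] | None = None) -> FitResult:
    """Select the final candidate by average EMD to the clustered data."""
    if not candidates:
        raise ValueError("candidate set is empty")
    k_range = range(config.k_range[0], config.k_range[1])
    window = (config.window, np.inf)
    data_cloud = clone_summary(data, window)
    data_clusters = kmeans_with_elbow(data_cloud, k_range, seed=seed)

    objs, mults = [], []
    for cand in candidates:
        emds = []
        mult = stage_eta_adjust(data, cand, band=config.eta_band)
        sim_params = cand.replace(eta_adjustments=list(mult))
        for rep in range(config.replicates):
            table = _simulate_table(sim_params, data.times,
                                    _candidate_seed(seed, sim_params, salt=rep + 1))
            try:
                cloud = clone_summary(table, window)
                if cloud.n_clones < max(k_range) + 1:
                    raise ValueError("simulated cloud too small to cluster")
                clusters = kmeans_with_elbow(cloud, k_range, seed=seed)
                emds.append(earth_movers_distance(data_clusters, clusters).distance)
            except (ValueError, RuntimeError) as exc:
                logger.info("candidate replicate failed (%s); penalized", exc)
                emds.append(np.inf)
        objs.append(float(np.mean(emds)))
        mults.append(mult)
    objs_arr = np.array(objs)
    if not np.isfinite(objs_arr).any():
        raise RuntimeError("all candidates failed simulation in the EMD stage")
    best = int(np.argmin(objs_arr))
    best_params = candidates[best].replace(eta_adjustments=list(mults[best]))

    family = []
    for cand, obj in zip(candidates, objs):
        if np.isfinite(obj) and obj <= objs_arr[best] * (1 + config.emd_family_rtol):
            family.append({
                "r_n": cand.r_n, "L": cand.L, "omega": cand.omega,
                "eta": cand.eta, "alpha": cand.alpha,
                "composite_alpha_2L_eta_over_mum": composite_output_rate(cand),
                "emd": float(obj),
            })
    record = StageRecord(
        name="emd_search",
        candidates=[c.to_dict() for c in candidates],
        objectives=objs,
        selected=[best],
        note=f"average over {config.replicates} replicates; data k*={data_clusters.k}",
    )
    records = list(prior_records or []) + [record]
    return FitResult(
        best_params=best_params,
        stage_records=records,
        eta_multipliers=mults[best],
        final_emd=float(objs_arr[best]),
        replicates=config.replicates,
        seed=seed,
        compensation_family=family,
    )


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------


def fit(data: SampleTable, config: FitConfig, seed: int = 0) -> FitResult:
    """Run the full staged estimation on a clone-abundance table."""
    cands, rec1 = stage_richness(data, config, seed=seed)
    cands, rec2 = stage_hspc_burst(data, cands, config, seed=seed)
    cands, rec3 = stage_totals_lsq(data, cands, config)
    result = stage_emd_search(data, cands, config, seed=seed,
                              prior_records=[rec1, rec2, rec3])
    return result
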