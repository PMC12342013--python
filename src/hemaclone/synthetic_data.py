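"""Ground-truthed synthetic clone-abundance tables.

Runs the full generative model end to end — engraftment, coupled
logistic birth-death of HSC clones (Gillespie), Poisson differentiation
event streams, deterministic progenitor bursts and mature-cell turnover,
and binomial blood sampling — and returns both the observable SampleTable
and the complete ground truth (per-clone origin, event times, whole-animal
mature populations at the sampling times).

Presets
-------
``ZH33``
    The reference macaque study conditions: 2500 tagged HSC clones,
    K = 2.5e5, L = 22, 15 samples over 49 months, eta = 1e-5 with the
    fitted per-time multipliers, and 800/1600/3200 transplanted HSPC
    clones at generations 0/1/2 (the source of the early richness spike).
``small_test``
    A ~20x miniaturized system (120 HSC clones, K = 1.2e4, L = 10,
    8 samples over 8 months) whose dimensionless regime matches ZH33:
    clone-level burst intermittency (alpha*h_i vs mu_m), data-like
    per-clone sampled counts (eta chosen so mean counts are ~tens), and a
    first sample early enough to catch the HSPC transient.  Runs the full
    pipeline in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config_io import ModelParams, SampleTable
from .hsc_compartment import (
    EngraftmentState,
    draw_all_differentiation,
    simulate_hsc,
)
from .observation_sampling import SamplingSchedule, sample_counts
from .progenitor_maturation import assemble_mature, mature_burst_kernel

__all__ = ["GroundTruth", "generate_dataset", "make_preset"]

ZH33_TIMES_MONTHS = [1, 2, 3, 4.5, 6.5, 9.5, 12, 14, 21, 28, 30, 38, 43, 46, 49]
ZH33_ETA_MULTIPLIERS = [1, 2.03, 1.07, 0.94, 0.68, 1.25, 0.61, 0.83, 1.29,
                        1.29, 1.01, 1.01, 0.99, 1.14, 0.83]

SMALL_TEST_TIMES_MONTHS = [0.25, 0.5, 1, 2, 3, 4, 6, 8]


@dataclass
class GroundTruth:
    """Everything the generator knows that the observer does not."""

    params: ModelParams
    schedule: SamplingSchedule
    seed: int
    origins: np.ndarray          # -1 = HSC clone, l0 >= 0 = HSPC clone
    diff_events: list[np.ndarray]  # per HSC clone
    m_true: np.ndarray           # whole-animal m_i at sampling times
    m_untagged: np.ndarray
    trajectory: object = None    # HSCTrajectory (kept for mechanism tests)


def make_preset(name: str) -> tuple[ModelParams, SamplingSchedule]:
    """Named study conditions; see the module docstring."""
    if name == "ZH33":
        params = ModelParams(
            r_h0=0.08, mu_h=0.02, alpha=0.016, K=2.5e5, C_h0=2500,
            r_n=2.0, mu_n=0.0, omega=0.2, L=22, mu_m=0.185, eta=1e-5,
            eta_adjustments=list(ZH33_ETA_MULTIPLIERS),
            hspc_init={0: 800, 1: 1600, 2: 3200},
            tagged_fraction=0.35,
        )
        schedule = SamplingSchedule.from_params(ZH33_TIMES_MONTHS, params)
    elif name == "small_test":
        params = ModelParams(
            r_h0=0.08, mu_h=0.02, alpha=0.016, K=1.2e4, C_h0=120,
            r_n=2.0, mu_n=0.0, omega=0.2, L=10, mu_m=0.185, eta=0.02,
            eta_adjustments=None,
            hspc_init={0: 40, 1: 80, 2: 160},
            tagged_fraction=0.35,
        )
        schedule = SamplingSchedule.from_params(SMALL_TEST_TIMES_MONTHS, params)
    else:
        raise ValueError(f"unknown preset {name!r}")
    return params, schedule


def generate_dataset(
    params: ModelParams,
    schedule: SamplingSchedule,
    seed: int = 0,
    keep_trajectory: bool = False,
    kernels: dict | None = None,
) -> tuple[SampleTable, GroundTruth]:
    """Simulate one barcoded-transplant experiment.

    Deterministic in ``(params, schedule, seed)``: the master seed spawns
    independent sub-streams for the Gillespie path, the per-clone
    differentiation draws, and the sampling step.
    """
    t_grid = schedule.times_days
    t_max = float(t_grid.max())
    ss = np.random.SeedSequence(seed)
    seed_gillespie, seed_diff, seed_sample = [
        int(s.generate_state(1)[0]) & 0x7FFFFFFF for s in ss.spawn(3)
    ]

    init = EngraftmentState(
        h_init=np.ones(params.C_h0, dtype=np.int64), h0_init=params.h0_0
    )
    traj = simulate_hsc(params, init, t_max=t_max, seed=seed_gillespie)
    draw_all_differentiation(traj, params.alpha, seed=seed_diff)
    mature = assemble_mature(traj, params, t_grid, kernels=kernels)

    n_hsc = params.C_h0
    width = len(str(max(mature.n_clones, 1)))
    ids = [f"HSC{idx:0{width}d}" for idx in range(n_hsc)]
    for row in range(n_hsc, mature.n_clones):
        ids.append(f"PRO{mature.origins[row]}_{row:0{width}d}")

    table = sample_counts(
        mature, schedule, seed=np.random.default_rng(seed_sample), clone_ids=ids
    )
    truth = GroundTruth(
        params=params,
        schedule=schedule,
        seed=seed,
        origins=mature.origins,
        diff_events=traj.diff_events,
        m_true=mature.m,
        m_untagged=mature.m_untagged,
        trajectory=traj if keep_trajectory else None,
    )
    return table, truth


def kernels_for(params: ModelParams) -> dict:
    """Burst kernels for every origin generation the parameters require."""
    return {
        l0: mature_burst_kernel(params, origin=l0)
        for l0 in sorted({0, *params.hspc_init.keys()})
    }
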