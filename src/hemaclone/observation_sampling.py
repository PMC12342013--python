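"""Binomial small-sample observation of the mature pool.

A blood sample at time ``t_j`` captures a fraction ``eta(t_j)`` of the
animal's circulating mature cells.  Because ``eta`` is tiny, the exact
multivariate hypergeometric draw factorizes into independent binomials per
clone: ``s_i ~ Binomial(round(m_i(t_j)), eta_j)``.  Small clones are easily
missed entirely; the detection probability of a clone of size ``m`` is
``1 - (1 - eta)^m``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config_io import ModelParams, SampleTable, months_to_days
from .progenitor_maturation import MatureTrajectory

__all__ = [
    "SamplingSchedule",
    "sample_counts",
    "expected_tagged_total",
    "detection_probability",
]


@dataclass
class SamplingSchedule:
    """Sampling times (months) and per-time sampling fractions eta(t_j)."""

    times: np.ndarray        # months, strictly increasing
    eta: np.ndarray          # absolute per-time fractions, each in [0, 1]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.eta.ndim == 0:
            self.eta = np.full_like(self.times, float(self.eta))
        if len(self.eta) != len(self.times):
            raise ValueError("times and eta must have equal length")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("sampling times must be strictly increasing")
        if ((self.eta < 0) | (self.eta > 1)).any():
            raise ValueError("eta values must lie in [0, 1]")

    @classmethod
    def from_params(cls, times_months, params: ModelParams) -> "SamplingSchedule":
        """Build a schedule from mean eta and optional per-time multipliers."""
        times_months = np.asarray(times_months, dtype=float)
        mult = (
            np.asarray(params.eta_adjustments, dtype=float)
            if params.eta_adjustments is not None
            else np.ones_like(times_months)
        )
        if len(mult) != len(times_months):
            raise ValueError("eta_adjustments length must match sampling times")
        return cls(times=times_months, eta=params.eta * mult)

    @property
    def times_days(self) -> np.ndarray:
        return months_to_days(self.times)

    @property
    def n_times(self) -> int:
        return len(self.times)


def sample_counts(
    mature: MatureTrajectory,
    schedule: SamplingSchedule,
    seed: int | np.random.Generator | None = None,
    clone_ids: list[str] | None = None,
) -> SampleTable:
    """Draw a SampleTable from the mature trajectory.

    Each whole-animal population ``m_i(t_j)`` is rounded to the nearest
    integer (ties to even) and thinned by an independent binomial with the
    per-time sampling fraction.
    """
    t_days = schedule.times_days
    grid = mature.t_grid
    if t_days.min() < grid.min() - 1e-9 or t_days.max() > grid.max() + 1e-9:
        raise ValueError("schedule times outside the trajectory grid span")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if grid.size == t_days.size and np.allclose(grid, t_days):
        m_at = mature.m
    else:
        m_at = np.empty((mature.n_clones, t_days.size))
        for i in range(mature.n_clones):
            m_at[i] = np.interp(t_days, grid, mature.m[i])
    m_int = np.rint(m_at).astype(np.int64)
    counts = np.empty_like(m_int)
    for j in range(t_days.size):
        counts[:, j] = rng.binomial(m_int[:, j], schedule.eta[j])
    if clone_ids is None:
        width = len(str(max(mature.n_clones, 1)))
        clone_ids = [f"BC{idx:0{width}d}" for idx in range(mature.n_clones)]
    return SampleTable(clone_ids=clone_ids, times=schedule.times.copy(), counts=counts)


def expected_tagged_total(M, params: ModelParams) -> np.ndarray:
    """Expected tagged sample total S(t) = (H*/H) * eta * M(t).

    ``M`` is the whole-animal mature population including untagged cells.
    The companion all-cell variant is ``eta * M(t)`` (the data convention
    for sample totals differs between studies; both are linear in M).
    """
    return params.tagged_fraction * params.eta * np.asarray(M, dtype=float)


def expected_sample_total(M, params: ModelParams) -> np.ndarray:
    """All-cell variant of the expected sample total, eta * M(t)."""
    return params.eta * np.asarray(M, dtype=float)


def detection_probability(m, eta: float) -> np.ndarray:
    """Probability that a clone of whole-animal size m appears in a sample."""
    m = np.asarray(m, dtype=float)
    return -np.expm1(m * np.log1p(-eta)) if eta < 1 else (m > 0).astype(float)
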