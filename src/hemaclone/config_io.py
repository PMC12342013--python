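"""Clone-abundance tables, model configuration, and fit reports.

Conventions
-----------
* Sampling times are expressed in **months** in tables and schedules; all
  rates are **per day**.  Internally times convert at 1 month = 30 days
  (:data:`DAYS_PER_MONTH`).
* Count tables are TSV: first column ``barcode`` holds opaque clone labels,
  the remaining column headers are sampling times in months (decimals
  allowed, e.g. ``4.5``), and the body holds nonnegative integer counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.0


def months_to_days(t_months):
    """Convert sampling times in months to model time in days."""
    return np.asarray(t_months, dtype=float) * DAYS_PER_MONTH


def days_to_months(t_days):
    return np.asarray(t_days, dtype=float) / DAYS_PER_MONTH


# ---------------------------------------------------------------------------
# SampleTable
# ---------------------------------------------------------------------------


@dataclass
class SampleTable:
    """Clone x time matrix of sampled cell counts.

    Attributes
    ----------
    clone_ids : list of str
        Opaque barcode labels, one per row; must be unique.
    times : ndarray
        Sampling times in months, strictly increasing.
    counts : ndarray of int
        Shape ``(n_clones, n_times)``, entries >= 0.
    """

    clone_ids: list[str]
    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.size and not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64, copy=False)
        self.counts = self.counts.reshape(len(self.clone_ids), len(self.times))
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at clone {self.clone_ids[i]!r}, time {self.times[j]}"
            )
        if len(set(self.clone_ids)) != len(self.clone_ids):
            raise ValueError("duplicate clone_ids")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("sampling times must be strictly increasing")
        n_zero = int((self.counts.sum(axis=1) == 0).sum())
        if n_zero:
            logger.info("SampleTable contains %d all-zero clone rows", n_zero)

    # -- derived summaries --------------------------------------------------

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def times_days(self) -> np.ndarray:
        return months_to_days(self.times)

    @property
    def totals(self) -> np.ndarray:
        """Per-sample total tagged abundance S(t_j)."""
        return self.counts.sum(axis=0)

    @property
    def richness(self) -> np.ndarray:
        """Per-sample richness C_s(t_j): clones with count > 0."""
        return (self.counts > 0).sum(axis=0)

    def cumulative_richness(self, after_months: float = 2.0) -> int:
        """Number of distinct clones detected at any time > ``after_months``."""
        cols = self.times > after_months
        if not cols.any():
            return 0
        return int((self.counts[:, cols] > 0).any(axis=1).sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts,
            index=pd.Index(self.clone_ids, name="barcode"),
            columns=[format(t, "g") for t in self.times],
        )
        return df


def read_counts_table(path: str | Path, dialect: str = "tsv") -> SampleTable:
    """Read a clone-abundance table.

    The only built-in dialect is ``tsv`` (see module docstring).  Other
    layouts can be adapted by constructing :class:`SampleTable` directly.
    """
    if dialect != "tsv":
        raise ValueError(f"unknown table dialect {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0].lower() != "barcode":
        raise ValueError(
            f"malformed header: first column must be 'barcode', got {df.columns[0]!r}"
        )
    try:
        times = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"malformed header: non-numeric time column ({exc})") from exc
    clone_ids = df.iloc[:, 0].tolist()
    body = df.iloc[:, 1:]
    counts = np.zeros((len(clone_ids), len(times)), dtype=np.int64)
    for j, col in enumerate(body.columns):
        for i, raw in enumerate(body[col]):
            try:
                val = int(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-integer count {raw!r} at row {clone_ids[i]!r}, column {col!r}"
                ) from None
            if val < 0:
                raise ValueError(
                    f"negative count {val} at row {clone_ids[i]!r}, column {col!r}"
                )
            counts[i, j] = val
    return SampleTable(clone_ids=clone_ids, times=times, counts=counts)


def write_counts_table(table: SampleTable, path: str | Path) -> None:
    """Write a SampleTable as TSV (exact integer round-trip)."""
    table.to_frame().to_csv(Path(path), sep="\t")


# ---------------------------------------------------------------------------
# ModelParams
# ---------------------------------------------------------------------------


@dataclass
class ModelParams:
    """All rates and capacities of the clonal hematopoiesis model.

    Rates are per day.  ``hspc_init`` maps a progenitor generation ``l`` to
    the number of transplanted single-cell HSPC clones founded at that
    generation; keys must satisfy ``0 <= l <= L``.
    """

    r_h0: float = 0.08       # intrinsic HSC self-renewal rate
    mu_h: float = 0.02       # HSC death rate
    alpha: float = 0.016     # HSC (asymmetric) differentiation rate
    K: float = 2.5e5         # niche carrying capacity
    C_h0: int = 2500         # initial tagged HSC clone count
    h0_0: float | None = None  # untagged HSCs; default ties to tagged_fraction
    r_n: float = 2.0         # progenitor division rate
    mu_n: float = 0.0        # progenitor death rate
    omega: float = 0.2       # terminal differentiation rate
    L: int = 22              # proliferative potential (generations)
    mu_m: float = 0.185      # mature-cell turnover (granulocytes)
    eta: float = 1e-5        # mean sampling fraction
    eta_adjustments: list[float] | None = None  # per-time multipliers eta(t_j)/eta
    hspc_init: dict[int, int] = field(default_factory=dict)
    tagged_fraction: float = 0.35  # H*/H, the GFP+ fraction

    def __post_init__(self) -> None:
        if self.h0_0 is None:
            # h(0) = C_h0 / tagged_fraction, so untagged = C_h0 (1/f - 1)
            self.h0_0 = self.C_h0 * (1.0 / self.tagged_fraction - 1.0)
        self.hspc_init = {int(k): int(v) for k, v in self.hspc_init.items()}
        self.validate()

    def validate(self) -> None:
        checks = [
            (self.r_h0 >= 0, "r_h0 >= 0"),
            (self.mu_h >= 0, "mu_h >= 0"),
            (self.alpha >= 0, "alpha >= 0"),
            (self.K > 0, "K > 0"),
            (self.C_h0 >= 0, "C_h0 >= 0"),
            (self.h0_0 >= 0, "h0_0 >= 0"),
            (self.r_n > 0, "r_n > 0"),
            (self.mu_n >= 0, "mu_n >= 0"),
            (self.omega > 0, "omega > 0"),
            (self.L >= 1, "L >= 1"),
            (self.mu_m > 0, "mu_m > 0"),
            (0 < self.eta <= 1, "0 < eta <= 1"),
            (0 < self.tagged_fraction <= 1, "0 < tagged_fraction <= 1"),
        ]
        for ok, msg in checks:
            if not (ok and np.isfinite(
                [self.r_h0, self.mu_h, self.alpha, self.K, self.h0_0,
                 self.r_n, self.mu_n, self.omega, self.mu_m, self.eta]
            ).all()):
                raise ValueError(f"invalid ModelParams: requires {msg}")
        for l, c in self.hspc_init.items():
            if not (0 <= l <= self.L):
                raise ValueError(f"hspc_init generation {l} outside [0, L={self.L}]")
            if c < 0:
                raise ValueError("hspc_init counts must be >= 0")

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hspc_init"] = {str(k): v for k, v in self.hspc_init.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParams":
        d = dict(d)
        if "hspc_init" in d and d["hspc_init"]:
            d["hspc_init"] = {int(k): int(v) for k, v in d["hspc_init"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML config holding ModelParams, schedule, seeds and grids.

    Returns a dict with keys ``params`` (ModelParams), ``times_months``
    (list), ``seed`` (int) and ``fitting`` (dict, possibly empty).
    Missing keys fall back to the ZH33 defaults.
    """
    from .synthetic_data import make_preset  # local import, avoids cycle

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    default_params, default_schedule = make_preset("ZH33")
    params = (
        ModelParams.from_dict({**default_params.to_dict(), **raw.get("params", {})})
        if raw.get("params")
        else default_params
    )
    times = raw.get("times_months", list(default_schedule.times))
    return {
        "params": params,
        "times_months": [float(t) for t in times],
        "seed": int(raw.get("seed", 0)),
        "fitting": raw.get("fitting", {}),
    }


def save_config(config: Mapping, path: str | Path) -> None:
    out = dict(config)
    if isinstance(out.get("params"), ModelParams):
        out["params"] = out["params"].to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Fit reports
# ---------------------------------------------------------------------------


def write_fit_report(result, path: str | Path) -> None:
    """Serialize a FitResult to a JSON report.

    The report contains the full parameter estimate, per-stage candidate
    records and objectives, fitted sampling-fraction multipliers, the final
    EMD, the seeds used, and the package version.
    """
    from . import __version__

    payload = result.to_dict()
    payload["software_version"] = __version__
    try:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write fit report to {path}: {exc}") from exc


def read_fit_report(path: str | Path) -> dict:
    """Load a fit report; 'best_params' is reconstructed as ModelParams."""
    with open(path) as fh:
        payload = json.load(fh)
    payload["best_params"] = ModelParams.from_dict(payload["best_params"])
    return payload
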