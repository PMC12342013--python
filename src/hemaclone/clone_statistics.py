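"""Per-clone summary statistics and the clone-density estimate.

Each detected clone is summarized by the mean and population standard
deviation of its sampled abundances over a time window (zeros inside the
window count: a clone absent from a sample is a measured zero).  The local
clone density rho over (mean, SD) space is estimated with an isotropic
Gaussian KDE, by default in log10(1 + x) coordinates because clone sizes
span several decades.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KernelDensity

from .config_io import SampleTable

__all__ = ["CloneCloud", "KDEResult", "clone_summary", "kde_density"]

DEFAULT_WINDOW_MONTHS = 2.0  # post-transplant transient excluded by default


@dataclass
class CloneCloud:
    """Per-clone (mean, SD) records over a time window.

    ``density`` is filled by :func:`kde_density`.  ``J_effective`` is the
    number of time points inside the window (the divisor of mean and SD).
    """

    clone_ids: list[str]
    mean: np.ndarray
    sd: np.ndarray
    window: tuple[float, float]
    J_effective: int
    density: np.ndarray | None = field(default=None)

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.mean, self.sd])

    def to_frame(self):
        import pandas as pd

        d = {"clone_id": self.clone_ids, "mean": self.mean, "sd": self.sd}
        if self.density is not None:
            d["density"] = self.density
        return pd.DataFrame(d)


def clone_summary(
    table: SampleTable,
    window: tuple[float, float] | str = (DEFAULT_WINDOW_MONTHS, np.inf),
) -> CloneCloud:
    """Mean and population SD of each clone's sampled abundance.

    ``window`` is ``(lo, hi)`` in months selecting time points with
    ``lo < t_j <= hi``, or the string ``"all"``.  A clone enters the cloud
    if it was detected at least once inside the window; the mean and SD are
    taken over *all* windowed time points (divisor J, zeros included).
    """
    if window == "all":
        cols = np.ones(table.n_times, dtype=bool)
        window = (-np.inf, np.inf)
    else:
        lo, hi = window
        cols = (table.times > lo) & (table.times <= hi)
    J = int(cols.sum())
    if J < 2:
        raise ValueError(f"window {window} selects {J} < 2 time points")
    sub = table.counts[:, cols].astype(float)
    detected = (sub > 0).any(axis=1)
    sub = sub[detected]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1)  # population SD (divisor J)
    ids = [cid for cid, keep in zip(table.clone_ids, detected) if keep]
    return CloneCloud(clone_ids=ids, mean=mean, sd=sd,
                      window=(float(window[0]), float(window[1])), J_effective=J)


def transform_points(points: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log10p1":
        return np.log10(1.0 + points)
    if transform == "linear":
        return np.asarray(points, dtype=float)
    raise ValueError(f"unknown transform {transform!r}")


def silverman_bandwidth(X: np.ndarray) -> float:
    """Isotropic Silverman rule in d = 2: h = sigma_bar * n^{-1/6}."""
    n, d = X.shape
    sigma = X.std(axis=0, ddof=1).mean()
    factor = (4.0 / (d + 2.0)) ** (1.0 / (d + 4.0))  # = 1 at d = 2
    return float(sigma * factor * n ** (-1.0 / (d + 4.0)))


@dataclass
class KDEResult:
    """Evaluable clone-density estimate in transformed (mean, SD) space."""

    estimator: KernelDensity
    bandwidth: float
    transform: str
    max_density: float

    def density(self, mean, sd) -> np.ndarray:
        """Density (integrates to 1 over the transformed plane)."""
        pts = transform_points(np.column_stack([np.atleast_1d(mean),
                                                np.atleast_1d(sd)]), self.transform)
        return np.exp(self.estimator.score_samples(pts))

    def density_max_normalized(self, mean, sd) -> np.ndarray:
        """Density rescaled so its maximum over the cloud equals 1."""
        return self.density(mean, sd) / self.max_density


def kde_density(
    cloud: CloneCloud,
    bandwidth_rule: str | float = "silverman",
    transform: str = "log10p1",
) -> tuple[CloneCloud, KDEResult]:
    """Attach a local density rho_i to each clone of the cloud.

    An isotropic Gaussian KDE with a single common bandwidth (Silverman's
    rule by default, the usual stand-in for the MISE-optimal choice) is fit
    in transformed coordinates.  Returns the cloud (with ``density`` set)
    and the evaluable estimate.
    """
    if cloud.n_clones < 2:
        raise ValueError("need at least 2 clones for a density estimate")
    X = transform_points(cloud.points, transform)
    if isinstance(bandwidth_rule, (int, float)):
        bw = float(bandwidth_rule)
    elif bandwidth_rule == "silverman":
        bw = silverman_bandwidth(X)
    else:
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
    if bw <= 0:
        warnings.warn("degenerate clone cloud (all points identical); "
                      "density is a point mass")
        bw = 1e-9
    est = KernelDensity(kernel="gaussian", bandwidth=bw).fit(X)
    rho = np.exp(est.score_samples(X))
    cloud.density = rho
    return cloud, KDEResult(estimator=est, bandwidth=bw, transform=transform,
                            max_density=float(rho.max()))
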