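"""k-means compression of clone clouds and the Earth mover's distance.

Clone clouds from model and data have different sizes (clones go extinct,
sampling drops clones), so they are first compressed into ~k* weighted
cluster centers by k-means, with k* chosen where the discrete curvature of
the distortion (inertia) curve is maximal — the elbow.  Two weighted
cluster sets are then compared with the Earth mover's distance, the
minimal-cost transportation plan between the two unit-mass point sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .clone_statistics import CloneCloud, transform_points

__all__ = ["ClusterSet", "EMDResult", "kmeans_with_elbow", "earth_movers_distance"]


@dataclass
class ClusterSet:
    """Weighted cluster centers in (mean, SD) space (possibly transformed)."""

    centers: np.ndarray          # (k, 2)
    weights: np.ndarray          # (k,), sums to 1
    k: int
    inertia_curve: dict[int, float]
    transform: str = "log10p1"

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("cluster weights must be >= 0")
        s = self.weights.sum()
        if not np.isclose(s, 1.0):
            raise ValueError(f"cluster weights must sum to 1 (got {s})")
        if not np.isfinite(self.centers).all():
            raise ValueError("cluster centers must be finite")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "center_mean": self.centers[:, 0],
            "center_sd": self.centers[:, 1],
            "weight": self.weights,
        })


def select_elbow(ks: np.ndarray, distortion: np.ndarray) -> int:
    """k at maximal discrete curvature of the distortion curve.

    Both axes are normalized to [0, 1] so the curvature
    kappa = d2 / (1 + d1^2)^(3/2) is scale-free; endpoints are excluded
    (second derivatives there are one-sided).
    """
    if len(ks) < 3:
        raise ValueError("need at least 3 k values to locate an elbow")
    ks = np.asarray(ks, dtype=float)
    d = np.asarray(distortion, dtype=float)
    x = (ks - ks.min()) / max(ks.max() - ks.min(), 1e-300)
    y = d / max(d.max(), 1e-300)
    d1 = np.gradient(y, x)
    d2 = np.gradient(d1, x)
    curv = d2 / (1.0 + d1 ** 2) ** 1.5
    inner = slice(1, -1)
    return int(ks[inner][int(np.argmax(curv[inner]))])


def kmeans_with_elbow(
    cloud: CloneCloud,
    k_range=range(1, 16),
    seed: int = 0,
    transform: str = "log10p1",
    n_init: int = 10,
    k_override: int | None = None,
) -> ClusterSet:
    """Compress a clone cloud into weighted cluster centers.

    Runs k-means (k-means++ seeding, ``n_init`` restarts) for each candidate
    k, records the distortion score, selects k* at the elbow and returns the
    clustering at k* with weights equal to cluster occupancy fractions.
    """
    ks = np.array(sorted(set(int(k) for k in k_range)))
    if k_override is None and len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values for the elbow")
    if cloud.n_clones < ks.max():
        ks = ks[ks <= cloud.n_clones]
        if len(ks) < 3 and k_override is None:
            raise ValueError(
                f"cloud of {cloud.n_clones} points too small for k_range"
            )
    X = transform_points(cloud.points, transform)
    inertia: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in ks:
        km = KMeans(n_clusters=int(k), n_init=n_init, random_state=seed)
        km.fit(X)
        inertia[int(k)] = float(km.inertia_)
        fits[int(k)] = km
    k_star = int(k_override) if k_override is not None else select_elbow(
        ks, np.array([inertia[int(k)] for k in ks])
    )
    km = fits[k_star]
    weights = np.bincount(km.labels_, minlength=k_star) / cloud.n_clones
    return ClusterSet(centers=km.cluster_centers_, weights=weights, k=k_star,
                      inertia_curve=inertia, transform=transform)


@dataclass
class EMDResult:
    """Optimal transport distance and flow between two weighted point sets."""

    distance: float
    flow: np.ndarray

    def __post_init__(self) -> None:
        if self.distance < 0:
            # LP round-off can produce tiny negative values
            self.distance = max(self.distance, 0.0)


def earth_movers_distance(
    P: ClusterSet, Q: ClusterSet, metric: str = "euclidean"
) -> EMDResult:
    """Earth mover's distance between two equal-mass weighted cluster sets.

    Solves the transportation linear program
    ``min sum f_kl d_kl`` subject to ``f >= 0``, row sums equal to P's
    weights and column sums equal to Q's weights (weights renormalized to
    total mass 1).  The reported distance is the flow-weighted mean ground
    distance; since total flow is 1 this equals the LP optimum.
    """
    if P.transform != Q.transform:
        raise ValueError("cluster sets use different coordinate transforms")
    wp = P.weights / P.weights.sum()
    wq = Q.weights / Q.weights.sum()
    d = cdist(P.centers, Q.centers, metric=metric)
    k, l = d.shape
    # equality marginals; drop the last row constraint (redundant given
    # the column constraints sum to the same total mass)
    A_eq = []
    b_eq = []
    for i in range(k):
        row = np.zeros((k, l))
        row[i, :] = 1.0
        A_eq.append(row.ravel())
        b_eq.append(wp[i])
    for j in range(l):
        col = np.zeros((k, l))
        col[:, j] = 1.0
        A_eq.append(col.ravel())
        b_eq.append(wq[j])
    res = linprog(d.ravel(), A_eq=np.array(A_eq[:-1]), b_eq=np.array(b_eq[:-1]),
                  bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transportation LP infeasible: {res.message}")
    flow = res.x.reshape(k, l)
    flow[flow < 1e-12] = 0.0
    total = flow.sum()
    distance = float((flow * d).sum() / total) if total > 0 else 0.0
    return EMDResult(distance=distance, flow=flow)
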