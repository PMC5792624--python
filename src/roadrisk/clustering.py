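"""k-means clustering of mode-share profiles and share/rate correlations.

States are clustered on their commute mode-share vectors (proportions of
total commute distance by walk, cycle, 2W, car, IPT, bus, train). Because
shares are already commensurate proportions they are clustered
unstandardized. The number of clusters is chosen from the within-cluster
sum of squares (WSS) curve: the smallest k beyond which adding a cluster
no longer meaningfully reduces WSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

DEFAULT_RESTARTS = 50
DEFAULT_SEED = 20110301  # census reference date, 1 March 2011


@dataclass(frozen=True)
class ClusterResult:
    """k-means solution: 1-based labels, centroids and WSS decomposition."""

    k: int
    assignments: Mapping[str, int]  # unit_id -> label in 1..k
    centroids: np.ndarray  # shape (k, n_modes)
    wss: float
    per_cluster_wss: np.ndarray  # shape (k,)
    modes: tuple[str, ...]

    def members(self, label: int) -> list[str]:
        return [u for u, c in self.assignments.items() if c == label]


def _wss_decomposition(
    X: np.ndarray, labels: np.ndarray, centroids: np.ndarray
) -> np.ndarray:
    k = centroids.shape[0]
    per = np.zeros(k)
    for j in range(k):
        diff = X[labels == j] - centroids[j]
        per[j] = float((diff**2).sum())
    return per


def kmeans(
    shares: pd.DataFrame,
    k: int,
    seed: int = DEFAULT_SEED,
    restarts: int = DEFAULT_RESTARTS,
) -> ClusterResult:
    """Best-of-``restarts`` Lloyd k-means (k-means++ seeding) on share rows.

    Deterministic given ``seed``. Empty clusters arising during Lloyd
    updates are re-seeded from the point farthest from its centroid (the
    scikit-learn relocation rule).
    """
    X = np.asarray(shares, dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of units n={n}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        algorithm="lloyd",
        random_state=seed % (2**32),
    ).fit(X)
    labels = km.labels_
    per = _wss_decomposition(X, labels, km.cluster_centers_)
    return ClusterResult(
        k=k,
        assignments={u: int(c) + 1 for u, c in zip(shares.index, labels)},
        centroids=km.cluster_centers_.copy(),
        wss=float(per.sum()),
        per_cluster_wss=per,
        modes=tuple(shares.columns),
    )


def choose_k(
    shares: pd.DataFrame,
    k_range: Sequence[int] = range(1, 11),
    seed: int = DEFAULT_SEED,
    restarts: int = DEFAULT_RESTARTS,
    threshold: float = 0.01,
) -> tuple[int, dict[int, float]]:
    """Elbow selection of k from the WSS curve.

    Returns ``(k, curve)`` where ``curve`` maps each k in ``k_range`` to its
    best-of-restarts WSS. The chosen k is the smallest whose WSS reduction
    when moving to k+1 falls below ``threshold`` as a fraction of the total
    scatter (the WSS at the smallest k scanned); if no k qualifies, the
    largest scanned k is returned. To keep the curve monotone each k+1 run
    also tries a warm start built from the best k-solution's centroids plus
    its worst-fit point.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    X = np.asarray(shares, dtype=float)
    curve: dict[int, float] = {}
    results: dict[int, ClusterResult] = {}
    for k in ks:
        res = kmeans(shares, k, seed=seed, restarts=restarts)
        prev = results.get(k - 1)
        if prev is not None:
            # warm start: previous centroids + the point farthest from its own
            labels = np.array([prev.assignments[u] - 1 for u in shares.index])
            dist2 = ((X - prev.centroids[labels]) ** 2).sum(axis=1)
            init = np.vstack([prev.centroids, X[np.argmax(dist2)]])
            warm = KMeans(
                n_clusters=k, init=init, n_init=1, algorithm="lloyd"
            ).fit(X)
            if warm.inertia_ < res.wss:
                per = _wss_decomposition(X, warm.labels_, warm.cluster_centers_)
                res = ClusterResult(
                    k=k,
                    assignments={
                        u: int(c) + 1 for u, c in zip(shares.index, warm.labels_)
                    },
                    centroids=warm.cluster_centers_.copy(),
                    wss=float(per.sum()),
                    per_cluster_wss=per,
                    modes=tuple(shares.columns),
                )
        results[k] = res
        curve[k] = res.wss

    total = curve[ks[0]]
    if total <= 0:
        return ks[0], curve
    chosen = ks[-1]
    for k, k_next in zip(ks, ks[1:]):
        if (curve[k] - curve[k_next]) / total < threshold:
            chosen = k
            break
    return chosen, curve


def cluster_profile(
    result: ClusterResult, shares: pd.DataFrame, rates: pd.Series
) -> pd.DataFrame:
    """Per-cluster mean mode shares and median fatality rate.

    ``rates`` are deaths per 100,000 persons per year, indexed by unit_id.
    Medians of even-sized clusters are the mean of the central pair.
    """
    rows = []
    for label in range(1, result.k + 1):
        members = result.members(label)
        if not members:
            continue
        row = {"cluster": label, "n_units": len(members)}
        mean_shares = shares.loc[members].mean(axis=0)
        for m in shares.columns:
            row[f"share_{m}"] = float(mean_shares[m])
        row["median_rate"] = float(np.median(rates.loc[members]))
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


def share_rate_correlation(
    shares: pd.DataFrame, rates: pd.Series
) -> dict[str, float | None]:
    """Pearson correlation of each mode's share with the fatality rate.

    A constant share column has no defined correlation and is reported as
    ``None``.
    """
    if len(shares) < 3:
        raise ValueError("need at least 3 units for a correlation")
    r = {}
    y = np.asarray(rates.loc[shares.index], dtype=float)
    for m in shares.columns:
        x = np.asarray(shares[m], dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r[m] = None
        else:
            r[m] = float(stats.pearsonr(x, y).statistic)
    return r


__all__ = [
    "ClusterResult",
    "kmeans",
    "choose_k",
    "cluster_profile",
    "share_rate_correlation",
    "DEFAULT_RESTARTS",
    "DEFAULT_SEED",
]
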