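"""Pupil-based workload labeling.

Windows are clustered on their standardized pupil features with k-means.
The number of workload levels is chosen by scoring K = 2..k_max with two
curves — the Calinski–Harabasz index (between/within variance ratio,
larger is better) and the within-cluster sum of squares (cohesion, smaller
is better) — min–max normalizing both over the grid, and stopping at the
grid value where the rising CH curve meets the falling WSS curve. Cluster
stability is validated by the bootstrap Jaccard coefficient; levels are
numbered 1..K by ascending centroid pupil mean so "level" is semantically
monotone in workload.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .features import FEATURE_NAMES


@dataclass
class ClusteringReport:
    k_grid: list[int]
    ch_curve: list[float]
    wss_curve: list[float]
    k_selected: int
    centroids: np.ndarray
    labels: np.ndarray          # 1..K, ordered by ascending centroid mean
    jaccard: list[float] = field(default_factory=list)
    seed: int = 0
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "k_grid": list(map(int, self.k_grid)),
            "ch_curve": list(map(float, self.ch_curve)),
            "wss_curve": list(map(float, self.wss_curve)),
            "k_selected": int(self.k_selected),
            "centroids": np.asarray(self.centroids).tolist(),
            "jaccard": list(map(float, self.jaccard)),
            "seed": int(self.seed),
            "flags": list(self.flags),
        }


def kmeans(points: np.ndarray, k: int, seed: int,
           n_init: int = 10) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd's algorithm with restarts; returns (labels, centroids, wss)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < points.shape[1] and points.shape[0] == 1:
        points = points.T
    if k < 2:
        raise ValueError("K must be >= 2")
    if len(np.unique(points, axis=0)) < k:
        raise ValueError(f"fewer than {k} distinct points")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(points)
    return km.labels_, km.cluster_centers_, float(km.inertia_)


def wss(points: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster sum of squares of a given partition."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    total = 0.0
    for c in np.unique(labels):
        grp = points[labels == c]
        total += float(((grp - grp.mean(axis=0)) ** 2).sum())
    return total


def ch_index(points: np.ndarray, labels: np.ndarray) -> float:
    """Calinski–Harabasz: (B/(K−1)) / (W/(n−K)).

    B is the between-cluster and W the within-cluster sum of squares. The
    index is invariant to global translation and grows without bound as the
    within-cluster spread of a fixed separation shrinks.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    k = len(clusters)
    n = len(points)
    if k < 2:
        raise ValueError("need at least 2 clusters")
    overall = points.mean(axis=0)
    b = 0.0
    w = 0.0
    for c in clusters:
        grp = points[labels == c]
        if len(grp) == 0:
            raise ValueError(f"empty cluster {c}")
        cen = grp.mean(axis=0)
        b += len(grp) * float(((cen - overall) ** 2).sum())
        w += float(((grp - cen) ** 2).sum())
    if w == 0:
        return np.inf
    return (b / (k - 1)) / (w / (n - k))


def _minmax(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    span = v.max() - v.min()
    if span == 0:
        return np.zeros_like(v)
    return (v - v.min()) / span


def select_k(points: np.ndarray, k_grid: range | list[int] | None = None,
             seed: int = 0, n_init: int = 10) -> ClusteringReport:
    """CH/WSS intersection stop rule over a K grid.

    Both curves are min–max normalized over the grid; the normalized WSS
    curve starts at 1 and falls while the normalized CH curve rises as the
    partition quality improves, and the selected K is the smallest grid
    value at which the CH curve has reached or crossed the WSS curve (the
    grid point at the intersection; exact ties resolve to the smaller K).
    If the curves never cross, the K minimizing their gap is returned and
    flagged.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    if k_grid is None:
        k_grid = range(2, 11)
    k_grid = [int(k) for k in k_grid]

    ch_curve, wss_curve, fits = [], [], {}
    for k in k_grid:
        labels, cents, inertia = kmeans(points, k, seed, n_init)
        fits[k] = (labels, cents)
        wss_curve.append(inertia)
        ch_curve.append(ch_index(points, labels))

    chn = _minmax(np.array(ch_curve))
    wssn = _minmax(np.array(wss_curve))
    diff = chn - wssn
    flags: list[str] = []
    crossed = np.flatnonzero(diff >= 0)
    if len(crossed):
        k_selected = k_grid[int(crossed[0])]
    else:
        k_selected = k_grid[int(np.argmin(np.abs(diff)))]
        flags.append("curves_never_cross")
    if k_selected == k_grid[-1]:
        flags.append("boundary_selection")

    labels, cents = fits[k_selected]
    labels, cents = _canonical_order(labels, cents)
    return ClusteringReport(
        k_grid=k_grid, ch_curve=ch_curve, wss_curve=wss_curve,
        k_selected=k_selected, centroids=cents, labels=labels,
        seed=seed, flags=flags,
    )


def _canonical_order(labels: np.ndarray,
                     centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel clusters 1..K by ascending centroid mean (first coordinate)."""
    order = np.argsort(centroids[:, 0])
    remap = np.empty(len(order), dtype=int)
    remap[order] = np.arange(1, len(order) + 1)
    return remap[labels], centroids[order]


def bootstrap_jaccard(points: np.ndarray, k: int, n_boot: int = 100,
                      seed: int = 0, n_init: int = 10) -> np.ndarray:
    """Per-cluster stability: mean best-match Jaccard over bootstrap refits.

    For each resample the data are re-clustered and every original cluster
    is matched to the resample cluster maximizing the Jaccard overlap on
    the points the resample contains; the cluster's stability is the mean
    of those best overlaps. Values above ~0.85 indicate a highly stable
    cluster; below ~0.6, structure that the data do not support.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    rng = np.random.default_rng(seed)
    base_labels, _, _ = kmeans(points, k, seed, n_init)
    n = len(points)
    sums = np.zeros(k)
    counts = np.zeros(k)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        shared = np.unique(idx)
        try:
            boot_labels, _, _ = kmeans(points[idx], k, int(rng.integers(2 ** 31)),
                                       n_init)
        except ValueError:  # degenerate resample
            continue
        # labels of the shared points under the bootstrap clustering
        boot_of = {}
        for pos, point_i in enumerate(idx):
            boot_of.setdefault(point_i, boot_labels[pos])
        for c in range(k):
            orig = set(np.flatnonzero(base_labels == c)) & set(shared)
            if not orig:
                continue
            best = 0.0
            for d in range(k):
                boot_set = {i for i in shared if boot_of[i] == d}
                inter = len(orig & boot_set)
                union = len(orig | boot_set)
                if union:
                    best = max(best, inter / union)
            sums[c] += best
            counts[c] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)


def label_dataset(feature_table: pd.DataFrame, report: ClusteringReport) -> pd.DataFrame:
    """Attach cluster-derived workload levels (1..K) to the feature table."""
    if len(report.labels) != len(feature_table):
        raise ValueError("report labels do not match feature table length")
    out = feature_table.copy()
    out["level"] = report.labels
    return out


def cluster_pupil_windows(feature_table: pd.DataFrame, k_max: int = 10,
                          seed: int = 0, use_variance: bool = False,
                          n_boot: int = 100) -> ClusteringReport:
    """Pool all windows and cluster their standardized pupil features.

    By default only the mean pupil area is used (the variance feature can
    be included); features are standardized across the pooled windows so
    every participant contributes on the same scale.
    """
    cols = ["pupil_mean_area"] + (["pupil_var_area"] if use_variance else [])
    pts = feature_table[cols].to_numpy(float)
    valid = ~np.isnan(pts).any(axis=1)
    if not valid.all():
        raise ValueError("NaN pupil features; drop unusable windows first")
    pts = (pts - pts.mean(axis=0)) / pts.std(axis=0, ddof=1)
    report = select_k(pts, range(2, k_max + 1), seed=seed)
    report.jaccard = list(bootstrap_jaccard(pts, report.k_selected,
                                            n_boot=n_boot, seed=seed))
    return report
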