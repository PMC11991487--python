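"""Multi-start K-means, silhouette evaluation and silhouette-based reallocation.

The clustering geometry is Euclidean on the (Hellinger-transformed) analysis
matrix; cluster quality and reallocation use the Bray-Curtis dissimilarity,
mirroring the two-metric toolchain common in vegetation classification.

The K-means initializer draws, for every centroid, a small sample of distinct
plots and uses their mean as the starting centroid (``centroid_sample=5``),
repeated over ``n_starts=20`` independent starts; the best run by total
within-cluster sum of squares wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "SilhouetteReport",
    "kmeans_multistart",
    "silhouette_widths",
    "choose_k",
    "remos_reallocate",
    "order_groups",
]


@dataclass
class Partition:
    """Plot -> group assignment, labels contiguous 1..k, no empty group."""

    labels: pd.Series  # index: plot ids, values: int 1..k
    k: int
    wss: float = float("nan")
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(int)
        present = set(self.labels.unique())
        if present != set(range(1, self.k + 1)):
            raise ValueError(f"labels must cover 1..{self.k}, got {sorted(present)}")

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def relabel(self, mapping: dict[int, int]) -> "Partition":
        labels = self.labels.map(mapping)
        return Partition(labels, self.k, self.wss, dict(self.provenance))


@dataclass
class SilhouetteReport:
    widths: pd.Series  # per-plot s(i) in [-1, 1]
    group_means: pd.Series
    overall_mean: float


def _lloyd(X: np.ndarray, centroids: np.ndarray, max_iter: int) -> tuple[np.ndarray, float]:
    """Lloyd iterations to a fixed assignment; ties go to the lowest index.

    Empty clusters are reseeded from the plot farthest from its centroid.
    Returns (labels0, wss); asserts the WSS never increases between iterations.
    """
    k = centroids.shape[0]
    prev_labels = None
    prev_wss = np.inf
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)  # argmin takes the lowest index on ties
        for j in range(k):
            if not np.any(labels == j):
                farthest = int(np.argmax(d2[np.arange(len(X)), labels]))
                log.debug("empty cluster %d reseeded from plot %d", j, farthest)
                centroids[j] = X[farthest]
                labels[farthest] = j
                d2[:, j] = ((X - centroids[j]) ** 2).sum(axis=1)
        wss = float(((X - centroids[labels]) ** 2).sum())
        assert wss <= prev_wss + 1e-8, "WSS increased during Lloyd iteration"
        prev_wss = wss
        if prev_labels is not None and np.array_equal(labels, prev_labels):
            break
        prev_labels = labels
        for j in range(k):
            members = labels == j
            if members.any():  # empty clusters keep their centroid until reseeded
                centroids[j] = X[members].mean(axis=0)
    wss = float(((X - centroids[labels]) ** 2).sum())
    return labels, wss


def kmeans_multistart(
    X: pd.DataFrame,
    k: int,
    n_starts: int = 20,
    centroid_sample: int = 5,
    seed: int | None = None,
    max_iter: int = 300,
) -> Partition:
    """Best-of-``n_starts`` K-means on a numeric plot x feature matrix."""
    arr = X.to_numpy(dtype=float)
    n = arr.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of plots ({n})")
    rng = np.random.default_rng(seed)
    best_labels, best_wss = None, np.inf
    sample = min(centroid_sample, n)
    for start in range(n_starts):
        centroids = np.stack(
            [arr[rng.choice(n, size=sample, replace=False)].mean(axis=0) for _ in range(k)]
        )
        labels, wss = _lloyd(arr, centroids.copy(), max_iter)
        if wss < best_wss - 1e-12:
            best_labels, best_wss = labels, wss
    part = Partition(
        pd.Series(best_labels + 1, index=X.index, name="group"),
        k,
        best_wss,
        {"seed": seed, "n_starts": n_starts, "centroid_sample": centroid_sample},
    )
    return part


def _cluster_mean_dissimilarity(D: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """n x k matrix of mean dissimilarity of each plot to each cluster.

    For a plot's own cluster the self-distance is excluded from the mean;
    singleton own-cluster entries are NaN.
    """
    n = len(labels)
    sums = np.zeros((n, k))
    counts = np.zeros(k, dtype=int)
    for j in range(k):
        members = labels == j
        counts[j] = members.sum()
        sums[:, j] = D[:, members].sum(axis=1)
    means = np.empty((n, k))
    for j in range(k):
        denom = np.where(labels == j, counts[j] - 1, counts[j])
        with np.errstate(invalid="ignore", divide="ignore"):
            means[:, j] = np.where(denom > 0, sums[:, j] / np.maximum(denom, 1), np.nan)
    return means


def silhouette_widths(D: pd.DataFrame, labels: pd.Series) -> SilhouetteReport:
    """Silhouette widths s(i) = (b - a)/max(a, b) from a precomputed dissimilarity."""
    labels = labels.reindex(D.index)
    if labels.isna().any():
        raise ValueError("labels missing for some plots in the dissimilarity matrix")
    lab = labels.to_numpy(dtype=int)
    uniq = np.unique(lab)
    if len(uniq) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    remap = {g: j for j, g in enumerate(uniq)}
    lab0 = np.array([remap[g] for g in lab])
    k = len(uniq)
    means = _cluster_mean_dissimilarity(D.to_numpy(dtype=float), lab0, k)
    n = len(lab0)
    a = means[np.arange(n), lab0]
    other = means.copy()
    other[np.arange(n), lab0] = np.inf
    b = np.nanmin(other, axis=1)
    with np.errstate(invalid="ignore"):
        s = np.where(np.isnan(a), 0.0, (b - a) / np.maximum(a, b))  # singleton -> 0
    s = np.where(np.maximum(a, b) == 0, 0.0, s)
    widths = pd.Series(s, index=D.index, name="silhouette")
    gm = widths.groupby(labels).mean()
    return SilhouetteReport(widths, gm, float(widths.mean()))


def choose_k(
    X: pd.DataFrame,
    D: pd.DataFrame,
    k_range: range | list[int],
    seed: int | None = None,
    **kmeans_kwargs,
) -> tuple[int, pd.DataFrame]:
    """Scan k over ``k_range`` and pick the k maximizing the mean silhouette.

    Ties are broken toward the smaller k.  Returns (k*, per-k table with the
    mean silhouette width and the winning WSS).
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    if any(k < 2 or k >= len(X) for k in ks):
        raise ValueError("k range must lie within 2..n_plots-1")
    rows = []
    ss = np.random.SeedSequence(seed).spawn(len(ks))
    for k, sub in zip(ks, ss):
        part = kmeans_multistart(X, k, seed=int(sub.generate_state(1)[0] % 2**31), **kmeans_kwargs)
        rep = silhouette_widths(D, part.labels)
        rows.append({"k": k, "mean_silhouette": rep.overall_mean, "wss": part.wss})
    table = pd.DataFrame(rows).set_index("k")
    best = int(table["mean_silhouette"].idxmax())  # idxmax -> first (smallest) k on ties
    return best, table


def remos_reallocate(
    D: pd.DataFrame, partition: Partition, max_iter: int = 100
) -> tuple[Partition, list[dict]]:
    """Silhouette-based reallocation: iteratively move the worst-fitting plot.

    Each step moves the plot with the most negative silhouette width into the
    cluster with the smallest mean dissimilarity to it (its best a-value).
    Stops when no width is negative, when a partition repeats (cycle) or after
    ``max_iter`` steps.  A move that would empty a cluster is skipped.
    Returns the final partition and the move log.
    """
    if partition.k < 2:
        raise ValueError("reallocation requires k >= 2")
    labels = partition.labels.reindex(D.index).to_numpy(dtype=int) - 1
    k = partition.k
    Dm = D.to_numpy(dtype=float)
    moves: list[dict] = []
    seen = {labels.tobytes()}
    if max_iter == 0:
        log.warning("remos called with max_iter=0; returning input unchanged")
    for _ in range(max_iter):
        rep = silhouette_widths(D, pd.Series(labels + 1, index=D.index))
        widths = rep.widths.to_numpy()
        order = np.argsort(widths)  # most negative first
        moved = False
        for i in order:
            if widths[i] >= 0:
                break
            src = labels[i]
            if np.sum(labels == src) <= 1:
                log.debug("skip move of %s: would empty cluster %d", D.index[i], src + 1)
                continue
            means = _cluster_mean_dissimilarity(Dm, labels, k)[i]
            means[src] = np.inf
            dst = int(np.nanargmin(means))
            new = labels.copy()
            new[i] = dst
            key = new.tobytes()
            if key in seen:
                log.debug("cycle detected at plot %s; stopping", D.index[i])
                continue
            labels = new
            seen.add(key)
            moves.append({"plot": str(D.index[i]), "from": src + 1, "to": dst + 1, "width": float(widths[i])})
            moved = True
            break
        if not moved:
            break
    out = Partition(
        pd.Series(labels + 1, index=D.index, name="group"),
        k,
        partition.wss,
        {**partition.provenance, "remos_moves": len(moves)},
    )
    return out, moves


def order_groups(
    partition: Partition, meta: pd.DataFrame, rock_threshold: float = 50.0
) -> Partition:
    """Relabel groups ecologically: 1..m by decreasing mean depth, rocky groups last.

    Groups whose mean bare rock exceeds ``rock_threshold`` (%) are placed after
    all others (rock-crevice vegetation); the remainder are numbered by
    decreasing mean plot depth.  Equal means keep the original order (stable).
    """
    missing = sorted(set(partition.labels.index) - set(meta.index))
    if missing:
        raise ValueError(f"metadata missing for plot(s): {missing}")
    depth = meta["depth"].reindex(partition.labels.index)
    rock = meta["bare_rock"].reindex(partition.labels.index)
    stats = pd.DataFrame(
        {
            "depth": depth.groupby(partition.labels).mean(),
            "rock": rock.groupby(partition.labels).mean(),
        }
    )
    rocky = stats[stats["rock"] > rock_threshold]
    plain = stats[stats["rock"] <= rock_threshold]
    # mergesort is stable: equal depths keep original label order
    ordered = list(plain.sort_values("depth", ascending=False, kind="mergesort").index)
    ordered += list(rocky.sort_values("depth", ascending=False, kind="mergesort").index)
    mapping = {old: new for new, old in enumerate(ordered, start=1)}
    out = partition.relabel(mapping)
    out.provenance["group_order"] = mapping
    return out
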