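"""Angle-indexed series analysis: ED/DTW/c-DTW distances, DBA, k-means.

Angular profiles (density and per-bin mean residual) are treated as
multivariate series indexed by angle.  Series start at bin 0 (the drawing
start at the top of the star) and are warped as *linear* sequences — the
drawing has a defined start, so no circular alignment is attempted.

Distances: ED is the pointwise L2 distance; DTW is the classic optimal
warping cost with squared local cost (square root of the total reported);
c-DTW restricts the warping path to a Sakoe–Chiba band.  Barycenters use
the pointwise mean for ED and DTW-barycenter averaging (DBA) otherwise.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit

from .metrics import AngularProfile

__all__ = [
    "SeriesMatrix",
    "ClusterResult",
    "series_distance",
    "barycenter",
    "cluster_kmeans",
]

METRICS = ("ed", "dtw", "cdtw")


@dataclasses.dataclass
class SeriesMatrix:
    """Stack of drawings x bins x channels, with no missing bins."""

    data: np.ndarray
    channels: tuple[str, ...] = ("density", "mean_residual")

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("SeriesMatrix data must be (drawings, bins, channels)")
        if self.data.shape[2] != len(self.channels):
            raise ValueError("channel count mismatch")
        if np.isnan(self.data).any():
            raise ValueError("missing bins must be imputed before series analysis")

    @classmethod
    def from_profiles(cls, profiles: list[AngularProfile],
                      channels: tuple[str, ...] = ("density", "mean_residual")):
        """Stack profiles; NaN bins are filled by circular linear interpolation."""
        rows = []
        for p in profiles:
            chans = [_impute_circular(np.asarray(getattr(p, c), dtype=float))
                     for c in channels]
            rows.append(np.stack(chans, axis=1))
        return cls(data=np.stack(rows), channels=tuple(channels))

    def standardized(self) -> "SeriesMatrix":
        """Z-score each channel over all drawings and bins."""
        mu = self.data.mean(axis=(0, 1), keepdims=True)
        sd = self.data.std(axis=(0, 1), keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        return SeriesMatrix(data=(self.data - mu) / sd, channels=self.channels)

    @property
    def n_drawings(self) -> int:
        return self.data.shape[0]


def _impute_circular(v: np.ndarray) -> np.ndarray:
    bad = np.isnan(v)
    if not bad.any():
        return v
    if bad.all():
        raise ValueError("cannot impute an all-missing channel")
    n = len(v)
    xs = np.arange(n)
    out = v.copy()
    out[bad] = np.interp(xs[bad], xs[~bad], v[~bad], period=n)
    return out


@dataclasses.dataclass
class ClusterResult:
    """k-means output: labels in {1..k}, per-cluster barycenters, inertia."""

    labels: np.ndarray
    metric: str
    window: int | None
    seed: int
    n_init: int
    inertia: float
    barycenters: np.ndarray


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@njit(cache=True)
def _dtw_acc(a, b, window):
    la, lb = a.shape[0], b.shape[0]
    nc = a.shape[1]
    acc = np.full((la, lb), np.inf)
    for i in range(la):
        lo, hi = 0, lb - 1
        if window >= 0:
            lo = max(0, i - window)
            hi = min(lb - 1, i + window)
        for j in range(lo, hi + 1):
            d = 0.0
            for c in range(nc):
                diff = a[i, c] - b[j, c]
                d += diff * diff
            if i == 0 and j == 0:
                acc[i, j] = d
            else:
                best = np.inf
                if i > 0 and acc[i - 1, j] < best:
                    best = acc[i - 1, j]
                if j > 0 and acc[i, j - 1] < best:
                    best = acc[i, j - 1]
                if i > 0 and j > 0 and acc[i - 1, j - 1] < best:
                    best = acc[i - 1, j - 1]
                acc[i, j] = d + best
    return acc


@njit(cache=True)
def _dtw_path(acc):
    i = acc.shape[0] - 1
    j = acc.shape[1] - 1
    path = np.empty((i + j + 1, 2), dtype=np.int64)
    pos = 0
    path[pos, 0] = i
    path[pos, 1] = j
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            best = acc[i - 1, j - 1]
            move = 0
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
                move = 1
            if acc[i, j - 1] < best:
                move = 2
            if move == 0:
                i -= 1
                j -= 1
            elif move == 1:
                i -= 1
            else:
                j -= 1
        pos += 1
        path[pos, 0] = i
        path[pos, 1] = j
    return path[: pos + 1][::-1]


def _as_series(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError("a series must be 1-D or (bins, channels)")
    return a


def series_distance(a, b, metric: str = "dtw", window: int | None = None) -> float:
    """Distance between two equal-length multichannel series.

    ``window`` (in bins) is the Sakoe–Chiba radius for ``cdtw``; window 0
    admits only the diagonal path and therefore equals ED.
    """
    a, b = _as_series(a), _as_series(b)
    if a.shape != b.shape:
        raise ValueError(f"series shape mismatch: {a.shape} vs {b.shape}")
    metric = metric.lower()
    if metric == "ed":
        return float(np.sqrt(np.sum((a - b) ** 2)))
    if metric == "dtw":
        w = -1
    elif metric == "cdtw":
        if window is None or window < 0:
            raise ValueError("cdtw requires a non-negative window")
        w = int(window)
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    acc = _dtw_acc(np.ascontiguousarray(a), np.ascontiguousarray(b), w)
    return float(np.sqrt(acc[-1, -1]))


# ---------------------------------------------------------------------------
# Barycenters
# ---------------------------------------------------------------------------

def _dba_objective(series: np.ndarray, center: np.ndarray, w: int) -> float:
    return float(sum(series_distance(s, center,
                                     "dtw" if w < 0 else "cdtw",
                                     None if w < 0 else w) ** 2
                     for s in series))


def barycenter(series_set, metric: str = "dtw", window: int | None = None,
               max_iter: int = 20, init: np.ndarray | None = None) -> np.ndarray:
    """Average series minimizing the sum of squared metric distances.

    ED: the exact pointwise mean.  DTW/c-DTW: DBA iterations warm-started
    from ``init`` (or the pointwise mean), stopping as soon as the objective
    stops improving; the returned center never scores worse than the start.
    """
    series = np.asarray(series_set, dtype=float)
    if series.ndim == 2:
        series = series[:, :, None]
    if series.shape[0] == 0:
        raise ValueError("cannot average an empty series set")
    mean = series.mean(axis=0)
    metric = metric.lower()
    if metric == "ed":
        return mean
    w = -1 if metric == "dtw" else int(window if window is not None else 10)
    center = np.array(init, dtype=float) if init is not None else mean
    if center.ndim == 1:
        center = center[:, None]
    best = center
    best_obj = _dba_objective(series, center, w)
    for _ in range(max_iter):
        sums = np.zeros_like(center)
        counts = np.zeros(center.shape[0])
        for s in series:
            acc = _dtw_acc(np.ascontiguousarray(s),
                           np.ascontiguousarray(center), w)
            for i, j in _dtw_path(acc):
                sums[j] += s[i]
                counts[j] += 1
        counts = np.where(counts == 0, 1.0, counts)
        center = sums / counts[:, None]
        obj = _dba_objective(series, center, w)
        if obj >= best_obj - 1e-12:
            break
        best, best_obj = center, obj
    return best


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

def _kmeanspp_init(data, k, metric, window, rng):
    """k-means++ seeding: spread initial centers by squared-distance sampling."""
    n = data.shape[0]
    centers = [data[int(rng.integers(n))]]
    d2 = np.array([series_distance(x, centers[0], metric, window) ** 2
                   for x in data])
    while len(centers) < k:
        total = d2.sum()
        if total <= 0:
            centers.append(data[int(rng.integers(n))])
        else:
            nxt = int(rng.choice(n, p=d2 / total))
            centers.append(data[nxt])
            d2 = np.minimum(d2, [series_distance(x, centers[-1], metric,
                                                 window) ** 2 for x in data])
            continue
        d2 = np.minimum(d2, [series_distance(x, centers[-1], metric,
                                             window) ** 2 for x in data])
    return np.stack(centers)


def _pairwise_to_centers(data, centers, metric, window):
    n, k = data.shape[0], centers.shape[0]
    d = np.empty((n, k))
    for i in range(n):
        for j in range(k):
            d[i, j] = series_distance(data[i], centers[j], metric, window)
    return d


def cluster_kmeans(series, k: int, metric: str = "dtw",
                   window: int | None = None, seed: int = 0, n_init: int = 2,
                   max_iter: int = 50) -> ClusterResult:
    """k-means over series with the chosen metric and barycenter update.

    Deterministic for a fixed seed; the best of ``n_init`` restarts by
    inertia is returned.  A cluster emptied during iteration is re-seeded
    from the point farthest from its assigned center.
    """
    if isinstance(series, SeriesMatrix):
        data = series.data
    else:
        data = np.asarray(series, dtype=float)
        if data.ndim == 2:
            data = data[:, :, None]
    n = data.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of drawings ({n})")
    metric = metric.lower()
    if metric == "cdtw" and window is None:
        window = 10
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for restart in range(n_init):
        rng = np.random.default_rng(seed * 10007 + restart)
        centers = _kmeanspp_init(data, k, metric, window, rng)
        labels = np.full(n, -1)
        inertia = np.inf
        for _ in range(max_iter):
            d = _pairwise_to_centers(data, centers, metric, window)
            new_labels = d.argmin(axis=1)
            for c in range(k):
                if not (new_labels == c).any():
                    far = int(d.min(axis=1).argmax())
                    centers[c] = data[far]
                    new_labels[far] = c
            new_inertia = float(np.sum(d[np.arange(n), new_labels] ** 2))
            if (new_labels == labels).all():
                inertia = min(inertia, new_inertia)
                break
            labels, inertia = new_labels, new_inertia
            for c in range(k):
                members = data[labels == c]
                centers[c] = barycenter(members, metric, window,
                                        init=centers[c])
        d = _pairwise_to_centers(data, centers, metric, window)
        inertia = float(np.sum(d[np.arange(n), d.argmin(axis=1)] ** 2))
        labels = d.argmin(axis=1)
        if best is None or inertia < best[0]:
            best = (inertia, labels, centers.copy())
    inertia, labels, centers = best
    return ClusterResult(labels=labels + 1, metric=metric,
                         window=None if metric != "cdtw" else int(window),
                         seed=seed, n_init=n_init, inertia=inertia,
                         barycenters=centers)
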