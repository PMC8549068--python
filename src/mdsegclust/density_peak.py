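"""Length-weighted density-peak clustering of segments (or raw frames).

Each element gets a local density ρ (Gaussian kernel over its distances
to every other element, each neighbor weighted by its segment length in
frames) and a separation δ — the distance to its nearest neighbor of
higher density.  Cluster centroids are elements with both large ρ and
large δ; every other element joins the cluster of its nearest
higher-density neighbor in a single pass.  Segments carry their lengths
as weights so that a long metastable dwell dominates the density field
even when it is represented by a single element; in the point-based
control every frame is an element of weight 1 and pairwise distances are
generated blockwise on the fly, never materializing the full N×N matrix.

The kernel cutoff d_c is the average distance to the round(ln N)-th
nearest neighbor — a choice with k(N) → ∞ but k(N)/N → 0, keeping the
estimate both non-degenerate and local.  The classical alternative
(second percentile of the pooled distance list) is available for the
point-based control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .segments import Segment

__all__ = [
    "DensityPeakState",
    "compute_cutoff",
    "local_density",
    "compute_delta",
    "select_centroids",
    "assign_clusters",
    "halo_flags",
    "frames_from_segments",
    "cluster_segments",
    "point_mode_cluster",
    "decision_graph_table",
]


@dataclass(frozen=True)
class DensityPeakState:
    """Everything the decision graph and assignment depend on."""

    d_c: float
    rho: np.ndarray
    delta: np.ndarray
    nneigh: np.ndarray
    centroids: np.ndarray
    labels: np.ndarray
    halo: np.ndarray

    @property
    def gamma(self) -> np.ndarray:
        return self.rho * self.delta

    @property
    def n_clusters(self) -> int:
        return int(self.centroids.size)


# ---------------------------------------------------------------------------
# blockwise distance provider — shared by segment and point modes so that
# both use bit-identical ρ/δ/tie conventions
# ---------------------------------------------------------------------------

RowProvider = Callable[[int, int], np.ndarray]
"""Maps (lo, hi) to the (hi−lo)×N block of distance-matrix rows."""


def _matrix_rows(D: np.ndarray) -> RowProvider:
    return lambda lo, hi: D[lo:hi]


def _euclidean_rows(X: np.ndarray) -> RowProvider:
    return lambda lo, hi: cdist(X[lo:hi], X)


def _knn_cutoff(rows: RowProvider, n: int, block: int) -> float:
    k = int(np.clip(np.round(np.log(n)), 1, n - 1))
    total = 0.0
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        d = rows(lo, hi).copy()
        d[np.arange(hi - lo), np.arange(lo, hi)] = np.inf  # exclude self
        part = np.partition(d, k - 1, axis=1)[:, k - 1]
        total += part.sum()
    d_c = total / n
    if d_c <= 0:
        raise ValueError("degenerate geometry: all pairwise distances are zero")
    return float(d_c)


def compute_cutoff(D: np.ndarray) -> float:
    """Average distance to the round(ln N)-th nearest other element."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two elements")
    return _knn_cutoff(_matrix_rows(D), n, block=4096)


def local_density(D: np.ndarray, d_c: float, w: np.ndarray | None = None) -> np.ndarray:
    """Weighted Gaussian-kernel density: ρ_i = Σ_{j≠i} w_j·exp(−(D_ij/d_c)²)."""
    D = np.asarray(D, dtype=float)
    if d_c <= 0:
        raise ValueError("d_c must be positive")
    n = D.shape[0]
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    return _rho_blockwise(_matrix_rows(D), n, d_c, w, block=4096)


def _rho_blockwise(rows: RowProvider, n: int, d_c: float, w: np.ndarray, block: int) -> np.ndarray:
    rho = np.empty(n)
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        kern = np.exp(-((rows(lo, hi) / d_c) ** 2))
        kern[np.arange(hi - lo), np.arange(lo, hi)] = 0.0  # j ≠ i
        rho[lo:hi] = kern @ w
    return rho


def compute_delta(D: np.ndarray, rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distance (and index) of each element's nearest higher-density neighbor.

    Exact ρ ties are broken by index: of two equal densities, the higher
    index is treated as the lower density.  The single global maximum has
    no higher-density neighbor; it gets δ = max of its distance row and
    itself as the sentinel neighbor.
    """
    D = np.asarray(D, dtype=float)
    rho = np.asarray(rho, dtype=float)
    return _delta_blockwise(_matrix_rows(D), rho, block=4096)


def _delta_blockwise(rows: RowProvider, rho: np.ndarray, block: int) -> tuple[np.ndarray, np.ndarray]:
    n = rho.size
    idx = np.arange(n)
    delta = np.empty(n)
    nneigh = np.empty(n, dtype=np.int64)
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        d = rows(lo, hi)
        rb = rho[lo:hi, None]
        ib = idx[lo:hi, None]
        higher = (rho[None, :] > rb) | ((rho[None, :] == rb) & (idx[None, :] < ib))
        masked = np.where(higher, d, np.inf)
        jmin = np.argmin(masked, axis=1)  # ties → smallest index
        dmin = masked[np.arange(hi - lo), jmin]
        top = ~higher.any(axis=1)
        delta[lo:hi] = np.where(top, d.max(axis=1), dmin)
        nneigh[lo:hi] = np.where(top, idx[lo:hi], jmin)
    return delta, nneigh


def select_centroids(
    rho: np.ndarray,
    delta: np.ndarray,
    mode: str = "auto",
    manual_ids: Sequence[int] | None = None,
    rho_min: float | None = None,
    delta_min: float | None = None,
) -> np.ndarray:
    """Pick cluster centroids from the decision graph.

    auto      — rank elements by γ = ρ·δ descending and cut before the
                largest ratio γ_m/γ_{m+1} over m ∈ [1, N/2]; automates the
                visual "gap in ρ·δ" reading of the decision graph.  With
                no gap (all γ equal) a single centroid is returned.
    manual    — use ``manual_ids`` verbatim (the fidelity mode: what a
                human picked off the decision graph).
    threshold — the classical rectangular selection ρ > rho_min and
                δ > delta_min.
    """
    rho = np.asarray(rho, float)
    delta = np.asarray(delta, float)
    n = rho.size
    if mode == "manual":
        if manual_ids is None or len(manual_ids) == 0:
            raise ValueError("manual mode requires a non-empty id list")
        ids = np.asarray(manual_ids, dtype=np.int64)
        if np.unique(ids).size != ids.size:
            raise ValueError("duplicate centroid ids")
        if ids.min() < 0 or ids.max() >= n:
            raise ValueError("centroid id out of range")
        return ids
    if mode == "threshold":
        if rho_min is None or delta_min is None:
            raise ValueError("threshold mode requires rho_min and delta_min")
        ids = np.flatnonzero((rho > rho_min) & (delta > delta_min))
        if ids.size == 0:
            raise ValueError("threshold selection is empty")
        return ids
    if mode != "auto":
        raise ValueError(f"unknown centroid mode {mode!r}")
    gamma = rho * delta
    order = np.lexsort((np.arange(n), -gamma))  # γ desc, index asc on ties
    g = gamma[order]
    if n == 1:
        return order[:1].copy()
    m_max = max(1, n // 2)
    best_m, best_ratio = 1, -np.inf
    for m in range(1, m_max + 1):
        if m >= n:
            break
        hi, lo_ = g[m - 1], g[m]
        if hi <= 0:
            continue
        ratio = np.inf if lo_ <= 0 else hi / lo_
        if ratio > best_ratio:
            best_ratio = ratio
            best_m = m
    return np.sort(order[:best_m])


def assign_clusters(rho: np.ndarray, nneigh: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """One-pass assignment in descending density order.

    Centroid k keeps label k (order of the ``centroids`` array); every
    other element copies the label of its nearest higher-density
    neighbor, which is already labeled when reached.  The neighbor chain
    must terminate at a centroid for every element — the global density
    maximum carries a self-sentinel, so it must either be a centroid or
    have been redirected to one (see :func:`_redirect_orphan_peak`).
    """
    centroids = np.asarray(centroids, dtype=np.int64)
    if centroids.size == 0:
        raise ValueError("need at least one centroid")
    n = rho.size
    labels = np.full(n, -1, dtype=np.int64)
    labels[centroids] = np.arange(centroids.size)
    order = np.lexsort((np.arange(n), -np.asarray(rho, float)))  # ρ desc, index asc
    for i in order:
        if labels[i] < 0:
            labels[i] = labels[nneigh[i]]
    if np.any(labels < 0):
        raise ValueError(
            "neighbor chain does not reach a centroid; the global density "
            "maximum is not among the centroids and was not redirected"
        )
    return labels


def _redirect_orphan_peak(
    nneigh: np.ndarray, centroids: np.ndarray, dist_to_cents: Callable[[int], np.ndarray]
) -> np.ndarray:
    """Point the self-sentinel global peak at its nearest centroid.

    With manually chosen centroids the global density maximum may not be
    one of them; its assignment chain then has nowhere to go.  It joins
    the nearest centroid (ties by centroid list order).
    """
    n = nneigh.size
    sentinel = np.flatnonzero(nneigh == np.arange(n))
    out = nneigh.copy()
    for peak in sentinel:
        if peak not in centroids:
            d = dist_to_cents(int(peak))
            out[peak] = centroids[int(np.argmin(d))]
    return out


def halo_flags(
    D: np.ndarray,
    rho: np.ndarray,
    labels: np.ndarray,
    d_c: float,
    enabled: bool = True,
) -> np.ndarray:
    """Flag cluster members below their cluster's highest border density.

    An element is a border element if some element of another cluster
    lies within d_c.  Each cluster's border density is the maximum ρ over
    its border elements (0 if it has none); members below it are halo —
    assignments in the overlap zone that may be treated as noise.
    """
    labels = np.asarray(labels)
    n = labels.size
    if not enabled:
        return np.zeros(n, dtype=bool)
    D = np.asarray(D, float)
    rho = np.asarray(rho, float)
    other = labels[None, :] != labels[:, None]
    border = ((D < d_c) & other).any(axis=1)
    halo = np.zeros(n, dtype=bool)
    for c in np.unique(labels):
        members = labels == c
        b = members & border
        rho_b = rho[b].max() if b.any() else 0.0
        halo[members] = rho[members] < rho_b
    return halo


def frames_from_segments(
    labels: np.ndarray, halo: np.ndarray, segments: list[Segment]
) -> tuple[np.ndarray, np.ndarray]:
    """Broadcast per-segment labels and halo flags to per-frame arrays."""
    lengths = np.array([s.n for s in segments])
    frame_labels = np.repeat(np.asarray(labels), lengths)
    frame_halo = np.repeat(np.asarray(halo, bool), lengths)
    return frame_labels, frame_halo


def cluster_segments(
    D: np.ndarray,
    weights: np.ndarray | None = None,
    *,
    centroid_mode: str = "auto",
    manual_ids: Sequence[int] | None = None,
    rho_min: float | None = None,
    delta_min: float | None = None,
    halo: bool = False,
) -> DensityPeakState:
    """Full segment-mode pipeline: cutoff → ρ → δ → centroids → labels → halo."""
    D = np.asarray(D, float)
    d_c = compute_cutoff(D)
    rho = local_density(D, d_c, weights)
    delta, nneigh = compute_delta(D, rho)
    cents = select_centroids(rho, delta, centroid_mode, manual_ids, rho_min, delta_min)
    chain = _redirect_orphan_peak(nneigh, cents, lambda i: D[i, cents])
    labels = assign_clusters(rho, chain, cents)
    halo_arr = halo_flags(D, rho, labels, d_c, enabled=halo)
    return DensityPeakState(d_c, rho, delta, nneigh, cents, labels, halo_arr)


def point_mode_cluster(
    X: np.ndarray,
    *,
    d_c_rule: str = "knn",
    percentile: float = 2.0,
    subsample_stride: int = 1,
    centroid_mode: str = "auto",
    manual_ids: Sequence[int] | None = None,
    halo: bool = False,
    block: int = 2048,
) -> DensityPeakState:
    """Point-based control: every frame is an element of weight 1.

    Pairwise Euclidean distances are generated blockwise on demand; the
    full N×N matrix is never allocated.  ``d_c_rule`` is either "knn"
    (the round(ln N)-neighbor rule) or "percentile" (the classical
    second-percentile rule, evaluated on the distance list of a
    subsampled trajectory to keep it tractable).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise ValueError("X must be frames × dimensions")
    n = X.shape[0]
    rows = _euclidean_rows(X)
    if d_c_rule == "knn":
        d_c = _knn_cutoff(rows, n, block)
    elif d_c_rule == "percentile":
        sub = X[::subsample_stride]
        d = cdist(sub, sub)[np.triu_indices(sub.shape[0], k=1)]
        if d.size == 0:
            raise ValueError("subsample too aggressive: no pairwise distances")
        d_c = float(np.percentile(d, percentile))
        if d_c <= 0:
            positive = d[d > 0]
            if positive.size == 0:
                raise ValueError("degenerate geometry: all pairwise distances are zero")
            d_c = float(positive.min())
    else:
        raise ValueError(f"unknown d_c rule {d_c_rule!r}")
    w = np.ones(n)
    rho = _rho_blockwise(rows, n, d_c, w, block)
    delta, nneigh = _delta_blockwise(rows, rho, block)
    cents = select_centroids(rho, delta, centroid_mode, manual_ids)
    chain = _redirect_orphan_peak(nneigh, cents, lambda i: rows(i, i + 1)[0, cents])
    labels = assign_clusters(rho, chain, cents)
    if halo:
        D = cdist(X, X) if n <= 4096 else None
        if D is None:
            raise NotImplementedError("halo control in point mode requires n ≤ 4096")
        halo_arr = halo_flags(D, rho, labels, d_c, enabled=True)
    else:
        halo_arr = np.zeros(n, dtype=bool)
    return DensityPeakState(d_c, rho, delta, nneigh, cents, labels, halo_arr)


def decision_graph_table(state: DensityPeakState):
    """Decision-graph table (id, rho, delta, gamma), sorted by gamma desc."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "id": np.arange(state.rho.size),
            "rho": state.rho,
            "delta": state.delta,
            "gamma": state.gamma,
        }
    )
    return df.sort_values("gamma", ascending=False, kind="mergesort").reset_index(drop=True)
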