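"""Trajectory segmentation and earth mover's distances between segments.

Change times cut the trajectory into segments; each segment is summarized
as a *signature* — a normalized weighted point mass in observable space
(total mass exactly 1).  The distance between two segments is the earth
mover's distance (1-Wasserstein): the minimum cost of transporting one
signature into the other, where cost is mass moved times Euclidean ground
distance.  Unlike overlap-based divergences (Jensen–Shannon,
Kullback–Leibler) the EMD stays continuous when supports are disjoint —
a signature shifted by θ is exactly |θ| away — which is what makes it a
usable geometry for metastable states that overlap only partially.

The transport problem is solved exactly: in one dimension by the
closed-form quantile coupling, in higher dimensions as a linear program
(HiGHS).  Both routes give the true optimum; the closed form is simply
the d = 1 specialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.spatial.distance import cdist
from scipy.stats import wasserstein_distance

from .changepoint import ChangePointSet
from .timeseries import TimeSeries

__all__ = [
    "Segment",
    "SegmentSignature",
    "segment_trajectory",
    "build_signature",
    "emd",
    "pairwise_distances",
    "segment_table",
]

_MASS_TOL = 1e-9


@dataclass(frozen=True)
class Segment:
    """A half-open frame range [start, end) with per-dimension means."""

    id: int
    start: int
    end: int
    mean: np.ndarray

    @property
    def n(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentSignature:
    """Normalized weighted point mass: support points and masses summing to 1."""

    support: np.ndarray  # (m, d)
    mass: np.ndarray  # (m,)

    def __post_init__(self) -> None:
        support = np.atleast_2d(np.asarray(self.support, dtype=float))
        mass = np.asarray(self.mass, dtype=float).ravel()
        if support.shape[0] != mass.size:
            raise ValueError("support/mass length mismatch")
        if not np.all(np.isfinite(support)):
            raise ValueError("support points must be finite")
        if np.any(mass < 0):
            raise ValueError("masses must be non-negative")
        if abs(mass.sum() - 1.0) > _MASS_TOL:
            raise ValueError(f"signature mass sums to {mass.sum()}, expected 1")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "mass", mass)

    @property
    def n_dims(self) -> int:
        return self.support.shape[1]


def segment_trajectory(series: TimeSeries, S: ChangePointSet) -> list[Segment]:
    """Cut the trajectory at the union of per-dimension change times.

    Boundaries are {0} ∪ union_times ∪ {T}; consecutive boundaries define
    half-open segments tiling [0, T).  Means are taken on the (already
    unwrapped) values.
    """
    T = series.n_frames
    if S.n_frames != T:
        raise ValueError("change-point set was built for a different length")
    bounds = np.concatenate(([0], S.union_times, [T]))
    segments = []
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        segments.append(
            Segment(id=i, start=int(a), end=int(b), mean=series.values[a:b].mean(axis=0))
        )
    return segments


def build_signature(
    values: np.ndarray,
    max_support: int = 256,
    bin_width: float | np.ndarray | None = None,
) -> SegmentSignature:
    """Length-normalize a segment's n×d values into a unit-mass signature.

    Default mode uses the raw frames, mass 1/n each; if the segment is
    longer than ``max_support`` it is thinned deterministically (every
    k-th frame in time order) and renormalized.  With ``bin_width`` a
    sparse histogram is built instead: occupied bin centers with mass
    proportional to occupancy — useful for very long segments.
    """
    if max_support < 1:
        raise ValueError("max_support must be ≥ 1")
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.ndim != 2 or values.shape[0] < 1:
        raise ValueError("segment values must be a non-empty n×d matrix")
    n, d = values.shape
    if bin_width is not None:
        widths = np.broadcast_to(np.asarray(bin_width, dtype=float), (d,))
        if np.any(widths <= 0):
            raise ValueError("bin widths must be positive")
        bins = np.floor(values / widths).astype(np.int64)
        uniq, counts = np.unique(bins, axis=0, return_counts=True)
        support = (uniq + 0.5) * widths
        mass = counts / n
    else:
        support, mass = values, np.full(n, 1.0 / n)
    if support.shape[0] > max_support:
        k = int(np.ceil(support.shape[0] / max_support))
        support = support[::k]
        mass = mass[::k]
        mass = mass / mass.sum()
    return SegmentSignature(support=support, mass=mass)


# ---------------------------------------------------------------------------
# earth mover's distance
# ---------------------------------------------------------------------------


def _check_normalized(sig: SegmentSignature, name: str) -> None:
    if abs(sig.mass.sum() - 1.0) > _MASS_TOL:
        raise ValueError(f"signature {name} is not normalized")


def _emd_lp(P: SegmentSignature, Q: SegmentSignature) -> float:
    """Exact transportation LP: min Σ f_ij·d_ij s.t. marginals P, Q, f ≥ 0."""
    D = cdist(P.support, Q.support)
    n, m = D.shape
    # equality constraints: n row sums + m column sums (last one redundant)
    cols_idx = np.arange(n * m).reshape(n, m)
    data_rows = np.zeros((n + m - 1, n * m))
    for i in range(n):
        data_rows[i, cols_idx[i, :]] = 1.0
    for j in range(m - 1):
        data_rows[n + j, cols_idx[:, j]] = 1.0
    b_eq = np.concatenate([P.mass, Q.mass[:-1]])
    res = linprog(D.ravel(), A_eq=data_rows, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def emd(P: SegmentSignature, Q: SegmentSignature, *, force_lp: bool = False) -> float:
    """Earth mover's distance between two unit-mass signatures.

    Euclidean ground distance between support points.  One-dimensional
    signatures are solved by the exact closed-form quantile coupling;
    higher dimensions by the exact transportation linear program
    (``force_lp=True`` routes 1-D inputs through the LP as well, e.g. for
    cross-validation).
    """
    _check_normalized(P, "P")
    _check_normalized(Q, "Q")
    if P.n_dims != Q.n_dims:
        raise ValueError("signatures have different dimensionality")
    if P.n_dims == 1 and not force_lp:
        return float(
            wasserstein_distance(P.support[:, 0], Q.support[:, 0], P.mass, Q.mass)
        )
    return _emd_lp(P, Q)


def pairwise_distances(signatures: list[SegmentSignature]) -> np.ndarray:
    """Symmetric zero-diagonal matrix of pairwise EMDs (N(N−1)/2 solves)."""
    N = len(signatures)
    if N < 2:
        raise ValueError("need at least two signatures")
    D = np.zeros((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            try:
                D[i, j] = D[j, i] = emd(signatures[i], signatures[j])
            except Exception as exc:  # pragma: no cover - solver failures are rare
                raise RuntimeError(f"EMD failed for segment pair ({i}, {j}): {exc}") from exc
    return D


def segment_table(segments: list[Segment], dim_names=None):
    """Segments as a tidy table: id, start, end, length, per-dimension means."""
    import pandas as pd

    d = segments[0].mean.size if segments else 0
    names = list(dim_names) if dim_names is not None else [f"x{j}" for j in range(d)]
    rows = []
    for s in segments:
        row = {"id": s.id, "start": s.start, "end": s.end, "length": s.n}
        for j, nm in enumerate(names):
            row[f"mean_{nm}"] = s.mean[j]
        rows.append(row)
    return pd.DataFrame(rows)
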