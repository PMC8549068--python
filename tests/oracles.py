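"""Independent reference implementations used to validate the package.

Everything here is deliberately naive — literal enumeration, double
loops, generic LP/assignment solvers — and shares no code with the
implementation paths it checks.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist


# ---------------------------------------------------------------------------
# change detection: exhaustive enumeration of admissible change-point sets
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def admissible_sets(T: int, min_len: int) -> tuple[tuple[int, ...], ...]:
    """All strictly increasing change sets in [1, T−1] with segments ≥ min_len."""
    out: list[tuple[int, ...]] = [()]

    def rec(prefix: tuple[int, ...], last: int) -> None:
        for t in range(last + min_len, T - min_len + 1):
            out.append(prefix + (t,))
            rec(prefix + (t,), t)

    rec((), 0)
    return tuple(out)


def naive_laplace(x: np.ndarray, floor: float) -> float:
    mu = np.median(x)
    dev = np.abs(x - mu).sum()
    b = max(dev / x.size, floor)
    return -x.size * np.log(2 * b) - dev / b


def segment_cost_table(x: np.ndarray, min_len: int, floor: float) -> dict:
    T = x.size
    return {
        (a, b): naive_laplace(x[a:b], floor)
        for a in range(T)
        for b in range(a + min_len, T + 1)
    }


def set_loglik(costs: dict, cps: tuple[int, ...], T: int) -> float:
    bounds = (0,) + cps + (T,)
    return sum(costs[(a, b)] for a, b in zip(bounds[:-1], bounds[1:]))


def exhaustive_max_objective(values: np.ndarray, lam: float, alpha: float, min_len: int, floor: float) -> float:
    """Exhaustively enumerate per-dimension change sets; exact for d ≤ 2."""
    values = np.atleast_2d(values.T).T
    T, d = values.shape
    sets = admissible_sets(T, min_len)
    costs = [segment_cost_table(values[:, j], min_len, floor) for j in range(d)]
    logliks = [
        np.array([set_loglik(costs[j], s, T) for s in sets]) for j in range(d)
    ]
    if d == 1:
        pen = lam * np.array([len(s) for s in sets], dtype=float)
        return float(np.max(logliks[0] - pen))
    if d == 2:
        best = -np.inf
        for i, s1 in enumerate(sets):
            for j, s2 in enumerate(sets):
                both = set(s1) & set(s2)
                pen = lam * (
                    (len(s1) - len(both)) + (len(s2) - len(both)) + len(both) * 2**alpha
                )
                v = logliks[0][i] + logliks[1][j] - pen
                if v > best:
                    best = v
        return float(best)
    raise NotImplementedError("oracle supports d ≤ 2")


# ---------------------------------------------------------------------------
# transport oracles
# ---------------------------------------------------------------------------


def emd_1d_closed_form(xs, ws, ys, wt) -> float:
    """1-D EMD as the area between the two weighted empirical CDFs."""
    xs, ws, ys, wt = map(np.asarray, (xs, ws, ys, wt))
    pts = np.unique(np.concatenate([xs, ys]))

    def cdf(points, weights):
        return np.array([weights[points <= p].sum() for p in pts])

    F = cdf(xs, ws / ws.sum())
    G = cdf(ys, wt / wt.sum())
    return float(np.sum(np.abs(F - G)[:-1] * np.diff(pts)))


def emd_assignment(A: np.ndarray, B: np.ndarray) -> float:
    """EMD of two equal-count uniform point clouds via optimal assignment."""
    D = cdist(A, B)
    r, c = linear_sum_assignment(D)
    return float(D[r, c].sum() / A.shape[0])


# ---------------------------------------------------------------------------
# density-peak oracles (literal double loops)
# ---------------------------------------------------------------------------


def naive_rho(D: np.ndarray, d_c: float, w: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    rho = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if j != i:
                rho[i] += w[j] * np.exp(-((D[i, j] / d_c) ** 2))
    return rho


def higher_density(rho: np.ndarray, i: int, j: int) -> bool:
    return rho[j] > rho[i] or (rho[j] == rho[i] and j < i)


def naive_delta(D: np.ndarray, rho: np.ndarray):
    n = rho.size
    delta = np.zeros(n)
    nneigh = np.zeros(n, dtype=int)
    for i in range(n):
        best, barg = np.inf, -1
        for j in range(n):
            if j != i and higher_density(rho, i, j):
                if D[i, j] < best:
                    best, barg = D[i, j], j
        if barg < 0:
            delta[i] = D[i].max()
            nneigh[i] = i
        else:
            delta[i], nneigh[i] = best, barg
    return delta, nneigh


def naive_cutoff(D: np.ndarray) -> float:
    n = D.shape[0]
    k = int(min(max(round(np.log(n)), 1), n - 1))
    dists = []
    for i in range(n):
        row = sorted(D[i, j] for j in range(n) if j != i)
        dists.append(row[k - 1])
    return float(np.mean(dists))


def resolve_labels_recursive(nneigh: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Follow nearest-higher-density pointers until a centroid is reached."""
    n = nneigh.size
    labels = np.full(n, -1, dtype=int)
    cent_label = {int(c): k for k, c in enumerate(centroids)}

    def resolve(i: int) -> int:
        if i in cent_label:
            return cent_label[i]
        return resolve(int(nneigh[i]))

    for i in range(n):
        labels[i] = resolve(i)
    return labels
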