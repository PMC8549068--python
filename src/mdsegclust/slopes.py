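"""Transition-segment detection by testing the slope of each segment.

A metastable dwell is a flat segment: samples scattered around a constant
mean.  When the sampling rate is finer than the time scale of a
conformational change, the detector also emits segments that *span* the
change — ramps connecting two plateaus.  Those are identified with an
ordinary least-squares slope test: under a flat normal null the fitted
slope is normally distributed around zero with standard deviation

    σ_slope = σ / sqrt(Σ_i (i − ī)²)

where σ is the residual standard deviation (n−2 degrees of freedom).
A segment is declared sloped when |slope| > 1.96·σ_slope, the two-sided
normal 5% rule.  For a multivariate segment, rejection in any one
dimension flags the segment; no multiple-testing correction is applied
across dimensions, so at d dimensions the per-segment false-positive
rate inflates toward 1 − 0.95^d (reported in the output, not corrected).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .segments import Segment
from .timeseries import TimeSeries

__all__ = ["SlopeResult", "SlopeReport", "slope_test", "slope_test_batch", "classify_segments"]

DEFAULT_LEVEL_Z = 1.96  # two-sided normal 5% critical value


class SlopeResult(NamedTuple):
    slope: float
    sigma_slope: float
    z: float
    sloped: bool


@dataclass(frozen=True)
class SlopeReport:
    """Per-(segment, dimension) slope statistics plus per-segment verdicts."""

    table: pd.DataFrame  # columns: segment_id, dim, slope, sigma_slope, z, sloped
    segment_sloped: np.ndarray  # per-segment any-dimension verdict
    testable: np.ndarray  # False where n < 3

    def sloped_segment_ids(self) -> np.ndarray:
        return np.flatnonzero(self.segment_sloped)


def slope_test_batch(X: np.ndarray, level_z: float = DEFAULT_LEVEL_Z):
    """Vectorized slope test over the rows of an m×n matrix of segments.

    Returns (slope, sigma_slope, z, sloped) arrays of length m.  Rows are
    regressed against the frame index 0..n−1; the residual standard
    deviation uses the n−2 regression denominator.  A zero-residual
    perfect ramp has σ_slope = 0 and is sloped whenever its slope is
    nonzero; a constant row has slope 0 and is not sloped.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m, n = X.shape
    if n < 3:
        raise ValueError(f"slope test needs n ≥ 3 frames, got {n}")
    t = np.arange(n, dtype=float)
    tc = t - t.mean()
    sxx = float(np.sum(tc**2))
    xc = X - X.mean(axis=1, keepdims=True)
    slope = (xc @ tc) / sxx
    resid = xc - slope[:, None] * tc[None, :]
    ssr = np.sum(resid**2, axis=1)
    sigma = np.sqrt(np.maximum(ssr, 0.0) / (n - 2))
    sigma_slope = sigma / np.sqrt(sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            sigma_slope > 0,
            np.abs(slope) / np.where(sigma_slope > 0, sigma_slope, 1.0),
            np.where(slope != 0, np.inf, 0.0),
        )
    sloped = z > level_z
    return slope, sigma_slope, z, sloped


def slope_test(x: np.ndarray, level_z: float = DEFAULT_LEVEL_Z) -> SlopeResult:
    """OLS slope test of a single 1-D segment against the flat null."""
    x = np.asarray(x, dtype=float).ravel()
    slope, sig, z, sloped = slope_test_batch(x[None, :], level_z)
    return SlopeResult(float(slope[0]), float(sig[0]), float(z[0]), bool(sloped[0]))


def classify_segments(
    segments: list[Segment],
    series: TimeSeries,
    level_z: float = DEFAULT_LEVEL_Z,
) -> SlopeReport:
    """Run the slope test on every segment and dimension.

    A segment is sloped if any dimension rejects the flat null.  Segments
    shorter than 3 frames cannot be tested and are reported untestable,
    never sloped.
    """
    n_seg = len(segments)
    d = series.n_dims
    rows = []
    seg_sloped = np.zeros(n_seg, dtype=bool)
    testable = np.ones(n_seg, dtype=bool)
    for k, seg in enumerate(segments):
        vals = series.values[seg.start : seg.end]
        if seg.n < 3:
            testable[k] = False
            for j in range(d):
                rows.append(
                    {
                        "segment_id": seg.id,
                        "dim": series.dim_names[j],
                        "slope": np.nan,
                        "sigma_slope": np.nan,
                        "z": np.nan,
                        "sloped": False,
                    }
                )
            continue
        slope, sig, z, sloped = slope_test_batch(vals.T, level_z)
        seg_sloped[k] = bool(sloped.any())
        for j in range(d):
            rows.append(
                {
                    "segment_id": seg.id,
                    "dim": series.dim_names[j],
                    "slope": slope[j],
                    "sigma_slope": sig[j],
                    "z": z[j],
                    "sloped": bool(sloped[j]),
                }
            )
    table = pd.DataFrame(
        rows, columns=["segment_id", "dim", "slope", "sigma_slope", "z", "sloped"]
    )
    return SlopeReport(table=table, segment_sloped=seg_sloped, testable=testable)
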