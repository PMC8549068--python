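"""Multivariate trajectory container, periodic unwrapping, subsampling and text I/O.

A trajectory is a T×d real matrix: one row per frame, one column per
observable (typically backbone dihedral angles in degrees).  Angular
observables live on a circle, so a physically tiny move across the
periodic boundary (179° → −179°) looks like a 358° jump in raw
coordinates.  :func:`unwrap_periodic` removes these artifacts by shifting
each periodic dimension so that consecutive differences always lie within
half a period — the standard preprocessing step before change detection.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "ParseError",
    "unwrap_periodic",
    "subsample",
    "read_series",
    "write_series",
]


class ParseError(ValueError):
    """Raised when a trajectory file cannot be parsed; carries the row number."""


@dataclass(frozen=True)
class TimeSeries:
    """A T×d multivariate time series with per-dimension periodicity metadata.

    Parameters
    ----------
    values : ndarray, shape (T, d)
        Observable values, one row per frame.  Must be finite.
    dt : float
        Sampling interval between consecutive frames (informational).
    dim_names : sequence of str
        One label per dimension.
    periodic : sequence of bool
        Whether each dimension lives on a circle.
    period : sequence of float
        Period of each periodic dimension (e.g. 360 for dihedral angles in
        degrees).  Ignored, but must still be positive, where ``periodic``
        is false.
    """

    values: np.ndarray
    dt: float = 1.0
    dim_names: tuple[str, ...] = ()
    periodic: np.ndarray = field(default=None)  # type: ignore[assignment]
    period: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D (frames × dimensions) array")
        if values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("need at least one frame and one dimension")
        if not np.all(np.isfinite(values)):
            raise ValueError("values contain non-finite entries")
        d = values.shape[1]
        names = tuple(self.dim_names) if self.dim_names else tuple(
            f"x{i}" for i in range(d)
        )
        if len(names) != d:
            raise ValueError(f"{len(names)} dim_names for {d} dimensions")
        periodic = (
            np.zeros(d, dtype=bool)
            if self.periodic is None
            else np.asarray(self.periodic, dtype=bool)
        )
        period = (
            np.full(d, 360.0)
            if self.period is None
            else np.asarray(self.period, dtype=float)
        )
        if periodic.shape != (d,) or period.shape != (d,):
            raise ValueError("periodic/period must have one entry per dimension")
        if np.any(period[periodic] <= 0):
            raise ValueError("period must be positive where periodic")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "dim_names", names)
        object.__setattr__(self, "periodic", periodic)
        object.__setattr__(self, "period", period)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]


def _wrap_halfopen(diffs: np.ndarray, period: float) -> np.ndarray:
    """Map differences into the half-open interval (−P/2, P/2].

    A difference of exactly +P/2 or −P/2 maps to +P/2 (deterministic ties).
    The rounding step can land a hair outside the interval for inputs within
    one ulp of the boundary; a correction pass enforces the postcondition.
    """
    k = np.ceil(diffs / period - 0.5)
    out = diffs - period * k
    out = np.where(out > period / 2, out - period, out)
    out = np.where(out <= -period / 2, out + period, out)
    return out


def unwrap_periodic(series: TimeSeries) -> TimeSeries:
    """Shift periodic dimensions so consecutive jumps never exceed half a period.

    The first frame is kept verbatim; every later frame is shifted by an
    integer number of periods so that each consecutive difference lies in
    (−P/2, P/2].  The output is congruent to the input modulo the period,
    elementwise.  Non-periodic dimensions are returned unchanged.
    """
    out = series.values.copy()
    for j in np.flatnonzero(series.periodic):
        p = series.period[j]
        d = np.diff(series.values[:, j])
        out[1:, j] = series.values[0, j] + np.cumsum(_wrap_halfopen(d, p))
    return replace(series, values=out)


def subsample(series: TimeSeries, stride: int) -> TimeSeries:
    """Keep frames 0, stride, 2·stride, … and scale ``dt`` by the stride.

    Applied *after* unwrapping: subsampling a wrapped angular series can
    manufacture spurious boundary crossings.
    """
    if not isinstance(stride, (int, np.integer)) or stride < 1:
        raise ValueError(f"stride must be a positive integer, got {stride!r}")
    return replace(series, values=series.values[::stride], dt=series.dt * stride)


# ---------------------------------------------------------------------------
# text I/O — delimited files, header row, full-precision round trip
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","


def read_series(
    path: str | Path,
    *,
    periodic: Sequence[bool] | None = None,
    period: Sequence[float] | None = None,
    dt: float = 1.0,
    delimiter: str | None = None,
) -> TimeSeries:
    """Read a delimited trajectory (header row of dimension names).

    Periodicity is metadata supplied by the caller, not stored in the file.
    Raises :class:`ParseError` naming the offending 1-based data row on
    ragged rows, non-numeric cells or non-finite values.
    """
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        d = len(header)
        rows: list[list[float]] = []
        for rownum, row in enumerate(reader, start=1):
            if len(row) != d:
                raise ParseError(
                    f"{path}: row {rownum} has {len(row)} fields, expected {d}"
                )
            try:
                vals = [float(c) for c in row]
            except ValueError:
                bad = next(c for c in row if not _is_float(c))
                raise ParseError(
                    f"{path}: row {rownum}: non-numeric cell {bad!r}"
                ) from None
            if not all(np.isfinite(vals)):
                raise ParseError(f"{path}: row {rownum}: non-finite value")
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    if periodic is not None and len(periodic) != d:
        raise ParseError(
            f"{path}: config declares {len(periodic)} dimensions, file has {d}"
        )
    return TimeSeries(
        values=np.array(rows, dtype=float),
        dt=dt,
        dim_names=tuple(header),
        periodic=None if periodic is None else np.asarray(periodic, bool),
        period=None if period is None else np.asarray(period, float),
    )


def _is_float(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def write_series(series: TimeSeries, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a trajectory as delimited text with full-precision decimals.

    Uses ``repr``-style shortest round-trip formatting so that
    ``read_series(write_series(x)) == x`` exactly.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(series.dim_names)
        for row in series.values:
            writer.writerow([repr(float(v)) for v in row])
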