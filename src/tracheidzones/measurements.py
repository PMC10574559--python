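"""Per-cell tracheid measurements: I/O, validation, tracheidogram handling.

A *tracheidogram* is the ordered sequence of cell traits (radial diameter D
and cell wall thickness CWT) along one radial file of tracheids across a
tree ring.  Rings are measured in several radial rows; rows are resampled
("normalized") to a common cell count and averaged position-wise to remove
random row-to-row differences.  Traits are then standardized (indexed) by
their dataset means, and the slope angle phi_i = arctan(CWT_i / D_i) is the
working coordinate for zonation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellMeasurement",
    "Tracheidogram",
    "IndexedCell",
    "DatasetSummary",
    "BinnedHistogram",
    "SchemaError",
    "ValidationError",
    "read_measurements",
    "write_measurements",
    "cells_to_frame",
    "frame_to_cells",
    "resample_profile",
    "normalize_row",
    "average_rows",
    "build_tracheidograms",
    "standardize",
    "compute_slope_angle",
    "bin_histogram",
]

#: canonical CSV column names
COLUMNS = ["tree_id", "year", "row_id", "rank", "D_um", "CWT_um"]


class SchemaError(ValueError):
    """Input table is missing required columns or is otherwise malformed."""


class ValidationError(ValueError):
    """A record violates the geometric constraints on tracheid traits."""


@dataclass(frozen=True)
class CellMeasurement:
    """One tracheid with positional context.

    ``rank`` counts from the ring's inner border: rank 1 is the
    first-formed cell of the season.
    """

    tree_id: str
    year: int
    row_id: int
    rank: int
    D: float
    CWT: float

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise ValidationError(f"D must be positive, got {self.D!r} ({self._where()})")
        if not self.CWT > 0:
            raise ValidationError(f"CWT must be positive, got {self.CWT!r} ({self._where()})")
        if not self.CWT / self.D < 0.5:
            raise ValidationError(
                f"CWT/D = {self.CWT / self.D:.4g} >= 0.5 implies non-positive lumen "
                f"(D={self.D}, CWT={self.CWT}, {self._where()})"
            )

    def _where(self) -> str:
        return f"tree={self.tree_id} year={self.year} row={self.row_id} rank={self.rank}"

    @property
    def lumen(self) -> float:
        """Radial lumen diameter L = D - 2*CWT."""
        return self.D - 2.0 * self.CWT

    @property
    def ratio(self) -> float:
        return self.CWT / self.D

    @property
    def phi(self) -> float:
        """Slope angle arctan(CWT/D) in degrees."""
        return compute_slope_angle(self.ratio)


@dataclass(frozen=True)
class Tracheidogram:
    """Ordered per-ring trait sequences, typically after row averaging."""

    tree_id: str
    year: int
    D_seq: np.ndarray
    CWT_seq: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.D_seq, dtype=float)
        w = np.asarray(self.CWT_seq, dtype=float)
        object.__setattr__(self, "D_seq", d)
        object.__setattr__(self, "CWT_seq", w)
        if d.ndim != 1 or d.size < 1 or d.shape != w.shape:
            raise ValidationError("D_seq and CWT_seq must be equal-length 1-D sequences of length >= 1")
        if not (np.all(d > 0) and np.all(w > 0) and np.all(w / d < 0.5)):
            raise ValidationError(
                f"tracheidogram tree={self.tree_id} year={self.year} violates 0 < CWT/D < 0.5"
            )

    @property
    def n_cells(self) -> int:
        return int(self.D_seq.size)


@dataclass(frozen=True)
class IndexedCell:
    """Standardized traits of one cell: D_i = D/mean(D), CWT_i = CWT/mean(CWT)."""

    D_i: float
    CWT_i: float

    @property
    def ratio(self) -> float:
        return self.CWT_i / self.D_i

    @property
    def phi_i(self) -> float:
        return compute_slope_angle(self.ratio)


@dataclass
class DatasetSummary:
    """Counts and per-trait mean (min-max) statistics for a dataset."""

    n_trees: int
    n_rings: int
    n_cells_raw: int
    n_cells_averaged: int | None
    traits: pd.DataFrame = field(repr=False)  # index: trait name; cols: mean, min, max

    def to_frame(self) -> pd.DataFrame:
        head = pd.DataFrame(
            {"mean": [self.n_trees, self.n_rings, self.n_cells_raw, self.n_cells_averaged]},
            index=["trees", "rings", "cells_raw", "cells_averaged"],
            dtype=float,
        )
        return pd.concat([head, self.traits])


@dataclass(frozen=True)
class BinnedHistogram:
    """Equal-width histogram with left-closed right-open bins.

    ``lower_edges`` are the lower boundaries of the bins (the labels used
    on plot axes); ``densities`` are counts normalized to sum to 1, i.e.
    probability per bin, not per unit.
    """

    lower_edges: np.ndarray
    width: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.lower_edges, dtype=float)
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "lower_edges", e)
        object.__setattr__(self, "counts", c)
        if e.ndim != 1 or e.size != c.size or e.size < 1:
            raise ValueError("edges and counts must be 1-D and of equal length")
        if e.size > 1 and not np.allclose(np.diff(e), self.width, rtol=0, atol=1e-9 * self.width):
            raise ValueError("lower_edges must be equally spaced by width")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def densities(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def centers(self) -> np.ndarray:
        return self.lower_edges + 0.5 * self.width

    @property
    def upper_edges(self) -> np.ndarray:
        return self.lower_edges + self.width


# ---------------------------------------------------------------------------
# I/O

def read_measurements(path: str | Path, delimiter: str = ",") -> list[CellMeasurement]:
    """Read per-cell measurements from a delimited text file.

    The file must have a header naming (at least) the columns
    ``tree_id, year, row_id, rank, D_um, CWT_um``.  Records failing the
    geometric constraints (D, CWT > 0 and CWT/D < 1/2) raise
    :class:`ValidationError` naming the offending cell.
    """
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")
    return frame_to_cells(df)


def write_measurements(cells: Iterable[CellMeasurement], path: str | Path, delimiter: str = ",") -> None:
    cells_to_frame(cells).to_csv(path, sep=delimiter, index=False)


def cells_to_frame(cells: Iterable[CellMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.tree_id, c.year, c.row_id, c.rank, c.D, c.CWT) for c in cells],
        columns=COLUMNS,
    )


def frame_to_cells(df: pd.DataFrame) -> list[CellMeasurement]:
    """Convert a measurement table to validated cells, ordered by rank within groups."""
    df = df.sort_values(["tree_id", "year", "row_id", "rank"], kind="stable")
    cells = [
        CellMeasurement(
            tree_id=str(r.tree_id), year=int(r.year), row_id=int(r.row_id),
            rank=int(r.rank), D=float(r.D_um), CWT=float(r.CWT_um),
        )
        for r in df.itertuples(index=False)
    ]
    for (tree, year, row), grp in _groupby(cells):
        ranks = [c.rank for c in grp]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValidationError(
                f"ranks in tree={tree} year={year} row={row} are not consecutive from 1: {ranks[:8]}..."
            )
    return cells


def _groupby(cells: Sequence[CellMeasurement]):
    out: dict[tuple, list[CellMeasurement]] = {}
    for c in cells:
        out.setdefault((c.tree_id, c.year, c.row_id), []).append(c)
    return out.items()


# ---------------------------------------------------------------------------
# Tracheidogram normalization and averaging

def resample_profile(values: Sequence[float], target_n: int) -> np.ndarray:
    """Stretch or compress an ordered trait sequence to ``target_n`` cells.

    Each of the ``n`` input cells is treated as an interval of width 1/n on
    [0, 1]; each output cell of width 1/target_n takes the overlap-weighted
    average of the input values covering its interval.  This conserves
    values exactly for constant rows, never extrapolates outside the input
    range, and is the identity when ``target_n == n``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("values must be a non-empty 1-D sequence")
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    n, m = v.size, int(target_n)
    if m == n:
        return v.copy()
    in_edges = np.arange(n + 1) / n
    out = np.empty(m)
    for j in range(m):
        lo, hi = j / m, (j + 1) / m
        left = np.maximum(in_edges[:-1], lo)
        right = np.minimum(in_edges[1:], hi)
        w = np.clip(right - left, 0.0, None)
        out[j] = np.dot(w, v) / w.sum()
    return out


def normalize_row(row: Sequence[CellMeasurement] | Tracheidogram, target_n: int) -> Tracheidogram:
    """Normalize one radial row to ``target_n`` cells (see :func:`resample_profile`)."""
    if isinstance(row, Tracheidogram):
        tree, year, d, w = row.tree_id, row.year, row.D_seq, row.CWT_seq
    else:
        row = list(row)
        if not row:
            raise ValueError("empty row")
        tree, year = row[0].tree_id, row[0].year
        d = np.array([c.D for c in row])
        w = np.array([c.CWT for c in row])
    return Tracheidogram(tree, year, resample_profile(d, target_n), resample_profile(w, target_n))


def average_rows(rows: Sequence[Tracheidogram]) -> Tracheidogram:
    """Position-wise arithmetic mean of normalized rows of equal length."""
    if not rows:
        raise ValueError("no rows to average")
    n = rows[0].n_cells
    if any(r.n_cells != n for r in rows):
        raise ValueError(f"row lengths differ: {[r.n_cells for r in rows]}")
    d = np.mean([r.D_seq for r in rows], axis=0)
    w = np.mean([r.CWT_seq for r in rows], axis=0)
    return Tracheidogram(rows[0].tree_id, rows[0].year, d, w)


def build_tracheidograms(cells: Sequence[CellMeasurement]) -> list[Tracheidogram]:
    """Full per-ring pipeline: normalize every row to the ring's mean cell
    count (rounded half-up) and average the rows."""
    rings: dict[tuple, dict[int, list[CellMeasurement]]] = {}
    for c in cells:
        rings.setdefault((c.tree_id, c.year), {}).setdefault(c.row_id, []).append(c)
    out = []
    for (tree, year), rows in sorted(rings.items()):
        lengths = [len(r) for r in rows.values()]
        target = int(np.floor(np.mean(lengths) + 0.5))  # round half-up
        normed = [normalize_row(sorted(r, key=lambda c: c.rank), target) for r in rows.values()]
        out.append(average_rows(normed))
    return out


# ---------------------------------------------------------------------------
# Standardization and slope angles

def compute_slope_angle(ratio: float | np.ndarray) -> float | np.ndarray:
    """Slope angle phi = arctan(ratio) in degrees; defined for ratio > 0."""
    r = np.asarray(ratio, dtype=float)
    if np.any(r <= 0):
        raise ValueError("ratio must be positive")
    out = np.degrees(np.arctan(r))
    return float(out) if np.isscalar(ratio) or out.ndim == 0 else out


def standardize(
    cells: Sequence[CellMeasurement] | pd.DataFrame,
    *,
    n_cells_averaged: int | None = None,
) -> tuple[pd.DataFrame, DatasetSummary]:
    """Index traits by their dataset means and compute slope angles.

    Returns a DataFrame with columns ``tree_id, year, D, CWT, ratio, phi,
    D_i, CWT_i, ratio_i, phi_i`` plus a :class:`DatasetSummary`.  By
    construction mean(D_i) = mean(CWT_i) = 1.
    """
    if isinstance(cells, pd.DataFrame):
        df = cells.rename(columns={"D_um": "D", "CWT_um": "CWT"}).copy()
    else:
        cells = list(cells)
        if not cells:
            raise ValueError("empty dataset")
        df = pd.DataFrame(
            {
                "tree_id": [c.tree_id for c in cells],
                "year": [c.year for c in cells],
                "D": [c.D for c in cells],
                "CWT": [c.CWT for c in cells],
            }
        )
    if len(df) == 0:
        raise ValueError("empty dataset")
    d_mean = float(df["D"].mean())
    cwt_mean = float(df["CWT"].mean())
    df["ratio"] = df["CWT"] / df["D"]
    df["phi"] = np.degrees(np.arctan(df["ratio"]))
    df["D_i"] = df["D"] / d_mean
    df["CWT_i"] = df["CWT"] / cwt_mean
    df["ratio_i"] = df["CWT_i"] / df["D_i"]
    df["phi_i"] = np.degrees(np.arctan(df["ratio_i"]))

    traits = pd.DataFrame(
        {
            "mean": df[["D", "CWT", "ratio", "phi", "D_i", "CWT_i", "ratio_i", "phi_i"]].mean(),
            "min": df[["D", "CWT", "ratio", "phi", "D_i", "CWT_i", "ratio_i", "phi_i"]].min(),
            "max": df[["D", "CWT", "ratio", "phi", "D_i", "CWT_i", "ratio_i", "phi_i"]].max(),
        }
    )
    n_rings = df.groupby(["tree_id", "year"]).ngroups if "year" in df else 0
    summary = DatasetSummary(
        n_trees=df["tree_id"].nunique() if "tree_id" in df else 0,
        n_rings=n_rings,
        n_cells_raw=len(df),
        n_cells_averaged=n_cells_averaged,
        traits=traits,
    )
    summary.d_mean = d_mean  # type: ignore[attr-defined]
    summary.cwt_mean = cwt_mean  # type: ignore[attr-defined]
    return df, summary


def bin_histogram(values: Sequence[float], width: float, origin: float = 0.0) -> BinnedHistogram:
    """Histogram with left-closed right-open equal-width bins anchored at
    ``origin``; bin labels are the lower bin boundaries."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to bin")
    if width <= 0:
        raise ValueError("width must be positive")
    idx = np.floor((v - origin) / width).astype(int)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    edges = origin + np.arange(lo, hi + 1) * width
    return BinnedHistogram(lower_edges=edges, width=float(width), counts=counts)
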