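"""Domain containers and CSV input/output for community phenology data.

A community phenology is a set of species-level intensity time series
(counts of calling males, numbers of open flowers, trap captures, ...)
recorded on a shared, evenly spaced time grid. Two tabular layouts are
supported:

* wide  — first column is time, one column per species;
* long  — three columns ``time,species,value``.

Values must be nonnegative. Missing cells are allowed: they are stored
as zeros and flagged in a per-species gap report, because the wavelet
smoothing stage is the intended gap-filling mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeGrid",
    "PhenologyCurve",
    "CommunityPhenology",
    "OverlapDistanceMatrix",
    "GridError",
    "ParseError",
    "DuplicationError",
    "read_community",
    "write_matrix",
]

#: Relative tolerance on the constancy of the time step.
GRID_SPACING_RTOL = 1e-9


class GridError(ValueError):
    """Raised when sampling times do not form a valid regular grid."""


class ParseError(ValueError):
    """Raised when a table cell cannot be interpreted as a nonnegative number."""


class DuplicationError(ValueError):
    """Raised when a (time, species) pair occurs more than once in long layout."""


@dataclass(frozen=True)
class TimeGrid:
    """Ordered, evenly spaced sampling times shared by all curves."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or t.size < 2:
            raise GridError("a time grid needs at least 2 one-dimensional sampling times")
        diffs = np.diff(t)
        if np.any(diffs <= 0):
            raise GridError("sampling times must be strictly increasing")
        step = diffs[0]
        if np.any(np.abs(diffs - step) > GRID_SPACING_RTOL * max(abs(step), 1.0) + GRID_SPACING_RTOL * np.abs(diffs)):
            raise GridError(
                "sampling times are not evenly spaced "
                f"(step varies between {diffs.min():g} and {diffs.max():g})"
            )

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return int(self.times.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeGrid):
            return NotImplemented
        return self.times.shape == other.times.shape and bool(np.array_equal(self.times, other.times))


@dataclass(frozen=True)
class PhenologyCurve:
    """One species' intensity trajectory on a time grid.

    ``stage`` records whether the curve is raw field data or the output
    of wavelet smoothing; smoothed curves are guaranteed nonnegative.
    """

    species_id: str
    values: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.stage not in ("raw", "smoothed"):
            raise ValueError(f"stage must be 'raw' or 'smoothed', got {self.stage!r}")
        if self.stage == "smoothed" and np.any(v < 0):
            raise ValueError(f"smoothed curve {self.species_id!r} has negative values")


@dataclass(frozen=True)
class CommunityPhenology:
    """S phenology curves on a common time grid, in fixed species order."""

    grid: TimeGrid
    curves: tuple[PhenologyCurve, ...]
    gap_report: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "curves", tuple(self.curves))
        n = len(self.grid)
        labels = [c.species_id for c in self.curves]
        if len(set(labels)) != len(labels):
            dupes = sorted({s for s in labels if labels.count(s) > 1})
            raise ValueError(f"duplicate species labels: {dupes}")
        for c in self.curves:
            if c.values.size != n:
                raise ValueError(
                    f"curve {c.species_id!r} has {c.values.size} values but the grid has {n} points"
                )

    @property
    def S(self) -> int:
        return len(self.curves)

    @property
    def species(self) -> list[str]:
        return [c.species_id for c in self.curves]

    def matrix(self) -> np.ndarray:
        """Stack curve values into an (S, T) array in species order."""
        return np.vstack([c.values for c in self.curves])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({c.species_id: c.values for c in self.curves})
        df.insert(0, "time", self.grid.times)
        return df


@dataclass(frozen=True)
class OverlapDistanceMatrix:
    """Symmetric S x S matrix of pairwise curve-overlap distances in [0, 1]."""

    values: np.ndarray
    species: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "species", tuple(self.species))
        s = len(self.species)
        if v.shape != (s, s):
            raise ValueError(f"matrix shape {v.shape} does not match {s} species")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be exactly 0")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise ValueError("distance matrix is not symmetric")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("distances must lie in [0, 1]")

    @property
    def S(self) -> int:
        return len(self.species)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.species), columns=list(self.species))


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _check_nonnegative(df: pd.DataFrame, value_cols: list[str]) -> None:
    for col in value_cols:
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, data row {row}"
            )
        neg = series < 0
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0])
            raise ParseError(
                f"negative intensity {series.iloc[row]!r} in column {col!r}, data row {row}"
            )


def read_community(path, layout: str = "wide", stage: str = "raw") -> CommunityPhenology:
    """Read a community phenology table from CSV.

    Parameters
    ----------
    path : str or path-like
        CSV file with a header row.
    layout : {"wide", "long"}
        ``wide``: first column time, remaining columns one species each.
        ``long``: columns ``time, species, value``.
    stage : {"raw", "smoothed"}
        Stage flag assigned to the curves read (a file of already
        wavelet-transformed curves should be read with ``stage="smoothed"``).

    Missing cells are filled with 0 and recorded in the returned
    community's ``gap_report`` (species label -> list of gap times).
    """
    if layout not in ("wide", "long"):
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    if layout == "long":
        expected = ["time", "species", "value"]
        if list(df.columns[:3]) != expected:
            raise ParseError(f"long layout requires columns {expected}, got {list(df.columns)}")
        dup = df.duplicated(subset=["time", "species"], keep=False)
        if dup.any():
            first = df.loc[dup, ["time", "species"]].iloc[0]
            raise DuplicationError(
                f"duplicate (time, species) pair: ({first['time']}, {first['species']})"
            )
        _check_nonnegative(df, ["value"])
        wide = df.pivot(index="time", columns="species", values="value")
        # preserve first-appearance order of species, as in the file
        order = list(dict.fromkeys(df["species"]))
        wide = wide.reindex(columns=order).reset_index()
    else:
        wide = df
        _check_nonnegative(wide, list(wide.columns[1:]))

    time_col = wide.columns[0]
    times = pd.to_numeric(wide[time_col], errors="coerce")
    if times.isna().any():
        row = int(np.flatnonzero(times.isna().to_numpy())[0])
        raise ParseError(f"non-numeric time {wide[time_col].iloc[row]!r} at data row {row}")
    grid = TimeGrid(times.to_numpy(dtype=float))

    curves: list[PhenologyCurve] = []
    gaps: dict[str, list[float]] = {}
    for col in wide.columns[1:]:
        vals = pd.to_numeric(wide[col], errors="coerce")
        missing = vals.isna()
        if missing.any():
            gaps[str(col)] = [float(t) for t in grid.times[missing.to_numpy()]]
        curves.append(PhenologyCurve(str(col), vals.fillna(0.0).to_numpy(dtype=float), stage=stage))
    if not curves:
        raise ParseError("no species columns found")
    return CommunityPhenology(grid, tuple(curves), gap_report=gaps)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_matrix(m, path) -> None:
    """Write a community (wide layout) or a distance matrix to CSV.

    Floating point values are written with 17 significant digits so that
    a write/read round trip is exact.
    """
    if isinstance(m, CommunityPhenology):
        if m.S == 0:
            raise ValueError("refusing to write an empty community")
        df = m.to_frame()
        df.to_csv(path, index=False, float_format="%.17g")
    elif isinstance(m, OverlapDistanceMatrix):
        m.to_frame().to_csv(path, index=True, index_label="species", float_format="%.17g")
    else:
        raise TypeError(f"cannot write object of type {type(m).__name__}")


def read_distance_matrix(path) -> OverlapDistanceMatrix:
    """Read a square labeled distance-matrix CSV written by :func:`write_matrix`."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise ParseError("distance matrix row and column labels differ")
    return OverlapDistanceMatrix(df.to_numpy(dtype=float), tuple(str(s) for s in df.columns))
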