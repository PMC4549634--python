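"""Grid geometry and in-memory gridded containers.

All layers share a :class:`GridSpec` describing a regular, axis-aligned grid
in projected (planar) coordinates. Arrays follow image convention: row 0 is
the northernmost row, column 0 the westernmost column. NoData is represented
internally by an explicit boolean ``valid`` mask, never by sentinel values;
sentinels only appear on disk (see :mod:`ignomap.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import AlignmentError, ValidationError

__all__ = [
    "GridSpec",
    "GriddedLayer",
    "CellSummaryLayer",
    "EffortLayer",
    "IgnoranceLayer",
]


@dataclass(frozen=True)
class GridSpec:
    """Extent, resolution and CRS of a regular grid.

    The extent is expanded outward (xmax up, ymax up) at construction so that
    both spans are exact integer multiples of ``cell_size``; callers may pass
    any bounding box.

    Parameters
    ----------
    xmin, ymin, xmax, ymax
        Bounding box in map units of ``crs``.
    cell_size
        Square cell edge length in map units, > 0.
    crs
        CRS identifier carried as metadata (e.g. ``"EPSG:3006"``). No
        transformation is ever performed; coordinates are assumed to already
        be in this CRS.
    """

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    cell_size: float
    crs: str = "EPSG:3006"

    def __post_init__(self) -> None:
        if not (self.cell_size > 0):
            raise ValidationError(f"cell_size must be > 0, got {self.cell_size}")
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValidationError(
                f"empty extent: ({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax})"
            )
        # expand outward to the next whole multiple of cell_size
        ncols = math.ceil(round((self.xmax - self.xmin) / self.cell_size, 9))
        nrows = math.ceil(round((self.ymax - self.ymin) / self.cell_size, 9))
        object.__setattr__(self, "xmax", self.xmin + ncols * self.cell_size)
        object.__setattr__(self, "ymax", self.ymin + nrows * self.cell_size)

    @property
    def ncols(self) -> int:
        return int(round((self.xmax - self.xmin) / self.cell_size))

    @property
    def nrows(self) -> int:
        return int(round((self.ymax - self.ymin) / self.cell_size))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_indices(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col) indices.

        Cells are the half-open squares ``[x0, x0+s) x [y0, y0+s)``; points on
        the global top/right edge of the extent are assigned to the last
        row/column so that every in-extent point lands in exactly one cell.

        Returns
        -------
        row, col : int arrays (valid only where ``inside``)
        inside : boolean array, True for points within the extent
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)
        col = np.floor((x - self.xmin) / self.cell_size).astype(int)
        row_s = np.floor((y - self.ymin) / self.cell_size).astype(int)  # 0 = southernmost
        col = np.clip(col, 0, self.ncols - 1)
        row_s = np.clip(row_s, 0, self.nrows - 1)
        row = self.nrows - 1 - row_s  # image convention: row 0 = north
        return row, col, inside

    def cell_centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """Centroid coordinates as 2-D arrays matching layer shape."""
        cx = self.xmin + (np.arange(self.ncols) + 0.5) * self.cell_size
        cy = self.ymax - (np.arange(self.nrows) + 0.5) * self.cell_size
        return np.meshgrid(cx, cy)

    def cell_origin(self, row: int, col: int) -> tuple[float, float]:
        """Lower-left corner of cell (row, col) in map units."""
        x0 = self.xmin + col * self.cell_size
        y0 = self.ymax - (row + 1) * self.cell_size
        return x0, y0

    def matches(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            abs(self.xmin - other.xmin) <= tol
            and abs(self.ymin - other.ymin) <= tol
            and abs(self.xmax - other.xmax) <= tol
            and abs(self.ymax - other.ymax) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
            and self.crs == other.crs
        )

    def require_match(self, other: "GridSpec", what: str = "layer") -> None:
        if not self.matches(other):
            raise AlignmentError(
                f"{what} grids are not aligned: {self} vs {other}; "
                "all layers must share the exact same extent, resolution and CRS"
            )


@dataclass
class GriddedLayer:
    """A single-band gridded layer: float values plus an explicit validity mask.

    ``valid`` is True where the cell carries data; NoData cells have
    ``values`` set to NaN in memory.
    """

    gridspec: GridSpec
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.gridspec.shape or self.valid.shape != self.gridspec.shape:
            raise ValidationError(
                f"array shape {self.values.shape} does not match grid {self.gridspec.shape}"
            )
        self.values = np.where(self.valid, self.values, np.nan)

    @classmethod
    def full(cls, gridspec: GridSpec, fill: float, valid: np.ndarray | None = None) -> "GriddedLayer":
        if valid is None:
            valid = np.ones(gridspec.shape, dtype=bool)
        return cls(gridspec, np.full(gridspec.shape, fill, dtype=float), valid)

    def equals(self, other: "GriddedLayer") -> bool:
        return (
            self.gridspec.matches(other.gridspec)
            and np.array_equal(self.valid, other.valid)
            and np.array_equal(self.values[self.valid], other.values[other.valid])
        )


@dataclass
class CellSummaryLayer:
    """Per-cell observation count N and species richness R for one grid.

    Invariants (checked at construction): R <= N everywhere, R == 0 exactly
    where N == 0, and cells outside ``region_mask`` are NoData (their counts
    are meaningless, not zero).
    """

    gridspec: GridSpec
    N: np.ndarray
    R: np.ndarray
    region_mask: np.ndarray

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=int)
        self.R = np.asarray(self.R, dtype=int)
        self.region_mask = np.asarray(self.region_mask, dtype=bool)
        for name, arr in (("N", self.N), ("R", self.R), ("region_mask", self.region_mask)):
            if arr.shape != self.gridspec.shape:
                raise ValidationError(f"{name} shape {arr.shape} != grid {self.gridspec.shape}")
        m = self.region_mask
        if np.any(self.N[m] < 0) or np.any(self.R[m] < 0):
            raise ValidationError("negative counts in summary layer")
        if np.any(self.R[m] > self.N[m]):
            raise ValidationError("species richness R exceeds observation count N in some cell")
        if np.any((self.R[m] == 0) != (self.N[m] == 0)):
            raise ValidationError("R == 0 must hold exactly where N == 0")

    def n_layer(self) -> GriddedLayer:
        return GriddedLayer(self.gridspec, self.N.astype(float), self.region_mask.copy())

    def r_layer(self) -> GriddedLayer:
        return GriddedLayer(self.gridspec, self.R.astype(float), self.region_mask.copy())


@dataclass
class EffortLayer:
    """Per-cell sampling-effort values feeding the ignorance algorithms.

    ``source`` records whether effort is raw observation counts (``"counts"``)
    or the observations-per-species index (``"obs_index"``).
    """

    gridspec: GridSpec
    x: np.ndarray
    valid: np.ndarray
    source: str = "counts"

    def __post_init__(self) -> None:
        if self.source not in ("counts", "obs_index"):
            raise ValidationError(f"unknown effort source {self.source!r}")
        self.x = np.asarray(self.x, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.x.shape != self.gridspec.shape or self.valid.shape != self.gridspec.shape:
            raise ValidationError(f"effort shape {self.x.shape} != grid {self.gridspec.shape}")
        vals = self.x[self.valid]
        if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals < 0)):
            raise ValidationError("effort values must be finite and non-negative")
        self.x = np.where(self.valid, self.x, np.nan)


@dataclass
class IgnoranceLayer:
    """Per-cell ignorance scores in [0, 1] plus provenance of how they were made.

    Provenance records at least the algorithm name, the half-saturation
    parameter (if any), the observed per-cell maximum effort (if any) and the
    effort source.
    """

    gridspec: GridSpec
    I: np.ndarray
    valid: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.I = np.asarray(self.I, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.I.shape != self.gridspec.shape or self.valid.shape != self.gridspec.shape:
            raise ValidationError(f"ignorance shape {self.I.shape} != grid {self.gridspec.shape}")
        vals = self.I[self.valid]
        if vals.size and (np.any(vals < 0) or np.any(vals > 1)):
            raise ValidationError("ignorance scores must lie in [0, 1]")
        self.I = np.where(self.valid, self.I, np.nan)

    def as_layer(self) -> GriddedLayer:
        return GriddedLayer(self.gridspec, self.I.copy(), self.valid.copy())
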