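"""Reading and writing occurrence tables, cell-summary tables, rasters and region masks.

Formats
-------
* Occurrence records: delimited text with a configurable column map
  (:class:`CsvDialect`); ISO-8601 dates by default. Rows that fail to parse
  are never silently dropped: they are collected into a :class:`ParseReport`
  that can be written to a sidecar file.
* Cell-summary tables: CSV with columns ``cell_x, cell_y`` (cell lower-left
  corner in map units), ``n_obs, n_species`` — the shape of per-cell summary
  exports from biodiversity portals.
* Rasters: single-band float64 GeoTIFF with CRS, geotransform and NoData
  recorded in standard GeoTIFF/GDAL tags. Row 0 is the northernmost row.
* Region masks: polygon geometry as GeoJSON or WKT text.

Coordinates are assumed to already be projected planar map units in the
grid's CRS; no reprojection is ever performed implicitly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import shape as geojson_shape
from shapely.validation import make_valid

from .errors import AlignmentError, ConfigurationError, ValidationError
from .grids import CellSummaryLayer, GriddedLayer, GridSpec

__all__ = [
    "OccurrenceRecord",
    "CsvDialect",
    "ParseReport",
    "ReadResult",
    "RegionMask",
    "read_occurrences",
    "read_region_mask",
    "read_cell_summary_table",
    "write_cell_summary_table",
    "write_raster",
    "read_raster",
    "normalize_taxon",
]

# GeoTIFF / GDAL tag codes
_TAG_PIXELSCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GEOASCII = 34737
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


def normalize_taxon(name: str) -> str:
    """Trim, collapse internal whitespace and case-fold a taxon name.

    No synonym resolution is attempted; this is purely lexical so that
    'Parus  Major ' and 'parus major' count as the same taxon.
    """
    return re.sub(r"\s+", " ", name.strip()).casefold()


@dataclass(frozen=True)
class OccurrenceRecord:
    """One reported observation: a taxon seen by someone at a place and date."""

    taxon: str
    group: str
    x: float
    y: float
    date: date

    def __post_init__(self) -> None:
        if not self.taxon.strip() or not self.group.strip():
            raise ValidationError("taxon and group must be non-empty")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValidationError("coordinates must be finite")


@dataclass(frozen=True)
class CsvDialect:
    """Column mapping and parsing conventions for occurrence CSV files.

    ``columns`` maps the logical fields (taxon, group, x, y, date) to the
    file's header names. ``date_format`` is a ``strptime`` pattern; ``None``
    means ISO-8601 (YYYY-MM-DD).
    """

    delimiter: str = ","
    columns: dict[str, str] = field(
        default_factory=lambda: {
            "taxon": "taxon",
            "group": "group",
            "x": "x",
            "y": "y",
            "date": "date",
        }
    )
    date_format: str | None = None

    def __post_init__(self) -> None:
        missing = {"taxon", "group", "x", "y", "date"} - set(self.columns)
        if missing:
            raise ConfigurationError(f"dialect is missing column mappings for {sorted(missing)}")


@dataclass
class ParseReport:
    """Per-row rejects from an occurrence file; never silently discarded."""

    n_rows: int = 0
    rejects: list[tuple[int, str]] = field(default_factory=list)  # (1-based data row, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)

    @property
    def n_parsed(self) -> int:
        return self.n_rows - self.n_rejected

    def write(self, path: str | Path) -> None:
        lines = [f"rows={self.n_rows} parsed={self.n_parsed} rejected={self.n_rejected}"]
        lines += [f"row {row}: {reason}" for row, reason in self.rejects]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ReadResult:
    records: list[OccurrenceRecord]
    report: ParseReport

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_occurrences(
    path: str | Path,
    dialect: CsvDialect | None = None,
    strict: bool = False,
) -> ReadResult:
    """Read occurrence records from a delimited text file.

    Every data row either becomes a record or a reject with a reason, so
    ``n_parsed + n_rejected`` always equals the number of data rows. With
    ``strict=True`` the first reject raises :class:`ValidationError` instead.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"occurrence file not found: {path}")
    dialect = dialect or CsvDialect()
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in dialect.columns.values() if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"mandatory column(s) {missing} not found in {path.name}; present: {list(df.columns)}"
        )

    cols = dialect.columns
    report = ParseReport(n_rows=len(df))
    records: list[OccurrenceRecord] = []
    raw = {f: df[cols[f]].to_numpy() for f in ("taxon", "group", "x", "y", "date")}
    for pos in range(1, len(df) + 1):
        i = pos - 1
        try:
            taxon = normalize_taxon(str(raw["taxon"][i]))
            group = str(raw["group"][i]).strip()
            if not taxon or not group:
                raise ValueError("empty taxon or group")
            x = float(raw["x"][i])
            y = float(raw["y"][i])
            raw_date = str(raw["date"][i]).strip()
            if dialect.date_format is None:
                d = date.fromisoformat(raw_date)
            else:
                d = datetime.strptime(raw_date, dialect.date_format).date()
            records.append(OccurrenceRecord(taxon=taxon, group=group, x=x, y=y, date=d))
        except (ValueError, ValidationError) as exc:
            if strict:
                raise ValidationError(f"row {pos}: {exc}") from exc
            report.rejects.append((pos, str(exc)))
    return ReadResult(records=records, report=report)


@dataclass
class RegionMask:
    """Study-region polygon in the grid's CRS.

    Geometry is repaired with ``make_valid`` at construction; a cell belongs
    to the region iff its centroid falls inside the polygon.
    """

    geometry: shapely.Geometry

    def __post_init__(self) -> None:
        if not self.geometry.is_valid:
            self.geometry = make_valid(self.geometry)
        if self.geometry.is_empty:
            raise ValidationError("region mask geometry is empty")

    def cells_inside(self, gridspec: GridSpec) -> np.ndarray:
        cx, cy = gridspec.cell_centroids()
        return shapely.contains_xy(self.geometry, cx, cy)


def read_region_mask(path: str | Path) -> RegionMask:
    """Read a region polygon from a GeoJSON or WKT text file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"region file not found: {path}")
    text = path.read_text().strip()
    if text[:1] in "{[":
        obj = json.loads(text)
        if obj.get("type") == "FeatureCollection":
            geoms = [geojson_shape(f["geometry"]) for f in obj["features"]]
            geom = shapely.union_all(geoms)
        elif obj.get("type") == "Feature":
            geom = geojson_shape(obj["geometry"])
        else:
            geom = geojson_shape(obj)
    else:
        geom = shapely.from_wkt(text)
    return RegionMask(geometry=geom)


# ---------------------------------------------------------------------------
# Cell-summary tables


def write_cell_summary_table(layer: CellSummaryLayer, path: str | Path) -> None:
    """Write one CSV row per in-region cell: cell_x, cell_y, n_obs, n_species."""
    rows = []
    gs = layer.gridspec
    for row, col in zip(*np.nonzero(layer.region_mask)):
        x0, y0 = gs.cell_origin(int(row), int(col))
        rows.append((x0, y0, int(layer.N[row, col]), int(layer.R[row, col])))
    pd.DataFrame(rows, columns=["cell_x", "cell_y", "n_obs", "n_species"]).to_csv(
        path, index=False
    )


def read_cell_summary_table(
    path: str | Path,
    gridspec: GridSpec,
    region: RegionMask | None = None,
) -> CellSummaryLayer:
    """Read a pre-summarized per-cell table onto a grid.

    ``cell_x, cell_y`` give each cell's lower-left corner in map units. Cells
    absent from the table are zero inside the region mask. A row whose corner
    does not land on a cell of ``gridspec`` is an error naming that row, as is
    any row with ``n_species > n_obs``.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"cell summary file not found: {path}")
    df = pd.read_csv(path)
    required = ["cell_x", "cell_y", "n_obs", "n_species"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"cell summary table missing column(s) {missing}")

    region_mask = (
        region.cells_inside(gridspec) if region is not None else np.ones(gridspec.shape, bool)
    )
    N = np.zeros(gridspec.shape, dtype=int)
    R = np.zeros(gridspec.shape, dtype=int)
    cs = gridspec.cell_size
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        fcol = (rec.cell_x - gridspec.xmin) / cs
        frow = (rec.cell_y - gridspec.ymin) / cs
        col, row_s = int(round(fcol)), int(round(frow))
        if (
            abs(fcol - col) > 1e-6
            or abs(frow - row_s) > 1e-6
            or not (0 <= col < gridspec.ncols)
            or not (0 <= row_s < gridspec.nrows)
        ):
            raise ValidationError(
                f"row {i}: cell corner ({rec.cell_x}, {rec.cell_y}) does not map to a "
                f"grid cell of {gridspec}"
            )
        if rec.n_species > rec.n_obs:
            raise ValidationError(
                f"row {i}: n_species={rec.n_species} exceeds n_obs={rec.n_obs}"
            )
        row = gridspec.nrows - 1 - row_s
        N[row, col] = int(rec.n_obs)
        R[row, col] = int(rec.n_species)
    return CellSummaryLayer(gridspec=gridspec, N=N, R=R, region_mask=region_mask)


# ---------------------------------------------------------------------------
# Rasters


def _geokeys_for(crs: str) -> tuple[tuple[int, ...], str]:
    """Build a minimal GeoKeyDirectory plus ascii params for a CRS string."""
    ascii_params = crs + "|"
    keys = [(1024, 0, 1, 1), (1025, 0, 1, 1), (3073, _TAG_GEOASCII, len(ascii_params), 0)]
    m = re.fullmatch(r"EPSG:(\d+)", crs, flags=re.IGNORECASE)
    if m:
        keys.append((3072, 0, 1, int(m.group(1))))
    keys.sort()
    header = (1, 1, 0, len(keys))
    flat = header + tuple(v for key in keys for v in key)
    return flat, ascii_params


def write_raster(layer, path: str | Path, nodata: float = DEFAULT_NODATA) -> None:
    """Write a gridded layer as a single-band float64 GeoTIFF.

    NoData cells are stored as the ``nodata`` sentinel, recorded in the file's
    GDAL_NODATA tag; geotransform and CRS go into the standard GeoTIFF tags.
    Row 0 of the array is the northernmost row.
    """
    layer = _as_gridded(layer)
    gs = layer.gridspec
    if np.any(np.isclose(layer.values[layer.valid], nodata)):
        raise ValidationError(f"data contains the NoData sentinel {nodata}; choose another")
    data = np.where(layer.valid, layer.values, nodata).astype(np.float64)
    geokeys, ascii_params = _geokeys_for(gs.crs)
    extratags = [
        (_TAG_PIXELSCALE, "d", 3, (gs.cell_size, gs.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, gs.xmin, gs.ymax, 0.0)),
        (_TAG_GEOKEYS, "H", len(geokeys), geokeys),
        (_TAG_GEOASCII, "s", 0, ascii_params),
        (_TAG_GDAL_NODATA, "s", 0, repr(nodata)),
    ]
    tifffile.imwrite(Path(path), data, extratags=extratags)


def read_raster(path: str | Path, expected: GridSpec | None = None) -> GriddedLayer:
    """Read a single-band GeoTIFF written by :func:`write_raster`.

    If ``expected`` is given, the file's extent, resolution and CRS must match
    it exactly; a mismatch raises :class:`AlignmentError` — the layer is never
    silently resampled.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"raster file not found: {path}")
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray().astype(np.float64)
        if values.ndim != 2:
            raise ValidationError(f"{path.name} is not a single-band raster")
        tags = page.tags
        try:
            sx, sy, _ = tags[_TAG_PIXELSCALE].value
            tie = tags[_TAG_TIEPOINT].value
        except KeyError as exc:
            raise ValidationError(f"{path.name} has no georeferencing tags") from exc
        xmin, ymax = tie[3], tie[4]
        crs = "unknown"
        if _TAG_GEOASCII in tags:
            crs = str(tags[_TAG_GEOASCII].value).split("|")[0].strip()
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    nrows, ncols = values.shape
    if abs(sx - sy) > 1e-9:
        raise ValidationError(f"{path.name} has non-square cells ({sx} x {sy})")
    gridspec = GridSpec(
        xmin=xmin,
        ymin=ymax - nrows * sy,
        xmax=xmin + ncols * sx,
        ymax=ymax,
        cell_size=sx,
        crs=crs,
    )
    if expected is not None:
        expected.require_match(gridspec, what=f"raster {path.name}")
        gridspec = expected
    valid = np.isfinite(values)
    if nodata is not None:
        valid &= values != nodata
    return GriddedLayer(gridspec=gridspec, values=values, valid=valid)


def _as_gridded(layer) -> GriddedLayer:
    if isinstance(layer, GriddedLayer):
        return layer
    if hasattr(layer, "as_layer"):
        return layer.as_layer()
    if hasattr(layer, "x"):  # EffortLayer
        return GriddedLayer(layer.gridspec, np.asarray(layer.x, float), layer.valid)
    raise TypeError(f"cannot interpret {type(layer).__name__} as a gridded layer")
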