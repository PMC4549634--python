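"""Filter occurrence records and summarize them onto a grid.

The pipeline stage between raw records and effort layers: select the
reference taxonomic group and time frame (optionally excluding the focal
species), then count per grid cell the number of observations N_i and the
number of distinct taxa R_i. Identical records are counted separately —
the data are reports, not unique events — unless deduplication is asked for
explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .grids import CellSummaryLayer, EffortLayer, GridSpec
from .io import OccurrenceRecord, RegionMask, normalize_taxon
from .errors import ValidationError

__all__ = [
    "FilterSpec",
    "SummarizeResult",
    "filter_records",
    "dedupe_records",
    "summarize_to_grid",
    "species_observation_index",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Reference-group, time-frame and exclusion filter.

    The reference group should contain only species surveyed with the same
    methodology; the focal (target) species is typically excluded when the
    result will serve as a bias/background layer. Date bounds are inclusive
    on both ends, and long time frames are preferred to damp temporal
    variability in effort.
    """

    group: str
    date_start: date
    date_end: date
    exclude_taxa: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.date_start > self.date_end:
            raise ValidationError(
                f"date_start {self.date_start} is after date_end {self.date_end}"
            )
        object.__setattr__(
            self, "exclude_taxa", frozenset(normalize_taxon(t) for t in self.exclude_taxa)
        )

    def accepts(self, rec: OccurrenceRecord) -> bool:
        return (
            rec.group == self.group
            and self.date_start <= rec.date <= self.date_end
            and normalize_taxon(rec.taxon) not in self.exclude_taxa
        )


def filter_records(
    records: list[OccurrenceRecord], spec: FilterSpec
) -> list[OccurrenceRecord]:
    """Keep records matching group, inclusive date window and not excluded; order preserved."""
    return [r for r in records if spec.accepts(r)]


def dedupe_records(records: list[OccurrenceRecord]) -> list[OccurrenceRecord]:
    """Drop exact duplicates (same taxon, coordinates and date), keeping first occurrence.

    Off the main path by default: repeated reports are legitimate effort
    signal, but some workflows want unique events.
    """
    seen: set[tuple] = set()
    out = []
    for r in records:
        key = (r.taxon, r.x, r.y, r.date)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


@dataclass
class SummarizeResult:
    """A cell-summary layer plus the bookkeeping of records that fell nowhere.

    Conservation: ``layer.N.sum() (over valid cells) + n_out_of_extent +
    n_out_of_region == number of input records``.
    """

    layer: CellSummaryLayer
    n_out_of_extent: int
    n_out_of_region: int


def summarize_to_grid(
    records: list[OccurrenceRecord],
    gridspec: GridSpec,
    region: RegionMask | None = None,
    out_of_extent_warn_fraction: float = 0.1,
) -> SummarizeResult:
    """Count observations and distinct taxa per grid cell.

    Cell membership uses half-open intervals [x0, x0+s) x [y0, y0+s); points
    on the global top/right boundary belong to the last row/column. Records
    outside the extent, or inside it but outside the region mask, are counted
    and reported, never silently dropped. If ``region`` is given, cells
    outside it carry NoData.
    """
    region_mask = (
        region.cells_inside(gridspec) if region is not None else np.ones(gridspec.shape, bool)
    )
    N = np.zeros(gridspec.shape, dtype=int)
    R = np.zeros(gridspec.shape, dtype=int)
    n_out_extent = 0
    n_out_region = 0

    if records:
        xs = np.array([r.x for r in records])
        ys = np.array([r.y for r in records])
        row, col, inside = gridspec.cell_indices(xs, ys)
        n_out_extent = int((~inside).sum())
        in_region = inside & region_mask[row, col]
        n_out_region = int((inside & ~in_region).sum())

        if in_region.any():
            df = pd.DataFrame(
                {
                    "row": row[in_region],
                    "col": col[in_region],
                    "taxon": [normalize_taxon(r.taxon) for r, keep in zip(records, in_region) if keep],
                }
            )
            g = df.groupby(["row", "col"])["taxon"]
            counts = g.size()
            richness = g.nunique()
            idx = tuple(np.array(counts.index.tolist()).T)
            N[idx] = counts.to_numpy()
            R[idx] = richness.to_numpy()

        if len(records) and n_out_extent / len(records) > out_of_extent_warn_fraction:
            log.warning(
                "%d of %d records (%.0f%%) fall outside the grid extent",
                n_out_extent,
                len(records),
                100 * n_out_extent / len(records),
            )

    layer = CellSummaryLayer(gridspec=gridspec, N=N, R=R, region_mask=region_mask)
    return SummarizeResult(layer=layer, n_out_of_extent=n_out_extent, n_out_of_region=n_out_region)


def species_observation_index(layer: CellSummaryLayer) -> EffortLayer:
    """Observations per observed species, O_i = N_i / R_i (0 where N_i = 0).

    For reference groups whose observers compile species lists at favourite
    sites, this index offsets raw counts by list-completion behaviour: a cell
    with many observations of few species scores high effort per species.
    O_i >= 1 wherever any observation exists.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        O = np.where(layer.N > 0, layer.N / np.maximum(layer.R, 1), 0.0)
    return EffortLayer(
        gridspec=layer.gridspec, x=O, valid=layer.region_mask.copy(), source="obs_index"
    )
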