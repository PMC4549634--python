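from datetime import date

import numpy as np
import pytest

from ignomap import GridSpec, OccurrenceRecord
from ignomap.grids import EffortLayer


@pytest.fixture
def grid5() -> GridSpec:
    return GridSpec(0, 0, 5, 5, 1, crs="EPSG:3006")


@pytest.fixture
def make_effort():
    """Build an EffortLayer from a 2-D array (valid everywhere unless given)."""

    def _make(values, valid=None, source="counts", cell_size=1.0):
        values = np.asarray(values, dtype=float)
        nr, nc = values.shape
        gs = GridSpec(0, 0, nc * cell_size, nr * cell_size, cell_size)
        if valid is None:
            valid = np.ones(values.shape, bool)
        return EffortLayer(gridspec=gs, x=values, valid=np.asarray(valid, bool), source=source)

    return _make


@pytest.fixture
def make_records():
    """Build OccurrenceRecords from (taxon, x, y) or (taxon, group, x, y, date) tuples."""

    def _make(points, group="birds", when=date(2005, 6, 1)):
        out = []
        for p in points:
            if len(p) == 3:
                taxon, x, y = p
                out.append(OccurrenceRecord(taxon=taxon, group=group, x=x, y=y, date=when))
            else:
                taxon, grp, x, y, d = p
                out.append(OccurrenceRecord(taxon=taxon, group=grp, x=x, y=y, date=d))
        return out

    return _make


def brute_force_grid_counts(records, gridspec):
    """Independent O(points x cells) oracle for summarize_to_grid.

    Checks each point against each cell's half-open square, with points on
    the global top/right edge of the extent assigned to the last row/column.
    Returns (N, R, n_out_of_extent).
    """
    s = gridspec.cell_size
    N = np.zeros(gridspec.shape, dtype=int)
    taxa_per_cell = [[set() for _ in range(gridspec.ncols)] for _ in range(gridspec.nrows)]
    n_out = 0
    for rec in records:
        hit = None
        for row in range(gridspec.nrows):
            for col in range(gridspec.ncols):
                x0 = gridspec.xmin + col * s
                y0 = gridspec.ymax - (row + 1) * s
                in_x = (x0 <= rec.x < x0 + s) or (col == gridspec.ncols - 1 and rec.x == gridspec.xmax)
                in_y = (y0 <= rec.y < y0 + s) or (row == 0 and rec.y == gridspec.ymax)
                if in_x and in_y:
                    hit = (row, col)
        if hit is None:
            n_out += 1
        else:
            N[hit] += 1
            taxa_per_cell[hit[0]][hit[1]].add(rec.taxon.strip().casefold())
    R = np.array(
        [[len(taxa_per_cell[r][c]) for c in range(gridspec.ncols)] for r in range(gridspec.nrows)]
    )
    return N, R, n_out
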