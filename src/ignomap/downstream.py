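"""Applying ignorance layers to other rasters.

Four prescribed uses: masking unreliable cells out of an estimate layer,
designating pseudo-absences in well-surveyed cells without focal-species
records, down-weighting estimates by certainty (1 - I), and building a
Bernoulli prior-probability layer for Bayesian occupancy/SDM work.

Threshold conventions: masking removes cells with I strictly greater than
the threshold; pseudo-absence selection keeps cells with I less than or
equal to it. The two partitions are complementary at the same threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .grids import CellSummaryLayer, GriddedLayer, GridSpec, IgnoranceLayer

__all__ = [
    "PseudoAbsenceSet",
    "mask_by_ignorance",
    "pseudo_absences",
    "weight_by_certainty",
    "bernoulli_prior",
]


def _check_threshold(threshold: float) -> None:
    if not (0.0 <= threshold <= 1.0):
        raise ConfigurationError(f"threshold must lie in [0, 1], got {threshold}")


@dataclass
class PseudoAbsenceSet:
    """Cells treated as likely true absences of the focal species.

    A cell qualifies iff the focal species has zero observations there, the
    ignorance score is at most ``threshold``, and the cell is inside the
    study region.
    """

    gridspec: GridSpec
    cells: frozenset[tuple[int, int]]  # (row, col)
    threshold: float

    def to_raster(self) -> GriddedLayer:
        """0/1 layer: 1 on designated cells, 0 elsewhere (valid everywhere)."""
        values = np.zeros(self.gridspec.shape)
        for r, c in self.cells:
            values[r, c] = 1.0
        return GriddedLayer(self.gridspec, values, np.ones(self.gridspec.shape, bool))

    def to_table(self) -> list[tuple[int, int, float, float]]:
        """(row, col, x_center, y_center) per designated cell, row-major order."""
        cx, cy = self.gridspec.cell_centroids()
        return [(r, c, float(cx[r, c]), float(cy[r, c])) for r, c in sorted(self.cells)]


def mask_by_ignorance(
    estimate: GriddedLayer, ign: IgnoranceLayer, threshold: float
) -> GriddedLayer:
    """NoData-out estimate cells whose ignorance exceeds the threshold.

    Cells with I_i > threshold become NoData; all others pass through
    unchanged. Idempotent at a fixed threshold.
    """
    _check_threshold(threshold)
    estimate.gridspec.require_match(ign.gridspec, what="estimate vs ignorance")
    keep = estimate.valid & ~(ign.valid & (ign.I > threshold))
    return GriddedLayer(estimate.gridspec, np.where(keep, estimate.values, np.nan), keep)


def pseudo_absences(
    focal: CellSummaryLayer, ign: IgnoranceLayer, threshold: float
) -> PseudoAbsenceSet:
    """Select well-surveyed cells without focal-species records.

    ``focal`` holds the focal species' own per-cell counts; ``ign`` comes
    from the reference group. Monotone in the threshold: a larger threshold
    can only add cells.
    """
    _check_threshold(threshold)
    focal.gridspec.require_match(ign.gridspec, what="focal vs ignorance")
    sel = focal.region_mask & ign.valid & (focal.N == 0) & (ign.I <= threshold)
    cells = frozenset((int(r), int(c)) for r, c in zip(*np.nonzero(sel)))
    return PseudoAbsenceSet(gridspec=focal.gridspec, cells=cells, threshold=threshold)


def weight_by_certainty(estimate: GriddedLayer, ign: IgnoranceLayer) -> GriddedLayer:
    """Multiply an estimate layer by certainty (1 - I) cell-wise.

    Zeros and NoData of the estimate are preserved; cells NoData in the
    ignorance layer become NoData in the result.
    """
    estimate.gridspec.require_match(ign.gridspec, what="estimate vs ignorance")
    valid = estimate.valid & ign.valid
    return GriddedLayer(estimate.gridspec, estimate.values * (1.0 - ign.I), valid)


def bernoulli_prior(ign: IgnoranceLayer) -> GriddedLayer:
    """Prior occurrence probability p_i = 1 - (1 - I_i + 0.5 * I_i) for unobserved cells.

    Algebraically p_i = 0.5 * I_i: a completely unsurveyed cell (I = 1) gets
    p = 0.5 — occupied or not with equal probability — while a thoroughly
    surveyed cell without records gets p near 0. The full layer is returned;
    it is meant to parameterize the prior only at cells without observations
    of the focal species, and no Bernoulli outcomes are sampled here (that
    belongs to the caller's model-fitting iterations).
    """
    p = 1.0 - (1.0 - ign.I + 0.5 * ign.I)
    return GriddedLayer(ign.gridspec, p, ign.valid.copy())
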