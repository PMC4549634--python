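"""The three ignorance algorithms.

Each maps a per-cell effort value x_i >= 0 (raw observation counts N_i, or
the observations-per-species index O_i) to an ignorance score I_i in [0, 1],
where 1 means no sampling information at all and 0 means maximal credibility
that a missing report reflects a true absence.

* Normalization:      I_i = 1 - x_i / x_m,  x_m the dataset maximum.
  Linear; suited to datasets whose maximum is not far from the mean. Scores
  depend on x_m, so they shift whenever the spatial/temporal extent of the
  dataset changes.
* Log-normalization:  I_i = 1 - ln(x_i + 1) / ln(x_m + 1).
  The natural-log analogue; separates "few" from "enough" observations when
  the count distribution has a long right tail. The added unit sends empty
  cells to exactly 1.
* Half-ignorance:     I_i = O50 / (x_i + O50).
  Independent of the dataset maximum. O50 is the effort at which the score is
  exactly 0.5 — the analyst's statement of how much one observation is worth.
  Larger O50 means scores decay more slowly toward 0.

All three satisfy I(0) = 1 and are non-increasing in effort. Results are
clamped to [0, 1] to absorb floating-point rounding at the endpoints; the
clamp is asserted to move values by less than 1e-12.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError, DegenerateEffortError
from .grids import EffortLayer, GriddedLayer, IgnoranceLayer

__all__ = [
    "ignorance_normalization",
    "ignorance_log_normalization",
    "ignorance_half",
    "certainty",
    "ALGORITHMS",
]

_CLAMP_TOL = 1e-12


def _clamp_unit(I: np.ndarray, valid: np.ndarray) -> np.ndarray:
    clipped = np.clip(I, 0.0, 1.0)
    drift = np.nanmax(np.abs(clipped[valid] - I[valid]), initial=0.0)
    assert drift < _CLAMP_TOL, f"clamping moved scores by {drift}"
    return clipped

def _effort_max(effort: EffortLayer) -> float:
    vals = effort.x[effort.valid]
    if vals.size == 0 or float(np.max(vals)) <= 0.0:
        raise DegenerateEffortError(
            "degenerate effort layer: no cell with positive effort, "
            "so the dataset maximum is zero and the score is undefined"
        )
    return float(np.max(vals))


def ignorance_normalization(effort: EffortLayer) -> IgnoranceLayer:
    """Linear rescaling against the dataset maximum: I_i = 1 - x_i / x_m.

    x_m is the maximum over the valid, in-region cells of *this* layer — it is
    a property of the dataset at hand, never a global constant.
    """
    x_m = _effort_max(effort)
    I = 1.0 - effort.x / x_m
    return IgnoranceLayer(
        gridspec=effort.gridspec,
        I=_clamp_unit(I, effort.valid),
        valid=effort.valid.copy(),
        provenance={"algorithm": "normalization", "effort_max": x_m, "source": effort.source},
    )


def ignorance_log_normalization(effort: EffortLayer) -> IgnoranceLayer:
    """Log-scaled rescaling: I_i = 1 - ln(x_i + 1) / ln(x_m + 1)."""
    x_m = _effort_max(effort)
    I = 1.0 - np.log1p(effort.x) / np.log1p(x_m)
    return IgnoranceLayer(
        gridspec=effort.gridspec,
        I=_clamp_unit(I, effort.valid),
        valid=effort.valid.copy(),
        provenance={"algorithm": "log_normalization", "effort_max": x_m, "source": effort.source},
    )


def ignorance_half(effort: EffortLayer, o50: float) -> IgnoranceLayer:
    """Half-saturation scoring: I_i = O50 / (x_i + O50).

    Well-defined even on an all-zero layer (every score is then 1), and
    adding better-sampled cells elsewhere never changes an existing cell's
    score — the property that makes datasets with very different maxima
    comparable.
    """
    if not (o50 > 0):
        raise ConfigurationError(f"half-ignorance parameter must be > 0, got {o50}")
    I = o50 / (effort.x + o50)
    return IgnoranceLayer(
        gridspec=effort.gridspec,
        I=_clamp_unit(I, effort.valid),
        valid=effort.valid.copy(),
        provenance={"algorithm": "half_ignorance", "o50": float(o50), "source": effort.source},
    )


def certainty(ign: IgnoranceLayer) -> GriddedLayer:
    """The complement 1 - I_i: a multiplicative credibility weight."""
    return GriddedLayer(ign.gridspec, 1.0 - ign.I, ign.valid.copy())


ALGORITHMS = {
    "normalization": ignorance_normalization,
    "log_normalization": ignorance_log_normalization,
    "half_ignorance": ignorance_half,
}
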