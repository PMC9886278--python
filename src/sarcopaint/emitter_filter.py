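"""Multi-emitter rejection using the PSF fit-width distribution.

Localizations produced by two or more simultaneously bound imagers fit
wider than the single-emitter PSF.  Kept localizations lie within a disc
in (sx, sy) space centred on the mode of the joint distribution; the
default radius is 0.2 px and the disc boundary is inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError, ValidationError
from .locio import LocalizationTable


@dataclass
class FilterParams:
    """``radius_px``: disc radius in (sx, sy) space; ``hist_bin_px``: 2-D
    histogram bin used to locate the distribution mode."""

    radius_px: float = 0.2
    hist_bin_px: float = 0.05

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValidationError("radius_px must be positive")
        if not (0 < self.hist_bin_px <= self.radius_px):
            raise ValidationError("hist_bin_px must be in (0, radius_px]")


def _anchored_edges(values: np.ndarray, bin_px: float) -> np.ndarray:
    i0 = int(np.floor(values.min() / bin_px))
    i1 = int(np.floor(values.max() / bin_px)) + 1
    return np.arange(i0, i1 + 1) * bin_px


def fit_width_mode(
    table: LocalizationTable, params: FilterParams | None = None
) -> tuple[float, float]:
    """Mode of the (sx, sy) distribution, reported at the bin centre.

    Ties between equally populated bins are broken in favour of the bin
    with the smaller sx^2 + sy^2 (narrower fits are likelier single
    emitters), then lexicographically.
    """
    params = params or FilterParams()
    if len(table) == 0:
        raise EmptyInputError("cannot locate fit-width mode of an empty table")
    ex = _anchored_edges(table.sx, params.hist_bin_px)
    ey = _anchored_edges(table.sy, params.hist_bin_px)
    hist, _, _ = np.histogram2d(table.sx, table.sy, bins=[ex, ey])
    cx = 0.5 * (ex[:-1] + ex[1:])
    cy = 0.5 * (ey[:-1] + ey[1:])
    best = None
    max_count = hist.max()
    for i, j in zip(*np.nonzero(hist == max_count)):
        key = (cx[i] ** 2 + cy[j] ** 2, cx[i], cy[j])
        if best is None or key < best[0]:
            best = (key, (float(cx[i]), float(cy[j])))
    return best[1]


def filter_multi_emitter(
    table: LocalizationTable,
    params: FilterParams | None = None,
    mode: tuple[float, float] | None = None,
) -> LocalizationTable:
    """Keep rows with sqrt((sx-sx0)^2 + (sy-sy0)^2) <= radius_px.

    The mode is recomputed from ``table`` unless passed explicitly (a
    channel's mode should come from that channel, not pooled across dyes).
    Row order and all other fields are untouched.
    """
    params = params or FilterParams()
    sx0, sy0 = mode if mode is not None else fit_width_mode(table, params)
    dist = np.hypot(table.sx - sx0, table.sy - sy0)
    keep = dist <= params.radius_px
    if len(table) and not keep.any():
        warnings.warn("multi-emitter filter rejected every localization",
                      stacklevel=2)
    return table.select(keep)
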