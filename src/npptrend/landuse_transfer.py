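"""Land-use transfer matrices between two categorical rasters.

The transfer (cross-tabulation) matrix counts, for every ordered class pair
(i, j), the area that was class i at the first date and class j at the
second.  Diagonal entries are retained area; off-diagonal entries are
conversions.  Areas are carried in km² as floats (cell area may be
fractional); percentage rounding happens only at the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster_core import RasterGrid

__all__ = ["TransferMatrix", "transfer_matrix", "retention_shares", "largest_transfer"]


@dataclass
class TransferMatrix:
    """Class-by-class area matrix (km²) between two dates."""

    classes: tuple
    areas: np.ndarray
    cell_area: float = 1.0

    def __post_init__(self):
        self.areas = np.asarray(self.areas, dtype=float)
        k = len(self.classes)
        if self.areas.shape != (k, k):
            raise ValueError("areas must be square and match class count")
        if (self.areas < 0).any():
            raise ValueError("areas must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.areas.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.areas, index=list(self.classes),
                            columns=list(self.classes))


def transfer_matrix(start: RasterGrid, end: RasterGrid, classes) -> TransferMatrix:
    """Exact cross-tabulation of two aligned categorical grids × cell area.

    ``classes`` maps position → label; grid values must be integer codes
    0..k−1 (an undeclared code raises, naming it).  Pixels nodata in either
    grid are excluded.
    """
    if start.shape != end.shape:
        raise ValueError("grids must share shape")
    k = len(classes)
    ok = start.valid_mask() & end.valid_mask()
    a = np.asarray(start.values)[ok].astype(np.int64)
    b = np.asarray(end.values)[ok].astype(np.int64)
    for name, codes in (("start", a), ("end", b)):
        if codes.size and (codes.min() < 0 or codes.max() >= k):
            bad = sorted(set(codes[(codes < 0) | (codes >= k)].tolist()))
            raise ValueError(f"undeclared class code(s) {bad} in {name} grid")
    counts = np.bincount(a * k + b, minlength=k * k).reshape(k, k)
    cell_area = start.cell_area
    return TransferMatrix(tuple(classes), counts * cell_area, cell_area=cell_area)


def retention_shares(m: TransferMatrix, decimals: int | None = 2) -> pd.DataFrame:
    """Per-class retained area and its share of the grand total, in percent.

    share_i = 100·areas[i][i]/total.  ``decimals`` rounds the reported share
    (None disables); the underlying areas are never rounded.
    """
    if m.total <= 0:
        raise ValueError("empty transfer matrix")
    retained = np.diag(m.areas)
    share = 100.0 * retained / m.total
    if decimals is not None:
        share = share.round(decimals)
    return pd.DataFrame({"retained_area": retained, "share_percent": share},
                        index=list(m.classes))


def largest_transfer(m: TransferMatrix, exclude_diagonal: bool = True):
    """Largest conversion (from_class, to_class, area); row-major tie-break.

    With only zero off-diagonals, returns (None, None, 0.0).
    """
    a = m.areas.copy()
    if exclude_diagonal:
        np.fill_diagonal(a, -1.0)
    if (a <= 0).all():
        return None, None, 0.0
    i, j = np.unravel_index(np.argmax(a), a.shape)
    return m.classes[i], m.classes[j], float(a[i, j])
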