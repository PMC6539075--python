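"""Small example datasets used in documentation and tests."""

from __future__ import annotations

import numpy as np

from .landuse_transfer import TransferMatrix
from .synthetic_data import LANDUSE_CLASSES

__all__ = ["landuse_transfer_2000_2015"]

# Published 7-class land-use cross-tabulation (km², 2000 -> 2015) for a
# semi-arid agro-pastoral transition region of northern China.  Rows are the
# class at 2000, columns the class at 2015.  Serves as a fully worked
# transfer-matrix example with known summaries (retention shares, dominant
# classes, largest conversion).
_TRANSFERS_2000_2015 = np.array([
    # farmland forest  grassland water   desert  built-up bare
    [659998,   2360,   4346,     1405,   8956,   124,     294],     # farmland
    [764,      462587, 890,      167,    468,    27,      46],      # forest
    [4994,     2966,   1793473,  1758,   2648,   3418,    322],     # grassland
    [1803,     138,    899,      164937, 466,    1036,    244],     # water
    [181,      27,     57,       82,     69398,  14,      1],       # desert
    [747,      302,    2856,     1513,   744,    250059,  155],     # built-up
    [18,       7,      101,      73,     15,     11,      265807],  # bare
], dtype=float)


def landuse_transfer_2000_2015() -> TransferMatrix:
    """The example land-use transfer matrix (km²) as a :class:`TransferMatrix`."""
    return TransferMatrix(LANDUSE_CLASSES, _TRANSFERS_2000_2015.copy(), cell_area=1.0)
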