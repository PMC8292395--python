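"""Shared low-level geometry: centroids and the diagonal quadrant sectors.

The quadrant partition divides the frame into two *axial* and two
*transverse* sectors by the two ±45° diagonals through a given centroid,
with the stretch axis defining "axial". Ties on the diagonals go to the
axial sectors; the centroid pixel itself is labelled axial_plus.
"""

from __future__ import annotations

import numpy as np

#: Sector code order used throughout the package.
QUADRANTS = ("axial_plus", "axial_minus", "transverse_plus", "transverse_minus")

AXIAL_PLUS, AXIAL_MINUS, TRANSVERSE_PLUS, TRANSVERSE_MINUS = range(4)


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Foreground center of mass as (row, col) in pixel coordinates."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask has no centroid")
    return float(rows.mean()), float(cols.mean())


def sector_labels(
    shape: tuple[int, int],
    centroid_rc: tuple[float, float],
    stretch_axis: str = "x",
) -> np.ndarray:
    """Label every pixel of a frame with its quadrant sector code.

    Parameters
    ----------
    shape : (n_rows, n_cols)
    centroid_rc : (row, col) centroid in pixel coordinates.
    stretch_axis : "x" (image columns) or "y" (image rows).

    Returns
    -------
    int8 array of shape ``shape`` with values in {0..3} following
    :data:`QUADRANTS` order.
    """
    if stretch_axis not in ("x", "y"):
        raise ValueError(f"stretch_axis must be 'x' or 'y', got {stretch_axis!r}")
    cy, cx = centroid_rc
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    if stretch_axis == "x":
        dax = cc - cx
        dtr = rr - cy
    else:
        dax = rr - cy
        dtr = cc - cx
    labels = np.full(shape, AXIAL_PLUS, dtype=np.int8)
    abs_ax = np.abs(dax)
    abs_tr = np.abs(dtr)
    labels[(dax < 0) & (abs_ax >= abs_tr)] = AXIAL_MINUS
    labels[dtr > abs_ax] = TRANSVERSE_PLUS
    labels[dtr < -abs_ax] = TRANSVERSE_MINUS
    # everything else (dax > 0 with dax >= |dtr|, the diagonals with dax > 0,
    # and the centroid pixel) keeps AXIAL_PLUS
    return labels
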