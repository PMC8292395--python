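"""Shared test fixtures-as-functions: analytic masks and random small masks."""

import numpy as np
from scipy import ndimage

from cyclostretch import CellMask


def rasterize_ellipse(semi_ax, semi_tr, theta_deg, shape=(256, 256), pixel_size=0.5):
    """Analytic ellipse mask: semi-axes in pixels, rotated by theta from x."""
    cy, cx = (shape[0] - 1) / 2, (shape[1] - 1) / 2
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    x, y = cc - cx, rr - cy
    th = np.deg2rad(theta_deg)
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    mask = (u / semi_ax) ** 2 + (v / semi_tr) ** 2 <= 1.0
    return CellMask(mask, pixel_size)


def random_small_mask(seed):
    """Seeded blob-like single-component mask on a 64×64 frame."""
    rng = np.random.default_rng(seed)
    px = np.zeros((64, 64), bool)
    r0, c0 = rng.integers(16, 40, 2)
    h, w = rng.integers(6, 20, 2)
    px[r0 : r0 + h, c0 : c0 + w] = True
    blob = rng.random((64, 64)) > 0.5
    px |= ndimage.binary_dilation(px) & blob
    px = ndimage.binary_closing(px)
    lab, n = ndimage.label(px)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab, dtype=float), lab, np.arange(1, n + 1))
        px = lab == 1 + np.argmax(sizes)
    px[0, :] = px[-1, :] = px[:, 0] = px[:, -1] = False
    return CellMask(px, 0.5)
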