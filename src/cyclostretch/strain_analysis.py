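"""Recover substrate strain from micropattern fiducial-grid images.

The elastic gel carries a microcontact-printed grid of bright 50 µm squares
at 100 µm pitch. Stretching the gel deforms the grid affinely; comparing a
reference and a deformed image therefore yields the axial and transverse
engineering strains, their ratio (a measure of how uniaxial the stretch
is), the linearity of strain transmission, and the residual strain after
release.

Strain is computed from the center-to-center pitch of the detected squares
rather than from their side lengths: centroid spacing is insensitive to the
threshold used to segment the squares, while the apparent side length
shifts with it. A side-based estimate is still reported in the
:class:`GridFit` for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import DetectionError, InputError, PairingError
from .synthetic_data import MicropatternImage


@dataclass(frozen=True)
class GridFit:
    """Geometry of the detected fiducial grid, in µm.

    ``side_ax``/``side_tr`` are the mean axis-aligned square extents along
    and across the stretch axis; ``pitch_ax``/``pitch_tr`` the mean
    center-to-center spacings.
    """

    centers: np.ndarray  # (n, 2) array of (x, y) µm, row-major order
    side_ax: float
    side_tr: float
    pitch_ax: float
    pitch_tr: float
    n_detected: int

    def __post_init__(self) -> None:
        if self.n_detected < 4:
            raise DetectionError(f"grid fit needs >= 4 squares, got {self.n_detected}")
        if min(self.side_ax, self.side_tr, self.pitch_ax, self.pitch_tr) <= 0:
            raise InputError("sides and pitches must be > 0")


@dataclass(frozen=True)
class StrainMeasurement:
    """Axial and transverse engineering strain; ratio is |eps_tr|/|eps_ax|."""

    eps_ax: float
    eps_tr: float
    ratio: float | None

    @property
    def eps_ax_percent(self) -> float:
        return 100.0 * self.eps_ax

    @property
    def eps_tr_percent(self) -> float:
        return 100.0 * self.eps_tr


class LinearFit(NamedTuple):
    slope: float
    intercept: float
    r_squared: float


def _group_rows(values: np.ndarray, gap: float) -> list[np.ndarray]:
    """Indices grouped by 1-D clustering: split sorted values at gaps > gap."""
    order = np.argsort(values)
    groups: list[list[int]] = [[order[0]]]
    for idx in order[1:]:
        if values[idx] - values[groups[-1][-1]] > gap:
            groups.append([idx])
        else:
            groups[-1].append(idx)
    return [np.asarray(g) for g in groups]


def detect_grid(image: MicropatternImage, stretch_axis: str = "x") -> GridFit:
    """Detect the bright squares and summarize the grid geometry.

    Otsu-thresholds the image, labels connected components, rejects
    components touching the border or deviating more than 50% from the
    median component area, and reports per-square centroids and
    axis-aligned extents. Centers are returned row-major (by transverse
    coordinate, then axial).
    """
    arr = image.pixels
    if arr.max() <= 0:
        raise DetectionError("blank image: no squares above background")
    bw = arr > threshold_otsu(arr)
    lab = label(bw)
    props = regionprops(lab)
    h, w = arr.shape
    kept = []
    for p in props:
        r0, c0, r1, c1 = p.bbox
        if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
            continue
        kept.append(p)
    if kept:
        med = float(np.median([p.area for p in kept]))
        kept = [p for p in kept if abs(p.area - med) <= 0.5 * med]
    if len(kept) < 4:
        raise DetectionError(f"only {len(kept)} squares detected, need >= 4")
    ps = image.pixel_size
    cx = np.array([p.centroid[1] for p in kept]) * ps
    cy = np.array([p.centroid[0] for p in kept]) * ps
    wx = np.array([(p.bbox[3] - p.bbox[1]) for p in kept]) * ps
    wy = np.array([(p.bbox[2] - p.bbox[0]) for p in kept]) * ps
    if stretch_axis == "x":
        ax, tr, side_ax, side_tr = cx, cy, wx, wy
    elif stretch_axis == "y":
        ax, tr, side_ax, side_tr = cy, cx, wy, wx
    else:
        raise InputError("stretch_axis must be 'x' or 'y'")
    gap = float(np.mean(side_ax))  # rows are ~1 pitch apart, >> in-row scatter
    row_groups = _group_rows(tr, gap)
    col_groups = _group_rows(ax, gap)
    pitch_ax_vals = [np.diff(np.sort(ax[g])) for g in row_groups if g.size >= 2]
    pitch_tr_vals = [np.diff(np.sort(tr[g])) for g in col_groups if g.size >= 2]
    if not pitch_ax_vals or not pitch_tr_vals:
        raise DetectionError("grid layout too sparse to measure pitch")
    order = np.lexsort((ax, tr))
    centers = np.column_stack([cx, cy])[order]
    return GridFit(
        centers=centers,
        side_ax=float(np.mean(side_ax)),
        side_tr=float(np.mean(side_tr)),
        pitch_ax=float(np.mean(np.concatenate(pitch_ax_vals))),
        pitch_tr=float(np.mean(np.concatenate(pitch_tr_vals))),
        n_detected=len(kept),
    )


def measure_strain(ref: GridFit, stretched: GridFit) -> StrainMeasurement:
    """Engineering strain of the deformed grid relative to the reference.

    Pitch-based: ``eps = (pitch_deformed - pitch_ref) / pitch_ref`` per
    axis. The anisotropy ratio ``|eps_tr|/|eps_ax|`` is reported when the
    axial strain is non-negligible.
    """
    if ref.n_detected != stretched.n_detected:
        raise PairingError(
            f"grids have {ref.n_detected} vs {stretched.n_detected} squares"
        )
    eps_ax = (stretched.pitch_ax - ref.pitch_ax) / ref.pitch_ax
    eps_tr = (stretched.pitch_tr - ref.pitch_tr) / ref.pitch_tr
    ratio = abs(eps_tr) / abs(eps_ax) if abs(eps_ax) > 1e-6 else None
    return StrainMeasurement(eps_ax=eps_ax, eps_tr=eps_tr, ratio=ratio)


def strain_linearity(
    commanded: Sequence[float], measured: Sequence[StrainMeasurement]
) -> dict[str, LinearFit]:
    """Ordinary least-squares fit of measured vs commanded strain, per axis."""
    if len(commanded) != len(measured):
        raise InputError("commanded and measured must have equal length")
    if len(commanded) < 3:
        raise InputError("need >= 3 points for a linear fit")
    x = np.asarray(commanded, dtype=float)
    out = {}
    for name, y in (
        ("axial", np.array([m.eps_ax for m in measured])),
        ("transverse", np.array([m.eps_tr for m in measured])),
    ):
        if np.allclose(y, y[0]):
            out[name] = LinearFit(0.0, float(y[0]), 1.0)
            continue
        res = stats.linregress(x, y)
        out[name] = LinearFit(float(res.slope), float(res.intercept), float(res.rvalue**2))
    return out


def residual_strain(ref: GridFit, relaxed: GridFit) -> StrainMeasurement:
    """Strain remaining after release: same computation as :func:`measure_strain`
    applied to the before-stretching / after-relaxation pair. Summaries report
    the magnitude in percent."""
    return measure_strain(ref, relaxed)
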