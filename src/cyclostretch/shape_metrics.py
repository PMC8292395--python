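"""Per-frame cell morphometrics and their time courses.

Implements the orientation/shape readouts used to quantify stretch-induced
reorientation: the moment-equivalent ellipse of the mask and the derived
orientation index cos 2θ, the stretch-axis-aligned bounding rectangle
(axial/transverse cell length), and the spreading area.

Angle convention: θ is the angle of the ellipse major axis measured from
the chosen reference axis, in degrees, wrapped into (−90, 90]. With the
default reference (the stretch axis) the orientation index is +1 for a
cell parallel to stretching and −1 perpendicular; with the transverse
reference the sign flips.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .synthetic_data import CellMask


@dataclass(frozen=True)
class EllipseFit:
    """Moment-equivalent ellipse of a binary mask (lengths in µm)."""

    centroid: tuple[float, float]  # (x, y) µm
    major: float
    minor: float
    theta: float  # degrees from the stretch axis, in (-90, 90]
    eccentricity: float


@dataclass(frozen=True)
class ShapeSummary:
    time: float
    cycle: int
    phase: str
    orientation_index: float
    axial_length: float
    transverse_length: float
    area: float


_ECC_TIE_BREAK = 0.01  # below this eccentricity the angle is reported as 0


def fit_ellipse(mask: CellMask) -> EllipseFit:
    """Fit the ellipse with the same area-normalized second central moments.

    For a near-circular mask (eccentricity < 0.01) the angle is undefined
    and reported as 0 by tie-break.
    """
    rows, cols = np.nonzero(mask.pixels)
    if rows.size == 0:
        raise InputError("cannot fit an ellipse to an empty mask")
    ps = mask.pixel_size
    x = cols * ps
    y = rows * ps
    xbar, ybar = x.mean(), y.mean()
    dx, dy = x - xbar, y - ybar
    mxx = np.mean(dx * dx)
    myy = np.mean(dy * dy)
    mxy = np.mean(dx * dy)
    if mask.stretch_axis == "y":  # measure the angle from the y image axis
        mxx, myy = myy, mxx
    common = np.hypot(mxx - myy, 2 * mxy)
    lam1 = (mxx + myy + common) / 2.0
    lam2 = (mxx + myy - common) / 2.0
    lam2 = max(lam2, 0.0)
    major = 4.0 * np.sqrt(lam1)
    minor = 4.0 * np.sqrt(lam2)
    ecc = np.sqrt(1.0 - lam2 / lam1) if lam1 > 0 else 0.0
    if ecc < _ECC_TIE_BREAK:
        theta = 0.0
    else:
        theta = np.degrees(0.5 * np.arctan2(2 * mxy, mxx - myy))
        if theta <= -90.0:
            theta += 180.0
    return EllipseFit(
        centroid=(float(xbar), float(ybar)),
        major=float(major),
        minor=float(minor),
        theta=float(theta),
        eccentricity=float(ecc),
    )


def orientation_index(fit: EllipseFit, reference: str = "stretch_axis") -> float:
    """cos 2θ of the major axis relative to the chosen reference axis.

    With ``reference="stretch_axis"`` (the convention used for all internal
    time courses) a cell parallel to stretching scores +1 and a
    perpendicular cell −1; ``reference="transverse_axis"`` flips the sign.
    """
    val = float(np.cos(np.deg2rad(2.0 * fit.theta)))
    if reference == "stretch_axis":
        return val
    if reference == "transverse_axis":
        return -val
    raise InputError(f"unknown reference {reference!r}")


def fit_rectangle(mask: CellMask) -> tuple[float, float]:
    """Axis-aligned bounding rectangle: (axial_length, transverse_length) µm."""
    rows, cols = np.nonzero(mask.pixels)
    if rows.size == 0:
        raise InputError("cannot fit a rectangle to an empty mask")
    ps = mask.pixel_size
    height = (rows.max() - rows.min() + 1) * ps
    width = (cols.max() - cols.min() + 1) * ps
    if mask.stretch_axis == "x":
        return float(width), float(height)
    return float(height), float(width)


def spreading_area(mask: CellMask) -> float:
    """Projected footprint area: foreground pixel count × pixel_size²."""
    if not mask.pixels.any():
        raise InputError("empty mask has no area")
    return mask.area_um2


def summarize_timecourse(
    stack: Sequence[CellMask],
    phase_filter: Iterable[str] | None = None,
) -> list[ShapeSummary]:
    """Apply the three shape metrics to every matching frame, ordered by time.

    By default only relaxed-substrate frames are summarized (everything
    except ``during_stretch``), so the affine distortion of the stretched
    substrate never contaminates the time course.
    """
    if not stack:
        raise InputError("empty frame stack")
    if phase_filter is None:
        keep = {"pre_stretch", "post_release", "relaxation_end"}
    elif isinstance(phase_filter, str):
        keep = {phase_filter}
    else:
        keep = set(phase_filter)
    frames = sorted(
        (f for f in stack if f.phase_tag in keep), key=lambda f: f.time
    )
    if not frames:
        raise InputError(f"no frames match phase filter {sorted(keep)}")
    out = []
    for f in frames:
        fit = fit_ellipse(f)
        ax_len, tr_len = fit_rectangle(f)
        out.append(
            ShapeSummary(
                time=f.time,
                cycle=f.cycle_index,
                phase=f.phase_tag,
                orientation_index=orientation_index(fit),
                axial_length=ax_len,
                transverse_length=tr_len,
                area=spreading_area(f),
            )
        )
    return out


def timecourse_frame(summaries: Sequence[ShapeSummary]) -> pd.DataFrame:
    """Tabulate summaries with the package's standard CSV columns."""
    return pd.DataFrame(
        {
            "time_s": [s.time for s in summaries],
            "cycle": [s.cycle for s in summaries],
            "phase": [s.phase for s in summaries],
            "orientation_index": [s.orientation_index for s in summaries],
            "axial_length_um": [s.axial_length for s in summaries],
            "transverse_length_um": [s.transverse_length for s in summaries],
            "area_um2": [s.area for s in summaries],
        }
    )
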