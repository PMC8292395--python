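"""Difference-imaging quantification of protrusion and retraction.

Consecutive frames are compared pixelwise: area gained between the two is
protrusion (+1), area lost is retraction (−1). The cell is divided into two
axial and two transverse quadrants by the ±45° diagonals through its
centroid, and the signed change in each quadrant is integrated and
normalized by the spreading area, yielding the per-cycle net
extension/retraction profiles that explain stretch-induced reorientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._geometry import QUADRANTS, mask_centroid, sector_labels
from .errors import ConfigurationError, InputError, ScheduleError
from .synthetic_data import CellMask


@dataclass(frozen=True)
class DifferenceMap:
    """Signed ternary change map between two frames taken at t1 < t2."""

    labels: np.ndarray  # int8, values in {-1, 0, +1}
    pixel_size: float
    t_pair: tuple[float, float]

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int8)
        object.__setattr__(self, "labels", lab)
        if self.t_pair[1] <= self.t_pair[0]:
            raise InputError("t_pair must satisfy t2 > t1")


@dataclass(frozen=True)
class QuadrantPartition:
    """Full-frame quadrant labelling anchored at the cell centroid."""

    labels: np.ndarray  # int8 codes following _geometry.QUADRANTS order
    centroid: tuple[float, float]  # (x, y) µm
    pixel_size: float


@dataclass(frozen=True)
class QuadrantChange:
    """Per-quadrant protrusion/retraction/net, as fractions of norm_area."""

    net: Mapping[str, float]
    protrusion: Mapping[str, float]
    retraction: Mapping[str, float]
    norm_area: float


def difference_map(frame1, frame2, intensity_threshold: float | None = None) -> DifferenceMap:
    """Classify each pixel as protrusion (+1), retraction (−1), or unchanged.

    Binary mask mode (``CellMask`` or boolean arrays): protrusion is
    ``frame2 & ~frame1``, retraction ``frame1 & ~frame2``; the threshold is
    ignored. Intensity mode (float arrays): after subtracting each frame's
    median background, pixels whose difference exceeds
    ``±intensity_threshold`` are labelled ±1.
    """
    if isinstance(frame1, CellMask) and isinstance(frame2, CellMask):
        a1, a2 = frame1.pixels, frame2.pixels
        ps = frame1.pixel_size
        t_pair = (frame1.time, frame2.time)
        binary = True
    else:
        a1 = np.asarray(frame1)
        a2 = np.asarray(frame2)
        ps = 1.0
        t_pair = (0.0, 1.0)
        binary = a1.dtype == bool and a2.dtype == bool
    if a1.shape != a2.shape:
        raise InputError(f"frame shapes differ: {a1.shape} vs {a2.shape}")
    if binary:
        labels = a2.astype(np.int8) - a1.astype(np.int8)
    else:
        if intensity_threshold is None:
            raise ConfigurationError(
                "intensity-image mode requires an intensity_threshold"
            )
        d = (a2 - np.median(a2)) - (a1 - np.median(a1))
        labels = (d > intensity_threshold).astype(np.int8) - (
            d < -intensity_threshold
        ).astype(np.int8)
    return DifferenceMap(labels=labels, pixel_size=ps, t_pair=t_pair)


def partition_quadrants(mask: CellMask) -> QuadrantPartition:
    """Quadrant partition of the frame by ±45° diagonals through the centroid.

    With dx the pixel offset from the centroid along the stretch axis and dy
    transverse: axial_plus where dx > 0 and dx ≥ |dy|, axial_minus where
    dx < 0 and −dx ≥ |dy|, transverse otherwise; diagonal ties and the
    centroid pixel go to the axial sectors.
    """
    if not mask.pixels.any():
        raise InputError("cannot partition an empty mask")
    cy, cx = mask_centroid(mask.pixels)
    labels = sector_labels(mask.pixels.shape, (cy, cx), mask.stretch_axis)
    return QuadrantPartition(
        labels=labels,
        centroid=(cx * mask.pixel_size, cy * mask.pixel_size),
        pixel_size=mask.pixel_size,
    )


def net_area_change(
    diff: DifferenceMap, part: QuadrantPartition, norm_area: float
) -> QuadrantChange:
    """Integrate the change map per quadrant, normalized by ``norm_area`` (µm²)."""
    if norm_area <= 0:
        raise InputError("norm_area must be > 0")
    if diff.labels.shape != part.labels.shape:
        raise InputError("difference map and partition shapes differ")
    px2 = diff.pixel_size**2
    protrusion, retraction, net = {}, {}, {}
    for code, name in enumerate(QUADRANTS):
        sel = part.labels == code
        pro = int(np.count_nonzero(diff.labels[sel] == 1)) * px2 / norm_area
        ret = int(np.count_nonzero(diff.labels[sel] == -1)) * px2 / norm_area
        protrusion[name] = pro
        retraction[name] = ret
        net[name] = pro - ret
    return QuadrantChange(
        net=net, protrusion=protrusion, retraction=retraction, norm_area=norm_area
    )


_PAIRS = {
    "retraction": ("pre_stretch", "post_release"),
    "extension": ("post_release", "relaxation_end"),
}


def cycle_response_profile(
    stack: Sequence[CellMask],
    schedule: Sequence[int] | None = None,
    normalization: str = "pair_mean_area",
) -> pd.DataFrame:
    """Per-checkpoint retraction- and extension-phase quadrant changes.

    For each checkpoint cycle the retraction-phase change is measured on the
    (pre_stretch → post_release) frame pair and the extension-phase change
    on (post_release → relaxation_end). The quadrant partition is anchored
    on the earlier frame of each pair. Axial entries are pooled as the mean
    of the two axial quadrants, transverse analogously, matching the usual
    bar-chart layout.

    ``normalization`` is ``"pair_mean_area"`` (mean spreading area of the
    two frames) or ``"initial_area"`` (area of the first frame in the
    stack).

    Returns a long-format table with columns
    ``cycle, pair_type, quadrant, value``.
    """
    if normalization not in ("pair_mean_area", "initial_area"):
        raise ConfigurationError(f"unknown normalization {normalization!r}")
    by_cycle: dict[int, dict[str, CellMask]] = {}
    for f in stack:
        by_cycle.setdefault(f.cycle_index, {})[f.phase_tag] = f
    cycles = sorted(by_cycle) if schedule is None else list(schedule)
    initial_area = min(stack, key=lambda f: f.time).area_um2
    rows = []
    for cyc in cycles:
        phases = by_cycle.get(cyc, {})
        for pair_type, (ph1, ph2) in _PAIRS.items():
            if ph1 not in phases or ph2 not in phases:
                if schedule is not None:
                    raise ScheduleError(
                        f"checkpoint cycle {cyc} is missing its "
                        f"({ph1}, {ph2}) frame pair"
                    )
                continue
            f1, f2 = phases[ph1], phases[ph2]
            norm = (
                (f1.area_um2 + f2.area_um2) / 2.0
                if normalization == "pair_mean_area"
                else initial_area
            )
            change = net_area_change(
                difference_map(f1, f2), partition_quadrants(f1), norm
            )
            pooled = {
                "axial": (change.net["axial_plus"] + change.net["axial_minus"]) / 2.0,
                "transverse": (
                    change.net["transverse_plus"] + change.net["transverse_minus"]
                )
                / 2.0,
            }
            for quadrant, value in pooled.items():
                rows.append(
                    {
                        "cycle": cyc,
                        "pair_type": pair_type,
                        "quadrant": quadrant,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows, columns=["cycle", "pair_type", "quadrant", "value"])
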