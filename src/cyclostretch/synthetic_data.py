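"""Synthetic time-lapse generator for cyclic-stretch experiments.

This module produces everything the analysis side of the package consumes:

* binary single-cell masks evolving under a per-cycle retraction/protrusion
  model of the response to uniaxial cyclic substrate stretch, and
* fluorescent micropattern images of a square fiducial grid under affine
  substrate strain, used to calibrate strain recovery.

The cell model formalizes the observed phenomenology of epithelial cells on
cyclically stretched elastic gels: on each release of stretch the cell
retracts uniformly around its perimeter, with a magnitude that decays
cycle-by-cycle, and during the relaxation phase it extends with a
*persistent* rate into the transverse quadrants and a *decaying* rate into
the axial quadrants. The cumulative result is transverse reorientation.

Rate laws (the model's own formalization; magnitudes are not measured
quantities):

* retraction at cycle ``n`` removes an area fraction
  ``r(n) = r0 * exp(-(n - 1) / r_decay)`` of the current spreading area;
* transverse protrusion adds area at constant rate ``p_T`` (fraction of
  spreading area per second of relaxation), split between the two
  transverse quadrants;
* axial protrusion rate decays with cumulative stretching time ``t``:
  ``p_A(t) = p_A0 * exp(-t / p_A_tau)``, split between the axial quadrants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ._geometry import (
    AXIAL_MINUS,
    AXIAL_PLUS,
    TRANSVERSE_MINUS,
    TRANSVERSE_PLUS,
    mask_centroid,
)
from .errors import ConfigurationError, DimensionError, DynamicsError, InputError

WAVEFORMS = ("square", "triangular", "trapezoid")
PHASES = ("pre_stretch", "during_stretch", "post_release", "relaxation_end")
CONDITIONS = ("control", "blebbistatin", "nocodazole", "nocodazole_blebbistatin")

#: 4-connectivity structuring element used for all component checks.
_CROSS = ndimage.generate_binary_structure(2, 1)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StretchProtocol:
    """Uniaxial stretch waveform plus the frame-acquisition schedule.

    ``stretch_duration + relax_duration`` must equal one period
    ``1 / frequency``. Amplitude is engineering strain along the stretch
    axis; the substrate contracts transversely by
    ``transverse_ratio * amplitude`` (Poisson-like, sign configurable at the
    point of use). ``sample_points`` lists ``(cycle_index, phase_tag)``
    pairs at which frames are emitted.
    """

    waveform: str = "square"
    amplitude: float = 0.15
    frequency: float = 0.5
    n_cycles: int = 10
    stretch_duration: float = 1.0
    relax_duration: float = 1.0
    transverse_ratio: float = 0.15
    ramp_time: float = 0.25
    sample_points: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.waveform not in WAVEFORMS:
            raise ConfigurationError(
                f"unknown waveform {self.waveform!r}; expected one of {WAVEFORMS}"
            )
        if not 0.0 < self.amplitude <= 0.20:
            raise ConfigurationError("amplitude must lie in (0, 0.20]")
        if not 0.0 <= self.transverse_ratio <= 0.16:
            raise ConfigurationError("transverse_ratio must lie in [0, 0.16]")
        if self.frequency <= 0 or self.n_cycles < 1:
            raise ConfigurationError("frequency must be > 0 and n_cycles >= 1")
        if self.stretch_duration < 0 or self.relax_duration <= 0:
            raise ConfigurationError("durations must be positive")
        if abs(self.stretch_duration + self.relax_duration - 1.0 / self.frequency) > 1e-9:
            raise ConfigurationError(
                "stretch_duration + relax_duration must equal 1/frequency"
            )
        if self.waveform == "trapezoid" and not (
            0 < self.ramp_time <= self.stretch_duration / 2
        ):
            raise ConfigurationError("trapezoid ramp_time must be in (0, stretch_duration/2]")
        for cyc, phase in self.sample_points:
            if phase not in PHASES:
                raise ConfigurationError(f"unknown phase tag {phase!r}")
            if not 1 <= cyc <= self.n_cycles:
                raise ConfigurationError(
                    f"sample point cycle {cyc} outside 1..{self.n_cycles}"
                )

    @property
    def period(self) -> float:
        return 1.0 / self.frequency


@dataclass(frozen=True)
class DynamicsParams:
    """Rate-law parameters of the per-cycle cell response model.

    Attributes
    ----------
    r0 : fraction of spreading area removed at the first stretch release.
    r_decay : per-cycle decay constant of retraction magnitude (cycles).
    p_T : transverse protrusion rate, area fraction per second of relaxation
        (constant across cycles).
    p_A0 : initial axial protrusion rate, area fraction per second.
    p_A_tau : decay time of the axial rate, minutes of cumulative stretching.
    noise_sigma : boundary roughness amplitude in µm; perturbs where on the
        edge the retraction/protrusion pixels are taken without changing the
        target areas.
    protrusion_cone_deg : half-angle (degrees) of the cone about each
        quadrant axis into which protrusion growth is directed; keeps the
        lobes spindle-like instead of fanning out to the sector diagonals.
    condition : label of the preset family this parameter set belongs to.
    """

    r0: float = 0.10
    r_decay: float = 1.3
    p_T: float = 1.2e-4
    p_A0: float = 2.0e-5
    p_A_tau: float = 5.0
    noise_sigma: float = 0.3
    protrusion_cone_deg: float = 20.0
    condition: str = "control"

    def __post_init__(self) -> None:
        if min(self.r0, self.p_T, self.p_A0) < 0:
            raise ConfigurationError("r0, p_T and p_A0 must be >= 0")
        if self.r_decay <= 0 or self.p_A_tau <= 0:
            raise ConfigurationError("r_decay and p_A_tau must be > 0")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if not 0 < self.protrusion_cone_deg <= 45:
            raise ConfigurationError("protrusion_cone_deg must be in (0, 45]")

    def retraction_fraction(self, cycle_index: int) -> float:
        """Area fraction removed at release of cycle ``cycle_index`` (1-based)."""
        if cycle_index < 1:
            raise ConfigurationError("cycle_index must be >= 1")
        return self.r0 * float(np.exp(-(cycle_index - 1) / self.r_decay))

    def axial_rate(self, t_cum_s: float) -> float:
        """Axial protrusion rate after ``t_cum_s`` seconds of cumulative stretching."""
        return self.p_A0 * float(np.exp(-t_cum_s / (self.p_A_tau * 60.0)))


@dataclass(frozen=True)
class CellMask:
    """One binary cell silhouette frame with calibration and phase annotation."""

    pixels: np.ndarray
    pixel_size: float
    time: float = 0.0
    cycle_index: int = 0
    phase_tag: str = "pre_stretch"
    stretch_axis: str = "x"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=bool))
        if self.pixel_size <= 0:
            raise InputError("pixel_size must be > 0")
        if self.stretch_axis not in ("x", "y"):
            raise InputError("stretch_axis must be 'x' or 'y'")

    def validate(self) -> "CellMask":
        """Check the mask invariants; returns self for chaining."""
        px = self.pixels
        if not px.any():
            raise InputError("cell mask is empty")
        n = ndimage.label(px, structure=_CROSS)[1]
        if n != 1:
            raise InputError(f"cell mask has {n} 4-connected components, expected 1")
        if px[0, :].any() or px[-1, :].any() or px[:, 0].any() or px[:, -1].any():
            raise InputError("cell mask touches the image border")
        return self

    @property
    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_size**2

    def replace(self, **kw) -> "CellMask":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class MicropatternImage:
    """Rendered fluorescence image of the square fiducial grid."""

    pixels: np.ndarray
    pixel_size: float
    grid_spec: tuple[float, float, int, int] = (50.0, 100.0, 6, 6)
    applied_strain: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=float)
        if (arr < 0).any():
            raise InputError("micropattern intensities must be >= 0")
        object.__setattr__(self, "pixels", arr)
        if self.pixel_size <= 0:
            raise InputError("pixel_size must be > 0")
        side, pitch, n_rows, n_cols = self.grid_spec
        if side <= 0 or pitch <= side:
            raise ConfigurationError("grid_spec requires pitch > square_side > 0")


# --------------------------------------------------------------------------
# waveform
# --------------------------------------------------------------------------


def waveform_strain(protocol: StretchProtocol, t):
    """Instantaneous axial substrate strain at time(s) ``t`` (seconds).

    Square returns the full amplitude throughout the stretch window;
    triangular ramps linearly to the amplitude at mid-window and back with
    zero dwell; trapezoid ramps over ``ramp_time`` with a dwell at the
    amplitude and at zero. All waveforms are periodic with period
    ``1/frequency`` and evaluate to 0 at the cycle start.
    """
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise InputError("t must be >= 0")
    tin = np.mod(t, protocol.period)
    sd = protocol.stretch_duration
    amp = protocol.amplitude
    if protocol.waveform == "square":
        eps = np.where((tin > 0) & (tin <= sd), amp, 0.0)
    elif protocol.waveform == "triangular":
        half = sd / 2.0
        up = amp * tin / half
        down = amp * (sd - tin) / half
        eps = np.where(tin <= half, up, np.where(tin <= sd, down, 0.0))
    else:  # trapezoid
        rt = protocol.ramp_time
        eps = np.select(
            [tin <= rt, tin <= sd, tin <= sd + rt],
            [amp * tin / rt, amp, amp * (sd + rt - tin) / rt],
            default=0.0,
        )
    eps = np.clip(eps, 0.0, amp)
    return float(eps) if eps.ndim == 0 else eps


# --------------------------------------------------------------------------
# initial cell and substrate strain
# --------------------------------------------------------------------------


def make_initial_cell(
    radius: float = 25.0,
    irregularity: float = 0.0,
    pixel_size: float = 0.5,
    image_shape: tuple[int, int] = (512, 512),
    seed=None,
    rng: np.random.Generator | None = None,
    stretch_axis: str = "x",
    n_harmonics: int = 5,
) -> CellMask:
    """Rasterize a near-circular well-spread cell mask.

    With ``irregularity == 0`` the mask is a disc of the given radius. With
    ``irregularity > 0`` the radius is modulated smoothly around the
    perimeter by a random low-order Fourier series whose peak relative
    amplitude equals ``irregularity``; the perturbation is reproducible from
    the seed.
    """
    if radius <= 0:
        raise ConfigurationError("radius must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    h, w = image_shape
    if radius * (1 + irregularity) / pixel_size >= min(h, w) / 2 - 2:
        raise DimensionError(
            f"cell of radius {radius} µm does not fit a {image_shape} frame "
            f"at {pixel_size} µm/pixel"
        )
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rr, cc = np.mgrid[0:h, 0:w]
    dy = (rr - cy) * pixel_size
    dx = (cc - cx) * pixel_size
    rho = np.hypot(dx, dy)
    if irregularity > 0:
        phi = np.arctan2(dy, dx)
        ks = np.arange(2, 2 + n_harmonics)
        amps = rng.normal(size=n_harmonics) / ks
        phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)
        s = np.zeros_like(phi)
        for a, k, p in zip(amps, ks, phases):
            s += a * np.cos(k * phi + p)
        peak = np.abs(s).max()
        if peak > 0:
            s /= peak
        r_phi = radius * (1.0 + irregularity * s)
    else:
        r_phi = radius
    mask = rho <= r_phi
    return CellMask(mask, pixel_size, stretch_axis=stretch_axis).validate()


def apply_substrate_strain(frame, eps_ax: float, eps_tr: float):
    """Affinely scale a frame about its center by the given strains.

    The length scale is ``1 + eps_ax`` along the stretch axis and
    ``1 + eps_tr`` transverse. Binary masks are linearly interpolated and
    re-binarized at 0.5; intensity images are linearly interpolated. Returns
    the same type as the input.
    """
    if eps_ax <= -1 or eps_tr <= -1:
        raise InputError("strains must be > -1")
    if isinstance(frame, CellMask):
        arr = frame.pixels.astype(float)
        axis = frame.stretch_axis
    elif isinstance(frame, MicropatternImage):
        arr = frame.pixels
        axis = "x"
    else:
        raise InputError(f"cannot strain object of type {type(frame).__name__}")
    if eps_ax == 0.0 and eps_tr == 0.0:
        return frame
    # image axes: rows (y), cols (x); the affine maps output -> input coords
    if axis == "x":
        scale_row, scale_col = 1.0 + eps_tr, 1.0 + eps_ax
    else:
        scale_row, scale_col = 1.0 + eps_ax, 1.0 + eps_tr
    h, w = arr.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    matrix = np.diag([1.0 / scale_row, 1.0 / scale_col])
    offset = center - matrix @ center
    out = ndimage.affine_transform(arr, matrix, offset=offset, order=1, mode="constant")
    if isinstance(frame, CellMask):
        return frame.replace(pixels=out >= 0.5)
    ax0, tr0 = frame.applied_strain
    return dataclasses.replace(
        frame,
        pixels=np.clip(out, 0.0, None),
        applied_strain=((1 + ax0) * (1 + eps_ax) - 1, (1 + tr0) * (1 + eps_tr) - 1),
    )


# --------------------------------------------------------------------------
# per-cycle dynamics
# --------------------------------------------------------------------------


def _noise(rng: np.random.Generator, shape, sigma_px: float) -> np.ndarray:
    if sigma_px <= 0:
        return np.zeros(shape)
    return rng.normal(0.0, sigma_px, size=shape)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=_CROSS)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def _retract(mask: np.ndarray, n_px: int, rng, sigma_px: float) -> tuple[np.ndarray, int]:
    """Remove ~n_px pixels as a uniform perimeter peel (smallest depth first)."""
    area = int(mask.sum())
    if n_px <= 0:
        return mask, 0
    if n_px >= area:
        raise DynamicsError(
            f"retraction of {n_px} px would empty a {area}-px cell mask"
        )
    depth = ndimage.distance_transform_edt(mask)
    score = depth + _noise(rng, mask.shape, sigma_px)
    flat = np.flatnonzero(mask)
    order = np.argsort(score.ravel()[flat], kind="stable")
    out = mask.copy()
    out.ravel()[flat[order[:n_px]]] = False
    out = _largest_component(out)
    return out, area - int(out.sum())


def _protrude(
    mask: np.ndarray,
    targets: dict[int, int],
    stretch_axis: str,
    rng,
    sigma_px: float,
    cone_deg: float = 20.0,
) -> tuple[np.ndarray, dict[int, int]]:
    """Grow the mask outward into per-quadrant cones by ~target pixels each.

    Directional boundary dilation: background pixels closest to the current
    edge are annexed first, restricted to a cone of half-angle ``cone_deg``
    about the quadrant axis through the centroid (always inside the ±45°
    quadrant sector).
    """
    if not any(v > 0 for v in targets.values()):
        return mask, {q: 0 for q in targets}
    cy, cx = mask_centroid(mask)
    rr, cc = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    if stretch_axis == "x":
        dax, dtr = cc - cx, rr - cy
    else:
        dax, dtr = rr - cy, cc - cx
    tan_a = np.tan(np.deg2rad(cone_deg))
    cones = {
        AXIAL_PLUS: (dax > 0) & (np.abs(dtr) <= tan_a * dax),
        AXIAL_MINUS: (dax < 0) & (np.abs(dtr) <= -tan_a * dax),
        TRANSVERSE_PLUS: (dtr > 0) & (np.abs(dax) <= tan_a * dtr),
        TRANSVERSE_MINUS: (dtr < 0) & (np.abs(dax) <= -tan_a * dtr),
    }
    dist = ndimage.distance_transform_edt(~mask)
    score = dist + _noise(rng, mask.shape, sigma_px)
    interior = np.zeros(mask.shape, dtype=bool)
    interior[1:-1, 1:-1] = True
    out = mask.copy()
    added = {}
    for q, n_px in targets.items():
        if n_px <= 0:
            added[q] = 0
            continue
        cand = np.flatnonzero(~mask & interior & cones[q])
        if cand.size < n_px:
            raise DynamicsError(
                f"sector {q} has only {cand.size} candidate pixels for a "
                f"{n_px}-px protrusion"
            )
        order = np.argsort(score.ravel()[cand], kind="stable")
        out.ravel()[cand[order[:n_px]]] = True
        added[q] = n_px
    before = int(mask.sum()) + sum(added.values())
    out = _largest_component(out)
    lost = before - int(out.sum())
    if lost:  # stray speckle dropped by the component filter; charge it evenly
        for q in added:
            take = min(added[q], lost)
            added[q] -= take
            lost -= take
            if lost == 0:
                break
    return out, added


def _cycle_events(
    cell: CellMask,
    params: DynamicsParams,
    cycle_index: int,
    relax_time: float,
    rng: np.random.Generator,
    t_cum_s: float,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """One release + relaxation: returns (post_release, relaxed, log)."""
    if relax_time < 0:
        raise ConfigurationError("relax_time must be >= 0")
    mask = cell.pixels
    area_px = int(mask.sum())
    sigma_px = params.noise_sigma / cell.pixel_size
    n_retract = int(round(params.retraction_fraction(cycle_index) * area_px))
    post, removed = _retract(mask, n_retract, rng, sigma_px)
    area_after = int(post.sum())
    n_t = int(round(params.p_T * relax_time * area_after))
    n_a = int(round(params.axial_rate(t_cum_s) * relax_time * area_after))
    targets = {
        TRANSVERSE_PLUS: n_t // 2,
        TRANSVERSE_MINUS: n_t - n_t // 2,
        AXIAL_PLUS: n_a // 2,
        AXIAL_MINUS: n_a - n_a // 2,
    }
    relaxed, added = _protrude(
        post, targets, cell.stretch_axis, rng, sigma_px, params.protrusion_cone_deg
    )
    px2 = cell.pixel_size**2
    log = {
        "cycle": cycle_index,
        "retraction_area_um2": removed * px2,
        "protrusion_T_um2": (added[TRANSVERSE_PLUS] + added[TRANSVERSE_MINUS]) * px2,
        "protrusion_A_um2": (added[AXIAL_PLUS] + added[AXIAL_MINUS]) * px2,
        "protrusion_by_quadrant_um2": {
            "axial_plus": added[AXIAL_PLUS] * px2,
            "axial_minus": added[AXIAL_MINUS] * px2,
            "transverse_plus": added[TRANSVERSE_PLUS] * px2,
            "transverse_minus": added[TRANSVERSE_MINUS] * px2,
        },
    }
    return post, relaxed, log


def step_cycle(
    cell: CellMask,
    params: DynamicsParams,
    cycle_index: int,
    relax_time: float,
    rng: np.random.Generator,
    t_cum_s: float | None = None,
) -> CellMask:
    """Advance a cell mask through one full stretch cycle.

    The cycle is composed of an immediate uniform perimeter retraction at
    stretch release, removing ``r(cycle_index)`` of the current area, and a
    protrusion phase of duration ``relax_time`` adding area into the
    transverse (rate ``p_T``) and axial (rate ``p_A``) quadrant pairs. The
    cumulative stretching time that drives the axial decay defaults to the
    input mask's ``time`` field. Returns the relaxed-state mask.
    """
    if cycle_index < 1:
        raise ConfigurationError("cycle_index must be >= 1")
    cell.validate()
    if t_cum_s is None:
        t_cum_s = cell.time
    _, relaxed, _ = _cycle_events(cell, params, cycle_index, relax_time, rng, t_cum_s)
    return cell.replace(
        pixels=relaxed,
        time=cell.time + relax_time,
        cycle_index=cycle_index,
        phase_tag="relaxation_end",
    ).validate()


def simulate_timecourse(
    protocol: StretchProtocol,
    params: DynamicsParams,
    cell0: CellMask,
    seed=None,
) -> tuple[list[CellMask], pd.DataFrame]:
    """Run the cell model under a periodic protocol, emitting scheduled frames.

    Frames are emitted at every ``(cycle, phase)`` in
    ``protocol.sample_points``; ``during_stretch`` frames are the current
    mask with the substrate affine map applied (the cell passively follows
    the substrate while stretched). The returned ground-truth table logs the
    realized retraction and per-direction protrusion areas of every cycle.
    Fully reproducible from the seed.
    """
    cell0.validate()
    rng = np.random.default_rng(seed)
    wanted = set(protocol.sample_points)
    for cyc, _ in wanted:
        if cyc > protocol.n_cycles:
            raise ConfigurationError(f"sample point cycle {cyc} beyond n_cycles")
    frames: list[CellMask] = []
    rows = []
    eps_tr = -protocol.transverse_ratio * protocol.amplitude
    t = 0.0
    mask = cell0
    for n in range(1, protocol.n_cycles + 1):
        pre = mask.replace(time=t, cycle_index=n, phase_tag="pre_stretch")
        if (n, "pre_stretch") in wanted:
            frames.append(pre)
        if (n, "during_stretch") in wanted:
            stretched = apply_substrate_strain(pre, protocol.amplitude, eps_tr)
            frames.append(
                stretched.replace(
                    time=t + protocol.stretch_duration / 2, phase_tag="during_stretch"
                )
            )
        post_px, relaxed_px, log = _cycle_events(
            pre, params, n, protocol.relax_duration, rng, t_cum_s=t
        )
        t_release = t + protocol.stretch_duration
        if (n, "post_release") in wanted:
            frames.append(
                pre.replace(pixels=post_px, time=t_release, phase_tag="post_release")
            )
        t_end = t_release + protocol.relax_duration
        relaxed = pre.replace(
            pixels=relaxed_px, time=t_end, phase_tag="relaxation_end"
        ).validate()
        if (n, "relaxation_end") in wanted:
            frames.append(relaxed)
        quad = log.pop("protrusion_by_quadrant_um2")
        rows.append(
            {
                "cycle": n,
                "time_s": t_end,
                **log,
                **{f"protrusion_{k}_um2": v for k, v in quad.items()},
                "area_um2": relaxed.area_um2,
            }
        )
        mask = relaxed
        t += protocol.period
    truth = pd.DataFrame(rows)
    return frames, truth


# --------------------------------------------------------------------------
# micropattern rendering
# --------------------------------------------------------------------------


def make_micropattern(
    grid_spec: tuple[float, float, int, int] = (50.0, 100.0, 6, 6),
    eps_ax: float = 0.0,
    eps_tr: float = 0.0,
    bead_noise_sigma: float = 0.0,
    pixel_size: float = 0.5,
    seed=None,
    margin_um: float = 40.0,
    max_strain: float = 0.25,
    bead_spacing: float = 1.0,
    spot_sigma: float = 0.4,
    bead_inset: float = 0.4,
) -> MicropatternImage:
    """Render the square fiducial grid as bead fluorescence under strain.

    Beads sit on a regular lattice inside each 50 µm square (microcontact
    printing concentrates them on the protein-coated regions); each square's
    corner coordinates are mapped by the affine substrate strain about the
    pattern center, then every bead position is perturbed by Gaussian
    localization noise of ``bead_noise_sigma`` (µm) and rendered as a
    Gaussian spot. The canvas is sized to hold the grid at up to
    ``max_strain``.
    """
    side, pitch, n_rows, n_cols = grid_spec
    if pitch <= side:
        raise ConfigurationError("grid pitch must exceed the square side")
    rng = np.random.default_rng(seed)
    span_x = pitch * (n_cols - 1) + side
    span_y = pitch * (n_rows - 1) + side
    w = int(round((span_x * (1 + max_strain) + 2 * margin_um) / pixel_size))
    h = int(round((span_y * (1 + max_strain) + 2 * margin_um) / pixel_size))
    if abs(eps_ax) > max_strain or abs(eps_tr) > max_strain:
        raise DimensionError("requested strain exceeds the canvas margin")
    offs = np.arange(bead_inset, side - bead_inset + 1e-9, bead_spacing)
    ox, oy = np.meshgrid(offs, offs)
    xs, ys = [], []
    for i in range(n_rows):
        for j in range(n_cols):
            x0 = -span_x / 2 + j * pitch
            y0 = -span_y / 2 + i * pitch
            xs.append(x0 + ox.ravel())
            ys.append(y0 + oy.ravel())
    bx = np.concatenate(xs) * (1 + eps_ax)
    by = np.concatenate(ys) * (1 + eps_tr)
    if bead_noise_sigma > 0:
        bx = bx + rng.normal(0.0, bead_noise_sigma, bx.shape)
        by = by + rng.normal(0.0, bead_noise_sigma, by.shape)
    px = bx / pixel_size + (w - 1) / 2.0
    py = by / pixel_size + (h - 1) / 2.0
    img = np.zeros((h, w))
    sig_px = spot_sigma / pixel_size
    reach = max(1, int(np.ceil(3 * sig_px)))
    dy, dx = np.mgrid[-reach : reach + 1, -reach : reach + 1]
    ix = np.round(px).astype(int)
    iy = np.round(py).astype(int)
    keep = (ix > reach) & (ix < w - reach - 1) & (iy > reach) & (iy < h - reach - 1)
    ix, iy, px, py = ix[keep], iy[keep], px[keep], py[keep]
    # all beads x all patch offsets, accumulated in one scatter-add
    gx = ix[:, None] + dx.ravel()[None, :]
    gy = iy[:, None] + dy.ravel()[None, :]
    val = np.exp(
        -((gx - px[:, None]) ** 2 + (gy - py[:, None]) ** 2) / (2 * sig_px**2)
    )
    np.add.at(img, (gy.ravel(), gx.ravel()), val.ravel())
    img *= 1000.0 / max(img.max(), 1e-12)
    return MicropatternImage(img, pixel_size, grid_spec, (eps_ax, eps_tr))


# --------------------------------------------------------------------------
# condition presets
# --------------------------------------------------------------------------

# Calibrated for the compressed checkpoint schedule of the pipeline (rates
# per second of elapsed experiment time); see docs/methods.md.
_PRESETS: dict[str, DynamicsParams] = {
    "control": DynamicsParams(
        r0=0.10, r_decay=1.3, p_T=1.2e-4, p_A0=2.0e-5, p_A_tau=5.0,
        noise_sigma=0.3, condition="control",
    ),
    # myosin II inhibition: retraction and transverse protrusion suppressed,
    # axial protrusion sustained -> axial orientation
    "blebbistatin": DynamicsParams(
        r0=0.005, r_decay=1.3, p_T=1.0e-5, p_A0=4.0e-5, p_A_tau=30.0,
        noise_sigma=0.3, condition="blebbistatin",
    ),
    # microtubule depolymerization: retraction and transverse protrusion
    # enhanced, axial decay faster -> stronger transverse reorientation
    "nocodazole": DynamicsParams(
        r0=0.14, r_decay=1.3, p_T=1.7e-4, p_A0=2.0e-5, p_A_tau=3.0,
        noise_sigma=0.3, condition="nocodazole",
    ),
    "nocodazole_blebbistatin": DynamicsParams(
        r0=0.003, r_decay=1.3, p_T=5.0e-6, p_A0=5.0e-5, p_A_tau=45.0,
        noise_sigma=0.3, condition="nocodazole_blebbistatin",
    ),
}


def preset_params(condition: str) -> DynamicsParams:
    """Documented default parameter set for a drug condition."""
    try:
        return _PRESETS[condition]
    except KeyError:
        raise ConfigurationError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        ) from None
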