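"""End-to-end experiments: simulate → measure → tabulate.

A run mirrors the structure of a live-cell cyclic-stretch experiment:
independent cells are simulated under a stretch protocol and a
drug-condition parameter set, shape metrics are computed on every
relaxed-substrate frame, and the difference-imaging quadrant analysis is
applied at each checkpoint. Population statistics are mean ± SEM across
cells.

To keep runs desk-scale the default schedule is *compressed*: frames are
taken at the checkpoints {0, 5, 15, 30, 45, 60, 90} min and each interval
between checkpoints is simulated as one *effective cycle* (release +
relaxation) whose rates are expressed per second of elapsed interval time.
An uncompressed per-cycle mode is available through
:func:`cyclostretch.synthetic_data.simulate_timecourse`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import AlignmentError, ConfigurationError, InputError
from .protrusion_analysis import cycle_response_profile
from .shape_metrics import summarize_timecourse, timecourse_frame
from .synthetic_data import (
    CellMask,
    DynamicsParams,
    StretchProtocol,
    _cycle_events,
    make_initial_cell,
    preset_params,
)

#: Checkpoint times of the compressed default schedule, minutes.
CHECKPOINTS_MIN = (0, 5, 15, 30, 45, 60, 90)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one simulated experiment."""

    condition: str = "control"
    params: DynamicsParams | None = None  # overrides the condition preset
    protocol: StretchProtocol = field(default_factory=StretchProtocol)
    n_cells: int = 6
    seed: int = 0
    pixel_size: float = 0.5
    image_shape: tuple[int, int] = (512, 512)
    cell_radius: float = 25.0
    irregularity: float = 0.15
    checkpoints_min: tuple[float, ...] = CHECKPOINTS_MIN
    normalization: str = "pair_mean_area"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if len(self.checkpoints_min) < 2 or list(self.checkpoints_min) != sorted(
            self.checkpoints_min
        ):
            raise ConfigurationError("checkpoints_min must be >= 2 increasing values")

    def resolved_params(self) -> DynamicsParams:
        return self.params if self.params is not None else preset_params(self.condition)


@dataclass
class ResultBundle:
    """Tables produced by one experiment run."""

    shape_timecourse: pd.DataFrame  # per cell, per checkpoint
    quadrant_profile: pd.DataFrame  # per cell, per checkpoint, long format
    population_means: pd.DataFrame  # per checkpoint mean ± SEM
    config: ExperimentConfig


def _simulate_cell(
    config: ExperimentConfig, params: DynamicsParams, cell_seed
) -> list[CellMask]:
    """One cell through the compressed checkpoint schedule."""
    rng = np.random.default_rng(cell_seed)
    cell = make_initial_cell(
        radius=config.cell_radius,
        irregularity=config.irregularity,
        pixel_size=config.pixel_size,
        image_shape=config.image_shape,
        rng=rng,
    )
    t_min = config.checkpoints_min
    frames: list[CellMask] = []
    mask = cell.replace(time=0.0, cycle_index=0, phase_tag="pre_stretch")
    for i in range(1, len(t_min)):
        t0, t1 = t_min[i - 1] * 60.0, t_min[i] * 60.0
        pre = mask.replace(time=t0, cycle_index=i, phase_tag="pre_stretch")
        frames.append(pre)
        post_px, relaxed_px, _ = _cycle_events(
            pre, params, i, relax_time=t1 - t0, rng=rng, t_cum_s=t0
        )
        # the release is effectively instantaneous on the checkpoint scale
        frames.append(
            pre.replace(pixels=post_px, time=t0 + 1.0, phase_tag="post_release")
        )
        mask = pre.replace(
            pixels=relaxed_px, time=t1, cycle_index=i, phase_tag="relaxation_end"
        ).validate()
        frames.append(mask)
    return frames


def run_experiment(config: ExperimentConfig) -> ResultBundle:
    """Simulate ``n_cells`` cells, measure them, and assemble result tables.

    Per-cell random streams are derived deterministically from the run seed,
    so a fixed config reproduces its outputs bitwise. If ``output_dir`` is
    set, all tables are written as CSV together with a JSON run manifest.
    """
    params = config.resolved_params()
    children = np.random.SeedSequence(config.seed).spawn(config.n_cells)
    shape_tables = []
    quadrant_tables = []
    for cell_id, child in enumerate(children):
        frames = _simulate_cell(config, params, child)
        relaxed = [f for f in frames if f.phase_tag in ("pre_stretch", "relaxation_end")]
        # keep one frame per checkpoint time (pre_stretch duplicates relaxation_end)
        seen: dict[float, CellMask] = {}
        for f in relaxed:
            seen.setdefault(f.time, f)
        tc = timecourse_frame(summarize_timecourse(list(seen.values())))
        tc.insert(0, "cell_id", cell_id)
        shape_tables.append(tc)
        qp = cycle_response_profile(frames, normalization=config.normalization)
        qp.insert(0, "cell_id", cell_id)
        quadrant_tables.append(qp)
    shape_timecourse = pd.concat(shape_tables, ignore_index=True)
    quadrant_profile = pd.concat(quadrant_tables, ignore_index=True)
    population = _population_means(shape_timecourse)
    bundle = ResultBundle(shape_timecourse, quadrant_profile, population, config)
    if config.output_dir is not None:
        _write_bundle(bundle, Path(config.output_dir))
    return bundle


_POP_METRICS = ("orientation_index", "axial_length_um", "transverse_length_um", "area_um2")


def _population_means(shape_timecourse: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SEM (sd/√n) over cells for every checkpoint."""
    rows = []
    for time_s, grp in shape_timecourse.groupby("time_s"):
        n = len(grp)
        row = {"time_s": time_s, "n": n}
        for metric in _POP_METRICS:
            vals = grp[metric].to_numpy()
            row[f"{metric}_mean"] = float(vals.mean())
            row[f"{metric}_sem"] = (
                float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows).sort_values("time_s", ignore_index=True)


def _write_bundle(bundle: ResultBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.shape_timecourse.to_csv(out_dir / "shape_timecourse.csv", index=False)
    bundle.quadrant_profile.to_csv(out_dir / "quadrant_profile.csv", index=False)
    bundle.population_means.to_csv(out_dir / "population_means.csv", index=False)
    cfg = dataclasses.asdict(bundle.config)
    cfg["params"] = dataclasses.asdict(bundle.config.resolved_params())
    cfg["protocol"] = dataclasses.asdict(bundle.config.protocol)
    manifest = {"package": "cyclostretch", "version": __version__, "config": cfg}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def compare_conditions(configs: Sequence[ExperimentConfig]) -> pd.DataFrame:
    """Run several conditions and merge their population means side by side.

    All configs must share the same checkpoint times. Returns a long table
    keyed by (condition, time_s).
    """
    if len(configs) < 2:
        raise InputError("need at least two configs to compare")
    ref_times = configs[0].checkpoints_min
    tables = []
    for cfg in configs:
        if tuple(cfg.checkpoints_min) != tuple(ref_times):
            raise AlignmentError("configs do not share checkpoint times")
        bundle = run_experiment(dataclasses.replace(cfg, output_dir=None))
        tab = bundle.population_means.copy()
        tab.insert(0, "condition", cfg.condition)
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)


def relaxation_fraction_check(
    rate: float,
    short_window: float,
    long_window: float,
    decay_tau: float | None = None,
) -> float:
    """Percent of the long-window extension accrued in the short window.

    For the constant transverse protrusion rate this is simply
    ``100 · short/long`` — e.g. a 1 s relaxation phase accrues 10% of the
    extension measured over a 10 s window. With ``decay_tau`` the rate is
    taken to decay exponentially within the relaxation and the closed form
    ``100 · (1 − e^(−t₁/τ)) / (1 − e^(−t₂/τ))`` is returned.
    """
    if short_window <= 0 or long_window <= 0:
        raise InputError("windows must be > 0")
    if rate < 0:
        raise InputError("rate must be >= 0")
    if decay_tau is None:
        long_integral = rate * long_window
        short_integral = rate * short_window
    else:
        if decay_tau <= 0:
            raise InputError("decay_tau must be > 0")
        long_integral = rate * decay_tau * (1.0 - np.exp(-long_window / decay_tau))
        short_integral = rate * decay_tau * (1.0 - np.exp(-short_window / decay_tau))
    if long_integral == 0:
        raise InputError("long-window integral is zero; ratio undefined")
    return 100.0 * short_integral / long_integral


def bundle_hashes(bundle: ResultBundle) -> dict[str, str]:
    """SHA-256 of each output table's CSV text (determinism checks)."""
    return {
        name: hashlib.sha256(
            getattr(bundle, name).to_csv(index=False).encode()
        ).hexdigest()
        for name in ("shape_timecourse", "quadrant_profile", "population_means")
    }
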