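"""Reading and writing the package's file formats.

Frame stacks travel as multi-page grayscale TIFF (8-bit 0/255 for binary
masks, float/16-bit for micropattern intensities) with a CSV sidecar
schedule describing each page (frame, time_s, cycle, phase). Configs are
YAML mirroring :class:`StretchProtocol` + :class:`DynamicsParams`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigurationError, InputError
from .pipeline import ExperimentConfig
from .synthetic_data import CellMask, DynamicsParams, MicropatternImage, StretchProtocol


def write_mask_stack(path, frames: Sequence[CellMask]) -> None:
    """Write masks as a multi-page 8-bit TIFF plus a CSV schedule sidecar."""
    if not frames:
        raise InputError("no frames to write")
    path = Path(path)
    data = np.stack([f.pixels.astype(np.uint8) * 255 for f in frames])
    tifffile.imwrite(path, data)
    schedule = pd.DataFrame(
        {
            "frame": range(len(frames)),
            "time_s": [f.time for f in frames],
            "cycle": [f.cycle_index for f in frames],
            "phase": [f.phase_tag for f in frames],
        }
    )
    schedule.to_csv(path.with_suffix(".schedule.csv"), index=False)


def read_mask_stack(
    path, pixel_size: float, stretch_axis: str = "x"
) -> list[CellMask]:
    """Read a mask TIFF (with optional schedule sidecar) back into CellMasks."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar = path.with_suffix(".schedule.csv")
    if sidecar.exists():
        sched = pd.read_csv(sidecar)
        times = sched["time_s"].tolist()
        cycles = sched["cycle"].tolist()
        phases = sched["phase"].tolist()
    else:
        times = list(range(len(data)))
        cycles = [0] * len(data)
        phases = ["pre_stretch"] * len(data)
    return [
        CellMask(
            page > 0,
            pixel_size,
            time=float(t),
            cycle_index=int(c),
            phase_tag=str(p),
            stretch_axis=stretch_axis,
        )
        for page, t, c, p in zip(data, times, cycles, phases)
    ]


def write_micropattern(path, image: MicropatternImage) -> None:
    """Write a micropattern image as 16-bit TIFF."""
    arr = image.pixels
    scale = 65535.0 / max(arr.max(), 1e-12)
    tifffile.imwrite(Path(path), (arr * scale).astype(np.uint16))


def read_micropattern(path, pixel_size: float, **kw) -> MicropatternImage:
    return MicropatternImage(tifffile.imread(Path(path)).astype(float), pixel_size, **kw)


def load_config(path) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML file.

    Recognized top-level keys: ``protocol`` (StretchProtocol fields),
    ``params`` (DynamicsParams fields) and any ExperimentConfig field.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a YAML mapping")
    kwargs = dict(raw)
    if "protocol" in kwargs:
        proto = kwargs.pop("protocol")
        if "sample_points" in proto:
            proto["sample_points"] = tuple(
                (int(c), str(p)) for c, p in proto["sample_points"]
            )
        kwargs["protocol"] = StretchProtocol(**proto)
    if "params" in kwargs and kwargs["params"] is not None:
        kwargs["params"] = DynamicsParams(**kwargs["params"])
    for key in ("image_shape", "checkpoints_min"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    try:
        return ExperimentConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"invalid config: {exc}") from None


def save_config(path, config: ExperimentConfig) -> None:
    data = dataclasses.asdict(config)
    data["protocol"]["sample_points"] = [
        list(p) for p in config.protocol.sample_points
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
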