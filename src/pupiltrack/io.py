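"""File I/O and experiment configuration.

Frame sequences travel as multi-page TIFF (or directories of numbered
PNGs), traces as ``t,x,y`` CSV, M-scan volumes as multi-page TIFF with a
JSON metadata sidecar, and experiment configuration as an INI-style text
file with ``[scene]``, ``[calibration]``, ``[loop]`` and ``[mscan]``
sections.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from .datatypes import ConfigError, ImageFrame, MotionTrace
from .synthetic import MScanParams, SceneParams
from .control import GainCalibration, LoopConfig

def write_trace(path: str | Path, trace: MotionTrace) -> None:
    """Write a trace as CSV with header ``t,x,y``."""
    trace.to_csv(path)


read_trace = MotionTrace.from_csv


@dataclass
class ExperimentConfig:
    """Everything one runnable experiment needs, plus seeds and output dir."""

    scene: SceneParams = field(default_factory=SceneParams)
    calibration: GainCalibration = field(default_factory=GainCalibration)
    loop: LoopConfig = field(default_factory=LoopConfig)
    mscan: MScanParams = field(default_factory=MScanParams)
    seeds: tuple[int, ...] = (0,)
    output_dir: Path = Path(".")

    def __post_init__(self) -> None:
        if len(self.seeds) == 0:
            raise ConfigError("experiment.seeds", "must be non-empty")


def write_frames(path: str | Path, frames: list[ImageFrame]) -> None:
    """Write a frame sequence as a multi-page TIFF."""
    import tifffile

    stack = np.stack([f.pixels for f in frames])
    tifffile.imwrite(path, stack, photometric="minisblack")


def read_frames(path: str | Path, pixel_size: float = 1.0,
                rate: float | None = None) -> list[ImageFrame]:
    """Read a frame sequence from multi-page TIFF or a PNG directory.

    Timestamps are assigned from ``rate`` (frame index / rate) when given.
    """
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(path.glob("*.png"))
        if not files:
            raise ConfigError(str(path), "no PNG frames found in directory")
        stack = [iio.imread(f) for f in files]
    else:
        import tifffile

        try:
            stack = tifffile.imread(path)
        except Exception as exc:
            raise ConfigError(str(path), f"unreadable TIFF: {exc}") from exc
        if stack.ndim == 2:
            stack = stack[None]
    return [ImageFrame(pixels=page, pixel_size=pixel_size,
                       timestamp=(i / rate if rate else 0.0))
            for i, page in enumerate(stack)]


def _build_section(cls, parser: configparser.ConfigParser, section: str):
    """Instantiate a params dataclass from one INI section."""
    kwargs = {}
    if parser.has_section(section):
        valid = {f.name: f for f in fields(cls)}
        for key, raw in parser.items(section):
            if key not in valid:
                raise ConfigError(f"{section}.{key}", "unknown field")
            ftype = valid[key].type
            try:
                if "int" in str(ftype):
                    kwargs[key] = int(raw)
                elif "tuple" in str(ftype):
                    kwargs[key] = tuple(float(v) for v in raw.split(","))
                else:
                    kwargs[key] = float(raw)
            except ValueError as exc:
                raise ConfigError(f"{section}.{key}", str(exc)) from exc
    try:
        return cls(**kwargs)
    except ValueError as exc:
        raise ConfigError(section, str(exc)) from exc


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse an INI experiment config; errors name the offending field."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(str(path), "config file not found")
    parser = configparser.ConfigParser()
    try:
        parser.read(path)
    except configparser.Error as exc:
        raise ConfigError(str(path), f"malformed config: {exc}") from exc

    scene = _build_section(SceneParams, parser, "scene")
    cal = _build_section(GainCalibration, parser, "calibration")
    mscan = _build_section(MScanParams, parser, "mscan")

    loop_kwargs = {}
    if parser.has_section("loop"):
        for key, raw in parser.items("loop"):
            if key == "reference":
                loop_kwargs[key] = tuple(float(v) for v in raw.split(","))
            elif key == "hold_frames":
                loop_kwargs[key] = int(raw)
            elif key in ("camera_rate", "latency", "tracking_range"):
                loop_kwargs[key] = float(raw)
            else:
                raise ConfigError(f"loop.{key}", "unknown field")
    try:
        loop = LoopConfig(**loop_kwargs)
    except ValueError as exc:
        raise ConfigError("loop", str(exc)) from exc

    seeds: tuple[int, ...] = (0,)
    output_dir = Path(".")
    if parser.has_section("experiment"):
        for key, raw in parser.items("experiment"):
            if key == "seeds":
                try:
                    seeds = tuple(int(v) for v in raw.split(","))
                except ValueError as exc:
                    raise ConfigError("experiment.seeds", str(exc)) from exc
            elif key == "output_dir":
                output_dir = Path(raw)
            else:
                raise ConfigError(f"experiment.{key}", "unknown field")
    return ExperimentConfig(scene=scene, calibration=cal, loop=loop,
                            mscan=mscan, seeds=seeds, output_dir=output_dir)
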