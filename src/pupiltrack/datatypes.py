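"""Shared data containers for the pupil-tracking motion-correction toolkit.

These are the common currency passed between the synthetic scene generator,
the pupil tracker, the closed-loop simulator and the OCT motion analytics:
camera frames with a physical pixel pitch, time-indexed lateral motion
traces in millimetres, M-scan volumes (repeated B-scans at one lateral
position) and frequency-response curves.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class InvalidParameterError(ValueError):
    """A generator or pipeline parameter violates its contract."""


class NoValleyError(ValueError):
    """The intensity histogram has no valley between two modes."""


class DegenerateTraceError(ValueError):
    """A trace carries no usable signal (constant, or zero variance)."""


class UndefinedShiftError(ValueError):
    """Cross-correlation shift is undefined (featureless input)."""


class ConfigError(ValueError):
    """A structured configuration file is invalid.

    Carries the offending section/field so callers can report it.
    """

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass
class ImageFrame:
    """A single 2D grayscale raster with physical pixel pitch.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols)
        Gray levels; integer dtype for camera frames, float allowed for
        derived images (SVPs, averages).
    pixel_size : float
        Physical pitch in mm/pixel (lateral pitch for SVP-like images).
    timestamp : float
        Acquisition time in seconds.
    degenerate : bool
        Set by the scene generator when the requested pupil fell entirely
        outside the frame, so no dark disk was rendered.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0
    timestamp: float = 0.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InvalidParameterError("pixels must be a non-empty 2D raster")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class MotionTrace:
    """Time-indexed lateral displacement series.

    ``t`` is in seconds (uniformly sampled, monotone increasing), ``x`` and
    ``y`` are displacements in millimetres unless a method's docstring says
    otherwise (edge traces may carry lateral samples before calibration).
    ``flags`` optionally marks interpolated/unreliable samples.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray | None = None
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.y is None:
            self.y = np.zeros_like(self.x)
        else:
            self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise InvalidParameterError("t, x, y must have equal lengths")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise InvalidParameterError("t must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise InvalidParameterError("t must be uniformly sampled")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.x))
                and np.all(np.isfinite(self.y))):
            raise InvalidParameterError("trace values must be finite")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def rate(self) -> float:
        """Sampling rate in Hz."""
        if len(self.t) < 2:
            raise InvalidParameterError("rate undefined for < 2 samples")
        return 1.0 / (self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        """Span from t[0] to one sample past t[-1] (seconds)."""
        if len(self.t) < 2:
            return 0.0
        return self.t[-1] - self.t[0] + (self.t[1] - self.t[0])

    def sample(self, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linearly resample (x, y) at the requested times."""
        times = np.asarray(times, dtype=float)
        return (np.interp(times, self.t, self.x),
                np.interp(times, self.t, self.y))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t": self.t, "x": self.x, "y": self.y}).to_csv(
            path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MotionTrace":
        df = pd.read_csv(path)
        for col in ("t", "x", "y"):
            if col not in df.columns:
                raise ConfigError(col, f"missing column in {path}")
        return cls(t=df["t"].to_numpy(), x=df["x"].to_numpy(),
                   y=df["y"].to_numpy())


@dataclass
class MScanVolume:
    """Repeated B-scans acquired at one lateral scan line.

    ``bscans`` has shape (n_bscans, depth, lateral).  B-scan *k* is taken to
    be acquired at time ``k / bscan_rate``.
    """

    bscans: np.ndarray
    bscan_rate: float
    lateral_pitch: float
    axial_pitch: float = 0.01

    def __post_init__(self) -> None:
        self.bscans = np.asarray(self.bscans)
        if self.bscans.ndim != 3:
            raise InvalidParameterError("bscans must be (n, depth, lateral)")
        if self.bscan_rate <= 0 or self.lateral_pitch <= 0 or self.axial_pitch <= 0:
            raise InvalidParameterError("rates and pitches must be positive")

    @property
    def n_bscans(self) -> int:
        return self.bscans.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_bscans) / self.bscan_rate

    def save(self, path: str | Path) -> None:
        """Write as multi-page TIFF with a JSON metadata sidecar."""
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.bscans, photometric="minisblack")
        meta = {"bscan_rate": self.bscan_rate,
                "lateral_pitch": self.lateral_pitch,
                "axial_pitch": self.axial_pitch}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MScanVolume":
        import tifffile

        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(bscans=tifffile.imread(path), **meta)


@dataclass
class TransferFunction:
    """Frequency-response magnitude on a frequency grid.

    ``magnitude`` is normalized so the DC (or lowest-frequency) value is the
    natural reference; ``rolloff_3db`` is the first frequency at which the
    response crosses its roll-off criterion, or None when the crossing is
    not reached within the grid.
    """

    frequencies: np.ndarray
    magnitude: np.ndarray
    rolloff_3db: float | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if len(self.frequencies) != len(self.magnitude):
            raise InvalidParameterError("frequency and magnitude grids differ")
        if len(self.frequencies) > 1 and np.any(np.diff(self.frequencies) <= 0):
            raise InvalidParameterError("frequencies must be strictly increasing")
        if np.any(~np.isfinite(self.magnitude)) or np.any(self.magnitude < 0):
            raise InvalidParameterError("magnitude must be finite and non-negative")


def replace(obj, **changes):
    """dataclasses.replace re-exported for convenient calibration tweaks."""
    return dataclasses.replace(obj, **changes)
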