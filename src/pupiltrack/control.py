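"""Proportional correction loop: gain calibration and closed-loop simulator.

The correction gain converts the tracker's pixel-space error into scanner
volts through the calibration chain

    g = (mm / pixel) × (deg / mm) × (volts / deg) × β

where β is the adjustable factor used to minimize residual motion.  The
simulator replaces the analog hardware with a discrete-time loop that
reflects the optical topology: the pupil camera images the eye directly
(through the hot mirror), so the tracker always measures the *absolute*
pupil motion, while the correction is summed onto the scan waveforms and
therefore only moves the OCT imaging coordinate.  At every camera tick the
simulator renders the pupil at its true position, runs the segmentation
tracker, and schedules a proportional correction that takes effect after
the loop latency Δt (quantized to the camera period).  For β = 1 the
applied correction is the absolute pupil position delayed by Δt, so the
residual the OCT sees is x(t) − x(t−Δt) — the behaviour the analytic
latency model describes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import InvalidParameterError, MotionTrace
from .synthetic import SceneParams, generate_pupil_frame
from .tracker import select_threshold, track_frame


@dataclass(frozen=True)
class GainCalibration:
    """Calibration constants of the correction chain (see module docstring)."""

    mm_per_pixel: float = 0.042
    deg_per_mm: float = 2.0
    volts_per_deg: float = 0.5
    beta: float = 1.0

    def __post_init__(self) -> None:
        if min(self.mm_per_pixel, self.deg_per_mm, self.volts_per_deg) <= 0:
            raise InvalidParameterError("calibration constants must be positive")
        if self.beta < 0:
            raise InvalidParameterError("beta must be >= 0")

    @property
    def volts_per_mm(self) -> float:
        return self.deg_per_mm * self.volts_per_deg


@dataclass(frozen=True)
class LoopConfig:
    """Timing and range of the correction loop.

    ``latency`` is the total motion-to-correction delay Δt; corrections are
    clamped to ±``tracking_range`` mm per axis.  ``hold_frames`` is how many
    consecutive lost-pupil frames keep the last correction before it is
    zeroed.
    """

    camera_rate: float = 500.0
    latency: float = 0.004
    tracking_range: float = 2.5
    reference: tuple[float, float] | None = None  # defaults to frame center
    hold_frames: int = 10

    def __post_init__(self) -> None:
        if self.camera_rate <= 0:
            raise InvalidParameterError("camera_rate must be positive")
        if self.latency < 0:
            raise InvalidParameterError("latency must be >= 0")
        if self.tracking_range <= 0:
            raise InvalidParameterError("tracking_range must be positive")


@dataclass
class SimulationResult:
    """Traces produced by one closed-loop run.

    ``uncorrected`` is the apparent motion with tracking off, ``corrected``
    the residual motion with tracking on, ``correction`` the applied
    correction offsets (mm); all share the camera time base.
    ``residual_std`` is the sample standard deviation of the corrected
    displacement (x and y variances summed under the root).
    """

    uncorrected: MotionTrace | None
    corrected: MotionTrace
    correction: MotionTrace
    residual_std: float


def compute_gain(cal: GainCalibration) -> float:
    """Correction gain g in volts per camera pixel."""
    return cal.mm_per_pixel * cal.deg_per_mm * cal.volts_per_deg * cal.beta


def correction_signal(deviation: tuple[float, float] | np.ndarray, g: float,
                      clamp: float, cal: GainCalibration,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis correction for one measured deviation.

    Returns ``(volts, mm)``: the voltage correction −g·deviation and the
    equivalent object-space offset, clamped (saturating) to ±clamp mm.
    The sign opposes the motion: a pupil displaced +x yields a correction
    shifting the scan −x in the camera's frame of reference.
    """
    if g < 0:
        raise InvalidParameterError("gain must be >= 0")
    dev = np.asarray(deviation, dtype=float)
    mm = -(g / cal.volts_per_mm) * dev          # = -mm_per_pixel * beta * dev
    mm = np.clip(mm, -clamp, clamp)
    volts = mm * cal.volts_per_mm
    return volts, mm


def simulate_closed_loop(trajectory: MotionTrace, scene: SceneParams,
                         cal: GainCalibration, loop: LoopConfig,
                         seed: int | None = None, tracking: bool = True,
                         include_uncorrected: bool = True,
                         threshold: float | None = None) -> SimulationResult:
    """Run the discrete-time correction loop over a motion trajectory.

    At tick k (period 1/camera_rate) the pupil is rendered at its true
    position ``trajectory(t_k)`` — the camera images the eye directly, so
    its view is independent of the applied correction.  The tracker
    measures the pixel deviation from the reference; the proportional
    correction command (β·mm_per_pixel times the deviation, clamped to the
    tracking range) takes effect on the imaging coordinate ``round(Δt ×
    camera_rate)`` ticks later (zero latency: the same tick).  The
    threshold is selected once from the first frame, as in a real session,
    unless given explicitly.

    ``uncorrected`` is the tracker-measured apparent motion — with the
    camera upstream of the correction this is what a tracking-off run
    records; ``corrected`` is the residual the OCT sees, true motion minus
    the applied correction.  Ticks where the pupil is lost hold the last
    deviation for up to ``loop.hold_frames`` frames, then drop the
    correction to zero.  ``tracking=False`` forces a zero correction
    throughout (corrected == true motion up to tracker noise).
    """
    rate = loop.camera_rate
    if len(trajectory) >= 2 and trajectory.rate + 1e-6 < rate:
        raise InvalidParameterError("trajectory must be sampled at >= camera_rate")
    n = int(np.floor(trajectory.duration * rate + 1e-9))
    if n < 2:
        raise InvalidParameterError("trajectory too short for the camera rate")
    t = np.arange(n) / rate
    true_x, true_y = trajectory.sample(t)
    reference = loop.reference if loop.reference is not None else scene.frame_center_px
    d = int(round(loop.latency * rate))
    rng = np.random.default_rng(seed)

    if threshold is None:
        first = generate_pupil_frame(scene, (true_x[0], true_y[0]),
                                     seed=rng, timestamp=0.0)
        threshold = select_threshold(first)

    scheduled = np.zeros((n + d + 1, 2))  # command taking effect at tick k
    applied_trace = np.zeros((n, 2))
    measured = np.full((n, 2), np.nan)
    held: np.ndarray | None = None
    hold_count = 0
    for k in range(n):
        frame = generate_pupil_frame(scene, (true_x[k], true_y[k]),
                                     seed=rng, timestamp=t[k])
        deviation, _ = track_frame(frame, threshold, reference)
        if deviation is None:
            if held is not None and hold_count < loop.hold_frames:
                deviation = held
                hold_count += 1
        else:
            held = deviation
            hold_count = 0

        if deviation is not None:
            measured[k] = deviation * scene.pixel_size
            if tracking:
                command = np.clip(cal.beta * cal.mm_per_pixel * deviation,
                                  -loop.tracking_range, loop.tracking_range)
                scheduled[k + d] = command
        applied_trace[k] = scheduled[k]

    # lost-pupil ticks: the apparent-motion record falls back to ground truth
    bad = np.isnan(measured[:, 0])
    measured[bad, 0] = true_x[bad]
    measured[bad, 1] = true_y[bad]

    residual = np.column_stack([true_x, true_y]) - applied_trace
    uncorrected = (MotionTrace(t=t, x=measured[:, 0], y=measured[:, 1])
                   if include_uncorrected else None)
    corrected = MotionTrace(t=t, x=residual[:, 0], y=residual[:, 1])
    correction = MotionTrace(t=t, x=applied_trace[:, 0], y=applied_trace[:, 1])
    residual_std = float(np.sqrt(np.var(residual[:, 0], ddof=1) +
                                 np.var(residual[:, 1], ddof=1)))
    return SimulationResult(uncorrected=uncorrected, corrected=corrected,
                            correction=correction, residual_std=residual_std)
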