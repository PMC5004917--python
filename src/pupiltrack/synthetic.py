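"""Synthetic pupil-camera scenes, eye-motion trajectories and OCT M-scans.

The generators here produce the inputs the tracker and characterization
pipelines assume:

* dark-pupil / bright-iris camera frames with a bimodal gray-level
  histogram (the contrast the segmentation algorithm exploits),
* deterministic test waveforms (steps, sinusoids) standing in for the
  bench's fast-steering-mirror drive,
* fixational eye motion with a 1/f-type power spectrum concentrated below
  10 Hz, plus Poisson-timed microsaccades,
* M-scan volumes (repeated B-scans of a dark/bright pupil edge) whose edge
  position follows a motion trajectory, with multiplicative speckle.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ImageFrame, InvalidParameterError, MotionTrace, MScanVolume

# Camera geometry: 320x256 px at 42 um/px (13.4 x 10.8 mm field of view).
DEFAULT_FRAME_WIDTH = 320
DEFAULT_FRAME_HEIGHT = 256
DEFAULT_PIXEL_SIZE = 0.042  # mm/pixel


@dataclass(frozen=True)
class Artifact:
    """A small dark blob (eyelash shadow, dust) painted onto a frame.

    ``center`` is in pixel coordinates (x, y); ``size`` is the blob's
    square side in pixels; ``intensity`` its gray level.
    """

    center: tuple[float, float]
    size: int
    intensity: float = 30.0


@dataclass(frozen=True)
class SceneParams:
    """Geometry and photometry of the simulated pupil-camera scene.

    The dark pupil (transmits the IR illumination) sits on a bright iris
    background (reflects it), giving the bimodal histogram the tracker
    thresholds.  Units: pixels for the raster, mm for physical lengths,
    8-bit gray levels for intensities.
    """

    frame_width: int = DEFAULT_FRAME_WIDTH
    frame_height: int = DEFAULT_FRAME_HEIGHT
    pixel_size: float = DEFAULT_PIXEL_SIZE
    pupil_radius: float = 2.0       # mm; ~4 mm pupil diameter
    iris_intensity: float = 200.0
    pupil_intensity: float = 20.0
    noise_sigma: float = 5.0        # additive gray-level noise
    artifacts: tuple[Artifact, ...] = ()

    def __post_init__(self) -> None:
        if self.frame_width <= 0 or self.frame_height <= 0:
            raise InvalidParameterError("frame dimensions must be positive")
        if not self.pupil_intensity < self.iris_intensity:
            raise InvalidParameterError(
                "dark pupil requires pupil_intensity < iris_intensity")
        if self.pixel_size <= 0 or self.pupil_radius <= 0:
            raise InvalidParameterError("pixel_size and pupil_radius must be positive")
        r_px = self.pupil_radius / self.pixel_size
        if 2 * r_px >= min(self.frame_width, self.frame_height):
            raise InvalidParameterError("pupil must fit in frame at zero offset")

    @property
    def frame_center_px(self) -> tuple[float, float]:
        """(x, y) pixel coordinates of the frame center (0-based)."""
        return ((self.frame_width - 1) / 2.0, (self.frame_height - 1) / 2.0)


@dataclass(frozen=True)
class MScanParams:
    """Acquisition geometry of a synthetic 2D M-scan."""

    alines_per_bscan: int = 240
    bscan_rate: float = 416.7       # Hz
    n_bscans: int = 1000
    lateral_fov: float = 8.0        # mm
    depth_samples: int = 64
    speckle_contrast: float = 0.2   # std/mean of multiplicative noise
    edge_position: float = 4.0      # mm, pupil-edge location on the scan line

    def __post_init__(self) -> None:
        if min(self.alines_per_bscan, self.n_bscans, self.depth_samples) <= 0:
            raise InvalidParameterError("counts must be positive")
        if self.bscan_rate <= 0 or self.lateral_fov <= 0:
            raise InvalidParameterError("rate and FOV must be positive")
        if self.speckle_contrast < 0:
            raise InvalidParameterError("speckle_contrast must be >= 0")

    @property
    def duration(self) -> float:
        """Acquisition time in seconds (n_bscans / bscan_rate)."""
        return self.n_bscans / self.bscan_rate

    @property
    def lateral_pitch(self) -> float:
        """Lateral sampling pitch in mm/sample."""
        return self.lateral_fov / self.alines_per_bscan


def generate_pupil_frame(scene: SceneParams,
                         center: tuple[float, float] = (0.0, 0.0),
                         seed: int | np.random.Generator | None = None,
                         timestamp: float = 0.0) -> ImageFrame:
    """Render one pupil-camera frame with the pupil at ``center``.

    ``center`` is the pupil displacement from the frame center in mm
    (x rightward, y downward).  The disk is anti-aliased with linear
    edge coverage so sub-pixel centroid recovery is meaningful; additive
    Gaussian noise of ``scene.noise_sigma`` gray levels is applied and the
    result quantized to 8-bit.

    A pupil entirely outside the frame yields a ``degenerate`` frame (no
    disk painted) rather than an exception.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    w, h = scene.frame_width, scene.frame_height
    cx0, cy0 = scene.frame_center_px
    cx = cx0 + center[0] / scene.pixel_size
    cy = cy0 + center[1] / scene.pixel_size
    r_px = scene.pupil_radius / scene.pixel_size

    img = np.full((h, w), scene.iris_intensity, dtype=np.float64)
    degenerate = (cx + r_px < -0.5 or cx - r_px > w - 0.5 or
                  cy + r_px < -0.5 or cy - r_px > h - 0.5)
    if not degenerate:
        # restrict rendering to the disk's bounding box
        x0 = max(int(np.floor(cx - r_px - 1)), 0)
        x1 = min(int(np.ceil(cx + r_px + 2)), w)
        y0 = max(int(np.floor(cy - r_px - 1)), 0)
        y1 = min(int(np.ceil(cy + r_px + 2)), h)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(yy - cy, xx - cx)
        coverage = np.clip(r_px - d + 0.5, 0.0, 1.0)  # linear anti-aliasing
        img[y0:y1, x0:x1] -= (scene.iris_intensity - scene.pupil_intensity) * coverage

    for art in scene.artifacts:
        ax, ay = art.center
        half = art.size / 2.0
        x0 = max(int(round(ax - half)), 0)
        x1 = min(int(round(ax + half)), w)
        y0 = max(int(round(ay - half)), 0)
        y1 = min(int(round(ay + half)), h)
        if x1 > x0 and y1 > y0:
            img[y0:y1, x0:x1] = art.intensity

    if scene.noise_sigma > 0:
        img += rng.normal(0.0, scene.noise_sigma, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return ImageFrame(pixels=pixels, pixel_size=scene.pixel_size,
                      timestamp=timestamp, degenerate=degenerate)


def generate_trajectory(kind: str, amplitude: float, frequency: float | None,
                        duration: float, rate: float) -> MotionTrace:
    """Deterministic test waveform: ``step``, ``sinusoid`` or ``constant``.

    * step: 0 before duration/2, ``amplitude`` from duration/2 on;
    * sinusoid: amplitude·sin(2π f t), requires rate > 2 f;
    * constant: identically zero.

    Displacement is carried on the x axis; y is zero.
    """
    if rate <= 0 or duration <= 0:
        raise InvalidParameterError("rate and duration must be positive")
    t = np.arange(int(round(duration * rate))) / rate
    if kind == "step":
        x = np.where(t >= duration / 2.0, float(amplitude), 0.0)
    elif kind == "sinusoid":
        if frequency is None or frequency <= 0:
            raise InvalidParameterError("sinusoid requires a positive frequency")
        if rate <= 2 * frequency:
            raise InvalidParameterError("rate must exceed twice the frequency")
        x = amplitude * np.sin(2 * np.pi * frequency * t)
    elif kind == "constant":
        x = np.zeros_like(t)
    else:
        raise InvalidParameterError(f"unknown trajectory kind {kind!r}")
    return MotionTrace(t=t, x=x)


def _colored_noise(n: int, rate: float, exponent: float, cutoff: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise, PSD ∝ 1/f**exponent with a 4th-order cutoff.

    The power-law band models drift; the steep roll-off above ``cutoff``
    reflects that tremor amplitude at high frequencies is negligible
    compared with a power-law extrapolation.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.zeros_like(freqs)
    shape[1:] = (freqs[1:] ** (-exponent / 2.0)
                 / (1.0 + (freqs[1:] / cutoff) ** 4))
    spec = shape * (rng.normal(size=len(freqs)) + 1j * rng.normal(size=len(freqs)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / np.std(x)


def generate_fixational_trajectory(duration: float, rate: float = 500.0,
                                   psd_exponent: float = 1.5,
                                   rms_amplitude: float = 0.1,
                                   microsaccade_rate: float = 1.0,
                                   tremor_cutoff: float = 80.0,
                                   seed: int | None = None) -> MotionTrace:
    """Fixational eye motion: 1/f-type drift/tremor plus microsaccades.

    The drift/tremor component is colored noise with power spectral density
    ∝ 1/f**psd_exponent per axis, scaled so the two axes combined have RMS
    ``rms_amplitude`` (mm).  A steep 4th-order roll-off above
    ``tremor_cutoff`` (Hz) bounds the high-frequency tremor: a pure power
    law extended to the Nyquist rate would put far more amplitude at tens
    of Hz than fixating eyes exhibit, where tremor is sub-micron.
    Microsaccades are Poisson-timed instantaneous steps of ~0.02-0.1 mm in
    a uniformly random direction, superimposed on the drift.  With this
    spectrum the bulk of the motion power sits below 10 Hz, matching
    reported fixational-motion spectra.
    """
    if rate < 100:
        raise InvalidParameterError("rate must be >= 100 Hz")
    if not 1.0 <= psd_exponent <= 2.0:
        raise InvalidParameterError("psd_exponent must lie in [1, 2]")
    if duration <= 0 or rms_amplitude < 0 or microsaccade_rate < 0:
        raise InvalidParameterError("duration/rms/microsaccade_rate invalid")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    per_axis = rms_amplitude / np.sqrt(2.0)
    x = per_axis * _colored_noise(n, rate, psd_exponent, tremor_cutoff, rng)
    y = per_axis * _colored_noise(n, rate, psd_exponent, tremor_cutoff, rng)

    n_sacc = rng.poisson(microsaccade_rate * duration)
    for _ in range(n_sacc):
        k = rng.integers(0, n)
        mag = rng.uniform(0.02, 0.1)
        ang = rng.uniform(0, 2 * np.pi)
        x[k:] += mag * np.cos(ang)
        y[k:] += mag * np.sin(ang)
    return MotionTrace(t=t, x=x, y=y)


def generate_mscan(params: MScanParams, trajectory: MotionTrace,
                   seed: int | None = None,
                   bright_level: float = 1.0,
                   dark_level: float = 0.1) -> MScanVolume:
    """Simulate an M-scan of the pupil edge under lateral motion.

    Each B-scan images a bright→dark lateral edge (iris to pupil) whose
    position is ``params.edge_position`` minus the trajectory's x
    displacement at that B-scan's acquisition time.  The edge is
    anti-aliased across one lateral sample.  A depth reflectivity profile
    (bright surface band over decaying bulk signal) provides axial
    structure, and multiplicative unit-mean speckle of the configured
    contrast is applied.
    """
    if trajectory.duration + 1e-9 < params.duration:
        raise InvalidParameterError(
            f"trajectory ({trajectory.duration:.3f} s) shorter than "
            f"acquisition ({params.duration:.3f} s)")
    rng = np.random.default_rng(seed)
    times = np.arange(params.n_bscans) / params.bscan_rate
    dx, _ = trajectory.sample(times)
    edge_mm = params.edge_position - dx

    pitch = params.lateral_pitch
    lateral_mm = (np.arange(params.alines_per_bscan) + 0.5) * pitch
    # (n_bscans, lateral): 1 on the bright side, 0 past the edge, linear ramp
    # across one sample at the boundary
    frac_bright = np.clip((edge_mm[:, None] - lateral_mm[None, :]) / pitch + 0.5,
                          0.0, 1.0)
    lateral_profile = dark_level + (bright_level - dark_level) * frac_bright

    z = np.arange(params.depth_samples)
    surface = np.exp(-0.5 * ((z - params.depth_samples / 4.0) / 2.0) ** 2)
    bulk = 0.4 * np.exp(-z / (params.depth_samples / 2.0))
    depth_profile = 0.2 + surface + bulk

    vol = depth_profile[None, :, None] * lateral_profile[:, None, :]
    if params.speckle_contrast > 0:
        k = 1.0 / params.speckle_contrast ** 2  # gamma: mean 1, std = contrast
        vol = vol * rng.gamma(shape=k, scale=1.0 / k, size=vol.shape)
    return MScanVolume(bscans=vol.astype(np.float32),
                       bscan_rate=params.bscan_rate,
                       lateral_pitch=pitch)
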