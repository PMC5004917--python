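"""Bench-characterization pipelines for the tracking loop.

Mirrors how the physical system was characterized on an optical bench:

* step responses are differentiated into impulse responses and Fourier
  transformed to estimate the algorithm's frequency response;
* loop latency is the lag maximizing the cross-correlation between the
  drive waveform and the (inverted) correction waveform;
* M-scan summed-voxel projections are reduced to motion traces by
  Gaussian smoothing, thresholding and Sobel edge detection;
* per-frequency corrected/uncorrected amplitude ratios form the motion
  correction transfer function, whose roll-off is quoted at the
  50 %-residual point;
* the adjustable gain β is optimized by minimizing the residual of the
  closed-loop simulation at a low probe frequency (0.5 Hz).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, optimize, signal

from .datatypes import (DegenerateTraceError, ImageFrame, MotionTrace,
                        TransferFunction, replace)
from .synthetic import SceneParams, generate_trajectory
from .control import GainCalibration, LoopConfig, simulate_closed_loop

_MINUS_3DB = 1.0 / np.sqrt(2.0)


def _first_crossing(freqs: np.ndarray, values: np.ndarray, level: float,
                    direction: str = "down") -> float | None:
    """First frequency at which ``values`` crosses ``level``, interpolated.

    ``direction`` 'down' finds the first drop below the level, 'up' the
    first rise above it.  None when no crossing occurs on the grid.
    """
    v = values if direction == "down" else -values
    lvl = level if direction == "down" else -level
    for i in range(1, len(v)):
        if v[i - 1] >= lvl and v[i] < lvl:
            f0, f1 = freqs[i - 1], freqs[i]
            v0, v1 = v[i - 1], v[i]
            if v0 == v1:
                return float(f0)
            return float(f0 + (lvl - v0) * (f1 - f0) / (v1 - v0))
    return None


def step_to_frequency_response(step: MotionTrace,
                               presmooth_hz: float | None = None,
                               fit: str | None = None) -> TransferFunction:
    """Estimate the frequency response from a recorded step response.

    The first difference of the step response approximates the impulse
    response; the magnitude of its discrete Fourier transform, normalized
    to DC = 1, is the frequency-response estimate.  The −3 dB roll-off is
    located by linear interpolation on the grid.

    ``presmooth_hz`` optionally low-passes (4th-order zero-phase
    Butterworth) before differencing.  ``fit='exponential'`` instead fits
    a ± b(1 − exp(−(t−t0)/τ)) to the recorded step and differentiates the
    fit analytically, mirroring a parametric step-fit workflow.
    """
    x = step.x.copy()
    dt = 1.0 / step.rate
    if np.ptp(x) == 0:
        raise DegenerateTraceError("constant trace: impulse response is zero")

    if fit == "exponential":
        t = step.t
        t0_guess = t[int(np.argmax(np.abs(np.diff(x))))]

        def model(t, a, b, t0, tau):
            return a + b * (1 - np.exp(-np.maximum(t - t0, 0) / tau))

        p0 = (x[0], x[-1] - x[0], t0_guess, 5 * dt)
        popt, _ = optimize.curve_fit(model, t, x, p0=p0, maxfev=20000)
        x = model(t, *popt)
    elif presmooth_hz is not None:
        sos = signal.butter(4, presmooth_hz, fs=step.rate, output="sos")
        x = signal.sosfiltfilt(sos, x)

    impulse = np.diff(x)
    spectrum = np.abs(np.fft.rfft(impulse))
    if spectrum[0] == 0:
        raise DegenerateTraceError("zero net step: DC response undefined")
    magnitude = spectrum / spectrum[0]
    freqs = np.fft.rfftfreq(len(impulse), d=dt)
    rolloff = _first_crossing(freqs, magnitude, _MINUS_3DB, "down")
    return TransferFunction(frequencies=freqs, magnitude=magnitude,
                            rolloff_3db=rolloff)


def estimate_latency(drive: MotionTrace, response: MotionTrace) -> float:
    """Loop latency from drive/response cross-correlation (seconds).

    The response is taken to be an inverted, delayed copy of the drive;
    the latency is the non-negative lag maximizing the cross-correlation
    of the drive with the negated response.  Resolution is one sampling
    interval.
    """
    if abs(drive.rate - response.rate) > 1e-6 * drive.rate:
        raise DegenerateTraceError("drive and response rates differ")
    a = drive.x - drive.x.mean()
    b = -(response.x - response.x.mean())
    if np.std(a) == 0 or np.std(b) == 0:
        raise DegenerateTraceError("zero-variance input: correlation undefined")
    corr = signal.correlate(b, a, mode="full")
    lags = signal.correlation_lags(len(b), len(a), mode="full")
    valid = lags >= 0
    lag = lags[valid][int(np.argmax(corr[valid]))]
    return float(lag / drive.rate)


def extract_edge_trace(svp: ImageFrame, bscan_rate: float = 1.0,
                       lateral_pitch: float | None = None,
                       threshold: float | None = None,
                       refine: bool = True) -> MotionTrace:
    """Per-B-scan pupil-edge location from an SVP image.

    Rows of ``svp`` are B-scans, columns lateral samples.  The image is
    smoothed with a 3×3 Gaussian kernel, intensity thresholded (Otsu by
    default) to a binary image, and Sobel edge detection along the lateral
    axis locates the edge in each row.  ``refine`` adds sub-sample
    precision by taking the gradient-magnitude centroid of the smoothed
    image in a ±2-sample window around the binary edge.

    Rows without a detectable edge are linearly interpolated from their
    neighbors and marked in the trace's ``flags``.  Output x is in lateral
    samples, or mm when ``lateral_pitch`` is given.
    """
    img = np.asarray(svp.pixels, dtype=float)
    # sigma/truncate chosen so the kernel support is exactly 3x3
    smooth = ndimage.gaussian_filter(img, sigma=0.8, truncate=1.25)
    if threshold is None:
        from skimage.filters import threshold_otsu

        threshold = threshold_otsu(smooth)
    binary = (smooth > threshold).astype(float)
    grad_bin = np.abs(ndimage.sobel(binary, axis=1))
    grad_img = np.abs(ndimage.sobel(smooth, axis=1))

    n_rows, n_cols = img.shape
    edges = np.full(n_rows, np.nan)
    flags = np.zeros(n_rows, dtype=bool)
    for i in range(n_rows):
        row = grad_bin[i]
        if row.max() <= 0:
            flags[i] = True
            continue
        j = int(np.argmax(row))
        if refine:
            lo, hi = max(j - 2, 0), min(j + 3, n_cols)
            w = grad_img[i, lo:hi]
            if w.sum() > 0:
                edges[i] = lo + float(np.sum(np.arange(hi - lo) * w) / w.sum())
                continue
        edges[i] = float(j)

    if flags.all():
        raise DegenerateTraceError("no edge found in any SVP row")
    if flags.any():
        good = ~flags
        edges[flags] = np.interp(np.flatnonzero(flags),
                                 np.flatnonzero(good), edges[good])
    t = np.arange(n_rows) / bscan_rate
    x = edges * lateral_pitch if lateral_pitch is not None else edges
    return MotionTrace(t=t, x=x, flags=flags)


def trace_amplitude(trace: MotionTrace, frequency: float,
                    method: str = "dft", skip: int = 0) -> float:
    """Amplitude of the component at ``frequency`` in a motion trace.

    ``dft`` (default) projects the mean-removed x signal onto a complex
    exponential at the exact drive frequency — robust to broadband noise
    and valid off the FFT bin grid.  ``ptp`` returns half the peak-to-peak
    excursion.  ``skip`` drops initial transient samples.
    """
    x = trace.x[skip:]
    t = trace.t[skip:]
    x = x - x.mean()
    if method == "ptp":
        return float(np.ptp(x) / 2.0)
    if method != "dft":
        raise ValueError(f"unknown amplitude method {method!r}")
    phasor = np.exp(-2j * np.pi * frequency * t)
    return float(2.0 * np.abs(np.mean(x * phasor)))


def correction_transfer_function(frequencies, uncorrected_amps, corrected_amps,
                                 criterion: str = "residual_half",
                                 ) -> tuple[TransferFunction, np.ndarray]:
    """Motion-correction transfer function from per-frequency amplitudes.

    The residual ratio r(f) = corrected/uncorrected gives the correction
    percentage 100·(1 − r); ratios above 1 (amplification) appear as
    negative percentages.  The roll-off is the first frequency where the
    residual ratio reaches 0.5 (``criterion='residual_half'``, the
    convention used to quote the correction bandwidth), or where the
    correction fraction 1 − r falls below 0.708 of its low-frequency value
    (``criterion='amplitude_3db'``).

    Returns ``(TransferFunction, correction_percent)`` where the transfer
    function's magnitude is the correction fraction 1 − r clipped at 0.
    """
    f = np.asarray(frequencies, dtype=float)
    unc = np.asarray(uncorrected_amps, dtype=float)
    cor = np.asarray(corrected_amps, dtype=float)
    if not (len(f) == len(unc) == len(cor)):
        raise ValueError("frequency and amplitude lists must match in length")
    if np.any(unc <= 0):
        raise ValueError("uncorrected amplitudes must be positive")
    ratio = cor / unc
    correction_percent = 100.0 * (1.0 - ratio)
    if criterion == "residual_half":
        rolloff = _first_crossing(f, ratio, 0.5, "up")
    elif criterion == "amplitude_3db":
        level = _MINUS_3DB * (1.0 - ratio[0])
        rolloff = _first_crossing(f, 1.0 - ratio, level, "down")
    else:
        raise ValueError(f"unknown roll-off criterion {criterion!r}")
    tf = TransferFunction(frequencies=f,
                          magnitude=np.clip(1.0 - ratio, 0.0, None),
                          rolloff_3db=rolloff)
    return tf, correction_percent


def residual_at_frequency(scene: SceneParams, cal: GainCalibration,
                          loop: LoopConfig, frequency: float,
                          amplitude: float = 1.0, seed: int | None = None,
                          min_duration: float = 1.0,
                          max_duration: float = 4.0) -> float:
    """Residual amplitude (mm) of the closed loop at one drive frequency.

    Runs the simulator over an integer number of periods (at least
    ``min_duration`` seconds, capped at ``max_duration``) and measures the
    residual component at the drive frequency after discarding a
    transient of two loop delays.
    """
    period = 1.0 / frequency
    n_per = max(1, int(np.ceil(min_duration / period)))
    duration = min(n_per * period, max(max_duration, period))
    traj = generate_trajectory("sinusoid", amplitude, frequency,
                               duration, loop.camera_rate)
    res = simulate_closed_loop(traj, scene, cal, loop, seed=seed,
                               include_uncorrected=False)
    skip = max(4, 2 * int(round(loop.latency * loop.camera_rate)))
    return trace_amplitude(res.corrected, frequency, skip=skip)


def optimize_beta(scene: SceneParams, cal: GainCalibration, loop: LoopConfig,
                  probe_frequency: float = 0.5,
                  bounds: tuple[float, float] = (0.25, 2.0),
                  grid_points: int = 8, seed: int | None = None) -> float:
    """Optimize the adjustable gain β at a low probe frequency.

    A coarse grid over ``bounds`` locates the basin, then bounded scalar
    minimization refines the β minimizing the closed-loop residual
    amplitude at ``probe_frequency``.  A non-unimodal residual over the
    grid triggers a warning and returns the grid minimum.
    """
    betas = np.linspace(bounds[0], bounds[1], grid_points)

    def objective(beta: float) -> float:
        return residual_at_frequency(scene, replace(cal, beta=float(beta)),
                                     loop, probe_frequency, seed=seed)

    values = np.array([objective(b) for b in betas])
    i = int(np.argmin(values))
    sign_changes = np.count_nonzero(np.diff(np.sign(np.diff(values))))
    if sign_changes > 1:
        warnings.warn("residual vs beta is not unimodal over the search "
                      "range; returning the grid minimum", stacklevel=2)
        return float(betas[i])
    lo = betas[max(i - 1, 0)]
    hi = betas[min(i + 1, len(betas) - 1)]
    result = optimize.minimize_scalar(objective, bounds=(lo, hi),
                                      method="bounded",
                                      options={"xatol": 1e-3})
    return float(np.clip(result.x, *bounds))
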