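# Methods

This note documents the models behind `pupiltrack`, the defaults and their
rationale, what the synthetic generators do and do not emulate, and the
numerical choices that matter.

## The tracking loop

The physical system couples a pupil camera into the OCT path with a hot
mirror: the camera images the eye directly, while the correction voltages
are summed onto the galvanometer scan waveforms. The camera is therefore
*upstream* of the correction — the tracker always measures absolute pupil
motion, and the loop is feedforward from the camera's point of view. The
simulator (`control.simulate_closed_loop`) reflects this: at each camera
tick it renders the pupil frame at the true position, segments it,
converts the pixel deviation to a millimetre correction through the gain
chain `β · mm_per_pixel`, clamps it to the ±2.5 mm tracking range, and
applies it to the imaging coordinate after the loop latency Δt (quantized
to the camera period; zero latency applies within the tick). The residual
the OCT sees is

    r(t) = x(t) − β·x(t − Δt)  (plus tracker noise),

whose amplitude for sinusoidal x at β = 1 is exactly the analytic envelope
2A·sin(πfΔt). We deliberately did not model the camera as seeing the
corrected scene: in that topology a proportional corrector needs an
integrating update, whose optimal gain diverges toward the stability
boundary at low probe frequencies and whose bandwidth no longer matches
the measured behaviour of the physical system.

Defaults: camera 500 Hz (the downsampled-sensor frame rate), Δt = 4 ms
(the measured loop latency, exactly 2 camera ticks), tracking range
±2.5 mm, gain calibration mm_per_pixel = 0.042 (42 µm pixels). β defaults
to 1 and is normally set by `characterize.optimize_beta`, which minimizes
the simulated residual at a 0.5 Hz probe; because the loop is feedforward
the optimum is β* = cos(2πfΔt) ≈ 1 at a low probe frequency.

Lost-pupil handling (not specified by the original system): the last valid
deviation is held for up to `hold_frames` (default 10) camera ticks, after
which the correction drops to zero.

## Pupil segmentation

Threshold (fixed once per session, as in practice) → binarize with pupil
dark → morphological closing with a 7×7 square → 8-connected components →
largest blob → unweighted center of mass, sub-pixel. Choices the original
description leaves open, resolved here: the threshold is the deepest
valley between the two most populated modes of a Gaussian-smoothed
(σ = 2 bins) 256-bin histogram, with Otsu available as an alternative;
connectivity is 8; equal-area ties go to the blob nearest the reference
position (the pupil is expected near the designated center); the centroid
is computed on the *closed* mask. The closing is implemented as separable
maximum/minimum filters, bit-identical to `scipy.ndimage.binary_closing`
with a 7×7 square but several times faster — the simulator runs the
tracker tens of thousands of times per experiment.

On noiseless synthetic frames the tracker recovers disk centers to
≤ 0.15 px (bound tested: 0.5 px); with σ = 10 gray-level noise the RMS
error stays under 1 px ≈ 42 µm, the same order as the 25–35 µm
accuracy/repeatability reported for the hardware.

## Synthetic scenes, motion and M-scans

*Pupil frames*: a dark disk (default radius 2 mm, gray level 20) on a
bright iris background (level 200) in a 320×256 frame at 42 µm/px, with
linear-coverage anti-aliasing at the disk edge (so sub-pixel centroids are
meaningful), optional square dark artifacts (eyelash/shadow stand-ins) and
additive Gaussian noise (default σ = 5 gray levels), quantized to 8 bits.
Not modelled: corneal glints, pupil dilation, eyelids, perspective.

*Fixational motion*: per axis, colored noise with PSD ∝ 1/f^α shaped in
the frequency domain, plus Poisson-timed microsaccades modelled as
instantaneous steps (0.02–0.1 mm, uniform direction; real ~20 ms saccade
durations are below the relevance threshold of a 500 Hz loop). Defaults:
α = 1.5 — midway between the 1/f and 1/f² families reported for fixating
eyes — with a 4th-order spectral cutoff at 80 Hz, because a pure power law
extended to the 250 Hz Nyquist would place tens of microns of "tremor" at
frequencies where real tremor is sub-micron; total RMS 0.1 mm (the scale
of measured fixational excursions over seconds), microsaccade rate 1 /s.
With these defaults >95 % of spectral power lies below 10 Hz and simulated
tracking reduces the motion-trace standard deviation by ~2.5–4.5×,
bracketing the ~3.4× reduction observed in vivo. The α and cutoff
parameters remain free knobs; the PSD-slope contract is tested at α = 1
explicitly.

*M-scans*: stacks of B-scans of a bright→dark lateral edge (iris to pupil)
whose position is `edge_position − x(t)` sampled at each B-scan time, with
one-sample linear anti-aliasing, a fixed depth profile (bright surface
band over decaying bulk), and multiplicative unit-mean gamma speckle of
configurable contrast (default 0.2). Defaults follow the bench protocol:
240 A-lines over 8 mm (33.3 µm pitch), 1000 B-scans at 416.7 Hz (2.4 s).
This is a geometric phantom, not OCT physics: no coherent speckle
statistics, dispersion, roll-off or shadowing — conclusions about the
*pipelines* transfer to real data; conclusions about image quality do not.

## Characterization pipelines

*Step → frequency response*: first difference of the recorded step
approximates the impulse response; the magnitude of its DFT, normalized to
DC = 1, is the frequency response, with the −3 dB (1/√2) crossing located
by linear interpolation. No window is applied (transient signal). Options:
zero-phase Butterworth pre-smoothing, or fitting a + b(1 − e^{−(t−t0)/τ})
and differentiating the fit analytically. Validated against closed forms:
a pure delay is flat; a first-order lag rolls off at 1/(2πτ) within 5 %
for τ ∈ [2, 20] ms at 1 kHz.

*Latency*: lag maximizing the cross-correlation of the drive waveform with
the negated response, restricted to non-negative lags; resolution one
sample (1 ms at the bench's oscilloscope rate). Unbiased to one sample for
injected delays of 1–10 ms at 0.5–2 Hz drives.

*SVP edge trace*: 3×3 Gaussian smoothing (σ = 0.8, kernel truncated to
one-pixel radius) → Otsu threshold → binary → Sobel along the lateral axis
→ per-row edge location, refined to sub-sample precision by the
gradient-magnitude centroid of the smoothed image in a ±2-sample window.
Rows without an edge are linearly interpolated from neighbours and
flagged.

*Correction transfer function*: per-frequency residual ratio
r(f) = corrected/uncorrected amplitude; correction percentage 100(1 − r);
amplification (r > 1) reports as negative. Amplitudes are measured by
projecting the mean-removed trace on a complex exponential at the exact
drive frequency (robust to broadband noise and off-grid frequencies;
half peak-to-peak is available as an alternative). The quoted roll-off is
the first r(f) = 0.5 crossing, the convention under which the bench
measurement (22 Hz) and the latency model (20 Hz at Δt = 4 ms) are
compared; a strict amplitude −3 dB variant (correction fraction falling to
0.708 of its low-frequency value) is available behind a flag.

*β optimization*: coarse grid over [0.25, 2] followed by bounded scalar
minimization of the simulated residual at the probe frequency; a
non-unimodal grid triggers a warning and returns the grid minimum.

## M-scan motion analytics

The SVP sums each B-scan over depth, giving an (n_bscans × lateral) image
whose dark band traces the pupil edge over time. The fast-axis motion
trace cross-correlates *sequential* depth-summed profiles and cumulatively
sums the per-pair shifts (no detrending, matching how such traces are
displayed). Two numerical choices matter:

* Correlation operates on Gaussian-smoothed (σ = 1 sample) lateral
  *gradients* of the profiles. A raw step-edge profile has a broad,
  plateau-like correlation peak whose argmax is noise-dominated; the
  gradient concentrates the match on the moving edge.
* Sub-sample refinement (`refine=True`) uses the cross-spectrum
  phase slope over the lowest sixth of the band, weighted by the
  stack-mean gradient-energy spectrum, after removing the integer shift.
  Parabolic peak interpolation was measured to carry a ~0.05-sample bias
  that depends on the sub-sample edge phase and therefore random-walks
  through the cumulative sum (1–2 samples RMS over 400 B-scans); the
  phase-difference form telescopes through the cumsum and holds the
  round-trip error to ≤ 0.65 samples RMS at speckle contrast 0.3.

Registration/averaging aligns each B-scan to the first by integer shifts —
depth-only (`axial_only`, from laterally summed depth profiles) or depth
plus lateral (`full`, from the 2D cross-correlation) — then averages.
Integer shifts by default; the reference is the first B-scan. `trace_std`
is the sample standard deviation (ddof = 1) of the fast-axis displacement.

## Problem sizes and determinism

Simulations in the test suite and the acceptance script use 1–2.4 s runs
at the 500 Hz camera rate and M-scans of 400–1000 B-scans; these sizes
give amplitude estimates stable to ~1 % while keeping a full run in
minutes on one CPU. Every stochastic component takes an explicit seed
(`numpy.random.default_rng` / `SeedSequence`), and generated frames,
trajectories and volumes are bit-reproducible for a fixed seed.

## Known limitations

* The feedforward loop model cannot exhibit instabilities a true
  camera-in-loop system could; it is the right model for this optical
  topology but not for retrofit designs where the camera sees the
  corrected beam.
* The 58 Hz step-response bandwidth of the physical tracking algorithm is
  hardware-coupled (FSM and galvo dynamics); the simulator's algorithmic
  step response is only qualitatively comparable, and the estimator is
  instead validated against closed forms.
* Scanner dynamics are ideal (instantaneous settling); the physical fast
  steering mirror's 560 Hz bandwidth sits far above the loop bandwidth of
  interest, so this changes nothing below ~50 Hz.
* The printed sum-to-product identity for the residual carries a sign
  error in its source; the implementation uses the mathematically correct
  form −2A sin(πfΔt) cos(πf(2t + Δt)), which leaves the envelope — the
  only quantity used downstream — unchanged.
* In-vivo values (116 → 33.8 µm std reduction) are not reproducible from a
  geometric phantom; the package demonstrates the ≥2× reduction property
  on synthetic fixational motion instead.
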