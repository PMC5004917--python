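"""End-to-end experiment drivers binding the modules into runnable studies.

`run_characterize` reproduces the bench characterization protocol in
silico: optimize β at 0.5 Hz, then for each drive frequency run the
closed loop with tracking off and on, image the (residual) motion with a
synthetic M-scan, extract edge traces from the SVPs, and reduce the
per-frequency amplitude ratios to a motion-correction transfer function
with its roll-off, plus a cross-correlation latency estimate.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MotionTrace, replace
from .synthetic import generate_mscan, generate_trajectory
from .control import simulate_closed_loop
from .characterize import (correction_transfer_function, estimate_latency,
                           extract_edge_trace, optimize_beta, trace_amplitude)
from .oct_motion import svp
from .io import ExperimentConfig


def _mscan_amplitude(config: ExperimentConfig, motion: MotionTrace,
                     frequency: float, seed: int) -> float:
    """Amplitude at ``frequency`` seen through the M-scan imaging chain."""
    vol = generate_mscan(config.mscan, motion, seed=seed)
    trace = extract_edge_trace(svp(vol), bscan_rate=config.mscan.bscan_rate,
                               lateral_pitch=config.mscan.lateral_pitch)
    return trace_amplitude(trace, frequency)


def run_characterize(config: ExperimentConfig, frequencies,
                     amplitude: float = 1.0, optimize_gain: bool = True,
                     use_mscan: bool = True) -> dict:
    """Run the full characterization sweep and write result files.

    For each drive frequency a sinusoid of ``amplitude`` mm drives the
    loop with tracking off and on; the motion the OCT would see is imaged
    as a synthetic M-scan (``use_mscan=False`` measures the simulator
    traces directly) and the per-frequency amplitude ratio yields the
    correction transfer function.  Writes ``transfer.csv`` and
    ``summary.json`` under ``config.output_dir`` and returns the summary.
    """
    freqs = sorted(float(f) for f in frequencies)
    if not freqs:
        raise ValueError("frequency list must be non-empty")
    seed = int(config.seeds[0])
    ss = np.random.SeedSequence(seed)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    cal = config.calibration
    if optimize_gain:
        beta = optimize_beta(config.scene, cal, config.loop,
                             seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31))
        cal = replace(cal, beta=beta)
    else:
        beta = cal.beta

    duration = max(config.mscan.n_bscans / config.mscan.bscan_rate,
                   2.0 / freqs[0])
    rows = []
    latency_est = None
    for i, f in enumerate(freqs):
        run_seed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
        periods = max(1, int(np.ceil(duration * f)))
        traj = generate_trajectory("sinusoid", amplitude, f,
                                   periods / f, config.loop.camera_rate)
        res = simulate_closed_loop(traj, config.scene, cal, config.loop,
                                   seed=run_seed)
        if use_mscan and traj.duration + 1e-9 >= config.mscan.duration:
            unc = _mscan_amplitude(config, res.uncorrected, f, run_seed + 1)
            cor = _mscan_amplitude(config, res.corrected, f, run_seed + 2)
        else:
            skip = 2 * int(round(config.loop.latency * config.loop.camera_rate))
            unc = trace_amplitude(res.uncorrected, f, skip=skip)
            cor = trace_amplitude(res.corrected, f, skip=skip)
        rows.append({"frequency": f, "uncorrected_amplitude": unc,
                     "corrected_amplitude": cor})
        if latency_est is None and f >= 0.5:
            # recorded correction voltage is the inverted waveform
            response = MotionTrace(t=res.correction.t, x=-res.correction.x)
            latency_est = estimate_latency(traj, response)

    df = pd.DataFrame(rows)
    tf, pct = correction_transfer_function(df["frequency"],
                                           df["uncorrected_amplitude"],
                                           df["corrected_amplitude"])
    df["correction_percent"] = pct
    df.to_csv(out / "transfer.csv", index=False, float_format="%.9g")

    summary = {"rolloff_3db_hz": tf.rolloff_3db, "latency_s": latency_est,
               "beta": beta, "frequencies_hz": freqs, "amplitude_mm": amplitude,
               "seeds": list(config.seeds),
               "scene": asdict(config.scene) | {"artifacts": []},
               "calibration": asdict(cal),
               "loop": asdict(config.loop),
               "mscan": asdict(config.mscan)}
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
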