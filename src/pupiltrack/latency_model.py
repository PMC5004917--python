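"""Analytic model of residual motion under loop latency.

Subject motion and the delayed correction are modeled as two sinusoids of
amplitude A and frequency f with a relative phase offset set by the loop
latency Δt:

    x(t) = A sin(2πft)              (subject motion)
    y(t) = −A sin(2πf(t + Δt))      (tracking output)

Their sum — the motion left uncorrected — collapses by the sum-to-product
identity to

    x(t) + y(t) = −2A sin(πfΔt) cos(πf(2t + Δt)),

an oscillation whose envelope 2A·sin(πfΔt) is the residual amplitude (the
overall sign is a phase convention and does not affect the envelope).  The
model predicts a 50 %-residual point near 20 Hz for Δt = 4 ms, and
amplification (residual > input) once 2·sin(πfΔt) exceeds 1, i.e. above
f = 1/(6Δt).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datatypes import InvalidParameterError


@dataclass(frozen=True)
class LatencyModelParams:
    """Motion amplitude A (mm), frequency f (Hz) and loop latency dt (s)."""

    A: float
    f: float
    dt: float

    def __post_init__(self) -> None:
        if self.A < 0 or self.f < 0 or self.dt < 0:
            raise InvalidParameterError("A, f, dt must be non-negative")


def residual_amplitude(p: LatencyModelParams) -> float:
    """Envelope amplitude 2A·sin(πfΔt) of the uncorrected residual (mm)."""
    return 2.0 * p.A * np.sin(np.pi * p.f * p.dt)


def residual_identity_check(p: LatencyModelParams, t: float | np.ndarray,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate both sides of the sum-to-product identity at time(s) t.

    Returns ``(lhs, rhs)`` where lhs = x(t) + y(t) from the two-sinusoid
    form and rhs is the product form; they agree to machine precision.
    """
    t = np.asarray(t, dtype=float)
    x = p.A * np.sin(2 * np.pi * p.f * t)
    y = -p.A * np.sin(2 * np.pi * p.f * (t + p.dt))
    rhs = -2 * p.A * np.sin(np.pi * p.f * p.dt) * np.cos(np.pi * p.f * (2 * t + p.dt))
    return x + y, rhs


def half_amplitude_frequency(dt: float) -> float:
    """Frequency (Hz) at which the residual is half the input amplitude.

    Solves 2·sin(πfΔt) = 0.5, i.e. f = arcsin(0.25)/(πΔt): about 20 Hz for
    Δt = 4 ms.  Monotone decreasing in Δt.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    return float(np.arcsin(0.25) / (np.pi * dt))


def residual_surface(dt_range: np.ndarray, f_range: np.ndarray) -> np.ndarray:
    """Normalized residual 2·sin(πfΔt) over a latency × frequency grid.

    Entry (i, j) corresponds to (dt_range[i], f_range[j]); values above 1
    mark the amplification regime where tracking worsens motion.
    """
    dt = np.asarray(dt_range, dtype=float)
    f = np.asarray(f_range, dtype=float)
    if dt.size == 0 or f.size == 0:
        raise InvalidParameterError("grids must be non-empty")
    return 2.0 * np.sin(np.pi * np.outer(dt, f))


def export_surface_csv(path: str | Path, dt_range: np.ndarray,
                       f_range: np.ndarray) -> None:
    """Write the residual surface as CSV with dt/f axis headers."""
    import pandas as pd

    surf = residual_surface(dt_range, f_range)
    df = pd.DataFrame(surf, index=np.asarray(dt_range, dtype=float),
                      columns=np.asarray(f_range, dtype=float))
    df.index.name = "dt_s"
    df.columns.name = "f_hz"
    df.to_csv(path, float_format="%.6g")
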