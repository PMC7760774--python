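"""3-minute all-out test (3MT) processing.

Extracts S150s (mean speed over the first 150 s), critical speed CS
(mean speed over the last 30 s) and the above-CS distance capacity
D' = 150 * (S150s - CS) from a 1-Hz speed trace.

Windows are half-open at 1 Hz: [0, 150) for S150s and [150, 180) for CS
(30 samples). The recording may run a few seconds past 180 s; samples
beyond the 180-s mark are ignored, trimming from the start of the run.
Irregular timestamps are linearly interpolated onto a 1-Hz grid; gaps
longer than 2 s are rejected.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SpeedTrace

T_TOTAL = 180.0
T_SPLIT = 150.0
MAX_GAP_S = 2.0


@dataclass
class AllOutResult:
    s150: float  # m/s, mean speed over [0, 150)
    cs: float  # m/s, mean speed over [150, 180)
    dprime: float  # m, 150 * (s150 - cs)
    n_samples: int
    flags: set = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "s150_mps": self.s150,
            "cs_mps": self.cs,
            "dprime_m": self.dprime,
            "n_samples": self.n_samples,
            "flags": sorted(self.flags),
        }


def mean_speed(trace: SpeedTrace, window_start: float, window_end: float) -> float:
    """Arithmetic mean of samples with window_start <= t < window_end."""
    if window_end <= window_start:
        raise ValueError("window_end must exceed window_start")
    t = trace.time
    if t[0] > window_start or t[-1] < window_end - 1.0:
        raise ValueError(
            f"trace [{t[0]:.0f}, {t[-1]:.0f}]s does not cover the window "
            f"[{window_start:.0f}, {window_end:.0f})s"
        )
    mask = (t >= window_start) & (t < window_end)
    if not mask.any():
        raise ValueError(
            f"no samples in window [{window_start:.0f}, {window_end:.0f})s"
        )
    return float(trace.speed[mask].mean())


def _regularize(trace: SpeedTrace) -> SpeedTrace:
    """Re-zero the clock at test start and resample onto a 1-Hz grid."""
    t = trace.time - trace.time[0]
    gaps = np.diff(t)
    if gaps.size and gaps.max() > MAX_GAP_S:
        raise ValueError(
            f"gap of {gaps.max():.1f}s in trace exceeds the {MAX_GAP_S:.0f}s tolerance"
        )
    grid = np.arange(0.0, np.floor(t[-1]) + 1.0)
    if t.size == grid.size and np.allclose(t, grid):
        return SpeedTrace(grid, trace.speed.copy())
    return SpeedTrace(grid, np.interp(grid, t, trace.speed))


def compute_allout(trace: SpeedTrace) -> AllOutResult:
    """S150s, CS and D' from a 3MT trace covering at least [0, 180] s."""
    if trace.duration < T_TOTAL:
        raise ValueError(
            f"trace covers only {trace.duration:.1f}s; the 3MT needs {T_TOTAL:.0f}s"
        )
    reg = _regularize(trace)
    s150 = mean_speed(reg, 0.0, T_SPLIT)
    cs = mean_speed(reg, T_SPLIT, T_TOTAL)
    dprime = T_SPLIT * (s150 - cs)
    flags: set = set()
    if dprime < 0:
        flags.add("pacing-suspect")  # end speed above the early mean
    n = int(((reg.time >= 0) & (reg.time < T_TOTAL)).sum())
    return AllOutResult(s150=s150, cs=cs, dprime=dprime, n_samples=n, flags=flags)
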