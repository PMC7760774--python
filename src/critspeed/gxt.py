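"""Graded-exercise-test processing.

Turns ramp and verification gas-exchange series into VO2max, the gas
exchange threshold (GET, v-slope method), the flat-equivalent speeds
evoking each, and their mean (50% delta), which downstream screens the
3-min all-out test for pacing.

Conventions
-----------
* Gas data are averaged in consecutive, non-overlapping 15-s bins,
  timestamped at the bin end.
* VO2max is the mean of the two highest consecutive 15-s VO2 averages.
* Because the metabolic response lags the belt by about one minute, the
  speed evoking a gas value is the protocol speed one minute (four 15-s
  samples) earlier, with the per-sample speed interpolated in quarter
  stages (the per-minute increment divided by four).
* Treadmill speed at a grade is mapped to a flat-equivalent outdoor
  running speed by equating the running metabolic demand
  ``demand = 3.5 + 0.2*S + 0.9*S*G`` (S in m/min, G fractional grade)
  at both inclines, which gives ``flat = S * (1 + 4.5*G)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GXTProtocol
from .data import MPH_TO_MPS, GasSeries

MPH_TO_M_PER_MIN = MPH_TO_MPS * 60.0
LAG_SAMPLES = 4  # one minute at 15-s sampling
BIN_SECONDS = 15.0

#: v-slope implementation constants (configurable via function arguments)
VSLOPE_MIN_SEGMENT = 3
VSLOPE_MIN_SLOPE_GAP = 0.10

VERIFICATION_TOLERANCE = 0.03  # inclusive acceptance band


class InsufficientDataError(ValueError):
    """Raised when a series has too few samples/bins for an operation."""


@dataclass
class GXTResult:
    vo2max: float  # mL/kg/min
    vo2max_time: float  # s, end of the later bin of the best pair
    get_vo2: float  # mL/kg/min
    speed_at_get: float  # m/s flat-equivalent
    speed_at_vo2max: float  # m/s flat-equivalent
    fifty_delta: float  # m/s flat-equivalent
    binned: pd.DataFrame
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.get_vo2 < self.vo2max:
            raise ValueError("GET must lie below VO2max")


@dataclass
class VerificationResult:
    vp_vo2max: float
    relative_difference: float
    accepted: bool


def running_demand(speed_m_per_min, grade):
    """Metabolic demand of inclined running, mL/kg/min (speed in m/min)."""
    s = np.asarray(speed_m_per_min, dtype=float)
    return 3.5 + 0.2 * s + 0.9 * s * grade


def invert_running_demand(vo2, grade) -> float:
    """Speed (m/min) whose running demand at ``grade`` equals ``vo2``."""
    denom = 0.2 + 0.9 * grade
    return (float(vo2) - 3.5) / denom


def flat_equivalent(speed, grade, unit: str = "mph"):
    """Flat-equivalent outdoor speed (m/s) of an inclined treadmill speed.

    Equates running metabolic demand at the two inclines:
    ``flat = speed * (1 + 4.5*grade)``, then converts units.
    """
    if np.any(np.asarray(grade) < 0):
        raise ValueError("grade must be >= 0")
    s = np.asarray(speed, dtype=float)
    if unit == "mph":
        s = s * MPH_TO_MPS
    elif unit in ("mps", "m/s"):
        pass
    else:
        raise ValueError(f"unknown speed unit {unit!r}")
    out = s * (1.0 + 4.5 * np.asarray(grade, dtype=float))
    return float(out) if out.ndim == 0 else out


def bin_15s(series: GasSeries, phase: str) -> pd.DataFrame:
    """Average a phase of a gas series into consecutive 15-s bins.

    Returns a frame with columns ``t_end`` (bin end, absolute series
    time), ``vo2`` and ``vco2``. Only complete bins (full 15 s of data)
    are kept.
    """
    mask = series.phase_mask(phase)
    if not mask.any():
        raise ValueError(f"phase {phase!r} not present in series")
    t = series.time[mask]
    vo2 = series.vo2[mask]
    vco2 = series.vco2[mask]
    t0 = t[0]
    idx = np.floor((t - t0) / BIN_SECONDS).astype(int)
    # infer samples-per-bin from the sampling interval of the phase
    if t.size > 1:
        dt = np.median(np.diff(t))
    else:
        dt = BIN_SECONDS
    full = max(int(round(BIN_SECONDS / dt)), 1)
    rows = []
    for j in np.unique(idx):
        sel = idx == j
        if sel.sum() < full:
            continue  # trailing partial bin
        rows.append(
            (
                t0 + BIN_SECONDS * (j + 1),
                float(vo2[sel].mean()),
                float(vco2[sel].mean()),
            )
        )
    if not rows:
        raise InsufficientDataError(f"phase {phase!r} shorter than one 15-s bin")
    return pd.DataFrame(rows, columns=["t_end", "vo2", "vco2"])


def vo2max_two_highest(binned: pd.DataFrame) -> tuple[float, float]:
    """Mean of the two highest *consecutive* 15-s VO2 averages.

    Returns ``(vo2max, time)`` where time is the end of the later bin of
    the winning pair; ties break toward the earlier pair.
    """
    vo2 = binned["vo2"].to_numpy(float)
    if vo2.size < 2:
        raise InsufficientDataError("need at least two 15-s bins")
    pair_means = 0.5 * (vo2[:-1] + vo2[1:])
    best = int(np.argmax(pair_means))  # argmax takes the earliest tie
    return float(pair_means[best]), float(binned["t_end"].iloc[best + 1])


def _segment_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line fit; returns (intercept, slope, rss)."""
    xm = x.mean()
    ym = y.mean()
    dx = x - xm
    sxx = float(dx @ dx)
    if sxx == 0.0:
        return ym, 0.0, float(((y - ym) ** 2).sum())
    slope = float(dx @ (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    return intercept, slope, float(resid @ resid)


def _hinge_fit(x: np.ndarray, y: np.ndarray, xk: float):
    """Continuous two-segment least squares with the joint fixed at xk.

    Solves the 3-parameter normal equations for
    ``y = a + b*x + c*max(0, x - xk)``; returns (a, b, c, rss) or None
    when the system is singular.
    """
    h = np.maximum(0.0, x - xk)
    X = np.column_stack([np.ones_like(x), x, h])
    xtx = X.T @ X
    if abs(np.linalg.det(xtx)) < 1e-12:
        return None
    coef = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ coef
    return float(coef[0]), float(coef[1]), float(coef[2]), float(resid @ resid)


def _smooth3(y: np.ndarray) -> np.ndarray:
    """Centered 3-point moving mean; endpoints kept raw (linearity-preserving)."""
    if y.size < 3:
        return y.copy()
    out = np.convolve(y, np.ones(3) / 3.0, mode="same")
    out[0] = y[0]
    out[-1] = y[-1]
    return out


def _vo2_axis(binned: pd.DataFrame) -> np.ndarray:
    """The VO2 axis used for the v-slope regression.

    Ramp VO2 rises linearly in time, so when the linear-in-time trend
    fits well (R^2 >= 0.95) the measured VO2 values are replaced by the
    trend evaluated at each bin — suppressing errors-in-variables noise
    that both axes otherwise share. Raw VO2 is used when the trend does
    not hold (e.g. hand-built fixtures with arbitrary timestamps).
    """
    x = binned["vo2"].to_numpy(float)
    t = binned["t_end"].to_numpy(float)
    var_x = float(((x - x.mean()) ** 2).sum())
    if var_x == 0.0:
        return x
    intercept, slope, rss = _segment_fit(t, x)
    if slope > 0 and 1.0 - rss / var_x >= 0.95:
        return intercept + slope * t
    return x


def detect_get_vslope(
    binned: pd.DataFrame,
    min_segment: int = VSLOPE_MIN_SEGMENT,
    min_slope_gap: float = VSLOPE_MIN_SLOPE_GAP,
):
    """Gas exchange threshold by the v-slope method.

    Scans every candidate breakpoint (midpoints between consecutive
    sorted VO2 values, leaving at least ``min_segment`` points per
    side), fits the continuous two-segment least-squares model of VCO2
    on VO2 with its joint at the candidate, and keeps the candidate with
    the smallest residual sum of squares among those whose upper slope
    exceeds the lower by at least ``min_slope_gap``. The GET is the VO2
    at the segment intersection, i.e. the fitted joint. Returns ``None``
    when no admissible breakpoint exists (VCO2-VO2 effectively linear).

    Two noise-control choices: the continuity constraint (two fully
    free segments can chase noise at the edges of the span and
    intersect outside the data) and light conditioning of both axes
    (VCO2 3-bin smoothed; VO2 replaced by its linear-in-time trend when
    that trend holds, see :func:`_vo2_axis`).
    """
    if len(binned) < 8:
        raise InsufficientDataError("v-slope needs at least 8 ramp bins")
    x_axis = _vo2_axis(binned)
    y_s = _smooth3(binned["vco2"].to_numpy(float))
    order = np.argsort(x_axis, kind="stable")
    x = x_axis[order]
    y = y_s[order]
    n = x.size
    best = None
    for k in range(min_segment, n - min_segment + 1):
        xk = 0.5 * (x[k - 1] + x[k])
        fit = _hinge_fit(x, y, xk)
        if fit is None:
            continue
        _, _, slope_gain, rss = fit
        if slope_gain < min_slope_gap:
            continue
        if best is None or rss < best[0]:
            best = (rss, xk)
    if best is None:
        return None
    return float(best[1])


def lagged_speed_at(
    protocol: GXTProtocol,
    t_since_ramp_start: float,
    ramp_duration: float | None = None,
) -> tuple[float, bool]:
    """Protocol speed (mph) evoking the gas value measured at ``t``.

    ``t_since_ramp_start`` is the 15-s sample timestamp (bin end)
    relative to ramp onset. The speed assigned to 15-s sample index j is
    ``start_speed + increment_per_min * j / 4`` (quarter-stage
    interpolation); the metabolic lag shifts the lookup back four
    samples (one minute). Lookups preceding ramp onset clamp to the
    start speed; the returned flag records the clamp.
    """
    if t_since_ramp_start < 0:
        raise ValueError("time precedes ramp start")
    if ramp_duration is not None and t_since_ramp_start > ramp_duration:
        raise ValueError(
            f"time {t_since_ramp_start:.0f}s is after ramp end ({ramp_duration:.0f}s)"
        )
    j = int(round(t_since_ramp_start / BIN_SECONDS)) - 1
    j = max(j, 0)
    lagged = j - LAG_SAMPLES
    clamped = lagged < 0
    lagged = max(lagged, 0)
    return protocol.start_speed + protocol.increment_per_min * lagged / 4.0, clamped


def ramp_sample_speed(protocol: GXTProtocol, j) -> np.ndarray:
    """Quarter-stage interpolated belt speed (mph) at 15-s sample index j."""
    return protocol.start_speed + protocol.increment_per_min * np.asarray(j) / 4.0


def _gas_value_time(binned: pd.DataFrame, value: float, vo2max: float) -> float:
    """Time at which the ramp VO2 trend reaches ``value``.

    Linear interpolation on the rising part of the binned VO2-vs-time
    relation (bins after the one-minute metabolic lag and below the
    plateau), which is far less noise-sensitive than taking the first
    bin whose measured VO2 happens to exceed the value. Falls back to
    the first-crossing rule when the trend is degenerate.
    """
    t = binned["t_end"].to_numpy(float)
    v = binned["vo2"].to_numpy(float)
    use = np.arange(v.size) >= LAG_SAMPLES
    use &= v < 0.97 * vo2max
    if use.sum() >= 3:
        intercept, slope, _ = _segment_fit(t[use], v[use])
        if slope > 1e-9:
            t_val = (value - intercept) / slope
            return float(np.clip(t_val, t[0], t[-1]))
    reach = np.nonzero(v >= value)[0]
    if reach.size == 0:
        raise ValueError("[v-slope] GET above every binned VO2 value")
    return float(t[reach[0]])


def process_gxt(series: GasSeries, protocol: GXTProtocol) -> GXTResult:
    """Full ramp analysis: VO2max, GET, flat speeds at each, and 50% delta."""
    if not series.has_phase("ramp"):
        raise ValueError("series has no ramp phase")
    try:
        binned = bin_15s(series, "ramp")
    except ValueError as exc:
        raise ValueError(f"[binning] {exc}") from exc
    try:
        vo2max, vo2max_time = vo2max_two_highest(binned)
    except ValueError as exc:
        raise ValueError(f"[vo2max] {exc}") from exc
    # v-slope runs on the rising region (after the one-minute metabolic
    # lag, below the plateau); all bins are used when too few remain
    idx = np.arange(len(binned))
    rising = (idx >= LAG_SAMPLES) & (binned["vo2"].to_numpy(float) < 0.97 * vo2max)
    vslope_bins = binned[rising].reset_index(drop=True) if rising.sum() >= 8 else binned
    try:
        get_vo2 = detect_get_vslope(vslope_bins)
    except ValueError as exc:
        raise ValueError(f"[v-slope] {exc}") from exc
    if get_vo2 is None:
        raise ValueError("[v-slope] no admissible VCO2-VO2 breakpoint")

    ramp_start = series.phase_start("ramp")
    ramp_end = float(series.time[series.phase_mask("ramp")][-1]) + 1.0
    duration = ramp_end - ramp_start

    get_time = _gas_value_time(binned, get_vo2, vo2max)

    flags: set = set()
    s_get_mph, clamped = lagged_speed_at(protocol, get_time - ramp_start, duration)
    if clamped:
        flags.add("get-speed-clamped-to-ramp-start")
    s_max_mph, clamped = lagged_speed_at(protocol, vo2max_time - ramp_start, duration)
    if clamped:
        flags.add("vo2max-speed-clamped-to-ramp-start")

    speed_at_get = flat_equivalent(s_get_mph, protocol.grade, unit="mph")
    speed_at_vo2max = flat_equivalent(s_max_mph, protocol.grade, unit="mph")
    fifty_delta = 0.5 * (speed_at_get + speed_at_vo2max)
    return GXTResult(
        vo2max=vo2max,
        vo2max_time=vo2max_time,
        get_vo2=get_vo2,
        speed_at_get=speed_at_get,
        speed_at_vo2max=speed_at_vo2max,
        fifty_delta=fifty_delta,
        binned=binned,
        flags=flags,
    )


def process_verification(ramp_vo2max: float, vp_series: GasSeries) -> VerificationResult:
    """Compare the verification-bout VO2max against the ramp value.

    Accepted (a "true max") iff the relative difference is within 3%,
    inclusive.
    """
    if not vp_series.has_phase("verification"):
        raise ValueError("series has no verification phase")
    binned = bin_15s(vp_series, "verification")
    vp_vo2max, _ = vo2max_two_highest(binned)
    rel = abs(ramp_vo2max - vp_vo2max) / ramp_vo2max
    return VerificationResult(
        vp_vo2max=vp_vo2max,
        relative_difference=rel,
        accepted=rel <= VERIFICATION_TOLERANCE,
    )


def design_protocol(
    predicted_vo2max: float,
    target_duration: float = 10.0,
    start_speed: float = 5.0,
    grade: float = 0.03,
) -> GXTProtocol:
    """Individualize a ramp so the predicted peak lands at ``target_duration``.

    The peak belt speed is the running-demand inversion of the predicted
    VO2max at the test grade; the per-minute increment divides the span
    from the 5-mph start evenly over the target duration (min), keeping
    the test in the intended 8-12 min window.
    """
    if not 8.0 <= target_duration <= 12.0:
        raise ValueError("target_duration must be within [8, 12] minutes")
    peak_m_per_min = invert_running_demand(predicted_vo2max, grade)
    peak_mph = peak_m_per_min / MPH_TO_M_PER_MIN
    if peak_mph <= start_speed:
        raise ValueError(
            f"predicted VO2max implies peak speed {peak_mph:.2f} mph "
            f"<= start speed {start_speed:.2f} mph"
        )
    increment = (peak_mph - start_speed) / target_duration
    proto = GXTProtocol(
        increment_per_min=increment, start_speed=start_speed, grade=grade
    )
    proto.validate()
    return proto
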