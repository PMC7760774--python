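"""Seeded synthetic cohort generator.

Emulates the field-test data the pipeline consumes: athlete-level truths
(critical speed CS, above-CS distance capacity D', VO2max, gas exchange
threshold GET, sex), 1-Hz all-out speed traces whose extraction recovers
the injected CS and D', ramp + verification gas-exchange series, and
injected quality-control violations (paced all-out efforts and blown
verification bouts).

Generative model
----------------
* sex ~ Bernoulli(male_fraction), coded F=0 / M=1.
* CS ~ Normal(sex-specific mean, SD), truncated above 1.0 m/s. The
  sex-specific means/SDs are *calibrated* (not asserted) so the pooled
  cohort reproduces the target CS mean/SD and the target CS-VO2max
  Pearson correlation.
* VO2max = coef_cs*CS + coef_sex*sex + intercept + Normal(0, residual_sd);
  GET = get_fraction * VO2max.
* Each athlete carries a linear flat-speed -> VO2 "economy line" anchored
  so the midpoint of the speeds at GET and VO2max equals
  CS*(1 + eps), eps ~ Normal(fifty_delta_bias, fifty_delta_sd), with a
  speed reserve (speed@VO2max - speed@GET) of speed_reserve_frac times
  that midpoint. This is what makes the GXT-derived 50% delta agree with
  CS for honest efforts, so the pacing screen passes non-violators.
* The all-out profile decays exponentially from a sprint start to an
  exact CS plateau at 150 s; the starting speed is solved so the
  above-CS distance integrates exactly to D'. Each 1-Hz sample is the
  profile's mean speed over its second (what a GPS distance-per-second
  sample measures), so the noiseless round trip through the 3MT
  extraction is exact.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import GeneratorConfig, GXTProtocol
from .data import MPH_TO_MPS, GasSeries, SpeedTrace
from .gxt import flat_equivalent, ramp_sample_speed

T_ALLOUT = 180.0
T_CS_ONSET = 150.0
S0_MAX = 12.0  # m/s; faster sprint starts are implausible

CS_TRUNCATION = 1.0  # m/s
DPRIME_TRUNCATION = 50.0  # m

RAMP_END_DEMAND_FACTOR = 1.00  # ramp stops once lagged demand reaches this x VO2max
RAMP_MAX_SECONDS = 26.0 * 60.0
VP_VIOLATOR_OFFSET = 0.05  # injected verification-phase inflation

# fixed sub-stream tags so every consumer draws from an independent stream
_TAG_CALIBRATE = 1
_TAG_SAMPLE = 10
_TAG_ALLOUT = 20
_TAG_PACING = 21
_TAG_GXT = 30


class CalibrationError(RuntimeError):
    """Raised when no sex gap reproduces the target correlation."""


@dataclass
class AthleteTruth:
    """Ground-truth quantities for one synthetic athlete."""

    id: int
    sex: int  # F=0, M=1
    true_cs: float  # m/s
    true_dprime: float  # m
    true_vo2max: float  # mL/kg/min
    true_get: float  # mL/kg/min
    true_speed_get: float  # m/s flat-equivalent speed evoking GET
    true_speed_vo2max: float  # m/s flat-equivalent speed evoking VO2max
    is_pacing_violator: bool = False
    is_vp_violator: bool = False
    mass_kg: float = 77.4

    def __post_init__(self) -> None:
        if self.true_cs <= 0:
            raise ValueError("true_cs must be positive")
        if self.true_dprime < 0:
            raise ValueError("true_dprime must be >= 0")
        if not self.true_get < self.true_vo2max:
            raise ValueError("true_get must lie below true_vo2max")

    @property
    def true_fifty_delta(self) -> float:
        return 0.5 * (self.true_speed_get + self.true_speed_vo2max)

    @property
    def economy_slope(self) -> float:
        """(mL/kg/min) per (m/s): slope of the athlete's VO2-speed line."""
        return (self.true_vo2max - self.true_get) / (
            self.true_speed_vo2max - self.true_speed_get
        )

    def vo2_at_flat_speed(self, speed_mps) -> np.ndarray:
        """Athlete's steady-state VO2 at a flat-equivalent speed (uncapped)."""
        return self.true_get + self.economy_slope * (
            np.asarray(speed_mps, dtype=float) - self.true_speed_get
        )


def _rng(config: GeneratorConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) % (2**31), *tags]))


def _truncated_normal(
    rng: np.random.Generator, mean, sd, lower: float, size: int
) -> np.ndarray:
    mean = np.broadcast_to(np.asarray(mean, float), (size,)).copy()
    sd = np.broadcast_to(np.asarray(sd, float), (size,)).copy()
    if np.all(sd == 0):
        return mean
    out = rng.normal(mean, sd)
    bad = out <= lower
    while bad.any():
        out[bad] = rng.normal(mean[bad], sd[bad])
        bad = out <= lower
    return out


def _sample_population(
    config: GeneratorConfig, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (sex, cs, vo2max) for n athletes; shared by calibration and sampling."""
    sex = (rng.random(n) < config.male_fraction).astype(int)
    mean = np.where(sex == 1, config.cs_mean_male, config.cs_mean_female)
    sd = np.where(sex == 1, config.cs_sd_male, config.cs_sd_female)
    cs = _truncated_normal(rng, mean, sd, CS_TRUNCATION, n)
    vo2 = (
        config.coef_cs * cs
        + config.coef_sex * sex
        + config.intercept
        + rng.normal(0.0, config.residual_sd, n)
    )
    return sex, cs, vo2


def _config_with_gap(config: GeneratorConfig, gap: float) -> GeneratorConfig:
    """Sex-specific CS parameters for a male-female mean gap preserving pooled moments."""
    p = config.male_fraction
    within_var = config.cs_target_sd**2 - p * (1 - p) * gap**2
    if within_var <= 0:
        raise CalibrationError(
            f"gap {gap:.3f} m/s exceeds the pooled CS SD {config.cs_target_sd}"
        )
    sw = math.sqrt(within_var)
    return config.replace(
        cs_mean_male=config.cs_target_mean + (1 - p) * gap,
        cs_sd_male=sw,
        cs_mean_female=config.cs_target_mean - p * gap,
        cs_sd_female=sw,
    )


def calibrate_sex_cs_distributions(
    config: GeneratorConfig,
    n_sim: int = 100_000,
    tol: float = 0.01,
    gap_range: tuple[float, float] = (0.0, 1.5),
) -> GeneratorConfig:
    """Find sex-specific CS distributions matching the pooled cohort structure.

    Searches (by bisection on the male-female CS mean gap, with a fixed
    simulation seed so the objective is deterministic) for the gap at
    which a large simulated population reproduces the target pooled
    CS-VO2max correlation, while the pooled CS mean and SD are held at
    their targets by construction.
    """
    config.validate()
    single_sex = config.male_fraction in (0.0, 1.0)
    if config.residual_sd == 0 and single_sex:
        raise CalibrationError(
            "degenerate population: with residual_sd=0 and a single sex, VO2max "
            "is an exact linear function of CS and the correlation is exactly 1; "
            "no gap can be calibrated"
        )

    def simulated_r(gap: float) -> float:
        cfg = _config_with_gap(config, gap)
        rng = _rng(config, _TAG_CALIBRATE)
        _, cs, vo2 = _sample_population(cfg, n_sim, rng)
        return float(np.corrcoef(cs, vo2)[0, 1])

    lo, hi = gap_range
    # a gap larger than this would need negative within-sex variance to
    # preserve the pooled SD
    p = config.male_fraction
    feasible = config.cs_target_sd / math.sqrt(p * (1 - p)) if 0 < p < 1 else math.inf
    hi = min(hi, 0.999 * feasible)
    if single_sex:
        # the gap is inert; accept iff the zero-gap population already matches
        r0 = simulated_r(0.0)
        if abs(r0 - config.r_target) <= tol:
            return _config_with_gap(config, 0.0)
        raise CalibrationError(
            f"single-sex population yields r={r0:.3f}; the sex gap cannot move it "
            f"to the target {config.r_target}"
        )
    r_lo, r_hi = simulated_r(lo), simulated_r(hi)
    if not (min(r_lo, r_hi) - tol <= config.r_target <= max(r_lo, r_hi) + tol):
        raise CalibrationError(
            f"no gap in [{lo}, {hi}] m/s reaches r={config.r_target}: "
            f"r({lo})={r_lo:.3f}, r({hi})={r_hi:.3f}"
        )
    gap = 0.5 * (lo + hi)
    for _ in range(60):
        gap = 0.5 * (lo + hi)
        r_mid = simulated_r(gap)
        if abs(r_mid - config.r_target) <= tol / 4 or hi - lo < 1e-6:
            break
        # r increases with the gap (sex reinforces the CS-VO2max link)
        if (r_mid < config.r_target) == (r_hi > r_lo):
            lo = gap
        else:
            hi = gap
    out = _config_with_gap(config, gap)
    final_r = simulated_r(gap)
    if abs(final_r - config.r_target) > tol:
        raise CalibrationError(
            f"calibration stalled at r={final_r:.4f} (target {config.r_target})"
        )
    return out


def sample_athletes(config: GeneratorConfig) -> list[AthleteTruth]:
    """Draw athlete truths; the first athletes carry the injected violations."""
    config.validate()
    if not config.is_calibrated:
        raise ValueError(
            "config has no sex-specific CS distributions; run "
            "calibrate_sex_cs_distributions first"
        )
    n = config.n_athletes
    if n == 0:
        return []
    rng = _rng(config, _TAG_SAMPLE)
    sex, cs, vo2 = _sample_population(config, n, rng)
    dprime = _truncated_normal(
        rng, config.dprime_mean, config.dprime_sd, DPRIME_TRUNCATION, n
    )
    eps = rng.normal(config.fifty_delta_bias, config.fifty_delta_sd, n)
    s_mid = cs * (1.0 + eps)
    half_reserve = 0.5 * config.speed_reserve_frac * s_mid
    get = config.get_fraction * vo2
    truths = []
    for i in range(n):
        truths.append(
            AthleteTruth(
                id=i,
                sex=int(sex[i]),
                true_cs=float(cs[i]),
                true_dprime=float(dprime[i]),
                true_vo2max=float(vo2[i]),
                true_get=float(get[i]),
                true_speed_get=float(s_mid[i] - half_reserve[i]),
                true_speed_vo2max=float(s_mid[i] + half_reserve[i]),
                is_pacing_violator=i < config.n_pacing_violators,
                is_vp_violator=config.n_pacing_violators
                <= i
                < config.n_pacing_violators + config.n_vp_violators,
            )
        )
    return truths


# ---------------------------------------------------------------------------
# all-out speed traces
# ---------------------------------------------------------------------------

def _profile_amplitude(dprime: float, tau: float) -> float:
    """Start-speed excess A = S0 - CS expending D' over [0, 150] s."""
    E = math.exp(-T_CS_ONSET / tau)
    denom = tau * (1.0 - E) - T_CS_ONSET * E
    return dprime * (1.0 - E) / denom


def _allout_profile_samples(cs: float, dprime: float, tau: float) -> np.ndarray:
    """Noiseless 1-Hz all-out samples on t = 0..180 (per-second mean speeds).

    Continuous profile for t < 150:
        speed(t) = CS + A * (exp(-t/tau) - E) / (1 - E),   E = exp(-150/tau)
    and speed = CS on [150, 180]. A = S0 - CS is solved so the above-CS
    distance over [0, 150] equals D' exactly. Each sample is the mean of
    the profile over its one-second interval, so the discrete sum over
    the first 150 samples reproduces D' with no discretization error.

    Athletes with a large D' relative to their CS would need an
    implausible sprint start under the default decay constant; for them
    the decay is stretched (a flatter, more evenly spent effort) just
    enough to keep the start below the plausibility cap. When even the
    flattest profile (linear decay, S0 = CS + D'/75) cannot, the
    CS/D'/tau combination is rejected.
    """
    amp = _profile_amplitude(dprime, tau)
    if cs + amp > S0_MAX:
        # flattest achievable start: lim tau->inf A = D'/75 (linear decay)
        if cs + dprime / 75.0 > S0_MAX * 0.999:
            raise ValueError(
                f"solved sprint start {cs + amp:.2f} m/s exceeds {S0_MAX} m/s "
                "for every decay constant: inconsistent CS/D'/tau combination"
            )
        lo, hi = tau, 1e6
        target = 0.98 * (S0_MAX - cs)
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if _profile_amplitude(dprime, mid) > target:
                lo = mid
            else:
                hi = mid
        tau = hi
        amp = _profile_amplitude(dprime, tau)
    s0 = cs + amp
    E = math.exp(-T_CS_ONSET / tau)
    t = np.arange(0, int(T_ALLOUT) + 1, dtype=float)
    speed = np.full(t.size, cs)
    decay = t < T_CS_ONSET
    td = t[decay]
    # mean over [t, t+1] of the continuous profile
    seg = tau * (np.exp(-td / tau) - np.exp(-(td + 1.0) / tau))
    speed[decay] = cs + amp * (seg - E) / (1.0 - E)
    return speed


def render_allout_trace(
    truth: AthleteTruth, config: GeneratorConfig, noiseless: bool = False
) -> SpeedTrace:
    """All-out 3-min trace for an honest (non-paced) effort."""
    speed = _allout_profile_samples(truth.true_cs, truth.true_dprime, config.tau)
    if not noiseless and config.gps_noise_sd > 0:
        rng = _rng(config, _TAG_ALLOUT, truth.id)
        speed = speed + rng.normal(0.0, config.gps_noise_sd, speed.size)
    t = np.arange(speed.size, dtype=float)
    return SpeedTrace(t, np.clip(speed, 0.0, None))


def render_pacing_violation(
    truth: AthleteTruth,
    config: GeneratorConfig,
    target_deviation: float | None = None,
) -> SpeedTrace:
    """A held-back all-out effort that trips the pacing screen.

    The runner conserves D' and finishes fast: the end-test plateau sits
    ``target_deviation`` above the athlete's true 50% delta instead of
    decaying to CS, so extracted "CS" is inflated.
    """
    if target_deviation is None:
        target_deviation = config.pacing_target_deviation
    if target_deviation < 0:
        raise ValueError("target_deviation must be >= 0")
    end_speed = (1.0 + target_deviation) * truth.true_fifty_delta
    held_back_dprime = 0.6 * truth.true_dprime
    speed = _allout_profile_samples(end_speed, held_back_dprime, config.tau)
    if config.gps_noise_sd > 0:
        rng = _rng(config, _TAG_PACING, truth.id)
        speed = speed + rng.normal(0.0, config.gps_noise_sd, speed.size)
    t = np.arange(speed.size, dtype=float)
    return SpeedTrace(t, np.clip(speed, 0.0, None))


def render_allout_cohort(
    truths: list[AthleteTruth], config: GeneratorConfig, noiseless: bool = False
) -> list[SpeedTrace]:
    """Render every athlete's all-out trace (violators get paced efforts)."""
    out = []
    for truth in truths:
        if truth.is_pacing_violator:
            out.append(render_pacing_violation(truth, config))
        else:
            out.append(render_allout_trace(truth, config, noiseless=noiseless))
    return out


# ---------------------------------------------------------------------------
# GXT gas-exchange series
# ---------------------------------------------------------------------------

def design_protocol_for(
    truth: AthleteTruth, target_duration: float = 10.0, grade: float = 0.03
) -> GXTProtocol:
    """Individualized ramp for a synthetic athlete.

    Stands in for the study's pre-test estimate of peak speed: the peak
    belt speed is set so the athlete's own economy line reaches 110% of
    VO2max at the flat-equivalent of that speed, and the increment
    divides the span from the start speed over the target duration,
    which lands exhaustion (and the 8-12 min window) near the target.
    """
    b = truth.economy_slope
    reserve = truth.true_speed_vo2max - truth.true_speed_get
    peak_flat = truth.true_speed_vo2max + 0.10 * truth.true_vo2max / b
    peak_mph = peak_flat / (1.0 + 4.5 * grade) / MPH_TO_MPS
    # the start-speed demand must sit clearly below the athlete's GET so
    # the v-slope lower segment exists; slower athletes start below 5 mph
    start_flat_cap = truth.true_speed_get - 0.3 * reserve
    start = min(5.0, start_flat_cap / (1.0 + 4.5 * grade) / MPH_TO_MPS)
    start = max(1.0, min(start, peak_mph - 0.8))
    return GXTProtocol(
        increment_per_min=(peak_mph - start) / target_duration,
        start_speed=start,
        grade=grade,
    )


def _vco2_from_vo2(vo2: np.ndarray, get: float, below: float, above: float) -> np.ndarray:
    """Piecewise-linear VCO2 with a v-slope breakpoint at the GET."""
    vo2 = np.asarray(vo2, dtype=float)
    return np.where(
        vo2 <= get, below * vo2, below * get + above * (vo2 - get)
    )


def render_gxt_series(
    truth: AthleteTruth,
    protocol: GXTProtocol,
    config: GeneratorConfig,
    noiseless: bool = False,
) -> GasSeries:
    """1-Hz gas-exchange series: rest, warm-up, ramp, recovery, verification.

    Ramp VO2 at time t is the athlete's demand for the belt speed one
    minute earlier (quarter-stage interpolated), capped at VO2max; the
    ramp ends one sample after the lagged demand exceeds VO2max by 2%.
    The verification bout runs at 105% of the peak ramp speed and
    plateaus at VO2max*(1+e), e ~ N(0, vp_noise_sd) for honest bouts and
    +5% for injected verification violators.
    """
    protocol.validate()
    vmax = truth.true_vo2max
    get = truth.true_get
    grade = protocol.grade

    # --- ramp schedule: find the end sample from the lagged demand
    j = np.arange(0, int(RAMP_MAX_SECONDS // 15) + 8)
    lagged_mph = ramp_sample_speed(protocol, np.maximum(j - 4, 0))
    lagged_demand = truth.vo2_at_flat_speed(flat_equivalent(lagged_mph, grade, "mph"))
    over = np.nonzero(lagged_demand >= RAMP_END_DEMAND_FACTOR * vmax)[0]
    if over.size == 0 or 15.0 * (over[0] + 1) > RAMP_MAX_SECONDS:
        raise ValueError(
            "ramp would exceed 26 min before exhaustion: protocol mis-designed "
            f"(increment {protocol.increment_per_min:.3f} mph/min)"
        )
    j_end = int(over[0])
    ramp_dur = int(15 * (j_end + 1))
    peak_belt_mph = float(ramp_sample_speed(protocol, j_end))

    rest_dur, warmup_dur, rec_dur, vp_dur = 120, 300, 600, 120

    # per-phase noiseless VO2 at 1 Hz
    vo2_rest = np.full(rest_dur, 5.0)
    warmup_flat = flat_equivalent(protocol.warmup_speed, 0.0, "mph")
    vo2_warm = np.full(warmup_dur, max(6.0, float(truth.vo2_at_flat_speed(warmup_flat))))

    t_ramp = np.arange(ramp_dur)
    demand_t = lagged_demand[np.minimum(t_ramp // 15, j_end)]
    vo2_ramp = np.minimum(vmax, demand_t)

    ramp_end_vo2 = vo2_ramp[-1]
    t_rec = np.arange(rec_dur, dtype=float)
    vo2_rec = 10.0 + (ramp_end_vo2 - 10.0) * np.exp(-t_rec / 60.0)

    if truth.is_vp_violator:
        vp_level = vmax * (1.0 + VP_VIOLATOR_OFFSET)
    else:
        vp_rng = _rng(config, _TAG_GXT, truth.id, 1)
        vp_level = vmax * (1.0 + vp_rng.normal(0.0, config.vp_noise_sd))
    t_vp = np.arange(vp_dur, dtype=float)
    vo2_vp = vp_level - (vp_level - vo2_rec[-1]) * np.exp(-t_vp / 20.0)

    vo2 = np.concatenate([vo2_rest, vo2_warm, vo2_ramp, vo2_rec, vo2_vp])
    vco2 = _vco2_from_vo2(
        vo2, get, config.vslope_slope_below, config.vslope_slope_above
    )

    if not noiseless and config.gas_noise_sd > 0:
        rng = _rng(config, _TAG_GXT, truth.id, 0)
        per_sample_sd = config.gas_noise_sd * math.sqrt(15.0)
        vo2 = vo2 + rng.normal(0.0, per_sample_sd, vo2.size)
        vco2 = vco2 + rng.normal(0.0, per_sample_sd, vco2.size)

    n_total = rest_dur + warmup_dur + ramp_dur + rec_dur + vp_dur
    time = np.arange(n_total, dtype=float)
    phase = np.concatenate(
        [
            np.repeat("rest", rest_dur),
            np.repeat("warmup", warmup_dur),
            np.repeat("ramp", ramp_dur),
            np.repeat("recovery", rec_dur),
            np.repeat("verification", vp_dur),
        ]
    ).astype(object)
    speed = np.concatenate(
        [
            np.zeros(rest_dur),
            np.full(warmup_dur, protocol.warmup_speed),
            ramp_sample_speed(protocol, np.minimum(t_ramp // 15, j_end)),
            np.full(rec_dur, 3.0),
            np.full(vp_dur, 1.05 * peak_belt_mph),
        ]
    )
    grade_col = np.concatenate(
        [
            np.zeros(rest_dur),
            np.zeros(warmup_dur),
            np.full(ramp_dur, grade),
            np.zeros(rec_dur),
            np.full(vp_dur, grade),
        ]
    )
    return GasSeries(
        time=time,
        vo2=np.clip(vo2, 0.0, None),
        vco2=np.clip(vco2, 0.0, None),
        speed=speed,
        grade=grade_col,
        phase=phase,
        speed_unit="mph",
    )
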