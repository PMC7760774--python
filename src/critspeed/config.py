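"""Configuration objects for the synthetic cohort generator and the GXT protocol."""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import yaml

#: Published prediction-equation coefficients (relative VO2max, mL/kg/min).
EQ2_COEF_CS = 8.449
EQ2_COEF_SEX = 4.387
EQ2_INTERCEPT = 14.683
EQ2_SEE = 3.34

#: Cohort moments the calibration reproduces.
CS_POOLED_MEAN = 3.56  # m/s
CS_POOLED_SD = 0.55  # m/s
CS_VO2MAX_R = 0.819
DPRIME_MEAN = 208.5  # m
DPRIME_SD = 54.3  # m


@dataclass
class GeneratorConfig:
    """All distributional parameters of the synthetic cohort.

    Sex-specific CS means/SDs default to None and are filled in by
    :func:`critspeed.synthetic.calibrate_sex_cs_distributions`, which
    searches for the male-female CS gap reproducing the pooled CS moments
    and the pooled CS-VO2max correlation.
    """

    n_athletes: int = 37
    male_fraction: float = 17 / 25
    cs_mean_male: Optional[float] = None
    cs_sd_male: Optional[float] = None
    cs_mean_female: Optional[float] = None
    cs_sd_female: Optional[float] = None
    dprime_mean: float = DPRIME_MEAN
    dprime_sd: float = DPRIME_SD
    residual_sd: float = EQ2_SEE
    coef_cs: float = EQ2_COEF_CS
    coef_sex: float = EQ2_COEF_SEX
    intercept: float = EQ2_INTERCEPT
    tau: float = 35.0  # all-out decay constant, s
    gps_noise_sd: float = 0.05  # m/s per 1-Hz sample
    gas_noise_sd: float = 0.25  # mL/kg/min per 15-s bin average
    get_fraction: float = 0.65  # GET as a fraction of VO2max
    vslope_slope_below: float = 0.85
    vslope_slope_above: float = 1.15
    vp_noise_sd: float = 0.008  # proportional verification-plateau scatter
    n_pacing_violators: int = 0
    n_vp_violators: int = 0
    seed: int = 0
    # calibration targets (pooled cohort moments)
    cs_target_mean: float = CS_POOLED_MEAN
    cs_target_sd: float = CS_POOLED_SD
    r_target: float = CS_VO2MAX_R
    # speed-economy structure linking the GXT speeds to CS: the midpoint of
    # the speeds at GET and at VO2max sits at CS*(1+eps),
    # eps ~ N(fifty_delta_bias, fifty_delta_sd); their spread is
    # speed_reserve_frac of that midpoint.
    speed_reserve_frac: float = 0.30
    fifty_delta_bias: float = 0.008
    fifty_delta_sd: float = 0.005
    pacing_target_deviation: float = 0.08  # injected pacing-violation offset

    def validate(self) -> None:
        sds = {
            "dprime_sd": self.dprime_sd,
            "residual_sd": self.residual_sd,
            "gps_noise_sd": self.gps_noise_sd,
            "gas_noise_sd": self.gas_noise_sd,
            "vp_noise_sd": self.vp_noise_sd,
            "fifty_delta_sd": self.fifty_delta_sd,
        }
        for name in ("cs_sd_male", "cs_sd_female"):
            value = getattr(self, name)
            if value is not None:
                sds[name] = value
        for name, value in sds.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0.0 < self.get_fraction < 1.0:
            raise ValueError("get_fraction must be in (0, 1)")
        if self.vslope_slope_above <= self.vslope_slope_below:
            raise ValueError("vslope_slope_above must exceed vslope_slope_below")
        if self.n_athletes < 0:
            raise ValueError("n_athletes must be >= 0")
        if self.n_pacing_violators < 0 or self.n_vp_violators < 0:
            raise ValueError("violator counts must be >= 0")
        if self.n_pacing_violators + self.n_vp_violators > self.n_athletes:
            raise ValueError("more injected violators than athletes")
        if not 0.0 < self.speed_reserve_frac < 1.0:
            raise ValueError("speed_reserve_frac must be in (0, 1)")

    @property
    def is_calibrated(self) -> bool:
        return None not in (
            self.cs_mean_male,
            self.cs_sd_male,
            self.cs_mean_female,
            self.cs_sd_female,
        )

    def replace(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class GXTProtocol:
    """Individualized ramp protocol: fixed grade, per-minute speed increments."""

    increment_per_min: float  # mph added per minute
    start_speed: float = 5.0  # mph
    grade: float = 0.03
    warmup_speed: float = 3.25  # mph, walking warm-up
    stage_length: float = 60.0  # s

    def validate(self) -> None:
        if self.increment_per_min <= 0:
            raise ValueError("increment_per_min must be positive")
        if self.grade < 0:
            raise ValueError("grade must be >= 0")
        if self.start_speed <= 0:
            raise ValueError("start_speed must be positive")

    @classmethod
    def from_file(cls, path) -> "GXTProtocol":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        proto = cls(**data)
        proto.validate()
        return proto

    def to_dict(self) -> dict:
        return asdict(self)
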