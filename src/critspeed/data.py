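"""Core data containers: speed traces and gas-exchange series.

Both are thin wrappers over numpy arrays with CSV round-trip helpers.
All internal speeds are m/s unless a unit tag says otherwise; treadmill
speeds cross the boundary in mph and are tagged as such.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MPH_TO_MPS = 0.44704

PHASES = ("rest", "warmup", "ramp", "recovery", "verification")


@dataclass
class SpeedTrace:
    """1-Hz speed record of an all-out field run.

    time is in seconds, strictly increasing; speed is non-negative m/s.
    """

    time: np.ndarray
    speed: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.time.shape != self.speed.shape:
            raise ValueError("time and speed must have the same length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.speed < 0):
            raise ValueError("speed must be non-negative")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "speed_mps": self.speed})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpeedTrace":
        missing = {"time_s", "speed_mps"} - set(df.columns)
        if missing:
            raise ValueError(f"trace table missing columns: {sorted(missing)}")
        return cls(df["time_s"].to_numpy(float), df["speed_mps"].to_numpy(float))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpeedTrace":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class GasSeries:
    """Timestamped gas-exchange record of a treadmill test.

    vo2/vco2 are relative rates (mL/kg/min); speed is the treadmill belt
    speed in the declared unit (mph by default); grade is fractional
    incline; phase labels each sample with one of: rest, warmup, ramp,
    recovery, verification. Phase segments are contiguous.
    """

    time: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray
    speed: np.ndarray
    grade: np.ndarray
    phase: np.ndarray
    speed_unit: str = "mph"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.vco2 = np.asarray(self.vco2, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.grade = np.asarray(self.grade, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        n = self.time.size
        for name in ("vo2", "vco2", "speed", "grade", "phase"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match time")
        if np.any(self.vo2 < 0) or np.any(self.vco2 < 0):
            raise ValueError("gas values must be non-negative")
        unknown = set(np.unique(self.phase)) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phase labels: {sorted(unknown)}")

    def phase_mask(self, phase: str) -> np.ndarray:
        return self.phase == phase

    def has_phase(self, phase: str) -> bool:
        return bool(np.any(self.phase == phase))

    def phase_start(self, phase: str) -> float:
        mask = self.phase_mask(phase)
        if not mask.any():
            raise ValueError(f"phase {phase!r} not present in series")
        return float(self.time[mask][0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "vo2_mlkgmin": self.vo2,
                "vco2_mlkgmin": self.vco2,
                "speed": self.speed,
                "speed_unit": self.speed_unit,
                "grade": self.grade,
                "phase": self.phase,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GasSeries":
        required = {"time_s", "vo2_mlkgmin", "vco2_mlkgmin", "speed", "grade", "phase"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"gas table missing columns: {sorted(missing)}")
        unit = "mph"
        if "speed_unit" in df.columns and len(df):
            units = df["speed_unit"].unique()
            if len(units) > 1:
                raise ValueError("mixed speed units in one series")
            unit = str(units[0])
        return cls(
            df["time_s"].to_numpy(float),
            df["vo2_mlkgmin"].to_numpy(float),
            df["vco2_mlkgmin"].to_numpy(float),
            df["speed"].to_numpy(float),
            df["grade"].to_numpy(float),
            df["phase"].to_numpy(object),
            speed_unit=unit,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GasSeries":
        return cls.from_frame(pd.read_csv(path))
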