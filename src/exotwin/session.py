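"""Synchronized session logs at 100 samples/s.

A :class:`SessionLog` wraps a pandas DataFrame with a fixed schema: time,
pivot pose, mouse-frame forces, commanded velocities, zone label, and task
event marker.  CSV is the interchange format; parquet is offered as the
compact binary container with an identical schema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SCHEMA = [
    "t_s",
    "x_m",
    "y_m",
    "z_m",
    "pitch_rad",
    "roll_rad",
    "yaw_rad",
    "fx_N",
    "fy_N",
    "tz_Nm",
    "vcmd_x",
    "vcmd_y",
    "vcmd_yaw",
    "zone",
    "event",
]

SAMPLE_RATE = 100.0


@dataclass
class SessionLog:
    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in SCHEMA if c not in self.data.columns]
        if missing:
            raise ValueError(f"session log missing columns: {missing}")
        self.data = self.data[SCHEMA].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dt(self) -> float:
        t = self.data["t_s"].to_numpy()
        return float(t[1] - t[0]) if len(t) > 1 else 1.0 / SAMPLE_RATE

    def positions(self) -> np.ndarray:
        return self.data[["x_m", "y_m"]].to_numpy()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SessionLog":
        df = pd.read_csv(path)
        for col in ("zone", "event"):
            df[col] = df[col].fillna("").astype(str)
        return cls(df)

    def to_parquet(self, path) -> None:
        self.data.to_parquet(path, index=False)

    @classmethod
    def from_parquet(cls, path) -> "SessionLog":
        return cls(pd.read_parquet(path))


def empty_frame(n: int, dt: float = 1.0 / SAMPLE_RATE) -> pd.DataFrame:
    df = pd.DataFrame({c: np.zeros(n) for c in SCHEMA if c not in ("zone", "event")})
    df["t_s"] = np.arange(n) * dt
    df["zone"] = ""
    df["event"] = ""
    return df
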