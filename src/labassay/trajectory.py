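"""CIELAB time courses from frame series, and b*-phase classification.

The a* trajectory tracks chromophore release (the enzymatic signal);
the b* trajectory tracks dissolution of the yellow substrate, so its
slope classifies the run into solubilization-dominated, steady-state
or cleavage-dominated regimes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .colorspace import (
    ColorSample,
    ColorspaceConfig,
    Rect,
    WhiteBalanceGains,
    compute_white_balance,
    region_color_stats,
)

__all__ = [
    "ColorTrajectory",
    "PhaseCall",
    "extract_trajectory",
    "homogeneity_index",
    "classify_b_phase",
    "CSV_COLUMNS",
]

CSV_COLUMNS = ["time_min", "L", "a", "b", "L_sd", "a_sd", "b_sd", "n_pixels"]


@dataclass
class ColorTrajectory:
    """Per-frame CIELAB means and dispersions with timestamps."""

    times: np.ndarray
    samples: list[ColorSample]
    gains_used: WhiteBalanceGains | None = None
    roi: Rect | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.samples) != len(self.times):
            raise ValueError("one sample per time point required")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def L(self) -> np.ndarray:
        return np.array([s.L_star for s in self.samples])

    @property
    def a(self) -> np.ndarray:
        return np.array([s.a_star for s in self.samples])

    @property
    def b(self) -> np.ndarray:
        return np.array([s.b_star for s in self.samples])

    def signal(self, kind: str) -> np.ndarray:
        try:
            return {"L_star": self.L, "a_star": self.a, "b_star": self.b}[kind]
        except KeyError:
            raise ValueError(f"unknown signal kind {kind!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "L": self.L,
                "a": self.a,
                "b": self.b,
                "L_sd": [s.L_sd for s in self.samples],
                "a_sd": [s.a_sd for s in self.samples],
                "b_sd": [s.b_sd for s in self.samples],
                "n_pixels": [s.n_pixels for s in self.samples],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source: str = "") -> "ColorTrajectory":
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns {missing}")
        samples = [
            ColorSample(r.L, r.a, r.b, r.L_sd, r.a_sd, r.b_sd, int(r.n_pixels))
            for r in df.itertuples()
        ]
        return cls(times=df["time_min"].to_numpy(), samples=samples, source=source)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ColorTrajectory":
        return cls.from_frame(pd.read_csv(path), source=str(path))


@dataclass(frozen=True)
class PhaseCall:
    """Classification of the b* dynamics over a window."""

    phase: str  # solubilization-dominated | steady-state | cleavage-dominated
    b_slope: float  # b* units per min
    window: tuple[float, float]
    threshold_used: float

    def __post_init__(self) -> None:
        if self.threshold_used <= 0:
            raise ValueError("threshold must be positive")


def extract_trajectory(
    series,
    config: ColorspaceConfig | None = None,
    per_frame_balance: bool = False,
) -> ColorTrajectory:
    """Extract the CIELAB trajectory of the chamber ROI from a frame series.

    By default white-balance gains are computed once, from the white
    patch of the first frame, and reused for all frames: per-frame
    balancing would silently absorb genuine colour change if the
    reference patch were ever contaminated.  Set
    ``per_frame_balance=True`` to re-balance every frame.
    """
    config = config or ColorspaceConfig()
    first_white = series.frames[0][series.roi_white.slices()]
    gains = compute_white_balance(first_white, config)
    samples = []
    for frame in series.frames:
        g = (
            compute_white_balance(frame[series.roi_white.slices()], config)
            if per_frame_balance
            else gains
        )
        samples.append(region_color_stats(frame, series.roi_chamber, g, config))
    return ColorTrajectory(
        times=series.times,
        samples=samples,
        gains_used=gains,
        roi=series.roi_chamber,
        source=str(series.metadata.get("scenario", "")),
    )


def homogeneity_index(traj: ColorTrajectory, t: float) -> float:
    """Colour uniformity at the sample nearest to ``t``: ||(L_sd, a_sd, b_sd)||.

    Zero for a perfectly uniform chamber; undissolved spots or
    aggregates raise it.
    """
    if not (traj.times.min() - 1e-9 <= t <= traj.times.max() + 1e-9):
        raise ValueError(f"t={t} outside trajectory range")
    i = int(np.argmin(np.abs(traj.times - t)))
    s = traj.samples[i]
    return float(np.linalg.norm([s.L_sd, s.a_sd, s.b_sd]))


def classify_b_phase(
    traj: ColorTrajectory,
    window: tuple[float, float] | None = None,
    threshold: float = 0.01,
) -> PhaseCall:
    """Classify solubilization vs cleavage from the b* slope.

    Least-squares b* slope over the window (default: full trajectory
    up to 30 min).  Slopes above ``+threshold`` (b* rising, yellow
    increasing) are solubilization-dominated; below ``-threshold``
    cleavage-dominated; in between the two processes balance
    (steady state).
    """
    if window is None:
        window = (float(traj.times.min()), min(30.0, float(traj.times.max())))
    t0, t1 = window
    mask = (traj.times >= t0 - 1e-9) & (traj.times <= t1 + 1e-9)
    if mask.sum() < 3:
        raise ValueError("need at least 3 samples in the window")
    slope = float(np.polyfit(traj.times[mask], traj.b[mask], 1)[0])
    if slope > threshold:
        phase = "solubilization-dominated"
    elif slope < -threshold:
        phase = "cleavage-dominated"
    else:
        phase = "steady-state"
    return PhaseCall(phase=phase, b_slope=slope, window=(t0, t1), threshold_used=threshold)
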