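"""Core data containers shared across the pipeline.

Positions live in a local Earth-fixed east/north/up (ENU) frame, metres;
time is seconds from trial start. The per-sample ``fix`` flag mirrors the
carrier-phase ambiguity status of differential GNSS solutions: only
``fixed`` samples carry centimetre accuracy and enter the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

FIXED = "fixed"
FLOAT = "float"

#: labels emitted by the generator / training corpus (left/right resolved)
SIDE_LABELS = ("G2L", "G2R", "G3", "G4L", "G4R", "G5", "Tuck")
#: labels emitted by the classifier and used in evaluation
MERGED_LABELS = ("G2", "G3", "G4", "G5", "Turn", "Tuck")

_MERGE = {"G2L": "G2", "G2R": "G2", "G4L": "G4", "G4R": "G4",
          "G2": "G2", "G3": "G3", "G4": "G4",
          "G5": "G5", "Tuck": "Tuck", "Turn": "Turn", "none": "none",
          # a cycle the decision tree could not label (no trained model)
          # counts as undetected for evaluation purposes
          "unclassified": "none"}


def merge_label(label: str) -> str:
    """Map left/right technique variants onto their merged class (G2L/G2R -> G2)."""
    try:
        return _MERGE[label]
    except KeyError:
        raise ValueError(f"unknown technique label {label!r}") from None


@dataclass
class TrajectorySeries:
    """Uniformly sampled 3-D head trajectory in the ENU frame.

    Attributes
    ----------
    time : (n,) float array, strictly increasing, seconds.
    pos : (n, 3) float array, east/north/up metres.
    fix : (n,) bool array, True where the ambiguity solution is fixed.
    vel : optional (n, 3) float array, m/s (populated by the smoother).
    """

    time: np.ndarray
    pos: np.ndarray
    fix: np.ndarray = None  # type: ignore[assignment]
    vel: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.ndim != 2 or self.pos.shape != (self.time.size, 3):
            raise ValueError("pos must have shape (n, 3) matching time")
        if self.fix is None:
            self.fix = np.ones(self.time.size, dtype=bool)
        else:
            self.fix = np.asarray(self.fix, dtype=bool)
            if self.fix.shape != self.time.shape:
                raise ValueError("fix flag must match time length")
        if self.time.size > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.vel is not None:
            self.vel = np.asarray(self.vel, dtype=float)
            if self.vel.shape != self.pos.shape:
                raise ValueError("vel must match pos shape")

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def sample_rate(self) -> float:
        """Nominal sample rate from the median time step."""
        if self.n < 2:
            raise ValueError("need at least two samples for a sample rate")
        return 1.0 / float(np.median(np.diff(self.time)))

    def slice(self, sl: slice) -> "TrajectorySeries":
        return TrajectorySeries(
            self.time[sl], self.pos[sl], self.fix[sl],
            None if self.vel is None else self.vel[sl],
        )

    def copy(self, **changes) -> "TrajectorySeries":
        base = dict(time=self.time.copy(), pos=self.pos.copy(),
                    fix=self.fix.copy(),
                    vel=None if self.vel is None else self.vel.copy())
        base.update(changes)
        return TrajectorySeries(**base)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time_s": self.time,
            "east_m": self.pos[:, 0],
            "north_m": self.pos[:, 1],
            "up_m": self.pos[:, 2],
            "fix": np.where(self.fix, FIXED, FLOAT),
        })
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrajectorySeries":
        required = ["time_s", "east_m", "north_m", "up_m"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns {missing}")
        if len(df) == 0:
            raise ValueError("empty trajectory table")
        pos = df[["east_m", "north_m", "up_m"]].to_numpy(dtype=float)
        if "fix" in df.columns:
            flags = df["fix"].astype(str).str.strip().to_numpy()
            bad = set(flags) - {FIXED, FLOAT}
            if bad:
                raise ValueError(f"unknown fix flags {sorted(bad)}")
            fix = flags == FIXED
        else:
            fix = np.ones(len(df), dtype=bool)
        return cls(df["time_s"].to_numpy(dtype=float), pos, fix)


@dataclass
class LocalFrameSeries:
    """Head kinematics expressed in the moving local coordinate system.

    The origin follows the 0.3 Hz low-pass head trajectory; the axes are the
    skiing direction (normalized origin velocity), sideways (skiing x vertical,
    pointing to the skier's right) and global up. ``pos_lcs``/``vel_lcs``
    columns are ordered (fore-aft, sideways, vertical).
    """

    time: np.ndarray
    origin: np.ndarray
    e_ski: np.ndarray
    e_side: np.ndarray
    e_vert: np.ndarray
    pos_lcs: np.ndarray
    vel_lcs: np.ndarray
    heading_deg: np.ndarray  # unwrapped azimuth of e_ski, degrees
    valid: np.ndarray        # False where |origin velocity| < speed floor

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def vel_side(self) -> np.ndarray:
        return self.vel_lcs[:, 1]

    @property
    def vel_vert(self) -> np.ndarray:
        return self.vel_lcs[:, 2]


@dataclass
class GroundTruth:
    """Known cycle events and labels attached to a synthetic trajectory."""

    cycle_events: np.ndarray = field(default_factory=lambda: np.empty(0))
    labels: list = field(default_factory=list)
    pole_plants: np.ndarray = field(default_factory=lambda: np.empty(0))
    intervals: list = field(default_factory=list)  # (t0, t1, label) non-cyclic
    com_positions: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.cycle_events = np.asarray(self.cycle_events, dtype=float)
        if self.cycle_events.size > 1 and np.any(np.diff(self.cycle_events) <= 0):
            raise ValueError("cycle_events must be strictly increasing")
        n_intervals = max(self.cycle_events.size - 1, 0)
        if len(self.labels) != n_intervals:
            raise ValueError("need one label per inter-event interval")

    def cycle_table(self) -> pd.DataFrame:
        """Truth cycles as an annotation table (t_start_s, t_end_s, label)."""
        ev = self.cycle_events
        rows = [
            {"t_start_s": ev[i], "t_end_s": ev[i + 1], "label": self.labels[i]}
            for i in range(max(ev.size - 1, 0))
        ]
        return pd.DataFrame(rows, columns=["t_start_s", "t_end_s", "label"])

    def annotation_table(self, merged: bool = True) -> pd.DataFrame:
        """Cycles plus non-cyclic intervals, optionally with L/R merged labels.

        Inter-event intervals labelled ``transition`` (spanning a segment
        join, hence not a cycle of any technique) are dropped.
        """
        df = self.cycle_table()
        if self.intervals:
            extra = pd.DataFrame(self.intervals,
                                 columns=["t_start_s", "t_end_s", "label"])
            df = pd.concat([df, extra], ignore_index=True)
        df = df[df["label"] != "transition"]
        df = df.sort_values("t_start_s", ignore_index=True)
        if merged:
            df["label"] = df["label"].map(merge_label)
        return df


@dataclass
class CycleRecord:
    """One detected movement cycle and its summary metrics."""

    t_start: float
    t_end: float
    duration: float
    length: float
    heading_change: float  # degrees, signed
    heading_rate: float    # degrees/s, absolute
    band_side: float = np.nan  # mean STFT band sum over the cycle, m/s
    band_vert: float = np.nan
    label: str = "unassigned"

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("cycle must have positive duration")


def records_to_frame(records: Sequence[CycleRecord]) -> pd.DataFrame:
    rows = [{
        "t_start_s": r.t_start, "t_end_s": r.t_end, "duration_s": r.duration,
        "length_m": r.length, "heading_rate_degs": r.heading_rate,
        "band_side_ms": r.band_side, "band_vert_ms": r.band_vert,
        "label": r.label,
    } for r in records]
    return pd.DataFrame(rows, columns=[
        "t_start_s", "t_end_s", "duration_s", "length_m",
        "heading_rate_degs", "band_side_ms", "band_vert_ms", "label"])


__all__ = [
    "FIXED", "FLOAT", "SIDE_LABELS", "MERGED_LABELS", "merge_label",
    "TrajectorySeries", "LocalFrameSeries", "GroundTruth", "CycleRecord",
    "records_to_frame", "replace",
]
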