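"""Trajectory container: time-ordered 2D localizations on a uniform frame grid.

The trajectory is the universal currency of the pipeline: the simulator emits
it (with ground-truth positions and motion states attached), the imaging chain
reconstructs it from frames, and the MSD / confinement analyses consume it.

Units: coordinates in micrometres, time in seconds. Noise parameters elsewhere
in the package are accepted in nanometres and converted once at the boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class MotionState(enum.IntEnum):
    """Ground-truth per-frame motion state (simulation only)."""

    LD = 0          # liquid-disordered background
    LO_FREE = 1     # liquid-ordered domain, between traps
    LO_TRAPPED = 2  # confined inside a nano-trap


_CSV_COLUMNS = ["frame", "t_s", "x_um", "y_um"]
_CSV_TRUTH_COLUMNS = ["true_x_um", "true_y_um", "state"]


@dataclass
class Trajectory:
    """A single-particle track sampled at a fixed frame interval.

    Parameters
    ----------
    frame : ndarray of int
        Strictly increasing frame indices with uniform unit spacing.
    t : ndarray of float
        Time stamps in seconds, ``t = frame * frame_interval``.
    x, y : ndarray of float
        Observed lateral positions in micrometres.
    true_x, true_y : ndarray of float, optional
        Ground-truth positions (simulation only).
    state : ndarray of int, optional
        Ground-truth :class:`MotionState` per frame (simulation only).
    """

    frame: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    true_x: np.ndarray | None = None
    true_y: np.ndarray | None = None
    state: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.frame.size
        if n < 2:
            raise ValueError("trajectory must have at least 2 frames")
        if not (self.t.size == self.x.size == self.y.size == n):
            raise ValueError("frame/t/x/y lengths differ")
        dframe = np.diff(self.frame)
        if np.any(dframe <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if np.any(dframe != dframe[0]):
            raise ValueError("frame spacing must be uniform")
        dt = np.diff(self.t)
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-15) or dt[0] <= 0:
            raise ValueError("time stamps must be uniformly spaced and increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("positions must be finite")
        for name in ("true_x", "true_y", "state"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.size != n:
                    raise ValueError(f"{name} length differs from frame count")
                setattr(self, name, arr)

    # ------------------------------------------------------------------
    @property
    def n_steps(self) -> int:
        """Number of frames in the track."""
        return int(self.frame.size)

    @property
    def frame_interval_s(self) -> float:
        """Uniform time between consecutive frames, seconds."""
        return float(self.t[1] - self.t[0]) / float(self.frame[1] - self.frame[0])

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of observed positions, micrometres."""
        return np.column_stack([self.x, self.y])

    @property
    def true_xy(self) -> np.ndarray:
        if self.true_x is None or self.true_y is None:
            raise AttributeError("trajectory carries no ground-truth positions")
        return np.column_stack([self.true_x, self.true_y])

    def has_truth(self) -> bool:
        return self.true_x is not None and self.true_y is not None

    # ------------------------------------------------------------------
    def downsample(self, factor: int) -> "Trajectory":
        """Keep every ``factor``-th frame, emulating a slower camera.

        A 50 kHz track downsampled by 50 reproduces a 1 kHz recording of the
        same particle (each retained localization is still an exposure average
        over the original short exposure, which is the conservative choice for
        the temporal-resolution comparison).
        """
        if factor < 1:
            raise ValueError("factor must be >= 1")
        sl = slice(None, None, factor)
        return Trajectory(
            frame=self.frame[sl] // factor,
            t=self.t[sl],
            x=self.x[sl],
            y=self.y[sl],
            true_x=None if self.true_x is None else self.true_x[sl],
            true_y=None if self.true_y is None else self.true_y[sl],
            state=None if self.state is None else self.state[sl],
            meta=dict(self.meta),
        )

    def slice(self, start: int, stop: int) -> "Trajectory":
        """Sub-trajectory over frame positions [start, stop)."""
        sl = slice(start, stop)
        return Trajectory(
            frame=self.frame[sl],
            t=self.t[sl],
            x=self.x[sl],
            y=self.y[sl],
            true_x=None if self.true_x is None else self.true_x[sl],
            true_y=None if self.true_y is None else self.true_y[sl],
            state=None if self.state is None else self.state[sl],
            meta=dict(self.meta),
        )

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        data = {
            "frame": self.frame,
            "t_s": self.t,
            "x_um": self.x,
            "y_um": self.y,
        }
        if self.has_truth():
            data["true_x_um"] = self.true_x
            data["true_y_um"] = self.true_y
        if self.state is not None:
            data["state"] = np.asarray(self.state, dtype=int)
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        """Write the track as CSV (header mandatory, '.' decimal separator)."""
        self.to_frame().to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path)
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trajectory CSV missing columns: {missing}")
        kwargs = {}
        if all(c in df.columns for c in _CSV_TRUTH_COLUMNS[:2]):
            kwargs["true_x"] = df["true_x_um"].to_numpy()
            kwargs["true_y"] = df["true_y_um"].to_numpy()
        if "state" in df.columns:
            kwargs["state"] = df["state"].to_numpy(dtype=int)
        return cls(
            frame=df["frame"].to_numpy(),
            t=df["t_s"].to_numpy(),
            x=df["x_um"].to_numpy(),
            y=df["y_um"].to_numpy(),
            **kwargs,
        )
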