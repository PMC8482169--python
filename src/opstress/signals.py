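"""Core signal containers: RR-interval series and tri-axial acceleration traces.

Both containers mirror the CSV export dialect of chest-worn heart-rate /
accelerometer sensors: an RR file with beat times and interbeat intervals,
and an acceleration file with a fixed sampling rate and three axes in m/s².
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RRISeries", "AccelTrace"]

_T_TOL = 1e-9  # beat-time consistency tolerance, seconds


@dataclass
class RRISeries:
    """Timestamped interbeat intervals with per-beat exclusion flags.

    Attributes
    ----------
    t : ndarray
        Beat times in seconds, strictly increasing. ``t[i]`` is the time of
        the beat terminating interval ``rri[i]``, so successive differences
        of ``t`` equal ``rri / 1000``.
    rri : ndarray
        Interbeat intervals in milliseconds, all positive.
    excluded : ndarray of bool
        Per-beat artifact flags set by the artifact filter; retained beats
        are ``~excluded``.
    subject_id : str
        Identifier of the wearer.
    """

    t: np.ndarray
    rri: np.ndarray
    excluded: np.ndarray = None  # type: ignore[assignment]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rri = np.asarray(self.rri, dtype=float)
        if self.excluded is None:
            self.excluded = np.zeros(self.t.shape, dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.t.shape != self.rri.shape or self.t.ndim != 1:
            raise ValueError("t and rri must be 1-D arrays of equal length")
        if self.excluded.shape != self.t.shape:
            raise ValueError("excluded must match t in length")
        if self.t.size:
            if np.any(self.rri <= 0):
                raise ValueError("all interbeat intervals must be positive")
            if np.any(np.diff(self.t) <= 0):
                raise ValueError("beat times must be strictly increasing")
            dt = np.diff(self.t) - self.rri[1:] / 1000.0
            if np.any(np.abs(dt) > _T_TOL):
                raise ValueError(
                    "beat times inconsistent with intervals: "
                    f"max |Δt - rri/1000| = {np.abs(dt).max():.3g} s"
                )

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Time spanned by the record in seconds (first interval included)."""
        if not len(self):
            return 0.0
        return float(self.t[-1] - self.t[0] + self.rri[0] / 1000.0)

    @property
    def retained(self) -> "RRISeries":
        """Sub-series of beats not flagged as artifacts (flags cleared)."""
        keep = ~self.excluded
        rri = self.rri[keep]
        # rebuild beat times so the container invariant holds on the subset
        t0 = self.t[keep][0] if rri.size else 0.0
        t = t0 + np.concatenate([[0.0], np.cumsum(rri[1:]) / 1000.0])
        return RRISeries(t=t, rri=rri, subject_id=self.subject_id)

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.excluded)

    def with_flags(self, excluded: np.ndarray) -> "RRISeries":
        return replace(self, excluded=np.asarray(excluded, dtype=bool).copy())

    @classmethod
    def from_intervals(
        cls, rri_ms: np.ndarray, t0: float = 0.0, subject_id: str = ""
    ) -> "RRISeries":
        """Build a series from intervals alone, deriving beat times."""
        rri = np.asarray(rri_ms, dtype=float)
        t = t0 + np.cumsum(rri) / 1000.0
        return cls(t=t, rri=rri, subject_id=subject_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "rri_ms": self.rri, "excluded": self.excluded.astype(int)}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, subject_id: str = "") -> "RRISeries":
        df = pd.read_csv(path)
        excluded = (
            df["excluded"].to_numpy(dtype=bool)
            if "excluded" in df.columns
            else None
        )
        return cls(
            t=df["t_s"].to_numpy(float),
            rri=df["rri_ms"].to_numpy(float),
            excluded=excluded,
            subject_id=subject_id,
        )


@dataclass
class AccelTrace:
    """Tri-axial acceleration sampled at a fixed rate.

    ``ax``/``ay`` are the horizontal and lateral axes, ``az`` the vertical
    axis, all in m/s². ``fs`` is the sampling rate in Hz.
    """

    fs: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = self.ax.size
        if self.ay.size != n or self.az.size != n:
            raise ValueError("all three axes must have the same length")
        if n == 0:
            raise ValueError("trace must contain at least one sample")

    def __len__(self) -> int:
        return self.ax.size

    @property
    def duration(self) -> float:
        """Exposure time T = n / fs in seconds."""
        return len(self) / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs

    def axis(self, name: str) -> np.ndarray:
        try:
            return {"x": self.ax, "y": self.ay, "z": self.az}[name]
        except KeyError:
            raise ValueError(f"unknown axis {name!r}; expected 'x', 'y' or 'z'")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.time, "ax": self.ax, "ay": self.ay, "az": self.az}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, fs: float | None = None) -> "AccelTrace":
        df = pd.read_csv(path)
        if fs is None:
            dt = np.diff(df["t_s"].to_numpy(float))
            if dt.size == 0 or np.ptp(dt) > 1e-6 * dt.mean():
                raise ValueError("cannot infer a fixed sampling rate from t_s")
            fs = 1.0 / dt.mean()
        return cls(
            fs=float(fs),
            ax=df["ax"].to_numpy(float),
            ay=df["ay"].to_numpy(float),
            az=df["az"].to_numpy(float),
        )
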