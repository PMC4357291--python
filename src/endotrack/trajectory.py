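"""Core trajectory containers, delimited-table I/O, smoothing and lifetimes.

A *trajectory* is the time-ordered record of one fluorescent patch: the
centroid coordinates ``x, y`` (nm), the background-corrected fluorescence
``f`` (arbitrary units) and the time stamps ``t`` (s) on a uniform sampling
grid.  An *average trajectory* carries per-timepoint means and standard
errors over many aligned patches.

Internal units are fixed to nanometres and seconds; file dialects declare
their units and are converted on read.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "Trajectory",
    "AverageTrajectory",
    "CohortConfig",
    "TrajectoryError",
    "read_trajectories",
    "write_trajectories",
    "smooth_trajectory",
    "patch_lifetimes",
]

#: multiplicative factors to nm / s
_LENGTH_UNITS = {"nm": 1.0, "um": 1e3, "µm": 1e3, "micron": 1e3, "m": 1e9}
_TIME_UNITS = {"s": 1.0, "ms": 1e-3, "min": 60.0}

_DT_RTOL = 1e-6  # allowed jitter of the sampling interval, in seconds


class TrajectoryError(ValueError):
    """Raised for malformed trajectory tables or invariant violations."""


def _as_1d(name, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise TrajectoryError(f"{name} must be one-dimensional")
    return arr


@dataclass
class Trajectory:
    """One patch's centroid track.

    Attributes
    ----------
    id : identifier of the event (any hashable label).
    t, x, y, f : equal-length arrays; t strictly increasing on a uniform grid.
    channel : optional acquisition-channel label.
    complete : True when both appearance and disappearance were observed
        (first frame after movie start and last frame before movie end).
    """

    id: object
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    f: np.ndarray
    channel: str | None = None
    complete: bool = True

    def __post_init__(self):
        self.t = _as_1d("t", self.t)
        self.x = _as_1d("x", self.x)
        self.y = _as_1d("y", self.y)
        self.f = _as_1d("f", self.f)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.f) == n):
            raise TrajectoryError(f"trajectory {self.id!r}: t, x, y, f lengths differ")
        if n < 2:
            raise TrajectoryError(f"trajectory {self.id!r}: needs at least 2 points")
        if not np.all(np.isfinite(self.t)):
            raise TrajectoryError(f"trajectory {self.id!r}: non-finite time stamp")
        dts = np.diff(self.t)
        if np.any(dts <= 0):
            raise TrajectoryError(f"trajectory {self.id!r}: time not strictly increasing")
        if np.any(np.abs(dts - dts[0]) > _DT_RTOL):
            raise TrajectoryError(f"trajectory {self.id!r}: non-uniform sampling interval")
        if np.any(self.f < 0):
            raise TrajectoryError(f"trajectory {self.id!r}: negative fluorescence")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array."""
        return np.column_stack([self.x, self.y])

    def replace(self, **kw) -> "Trajectory":
        return dataclasses.replace(self, **kw)

    def peak_index(self) -> int:
        """Index of the fluorescence maximum (first one on ties)."""
        return int(np.argmax(self.f))


@dataclass
class AverageTrajectory:
    """Per-timepoint means and SEMs of a cohort of aligned trajectories.

    ``dx, dy, df`` are standard errors of the means; ``n`` counts the
    trajectories contributing at each time index.  SEMs at indices with a
    single contributor are NaN.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    f: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    df: np.ndarray
    n: np.ndarray = None

    def __post_init__(self):
        self.t = _as_1d("t", self.t)
        for name in ("x", "y", "f", "dx", "dy", "df"):
            setattr(self, name, _as_1d(name, getattr(self, name)))
        if self.n is None:
            self.n = np.ones(len(self.t), dtype=int)
        self.n = np.asarray(self.n, dtype=int)
        for name in ("x", "y", "f", "dx", "dy", "df", "n"):
            if len(getattr(self, name)) != len(self.t):
                raise TrajectoryError(f"average trajectory: {name} length differs from t")
        for name in ("dx", "dy", "df"):
            arr = getattr(self, name)
            if np.any(arr[np.isfinite(arr)] < 0):
                raise TrajectoryError(f"average trajectory: negative {name}")
        if np.any(self.n < 1):
            raise TrajectoryError("average trajectory: n must be >= 1 everywhere")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def replace(self, **kw) -> "AverageTrajectory":
        return dataclasses.replace(self, **kw)

    def peak_index(self) -> int:
        return int(np.argmax(self.f))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "i": np.arange(len(self.t)),
                "t": self.t,
                "Px": self.x,
                "Py": self.y,
                "Pf": self.f,
                "dx": self.dx,
                "dy": self.dy,
                "df": self.df,
                "n": self.n,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AverageTrajectory":
        return cls(
            t=frame["t"].to_numpy(),
            x=frame["Px"].to_numpy(),
            y=frame["Py"].to_numpy(),
            f=frame["Pf"].to_numpy(),
            dx=frame["dx"].to_numpy(),
            dy=frame["dy"].to_numpy(),
            df=frame["df"].to_numpy(),
            n=frame["n"].to_numpy() if "n" in frame else None,
        )


@dataclass
class CohortConfig:
    """Cohort-level processing options.

    smoothing : "savitzky_golay" | "moving_average" | "none"
    window : filter window length in frames (odd and >= 3 for Savitzky-Golay)
    order : Savitzky-Golay polynomial order (must be < window)
    invagination_only : truncate alignment costs at each trajectory's
        fluorescence peak (used for the abundant reference-protein cohorts
        whose post-peak disassembly phase is not stereotyped).
    """

    smoothing: str = "none"
    window: int = 11
    order: int = 3
    invagination_only: bool = False

    def __post_init__(self):
        if self.smoothing not in ("savitzky_golay", "moving_average", "none"):
            raise ValueError(f"unknown smoothing mode {self.smoothing!r}")
        if self.smoothing == "savitzky_golay":
            if self.window < 3 or self.window % 2 == 0:
                raise ValueError("Savitzky-Golay window must be odd and >= 3")
            if self.order >= self.window:
                raise ValueError("polynomial order must be smaller than the window")
        if self.smoothing == "moving_average" and self.window < 1:
            raise ValueError("moving-average window must be >= 1")


# ---------------------------------------------------------------------------
# I/O


def _unit_factors(units: dict | None) -> tuple[float, float]:
    units = units or {}
    length = units.get("length", "nm")
    time = units.get("time", "s")
    try:
        lf = _LENGTH_UNITS[length]
    except KeyError:
        raise TrajectoryError(f"unknown length unit {length!r}") from None
    try:
        tf = _TIME_UNITS[time]
    except KeyError:
        raise TrajectoryError(f"unknown time unit {time!r}") from None
    return lf, tf


def sniff_delimited(path, sep: str | None = None) -> pd.DataFrame:
    """Read a TSV/CSV table with exactly round-tripping float parsing."""
    if sep is None:
        if hasattr(path, "readline"):
            pos = path.tell()
            header = path.readline()
            path.seek(pos)
        else:
            with open(path) as fh:
                header = fh.readline()
        sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_trajectories(
    path,
    sep: str | None = None,
    units: dict | None = None,
    movie_start: float | None = None,
    movie_end: float | None = None,
) -> list[Trajectory]:
    """Read a delimited trajectory table into validated :class:`Trajectory` objects.

    The table needs columns ``id, t, x, y, f`` (an optional ``channel``
    column is carried through).  ``units`` declares the file's units, e.g.
    ``{"length": "um", "time": "s"}``; everything is converted to nm and s.

    ``movie_start`` / ``movie_end`` (in the file's time units) mark the
    recording limits used to flag *complete* trajectories: an event is
    complete when it appears after the first frame and disappears before the
    last one.  When omitted, the cohort's overall time span is used.
    """
    df = sniff_delimited(path, sep)
    required = {"id", "t", "x", "y", "f"}
    missing = required - set(df.columns)
    if missing:
        raise TrajectoryError(f"missing column(s): {sorted(missing)}")
    lf, tf = _unit_factors(units)

    if movie_start is None:
        movie_start = float(df["t"].min())
    if movie_end is None:
        movie_end = float(df["t"].max())

    out: list[Trajectory] = []
    for tid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("t", kind="stable")
        t = grp["t"].to_numpy(dtype=float)
        if len(t) >= 2 and np.any(np.diff(t) <= 0):
            raise TrajectoryError(f"trajectory {tid!r}: duplicated or non-monotone time stamps")
        channel = None
        if "channel" in grp.columns:
            ch = grp["channel"].unique()
            channel = str(ch[0]) if len(ch) == 1 else None
        dt = float(t[1] - t[0]) if len(t) >= 2 else 0.0
        complete = bool(
            t[0] > movie_start + 0.5 * dt and t[-1] < movie_end - 0.5 * dt
        )
        out.append(
            Trajectory(
                id=tid,
                t=t * tf,
                x=grp["x"].to_numpy(dtype=float) * lf,
                y=grp["y"].to_numpy(dtype=float) * lf,
                f=grp["f"].to_numpy(dtype=float),
                channel=channel,
                complete=complete,
            )
        )
    if not out:
        raise TrajectoryError("no trajectories found in table")
    return out


def write_trajectories(trajectories: Iterable[Trajectory], path, sep: str = "\t") -> None:
    """Write trajectories back to a delimited table in nm / s."""
    frames = []
    for traj in trajectories:
        frame = pd.DataFrame({"id": traj.id, "t": traj.t, "x": traj.x, "y": traj.y, "f": traj.f})
        if traj.channel is not None:
            frame["channel"] = traj.channel
        frames.append(frame)
    # default float formatting is the shortest exact repr, so write + read
    # (with round-trip parsing) is bitwise lossless
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Smoothing


def _shrink_window_savgol(v: np.ndarray, window: int, order: int) -> np.ndarray:
    """Savitzky-Golay with the window shrunk symmetrically at the boundaries."""
    n = len(v)
    out = savgol_filter(v, window, order, mode="interp") if n >= window else np.empty(n)
    half = window // 2
    for i in range(n):
        h = min(half, i, n - 1 - i)
        if h >= half and n >= window:
            continue  # interior point already filtered
        w = 2 * h + 1
        k = min(order, w - 1)
        seg = v[i - h : i + h + 1]
        if w == 1:
            out[i] = v[i]
        else:
            coeffs = np.polynomial.polynomial.polyfit(np.arange(-h, h + 1), seg, k)
            out[i] = coeffs[0]  # value of the local polynomial at the centre
    return out


def _shrink_window_mean(v: np.ndarray, window: int) -> np.ndarray:
    n = len(v)
    half = window // 2
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


def smooth_trajectory(traj: Trajectory, cfg: CohortConfig) -> Trajectory:
    """Filter x, y and f independently; time stamps are untouched.

    The edge policy shrinks the window symmetrically at the boundaries, so
    the output length equals the input length and a local polynomial of the
    configured order is preserved everywhere.
    """
    if cfg.smoothing == "none":
        return traj
    if len(traj) < cfg.window:
        raise TrajectoryError(
            f"trajectory {traj.id!r} shorter ({len(traj)}) than the filter window ({cfg.window})"
        )
    if cfg.smoothing == "savitzky_golay":
        smoothed = {k: _shrink_window_savgol(getattr(traj, k), cfg.window, cfg.order) for k in "xyf"}
    else:
        smoothed = {k: _shrink_window_mean(getattr(traj, k), cfg.window) for k in "xyf"}
    smoothed["f"] = np.clip(smoothed["f"], 0.0, None)
    return traj.replace(**smoothed)


# ---------------------------------------------------------------------------
# Lifetimes


def patch_lifetimes(
    cohort: Sequence[Trajectory],
    known_lifetime: float,
    movie_length: int | None = None,
    window_factor: float = 3.0,
) -> list[float]:
    """Lifetimes (last - first time stamp) of complete, early-starting patches.

    Only complete trajectories whose first time point falls within the
    initial window of ``window_factor`` x ``known_lifetime`` seconds from the
    movie start are used; later events are excluded to limit the
    photobleaching contribution.  Because incomplete events truncated by the
    finite movie are discarded, the mean of the returned lifetimes
    underestimates the true mean lifetime.
    """
    if known_lifetime <= 0:
        raise ValueError("known_lifetime must be positive")
    if not cohort:
        return []
    t0 = min(float(tr.t[0]) for tr in cohort)
    window = window_factor * known_lifetime
    if movie_length is not None:
        window = min(window, movie_length * cohort[0].dt)
    out = []
    for tr in cohort:
        if not tr.complete:
            continue
        if float(tr.t[0]) - t0 > window:
            continue
        out.append(float(tr.t[-1] - tr.t[0]))
    return out
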