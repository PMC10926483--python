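"""Trackball tracking-log I/O and stimulus alignment.

Consumes FicTrac-style delimited text logs (one row per video frame), exposes
a validated :class:`Trajectory`, and slices it into per-epoch
:class:`StimulusSegment` objects given a :class:`~optomotor.stimuli.Schedule`
and the trajectory time ``t0`` at which the schedule started.

Angles are radians throughout; leftward (counter-clockwise viewed from above)
yaw is positive.  Degrees appear only at the presentation layer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .stimuli import Epoch, Schedule, StimulusSpec

logger = logging.getLogger(__name__)

__all__ = [
    "Dialect",
    "DIALECTS",
    "Trajectory",
    "StimulusSegment",
    "PartialCoverageWarning",
    "TrackballFormatError",
    "TrajectoryDataError",
    "read_trackball_log",
    "write_trackball_log",
    "align",
    "trajectory_to_frame",
]


class TrackballFormatError(ValueError):
    """A log row does not match the declared dialect."""


class TrajectoryDataError(ValueError):
    """Parsed values violate trajectory invariants (e.g. non-monotone time)."""


class PartialCoverageWarning(UserWarning):
    """The trajectory does not fully cover the schedule."""


@dataclass(frozen=True)
class Dialect:
    """Column layout of one trackball-log flavor (0-based indices)."""

    name: str
    n_columns: int
    delimiter: str
    frame_index: int
    delta_rotation_lab: tuple[int, int, int]
    integrated_heading: int
    movement_speed: int
    timestamp: int
    timestamp_unit: float  # seconds per timestamp unit


# FicTrac v2 .dat: frame counter; camera-frame delta rotation x3; error;
# lab-frame delta rotation x3; camera-frame absolute rotation x3; lab-frame
# absolute rotation x3; integrated x/y position; integrated heading; movement
# direction; movement speed; integrated forward/side displacement; timestamp
# (ms); sequence counter; reserved x2.
FICTRAC_V2 = Dialect(
    name="fictrac-v2",
    n_columns=25,
    delimiter=",",
    frame_index=0,
    delta_rotation_lab=(5, 6, 7),
    integrated_heading=16,
    movement_speed=18,
    timestamp=21,
    timestamp_unit=1e-3,
)

DIALECTS: dict[str, Dialect] = {FICTRAC_V2.name: FICTRAC_V2}


@dataclass
class Trajectory:
    """Per-frame trackball state of one animal.

    Attributes
    ----------
    frame_index : int array
    time : float array
        Seconds; strictly increasing.
    integrated_heading : float array
        Unwrapped fictive yaw (rad), leftward positive.
    rotation_increment : (n, 3) float array or None
        Per-frame lab-frame ball rotation about 3 axes (rad).
    movement_speed : float array
        Per-frame total ball rotation magnitude (rad/frame).
    ball_diameter : float
        cm.
    frame_rate : float
        Nominal Hz.
    """

    frame_index: np.ndarray
    time: np.ndarray
    integrated_heading: np.ndarray
    rotation_increment: np.ndarray | None
    movement_speed: np.ndarray
    ball_diameter: float
    frame_rate: float

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.time = np.asarray(self.time, dtype=float)
        self.integrated_heading = np.asarray(self.integrated_heading, dtype=float)
        self.movement_speed = np.asarray(self.movement_speed, dtype=float)
        n = len(self.time)
        if not (len(self.frame_index) == len(self.integrated_heading) == len(self.movement_speed) == n):
            raise TrajectoryDataError("trajectory channels have unequal lengths")
        if self.rotation_increment is not None:
            self.rotation_increment = np.asarray(self.rotation_increment, dtype=float)
            if self.rotation_increment.shape != (n, 3):
                raise TrajectoryDataError(
                    f"rotation_increment must have shape ({n}, 3), got {self.rotation_increment.shape}"
                )
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise TrajectoryDataError("timestamps are not strictly increasing")
        if not self.ball_diameter > 0:
            raise TrajectoryDataError(f"ball_diameter must be > 0, got {self.ball_diameter}")

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class StimulusSegment:
    """Contiguous trajectory slice covering (part of) one epoch."""

    stimulus: StimulusSpec
    epoch: Epoch
    trajectory: Trajectory
    start: int  # first frame index into trajectory arrays
    stop: int  # one past last frame
    t0: float  # trajectory time at schedule time 0
    full_coverage: bool = True

    @property
    def n_frames(self) -> int:
        return self.stop - self.start

    @property
    def time(self) -> np.ndarray:
        return self.trajectory.time[self.start : self.stop]

    @property
    def heading(self) -> np.ndarray:
        return self.trajectory.integrated_heading[self.start : self.stop]


def _parse_rows(path, dialect: Dialect) -> np.ndarray:
    rows = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split(dialect.delimiter)]
            if len(fields) != dialect.n_columns:
                raise TrackballFormatError(
                    f"{path}: line {lineno}: expected {dialect.n_columns} fields "
                    f"({dialect.name}), got {len(fields)}"
                )
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise TrackballFormatError(f"{path}: line {lineno}: non-numeric field ({exc})") from exc
    return np.asarray(rows, dtype=float)


def read_trackball_log(
    path,
    dialect: str | Dialect = "fictrac-v2",
    ball_diameter: float = 5.0,
    frame_rate: float = 50.0,
) -> Trajectory:
    """Read a trackball log into a validated :class:`Trajectory`.

    The heading channel is unwrapped (no +-pi jumps survive).  If the
    timestamp column is unusable (all zero or constant) timestamps fall back
    to ``frame_index / frame_rate``; the fallback is logged.

    Raises
    ------
    TrackballFormatError
        Wrong column count or non-numeric field (names the line).
    TrajectoryDataError
        Non-monotone timestamps or other invariant violations.
    """
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise ValueError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}") from None
    data = _parse_rows(path, dialect)
    if data.size == 0:
        raise TrackballFormatError(f"{path}: no data rows")

    frame_idx = data[:, dialect.frame_index].astype(np.int64)
    heading = np.unwrap(data[:, dialect.integrated_heading])
    increments = data[:, list(dialect.delta_rotation_lab)]
    speed = data[:, dialect.movement_speed]
    ts = data[:, dialect.timestamp] * dialect.timestamp_unit
    if np.ptp(ts) == 0:
        logger.info("%s: timestamp column unusable; falling back to frame_index / frame_rate", path)
        ts = frame_idx / frame_rate
    return Trajectory(
        frame_index=frame_idx,
        time=ts,
        integrated_heading=heading,
        rotation_increment=increments,
        movement_speed=speed,
        ball_diameter=ball_diameter,
        frame_rate=frame_rate,
    )


def write_trackball_log(traj: Trajectory, path, dialect: str | Dialect = "fictrac-v2") -> None:
    """Write a Trajectory as a trackball log (synthetic writer).

    The heading is stored wrapped to [0, 2*pi) as trackers emit it; reading
    the file back unwraps it, so round-trips preserve heading to numeric
    tolerance.  Columns not represented in :class:`Trajectory` are zero.
    """
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    n = len(traj)
    out = np.zeros((n, dialect.n_columns))
    out[:, dialect.frame_index] = traj.frame_index
    out[:, dialect.integrated_heading] = np.mod(traj.integrated_heading, 2 * np.pi)
    if traj.rotation_increment is not None:
        out[:, list(dialect.delta_rotation_lab)] = traj.rotation_increment
    out[:, dialect.movement_speed] = traj.movement_speed
    out[:, dialect.timestamp] = traj.time / dialect.timestamp_unit
    with open(path, "w") as fh:
        for row in out:
            fh.write(dialect.delimiter.join(f"{v:.9g}" for v in row))
            fh.write("\n")


def align(traj: Trajectory, schedule: Schedule, t0: float) -> list[StimulusSegment]:
    """Slice a trajectory into one segment per schedule epoch.

    ``t0`` is the trajectory time at which schedule time 0 occurred.  Frames
    with ``epoch.onset <= t - t0 < epoch.offset`` belong to the epoch.
    Epochs not fully covered by the trajectory trigger a
    :class:`PartialCoverageWarning`; epochs with no frames at all are dropped
    (also reported in the warning), so truncation is never silent.
    """
    segments: list[StimulusSegment] = []
    missing: list[str] = []
    partial: list[str] = []
    t = traj.time
    dt = 1.0 / traj.frame_rate
    for spec, epoch in schedule.iter_epochs():
        lo = np.searchsorted(t, t0 + epoch.onset, side="left")
        hi = np.searchsorted(t, t0 + epoch.offset, side="left")
        if hi <= lo:
            missing.append(f"{spec.label}@{epoch.onset:g}s")
            continue
        # covered if the last frame reaches within one frame period of the end
        full = t[hi - 1] >= t0 + epoch.offset - 1.5 * dt and t[lo] <= t0 + epoch.onset + 1.5 * dt
        if not full:
            partial.append(f"{spec.label}@{epoch.onset:g}s")
        segments.append(
            StimulusSegment(
                stimulus=spec, epoch=epoch, trajectory=traj, start=int(lo), stop=int(hi), t0=t0, full_coverage=full
            )
        )
    if missing or partial:
        warnings.warn(
            PartialCoverageWarning(
                f"trajectory does not fully cover schedule: {len(missing)} epochs missing"
                f" ({', '.join(missing[:5])}{'...' if len(missing) > 5 else ''}),"
                f" {len(partial)} partially covered"
            )
        )
    return segments


def trajectory_to_frame(traj: Trajectory):
    """Normalized tabular export of a trajectory (pandas DataFrame)."""
    import pandas as pd

    cols = {
        "frame_index": traj.frame_index,
        "time_s": traj.time,
        "integrated_heading_rad": traj.integrated_heading,
        "movement_speed_rad_per_frame": traj.movement_speed,
    }
    if traj.rotation_increment is not None:
        for i, ax in enumerate(("x", "y", "z")):
            cols[f"rotation_increment_{ax}_rad"] = traj.rotation_increment[:, i]
    return pd.DataFrame(cols)
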