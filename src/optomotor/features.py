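"""Behavioral response features of the optomotor trackball assay.

Each stimulus presents alternating leftward/rightward grating epochs.  The
accumulated fictive rotation within each epoch (reset to 0 rad and 0 s at the
direction switch, leftward positive) is one *replicate path*; the default
protocol yields 8 replicates (4 per direction) per animal-stimulus pair.
Five features summarize them:

* ``ymax`` — maximum accumulated rotation of the sign-corrected path,
  averaged per direction and then over both directions (rad).
* ``tortuosity`` — mean R^2 of per-replicate linear regressions of
  accumulated rotation on time; low values flag wavering or slow-switching
  paths.
* ``walking_pace`` — total ball-surface path length over stimulation time
  (cm/s), averaged over the replicates.
* ``abs_turning_velocity`` — |mean of the 8 signed regression slopes|
  (rad/s); symmetric left/right following cancels to 0.
* ``rotation_asymmetry`` (y_sym) — |ymax_r - ymax_l| / max(ymax_r, ymax_l),
  in [0, 1]; 0 = symmetric responses, 1 = fully one-sided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fictrac import StimulusSegment, Trajectory
from .stimuli import Direction, Schedule

logger = logging.getLogger(__name__)

__all__ = [
    "ReplicatePath",
    "ReplicateFit",
    "AsymmetryResult",
    "segment_to_path",
    "fit_replicates",
    "turning_velocity",
    "tortuosity",
    "rotation_asymmetry",
    "walking_pace",
    "extract_features",
    "FEATURE_COLUMNS",
]

#: The five clustered feature columns, in canonical order.
FEATURE_COLUMNS = ("ymax", "tortuosity", "walking_pace", "abs_turning_velocity", "rotation_asymmetry")

_TIE_TOL = 1e-9  # rad; ymax differences below this count as an exact tie


@dataclass(frozen=True)
class ReplicatePath:
    """Accumulated rotation within one epoch, zeroed at epoch onset."""

    t: np.ndarray  # s from epoch onset, t[0] == 0
    y: np.ndarray  # rad, leftward positive, y[0] == 0
    direction: Direction

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if len(self.t) != len(self.y):
            raise ValueError("t and y must have equal length")
        if len(self.t) and (self.t[0] != 0 or self.y[0] != 0):
            raise ValueError("replicate paths must start at t=0, y=0")

    @property
    def sign_corrected(self) -> np.ndarray:
        """Path with rightward responses sign-inverted onto the leftward scale."""
        return self.y * self.direction.sign


@dataclass(frozen=True)
class ReplicateFit:
    """OLS fit of accumulated rotation on time for one replicate."""

    slope: float  # rad/s
    r_squared: float  # in [0, 1]
    direction: Direction
    n_points: int
    valid: bool = True


def segment_to_path(seg: StimulusSegment) -> ReplicatePath:
    """Reset a stimulus segment to the epoch origin.

    ``y`` is integrated heading minus heading at epoch onset (leftward
    positive, signed for both directions); ``t`` is zeroed at the first frame.
    """
    if seg.n_frames == 0:
        raise ValueError("cannot build a replicate path from an empty segment")
    t = seg.time - seg.time[0]
    y = seg.heading - seg.heading[0]
    return ReplicatePath(t=t, y=y, direction=seg.epoch.direction)


def _ols(t: np.ndarray, y: np.ndarray, fit_intercept: bool) -> tuple[float, float]:
    if np.ptp(y) == 0:
        # flat path: slope 0 by construction; R^2 conventionally 0 (no
        # variance for the line to explain)
        return 0.0, 0.0
    if fit_intercept:
        res = sps.linregress(t, y)
        return float(res.slope), float(res.rvalue**2)
    slope = float(np.dot(t, y) / np.dot(t, t))
    resid = y - slope * t
    ss_tot = float(np.dot(y, y))
    r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 0.0
    return slope, max(0.0, r2)


def fit_replicates(paths: list[ReplicatePath], fit_intercept: bool = True) -> list[ReplicateFit]:
    """Ordinary least squares of y on t, one fit per replicate path.

    The regression includes an intercept by default (reaction latency shifts
    the line; R^2 then measures tortuosity rather than origin misfit);
    ``fit_intercept=False`` forces the line through the origin.  Paths with
    fewer than 3 points are flagged invalid and excluded from feature means.
    """
    fits = []
    for path in paths:
        if len(path.t) < 3:
            warnings.warn(f"replicate with {len(path.t)} point(s) excluded from fits")
            fits.append(ReplicateFit(np.nan, np.nan, path.direction, len(path.t), valid=False))
            continue
        slope, r2 = _ols(path.t, path.y, fit_intercept)
        fits.append(ReplicateFit(slope, min(1.0, max(0.0, r2)), path.direction, len(path.t)))
    return fits


def _valid(fits: list[ReplicateFit]) -> list[ReplicateFit]:
    return [f for f in fits if f.valid]


def turning_velocity(fits: list[ReplicateFit]) -> float:
    """|mean of signed slopes| across replicates (rad/s).

    The signed mean is taken first, so perfectly symmetric left/right
    responses cancel to 0, while a consistent turn bias survives.
    Returns NaN when no valid fit exists.
    """
    good = _valid(fits)
    if not good:
        return np.nan
    return abs(float(np.mean([f.slope for f in good])))


def tortuosity(fits: list[ReplicateFit]) -> float:
    """Mean R^2 over valid replicate fits; NaN when none are valid."""
    good = _valid(fits)
    if not good:
        return np.nan
    return float(np.mean([f.r_squared for f in good]))


@dataclass(frozen=True)
class AsymmetryResult:
    ymax_left: float
    ymax_right: float
    ymax: float
    y_sym: float
    bias_direction: Direction | None  # None = no bias (exact tie)
    degenerate: bool = False  # both directions (near-)zero: y_sym defined as 0


def rotation_asymmetry(paths: list[ReplicatePath]) -> AsymmetryResult:
    """Rotation asymmetry y_sym = |ymax_r - ymax_l| / max(ymax_r, ymax_l).

    Rightward paths are sign-inverted onto the leftward scale, the maximum
    accumulated rotation of each replicate is averaged per direction, and the
    ratio is formed from the two direction means.  When both direction means
    are (near-)zero the ratio is 0/0; it is defined as 0 — a symmetrically
    absent response — and flagged ``degenerate``.
    """
    by_dir = {Direction.LEFT: [], Direction.RIGHT: []}
    for path in paths:
        if len(path.t) == 0:
            continue
        by_dir[path.direction].append(float(np.max(path.sign_corrected)))
    if not by_dir[Direction.LEFT] or not by_dir[Direction.RIGHT]:
        raise ValueError("rotation asymmetry requires replicates in both directions")
    ymax_l = float(np.mean(by_dir[Direction.LEFT]))
    ymax_r = float(np.mean(by_dir[Direction.RIGHT]))
    ymax = 0.5 * (ymax_l + ymax_r)
    denom = max(ymax_r, ymax_l)
    if denom <= _TIE_TOL:
        y_sym, degenerate = 0.0, True
    else:
        y_sym = min(1.0, max(0.0, abs(ymax_r - ymax_l) / denom))
        degenerate = False
    if abs(ymax_r - ymax_l) <= _TIE_TOL:
        bias = None
    else:
        bias = Direction.RIGHT if ymax_r > ymax_l else Direction.LEFT
    return AsymmetryResult(ymax_l, ymax_r, ymax, y_sym, bias, degenerate)


def walking_pace(segments: list[StimulusSegment], ball_diameter: float | None = None) -> float:
    """Mean walking pace (cm/s) over the stimulus presentations.

    Per segment, path length is the summed per-frame total rotation magnitude
    (norm of the 3-axis lab-frame rotation increment) times the ball radius;
    pace is path length over the segment's stimulated time.  When the 3-axis
    increments are absent the tracker's movement-speed column is used instead
    (logged).
    """
    if not segments:
        raise ValueError("walking pace requires at least one segment")
    diameter = ball_diameter if ball_diameter is not None else segments[0].trajectory.ball_diameter
    if not diameter > 0:
        raise ValueError(f"ball diameter must be > 0, got {diameter}")
    radius = diameter / 2.0
    paces = []
    for seg in segments:
        traj = seg.trajectory
        if traj.rotation_increment is not None:
            mags = np.linalg.norm(traj.rotation_increment[seg.start : seg.stop], axis=1)
        else:
            logger.info("rotation increments missing; walking pace falls back to movement_speed")
            mags = traj.movement_speed[seg.start : seg.stop]
        duration = seg.n_frames / traj.frame_rate
        paces.append(float(np.sum(mags)) * radius / duration)
    return float(np.mean(paces))


def extract_features(
    traj: Trajectory,
    schedule: Schedule,
    t0: float,
    animal_id: str = "",
    fit_intercept: bool = True,
) -> pd.DataFrame:
    """Per-stimulus behavioral response features for one animal.

    Returns a long-format DataFrame with one row per stimulus: the five
    features plus per-direction maxima, bias direction and QC flags
    (``full_coverage``, ``low_confidence`` when fewer than 2 valid replicates
    per direction survive, ``degenerate_asymmetry``).
    """
    from .fictrac import align

    segments = align(traj, schedule, t0)
    by_stim: dict[str, list[StimulusSegment]] = {}
    specs = {}
    for seg in segments:
        by_stim.setdefault(seg.stimulus.label, []).append(seg)
        specs[seg.stimulus.label] = seg.stimulus

    rows = []
    for label, segs in by_stim.items():
        spec = specs[label]
        paths = [segment_to_path(s) for s in segs if s.n_frames > 0]
        fits = fit_replicates(paths, fit_intercept=fit_intercept)
        asym = rotation_asymmetry(paths)
        n_valid = {d: sum(1 for f in fits if f.valid and f.direction is d) for d in Direction}
        rows.append(
            {
                "animal_id": animal_id,
                "stimulus_label": label,
                "spatial_frequency": spec.spatial_frequency,
                "temporal_frequency": spec.temporal_frequency,
                "ymax": asym.ymax,
                "tortuosity": tortuosity(fits),
                "walking_pace": walking_pace(segs),
                "abs_turning_velocity": turning_velocity(fits),
                "rotation_asymmetry": asym.y_sym,
                "ymax_left": asym.ymax_left,
                "ymax_right": asym.ymax_right,
                "bias_direction": asym.bias_direction.name if asym.bias_direction else "NONE",
                "n_replicates": len(paths),
                "full_coverage": all(s.full_coverage for s in segs)
                and len(segs) == schedule.epochs_per_stimulus,
                "low_confidence": min(n_valid.values()) < 2,
                "degenerate_asymmetry": asym.degenerate,
            }
        )
    return pd.DataFrame(rows)
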