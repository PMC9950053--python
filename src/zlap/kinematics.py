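"""Per-frame kinematics: from three-point poses to the 33-column feature stream.

Each frame of each well yields one record combining identity (plate, well,
frame, period, stimulus), the raw pose, and derived quantities:

* validity — a frame is usable only when all three body-part likelihoods are
  at least 0.5 (predictions below that are unreliable and are excluded);
* displacement of the yolk between consecutive valid frames (px per 6-s
  interval, also reported as speed);
* movement classes — moved (> 3 px), scoot (3-20 px), burst (> 20 px);
* location — upper-half flag, radial distance from the well center, edge
  flag (outer 50 % of the radius, i.e. thigmotaxis);
* orientation — body-axis angle of the yolk-to-eye-midpoint heading in
  well-centric y-up coordinates, clockwise/upward flags, and the signed and
  absolute turn between consecutive frames.

Derived fields are null (NaN / missing) on invalid frames, and
displacement-derived fields additionally when the prior frame is invalid.
All angular quantities live in degrees on (-180, 180].
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, SchemaError
from .pose_io import (FRAME_INTERVAL_S, FRAMES_PER_PERIOD, POSE_COLUMNS,
                      PoseFrame, StimulusSchedule)
from .well_grid import WellCircle

# a priori thresholds of the assay
VALIDITY_THRESHOLD = 0.5     # minimum body-part likelihood
MOVE_THRESHOLD_PX = 3.0      # moved iff displacement > 3 px per 6 s
BURST_THRESHOLD_PX = 20.0    # scoot (3, 20], burst (20, inf)
EDGE_FRACTION = 0.5          # edge iff radial distance > 0.5 * well radius
OMR_MIN_MOVE_FRACTION = 0.05  # period-level movement needed for OMR eligibility
CLOCKWISE_MIN_RADIUS_PX = 5.0  # tangent undefined near the well center

#: canonical 33-column order of the per-frame feature table
FEATURE_COLUMNS = [
    "plate_id", "well_id", "row", "col", "frame", "time_s", "period", "stimulus",
    "x_yolk", "y_yolk", "p_yolk", "x_left", "y_left", "p_left",
    "x_right", "y_right", "p_right",
    "valid", "displacement", "moved", "speed", "scoot", "burst",
    "up", "burst_up", "radial_dist", "edge",
    "angle", "clockwise", "upward", "turn", "turn_abs", "omr_eligible",
]

#: 0/1 columns stored as nullable integers in the table
FLAG_COLUMNS = ["valid", "moved", "scoot", "burst", "up", "burst_up", "edge",
                "clockwise", "upward", "omr_eligible"]


# ---------------------------------------------------------------------------
# per-frame scalar operations (reference semantics; the table builder is the
# vectorized equivalent)
# ---------------------------------------------------------------------------

def frame_validity(pose: PoseFrame, threshold: float = VALIDITY_THRESHOLD) -> bool:
    """A frame is valid iff every body-part likelihood reaches ``threshold``."""
    return min(pose.p_yolk, pose.p_left, pose.p_right) >= threshold


def displacement_series(
    yolk_positions: Sequence[tuple[float, float]],
    validity: Sequence[bool],
) -> list[float | None]:
    """Euclidean yolk displacement per step; None unless both frames are valid."""
    out: list[float | None] = [None]
    for t in range(1, len(yolk_positions)):
        if validity[t] and validity[t - 1]:
            (x0, y0), (x1, y1) = yolk_positions[t - 1], yolk_positions[t]
            out.append(math.hypot(x1 - x0, y1 - y0))
        else:
            out.append(None)
    return out


def classify_step(displacement: float | None) -> str | None:
    """Movement class from one 6-s displacement: none, scoot (3, 20], burst (20, inf)."""
    if displacement is None:
        return None
    if displacement > BURST_THRESHOLD_PX:
        return "burst"
    if displacement > MOVE_THRESHOLD_PX:
        return "scoot"
    return "none"


def spatial_flags(yolk: tuple[float, float], well: WellCircle) -> tuple[bool, float, bool]:
    """(upper-half flag, radial distance, edge flag) in well-centric y-up coordinates.

    The horizontal midline counts as the lower half (strict inequality).
    """
    x = yolk[0] - well.cx
    y = well.cy - yolk[1]  # image y-down -> well-centric y-up
    radial = math.hypot(x, y)
    return y > 0, radial, radial > EDGE_FRACTION * well.radius


def body_axis_angle(pose: PoseFrame) -> float | None:
    """Body-axis heading angle in degrees on (-180, 180].

    The heading points from the yolk to the eye midpoint (the eyes sit
    rostral to the yolk, so this approximates the facing direction), measured
    against the horizontal well axis in y-up coordinates.  None when the eye
    midpoint coincides with the yolk.
    """
    mx = 0.5 * (pose.x_left + pose.x_right)
    my = 0.5 * (pose.y_left + pose.y_right)
    hx = mx - pose.x_yolk
    hy = pose.y_yolk - my  # y-up
    if hx == 0 and hy == 0:
        return None
    angle = math.degrees(math.atan2(hy, hx))
    return 180.0 if angle == -180.0 else angle


def orientation_flags(pose: PoseFrame, well: WellCircle) -> tuple[bool | None, bool]:
    """(clockwise, upward) orientation flags.

    upward: the heading has a positive y-up component (angle in (0, 180)).
    clockwise: the heading has a clockwise tangential component with respect
    to circulation around the well center, i.e. cross(r, h) < 0 with
    r = yolk - center in y-up coordinates; None within 5 px of the center
    where the tangent direction is undefined.
    """
    mx = 0.5 * (pose.x_left + pose.x_right)
    my = 0.5 * (pose.y_left + pose.y_right)
    hx = mx - pose.x_yolk
    hy = pose.y_yolk - my
    upward = hy > 0
    rx = pose.x_yolk - well.cx
    ry = well.cy - pose.y_yolk
    if math.hypot(rx, ry) < CLOCKWISE_MIN_RADIUS_PX:
        return None, upward
    return (rx * hy - ry * hx) < 0, upward


def wrap_angle(delta: float) -> float:
    """Wrap an angle difference into (-180, 180]."""
    wrapped = (delta + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


def turn_series(angles: Sequence[float | None]) -> list[tuple[float, float] | None]:
    """Signed turn (shortest wrap of the angle change) and its absolute value."""
    out: list[tuple[float, float] | None] = [None]
    for t in range(1, len(angles)):
        if angles[t] is None or angles[t - 1] is None:
            out.append(None)
        else:
            turn = wrap_angle(angles[t] - angles[t - 1])
            out.append((turn, abs(turn)))
    return out


# ---------------------------------------------------------------------------
# vectorized feature computation
# ---------------------------------------------------------------------------

def _wrap_array(delta: np.ndarray) -> np.ndarray:
    wrapped = (delta + 180.0) % 360.0 - 180.0
    return np.where(wrapped == -180.0, 180.0, wrapped)


def compute_feature_arrays(
    pose: Mapping[str, np.ndarray],
    wells: Sequence[WellCircle],
    *,
    validity_threshold: float = VALIDITY_THRESHOLD,
) -> dict[str, np.ndarray]:
    """Derive all per-frame quantities for a stack of wells at once.

    ``pose`` maps the nine coordinate/likelihood names (``x_yolk`` ...
    ``p_right``) to arrays of shape (n_wells, n_frames) aligned with
    ``wells``.  Returns float arrays of the same shape for every derived
    column; flags are 0/1 with NaN where undefined.
    """
    x = np.asarray(pose["x_yolk"], dtype=float)
    if x.ndim != 2:
        raise InputError("pose arrays must be 2-D (wells x frames)")
    n_wells, n_frames = x.shape
    if len(wells) != n_wells:
        raise InputError(f"{n_wells} pose streams for {len(wells)} wells")
    arr = {k: np.asarray(pose[k], dtype=float) for k in POSE_COLUMNS[1:]}
    if any(a.shape != x.shape for a in arr.values()):
        raise InputError("pose arrays have mismatched shapes")

    cx = np.array([w.cx for w in wells])[:, None]
    cy = np.array([w.cy for w in wells])[:, None]
    radius = np.array([w.radius for w in wells])[:, None]

    valid = (
        np.fmin(np.fmin(arr["p_yolk"], arr["p_left"]), arr["p_right"])
        >= validity_threshold
    ).astype(float)
    nan = np.full((n_wells, n_frames), np.nan)

    def masked(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
        return np.where(mask, values, np.nan)

    vmask = valid == 1

    # displacement between consecutive valid frames
    dx = np.diff(arr["x_yolk"], axis=1)
    dy = np.diff(arr["y_yolk"], axis=1)
    step = np.hypot(dx, dy)
    pair_ok = vmask[:, 1:] & vmask[:, :-1]
    displacement = nan.copy()
    displacement[:, 1:] = np.where(pair_ok, step, np.nan)

    with np.errstate(invalid="ignore"):
        moved = np.where(np.isnan(displacement), np.nan,
                         (displacement > MOVE_THRESHOLD_PX).astype(float))
        scoot = np.where(np.isnan(displacement), np.nan,
                         ((displacement > MOVE_THRESHOLD_PX)
                          & (displacement <= BURST_THRESHOLD_PX)).astype(float))
        burst = np.where(np.isnan(displacement), np.nan,
                         (displacement > BURST_THRESHOLD_PX).astype(float))

    # well-centric y-up location
    xc = arr["x_yolk"] - cx
    yc = cy - arr["y_yolk"]
    radial = masked(np.hypot(xc, yc), vmask)
    with np.errstate(invalid="ignore"):
        up = np.where(np.isnan(radial), np.nan, (yc > 0).astype(float))
        edge = np.where(np.isnan(radial), np.nan,
                        (radial > EDGE_FRACTION * radius).astype(float))
    burst_up = np.where(np.isnan(burst) | np.isnan(up), np.nan, burst * up)

    # heading: yolk -> eye midpoint, y-up
    hx = 0.5 * (arr["x_left"] + arr["x_right"]) - arr["x_yolk"]
    hy = arr["y_yolk"] - 0.5 * (arr["y_left"] + arr["y_right"])
    degenerate = (hx == 0) & (hy == 0)
    with np.errstate(invalid="ignore"):
        angle = np.degrees(np.arctan2(hy, hx))
    angle = np.where(angle == -180.0, 180.0, angle)
    angle = masked(angle, vmask & ~degenerate)
    amask = ~np.isnan(angle)

    with np.errstate(invalid="ignore"):
        upward = np.where(amask, (hy > 0).astype(float), np.nan)
        cross = xc * hy - yc * hx
        clockwise = np.where(amask & (np.hypot(xc, yc) >= CLOCKWISE_MIN_RADIUS_PX),
                             (cross < 0).astype(float), np.nan)

    turn = nan.copy()
    turn[:, 1:] = np.where(amask[:, 1:] & amask[:, :-1],
                           _wrap_array(np.diff(angle, axis=1)), np.nan)
    turn_abs = np.abs(turn)

    # period-level OMR eligibility: movement fraction >= 5 % of valid frames
    frames = np.arange(n_frames)
    period = frames // FRAMES_PER_PERIOD + 1
    omr_eligible = nan.copy()
    for p in np.unique(period):
        cols = period == p
        n_valid = valid[:, cols].sum(axis=1)
        n_moved = np.nansum(moved[:, cols] == 1, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(n_valid > 0, n_moved / n_valid, np.nan)
        flag = np.where(np.isnan(frac), np.nan,
                        (frac >= OMR_MIN_MOVE_FRACTION).astype(float))
        omr_eligible[:, cols] = np.where(vmask[:, cols], flag[:, None], np.nan)

    return {
        "frame": np.broadcast_to(frames, x.shape).astype(float),
        "time_s": np.broadcast_to(frames * FRAME_INTERVAL_S, x.shape),
        "period": np.broadcast_to(period, x.shape).astype(float),
        **arr,
        "valid": valid,
        "displacement": displacement,
        "moved": moved,
        "speed": displacement,
        "scoot": scoot,
        "burst": burst,
        "up": up,
        "burst_up": burst_up,
        "radial_dist": radial,
        "edge": edge,
        "angle": angle,
        "clockwise": clockwise,
        "upward": upward,
        "turn": turn,
        "turn_abs": turn_abs,
        "omr_eligible": omr_eligible,
    }


def build_feature_table(
    poses: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
    wells: Sequence[WellCircle],
    schedule: StimulusSchedule,
    plate_id: str = "plate",
) -> pd.DataFrame:
    """Assemble the canonical 33-column feature table for one plate.

    ``poses`` holds one canonical pose table per well (dict keyed by well_id,
    or a sequence aligned with ``wells``); all streams must have equal length.
    Output has one row per (well, frame) in well-major order.
    """
    if isinstance(poses, Mapping):
        try:
            streams = [poses[w.well_id] for w in wells]
        except KeyError as exc:
            raise InputError(f"no pose stream for well {exc}") from exc
    else:
        streams = list(poses)
        if len(streams) != len(wells):
            raise InputError(f"{len(streams)} pose streams for {len(wells)} wells")
    if not wells:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    lengths = {len(s) for s in streams}
    if len(lengths) != 1:
        raise InputError(f"pose streams have unequal lengths: {sorted(lengths)}")
    for s in streams:
        if list(s.columns) != POSE_COLUMNS:
            raise SchemaError("pose streams must be canonical flat tables")

    n_frames = lengths.pop()
    pose_arrays = {
        key: np.stack([s[key].to_numpy(float) for s in streams])
        for key in POSE_COLUMNS[1:]
    }
    feats = compute_feature_arrays(pose_arrays, wells)
    return feature_arrays_to_table(feats, wells, schedule, plate_id, n_frames)


def feature_arrays_to_table(
    feats: Mapping[str, np.ndarray],
    wells: Sequence[WellCircle],
    schedule: StimulusSchedule,
    plate_id: str,
    n_frames: int,
) -> pd.DataFrame:
    """Flatten per-well feature arrays into the canonical 33-column DataFrame."""
    n_wells = len(wells)
    frames = np.arange(n_frames)
    period = frames // FRAMES_PER_PERIOD + 1
    stim = np.array(
        [schedule.stimulus(int(p)).label() if int(p) in schedule.periods else "none"
         for p in period]
    )
    df = pd.DataFrame({
        "plate_id": np.repeat(plate_id, n_wells * n_frames),
        "well_id": np.repeat([w.well_id for w in wells], n_frames),
        "row": np.repeat([w.row if w.row is not None else -1 for w in wells], n_frames),
        "col": np.repeat([w.col if w.col is not None else -1 for w in wells], n_frames),
        "frame": np.tile(frames, n_wells),
        "time_s": np.tile(frames * FRAME_INTERVAL_S, n_wells),
        "period": np.tile(period, n_wells),
        "stimulus": np.tile(stim, n_wells),
    })
    for col in FEATURE_COLUMNS[8:]:
        df[col] = np.asarray(feats[col]).reshape(-1)
    for col in FLAG_COLUMNS:
        df[col] = df[col].round().astype("Int64")
    return df[FEATURE_COLUMNS]
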