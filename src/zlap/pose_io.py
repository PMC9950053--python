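"""Reading and writing the pipeline's tabular formats.

Three body parts are tracked per larva: left eye, right eye, and yolk, each
with an x/y position and a detection likelihood in [0, 1].  Pose tables come
in two CSV dialects:

* flat — one header row: ``frame,x_yolk,y_yolk,p_yolk,x_left,y_left,p_left,
  x_right,y_right,p_right``;
* nested — the three-row scorer/bodyparts/coords header emitted by
  DeepLabCut-style pose estimators, with the frame index in the first column.

Both parse to the identical canonical flat frame-indexed table.  Frames absent
from the file are materialized with all likelihoods 0 so that downstream
validity filtering handles them uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InputError, SchemaError

BODY_PARTS = ("yolk", "left", "right")

#: canonical flat pose-table column order
POSE_COLUMNS = [
    "frame",
    "x_yolk", "y_yolk", "p_yolk",
    "x_left", "y_left", "p_left",
    "x_right", "y_right", "p_right",
]

_BODYPART_ALIASES = {
    "yolk": "yolk",
    "left": "left", "left_eye": "left", "lefteye": "left", "eye_left": "left",
    "right": "right", "right_eye": "right", "righteye": "right", "eye_right": "right",
}

N_PERIODS = 18
FRAMES_PER_PERIOD = 100  # 600 s per period / 6 s per frame
FRAME_INTERVAL_S = 6.0


@dataclass(frozen=True)
class PoseFrame:
    """One frame's three body-part coordinates and likelihoods for one well."""

    frame: int
    x_yolk: float
    y_yolk: float
    p_yolk: float
    x_left: float
    y_left: float
    p_left: float
    x_right: float
    y_right: float
    p_right: float


# ---------------------------------------------------------------------------
# pose tables
# ---------------------------------------------------------------------------

def read_pose_table(path: str | Path) -> pd.DataFrame:
    """Read a pose table (either dialect) into the canonical flat frame table.

    Returns a DataFrame with :data:`POSE_COLUMNS`, frames ascending and
    contiguous from 0; missing frames carry NaN coordinates and likelihood 0.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"pose table not found: {path}")
    with open(path) as fh:
        first = fh.readline().strip().split(",")
    if first and first[0].lower() in {"scorer", "bodyparts"}:
        df = _read_nested(path)
    else:
        df = _read_flat(path)
    return _canonicalize(df)


def _read_flat(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"pose table {path} missing columns {missing}")
    return df[POSE_COLUMNS].copy()


def _read_nested(path: Path) -> pd.DataFrame:
    raw = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    cols = {}
    for scorer, bodypart, coord in raw.columns:
        part = _BODYPART_ALIASES.get(str(bodypart).strip().lower())
        if part is None:
            raise SchemaError(f"unknown body part {bodypart!r} in {path}")
        coord = str(coord).strip().lower()
        if coord in {"x", "y"}:
            cols[f"{coord}_{part}"] = raw[(scorer, bodypart, coord)].to_numpy(float)
        elif coord == "likelihood":
            cols[f"p_{part}"] = raw[(scorer, bodypart, coord)].to_numpy(float)
        else:
            raise SchemaError(f"unknown coordinate field {coord!r} in {path}")
    df = pd.DataFrame(cols)
    df.insert(0, "frame", raw.index.to_numpy(int))
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"pose table {path} missing fields {missing}")
    return df[POSE_COLUMNS]


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    frames = df["frame"].to_numpy()
    if len(frames) == 0:
        return df.astype(float).astype({"frame": int})
    if (np.diff(frames) <= 0).any():
        raise InputError("pose table frame index is not strictly increasing")
    bad = (df[[f"p_{p}" for p in BODY_PARTS]] < 0).any().any() or (
        df[[f"p_{p}" for p in BODY_PARTS]] > 1
    ).any().any()
    if bad:
        raise SchemaError("likelihoods must lie in [0, 1]")
    full = pd.DataFrame({"frame": np.arange(int(frames.max()) + 1)})
    out = full.merge(df, on="frame", how="left")
    for p in BODY_PARTS:
        out[f"p_{p}"] = out[f"p_{p}"].fillna(0.0)
    return out.astype({c: float for c in POSE_COLUMNS[1:]}).astype({"frame": int})


def write_pose_table(df: pd.DataFrame, path: str | Path, dialect: str = "flat",
                     scorer: str = "zlap") -> None:
    """Write a canonical pose table in either CSV dialect."""
    if list(df.columns) != POSE_COLUMNS:
        raise SchemaError("pose table must have the canonical flat columns")
    if dialect == "flat":
        df.to_csv(path, index=False, float_format="%.4f")
    elif dialect == "nested":
        parts = {"yolk": "yolk", "left": "left_eye", "right": "right_eye"}
        data = {}
        for part, name in parts.items():
            data[(scorer, name, "x")] = df[f"x_{part}"]
            data[(scorer, name, "y")] = df[f"y_{part}"]
            data[(scorer, name, "likelihood")] = df[f"p_{part}"]
        nested = pd.DataFrame(data)
        nested.columns.names = ["scorer", "bodyparts", "coords"]
        nested.index = df["frame"].to_numpy(int)
        nested.to_csv(path, float_format="%.4f", index_label=None)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def pose_frames(df: pd.DataFrame) -> Iterable[PoseFrame]:
    """Iterate a canonical pose table as :class:`PoseFrame` records."""
    for rec in df.itertuples(index=False):
        yield PoseFrame(int(rec.frame), rec.x_yolk, rec.y_yolk, rec.p_yolk,
                        rec.x_left, rec.y_left, rec.p_left,
                        rec.x_right, rec.y_right, rec.p_right)


# ---------------------------------------------------------------------------
# stimulus schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stimulus:
    """Stimulus bound to one 10-minute period."""

    kind: str  # blank | lines | sound | none
    color: str | None = None       # lines: red | green | blue
    speed: str | None = None       # lines: slow | fast
    direction: str | None = None   # lines: up | down
    interval_s: float | None = None  # sound: pulse interval

    def label(self) -> str:
        if self.kind == "lines":
            return f"lines_{self.color}_{self.speed}_{self.direction}"
        if self.kind == "sound":
            return f"sound_{self.interval_s:g}s"
        return self.kind


@dataclass(frozen=True)
class StimulusSchedule:
    """Mapping of the eighteen 10-minute periods to stimuli.

    The standard 3-h protocol: periods 1-6 blank acclimatization, 7-14 moving
    lines in four color/speed blocks (red, green, blue, fast red) each shown
    as a direction-contrasted down/up pair, 15 stimulus-free, 16 sound pulses
    at 20-s intervals, 17 sound pulses at 1-s intervals, 18 post-stimulus.
    """

    periods: Mapping[int, Stimulus]

    def __post_init__(self) -> None:
        missing = [p for p in range(1, N_PERIODS + 1) if p not in self.periods]
        if missing or len(self.periods) != N_PERIODS:
            raise ConfigError(
                f"schedule must assign exactly periods 1..{N_PERIODS}; missing {missing}, "
                f"got {sorted(self.periods)}"
            )
        for a, b, _ in self.line_pairs():
            if {self.periods[a].direction, self.periods[b].direction} != {"down", "up"}:
                raise ConfigError(f"line periods {a},{b} are not a down/up pair")

    def stimulus(self, period: int) -> Stimulus:
        return self.periods[period]

    def line_pairs(self) -> list[tuple[int, int, str]]:
        """Direction-contrasted consecutive line-period pairs.

        Returns ``(first_period, second_period, name)`` triples in period
        order; the optomotor measures subtract the first of each pair from the
        second.  Names: R, G, B plus an F prefix for fast blocks (FR...).
        """
        pairs = []
        p = 1
        while p < N_PERIODS:
            a, b = self.periods.get(p), self.periods.get(p + 1)
            if (a is not None and b is not None and a.kind == "lines" and b.kind == "lines"
                    and a.color == b.color and a.speed == b.speed
                    and a.direction != b.direction):
                name = a.color[0].upper()
                if a.speed == "fast":
                    name = "F" + name
                pairs.append((p, p + 1, name))
                p += 2
            else:
                p += 1
        return pairs


def default_schedule() -> StimulusSchedule:
    """The standard 3-h visual + acoustic stimulus timeline."""
    periods: dict[int, Stimulus] = {p: Stimulus("blank") for p in range(1, 7)}
    blocks = [("red", "slow"), ("green", "slow"), ("blue", "slow"), ("red", "fast")]
    p = 7
    for color, speed in blocks:
        periods[p] = Stimulus("lines", color=color, speed=speed, direction="down")
        periods[p + 1] = Stimulus("lines", color=color, speed=speed, direction="up")
        p += 2
    periods[15] = Stimulus("none")
    periods[16] = Stimulus("sound", interval_s=20.0)
    periods[17] = Stimulus("sound", interval_s=1.0)
    periods[18] = Stimulus("none")
    return StimulusSchedule(periods)


def read_stimulus_schedule(path: str | Path | None = None) -> StimulusSchedule:
    """Read a YAML stimulus schedule; the default timeline when ``path`` is None.

    YAML layout::

        periods:
          1: blank
          7: {lines: {color: red, speed: slow, direction: down}}
          16: {sound: {interval_s: 20}}
          15: none
    """
    if path is None:
        return default_schedule()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "periods" not in raw:
        raise ConfigError("schedule config must contain a 'periods' mapping")
    periods: dict[int, Stimulus] = {}
    for key, val in raw["periods"].items():
        period = int(key)
        if isinstance(val, str):
            if val not in {"blank", "none"}:
                raise ConfigError(f"period {period}: unknown stimulus {val!r}")
            periods[period] = Stimulus(val)
        elif isinstance(val, dict) and "lines" in val:
            spec = val["lines"]
            periods[period] = Stimulus("lines", color=spec.get("color"),
                                       speed=spec.get("speed", "slow"),
                                       direction=spec.get("direction"))
        elif isinstance(val, dict) and "sound" in val:
            periods[period] = Stimulus("sound", interval_s=float(val["sound"]["interval_s"]))
        else:
            raise ConfigError(f"period {period}: cannot parse stimulus {val!r}")
    return StimulusSchedule(periods)


# ---------------------------------------------------------------------------
# treatment map
# ---------------------------------------------------------------------------

def read_treatment_map(path: str | Path) -> pd.DataFrame:
    """Read the plate-layout CSV: plate_id, well_id, treatment, concentration_uM."""
    df = pd.read_csv(path)
    required = ["plate_id", "well_id", "treatment"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"treatment map missing columns {missing}")
    if "concentration_uM" not in df.columns:
        df["concentration_uM"] = np.nan
    return df[required + ["concentration_uM"]].copy()


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

def write_feature_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write the 33-column per-frame feature table CSV.

    Flag columns are nullable integers (empty cells where undefined);
    continuous columns are printed at 4 decimal places, which is below the
    few-pixel accuracy of the pose layer.
    """
    from .kinematics import FEATURE_COLUMNS

    if list(rows.columns) != FEATURE_COLUMNS:
        raise SchemaError(
            f"feature table must have the canonical {len(FEATURE_COLUMNS)} columns; "
            f"got {list(rows.columns)}"
        )
    rows.to_csv(path, index=False, float_format="%.4f")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table CSV back with the canonical dtypes."""
    from .kinematics import FEATURE_COLUMNS, FLAG_COLUMNS

    df = pd.read_csv(path)
    if list(df.columns) != FEATURE_COLUMNS:
        raise SchemaError("not a canonical feature table")
    for col in FLAG_COLUMNS:
        df[col] = df[col].astype("Int64")
    return df
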