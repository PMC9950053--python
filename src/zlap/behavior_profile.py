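"""Aggregation of per-frame features into 25 behavioral parameters per larva.

The 3-h recording splits into eighteen 10-minute periods (100 frames each at
6 s/frame).  The parameters, named as in the screening literature:

========  ==================================================================
1h        % of valid frames moved, periods 1-6 (baseline activity)
P15       % moved during the stimulus-free period 15
Hab       habituation: % moved first 5 min of period 17 minus last 5 min
St        startle: % moved period 16 minus period 15
Ex        excitability: % moved period 17 minus period 16
R/G/B/FR  optomotor response per line block: % time in the upper well half,
          second (up-moving) period minus first (down-moving) period
RGB       mean of the four per-block OMR differences
Sc-*      % scoot frames (displacement 3-20 px); -1h = periods 1-6,
          -V = line periods 7-14
Bu-*      % burst frames (> 20 px)
Ed-*      % frames at the well edge (outer 50 % of the radius)
Cw-*      % frames in clockwise orientation
Or-*      orientation response per block: % frames facing up, second period
          minus first; Or-RGB the mean over blocks
Turn-1h   mean signed turn angle, periods 1-6 (degrees)
Tabs-1h   mean absolute turn angle, periods 1-6 (degrees)
========  ==================================================================

Exclusion rules (set a priori): larvae moving < 1 % of valid frames over the
whole recording are excluded outright; a line period contributes to OMR and
orientation measures only if the larva moved >= 5 % of its valid frames in
that period.

Percent measures use valid frames as denominator; an "absolute edge" variant
over all frames is emitted alongside (Ed-1h-abs, Ed-V-abs).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, SchemaError
from .kinematics import FRAMES_PER_PERIOD, OMR_MIN_MOVE_FRACTION
from .pose_io import StimulusSchedule, default_schedule

#: the 25 behavioral parameters, canonical order
PARAMETERS = [
    "1h", "P15", "Hab", "St", "Ex",
    "R", "G", "B", "FR", "RGB",
    "Sc-1h", "Sc-V", "Bu-1h", "Bu-V",
    "Ed-1h", "Ed-V", "Cw-1h", "Cw-V",
    "Or-R", "Or-G", "Or-B", "Or-FR", "Or-RGB",
    "Turn-1h", "Tabs-1h",
]

BASELINE_PERIODS = tuple(range(1, 7))   # first hour, pre-stimulus
VISION_PERIODS = tuple(range(7, 15))    # moving-line periods
EXCLUSION_MOVE_FRACTION = 0.01          # whole-recording minimum movement

_FLAG_OF_MEASURE = {"1h": "moved", "P15": "moved", "Sc": "scoot", "Bu": "burst",
                    "Ed": "edge", "Cw": "clockwise"}


def _to_arrays(rows: pd.DataFrame) -> dict[str, np.ndarray]:
    """View one larva's feature rows as (1, n_frames) float arrays."""
    needed = ["period", "valid", "moved", "scoot", "burst", "up", "edge",
              "clockwise", "upward", "turn", "turn_abs"]
    missing = [c for c in needed if c not in rows.columns]
    if missing:
        raise SchemaError(f"feature rows missing columns {missing}")
    return {c: rows[c].to_numpy(dtype=float, na_value=np.nan)[None, :] for c in needed}


def _pct(flag: np.ndarray, valid: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """100 x count(flag == 1) / count(valid) over the masked frames; NaN if no valid."""
    num = (flag[:, mask] == 1).sum(axis=1)
    den = (valid[:, mask] == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, 100.0 * num / den, np.nan)


def percent_measure(rows: pd.DataFrame, flag: str, periods: Iterable[int]) -> float:
    """Percent of valid frames in ``periods`` on which ``flag`` is set, for one larva."""
    if flag not in rows.columns:
        raise SchemaError(f"unknown flag column {flag!r}")
    arr = rows[flag].to_numpy(dtype=float, na_value=np.nan)
    valid = rows["valid"].to_numpy(dtype=float, na_value=np.nan)
    mask = rows["period"].isin(list(periods)).to_numpy()
    return float(_pct(arr[None, :], valid[None, :], mask)[0])


def _pair_measures(
    flag: np.ndarray, valid: np.ndarray, period: np.ndarray,
    move_frac: np.ndarray, pairs: Sequence[tuple[int, int, str]],
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-pair (second minus first period) differences of a percent measure.

    A pair is null for a larva unless its movement fraction reaches the OMR
    eligibility threshold in *both* periods.  The combined measure is the mean
    of the non-null pair differences (null when every pair is null).
    """
    values: dict[str, np.ndarray] = {}
    stack = []
    for first, second, name in pairs:
        pct_first = _pct(flag, valid, period[0] == first)
        pct_second = _pct(flag, valid, period[0] == second)
        eligible = ((move_frac[:, first - 1] >= 100 * OMR_MIN_MOVE_FRACTION)
                    & (move_frac[:, second - 1] >= 100 * OMR_MIN_MOVE_FRACTION))
        diff = np.where(eligible, pct_second - pct_first, np.nan)
        values[name] = diff
        stack.append(diff)
    if not stack:
        return values, np.full(flag.shape[0], np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-null larvae
        combined = np.nanmean(np.vstack(stack), axis=0)
    return values, combined


def _movement_fractions(moved: np.ndarray, valid: np.ndarray,
                        period: np.ndarray, n_periods: int = 18) -> np.ndarray:
    """Percent moved per period, shape (n_larvae, n_periods)."""
    out = np.full((moved.shape[0], n_periods), np.nan)
    for p in range(1, n_periods + 1):
        out[:, p - 1] = _pct(moved, valid, period[0] == p)
    return out


def profiles_from_arrays(
    feats: Mapping[str, np.ndarray],
    schedule: StimulusSchedule | None = None,
    *,
    apply_exclusion: bool = True,
) -> pd.DataFrame:
    """Compute behavioral profiles for a stack of larvae (vectorized).

    ``feats`` is the output of :func:`zlap.kinematics.compute_feature_arrays`
    (2-D arrays, one row per larva).  Returns one profile row per larva with
    the 25 parameters, the exclusion flag, the absolute-edge variants, and
    per-period movement fractions ``mv_P1`` .. ``mv_P18``.
    """
    schedule = schedule or default_schedule()
    period = np.asarray(feats["period"], dtype=float)
    if period.ndim != 2:
        raise InputError("feature arrays must be 2-D (larvae x frames)")
    period = period[:1, :]  # identical across larvae
    valid = np.asarray(feats["valid"], dtype=float)
    moved = np.asarray(feats["moved"], dtype=float)
    n = valid.shape[0]

    mv = _movement_fractions(moved, valid, period)

    base = np.isin(period[0], BASELINE_PERIODS)
    vision = np.isin(period[0], VISION_PERIODS)

    out: dict[str, np.ndarray] = {}
    out["1h"] = _pct(moved, valid, base)
    out["P15"] = _pct(moved, valid, period[0] == 15)
    out["St"] = mv[:, 15] - mv[:, 14]
    out["Ex"] = mv[:, 16] - mv[:, 15]

    # habituation inside period 17: first vs second half (5 min each)
    p17 = period[0] == 17
    in_p17 = np.flatnonzero(p17)
    half = len(in_p17) // 2
    first_half = np.zeros_like(p17)
    second_half = np.zeros_like(p17)
    first_half[in_p17[:half]] = True
    second_half[in_p17[half:]] = True
    out["Hab"] = _pct(moved, valid, first_half) - _pct(moved, valid, second_half)

    pairs = schedule.line_pairs()
    omr, omr_all = _pair_measures(np.asarray(feats["up"], float), valid, period, mv, pairs)
    ori, ori_all = _pair_measures(np.asarray(feats["upward"], float), valid, period, mv, pairs)
    for name in ("R", "G", "B", "FR"):
        out[name] = omr.get(name, np.full(n, np.nan))
        out[f"Or-{name}"] = ori.get(name, np.full(n, np.nan))
    out["RGB"] = omr_all
    out["Or-RGB"] = ori_all

    for prefix in ("Sc", "Bu", "Ed", "Cw"):
        flag = np.asarray(feats[_FLAG_OF_MEASURE[prefix]], float)
        out[f"{prefix}-1h"] = _pct(flag, valid, base)
        out[f"{prefix}-V"] = _pct(flag, valid, vision)

    turn = np.asarray(feats["turn"], float)
    turn_abs = np.asarray(feats["turn_abs"], float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # larvae with no transitions
        out["Turn-1h"] = np.nanmean(np.where(base, turn, np.nan), axis=1)
        out["Tabs-1h"] = np.nanmean(np.where(base, turn_abs, np.nan), axis=1)

    edge = np.asarray(feats["edge"], float)
    out["Ed-1h-abs"] = 100.0 * (edge[:, base] == 1).sum(axis=1) / max(base.sum(), 1)
    out["Ed-V-abs"] = 100.0 * (edge[:, vision] == 1).sum(axis=1) / max(vision.sum(), 1)

    # whole-recording exclusion: movement < 1 % of valid frames (or no data)
    n_valid = (valid == 1).sum(axis=1)
    n_moved = (moved == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        overall = np.where(n_valid > 0, n_moved / n_valid, np.nan)
    excluded = ~(overall >= EXCLUSION_MOVE_FRACTION)  # NaN -> excluded

    df = pd.DataFrame(out)
    df.insert(0, "excluded", excluded)
    if apply_exclusion:
        df.loc[excluded, PARAMETERS + ["Ed-1h-abs", "Ed-V-abs"]] = np.nan
    for p in range(1, 19):
        df[f"mv_P{p}"] = mv[:, p - 1]
    ordered = ["excluded"] + PARAMETERS + ["Ed-1h-abs", "Ed-V-abs"] + [
        f"mv_P{p}" for p in range(1, 19)]
    return df[ordered]


# ---------------------------------------------------------------------------
# single-larva / table-level interfaces
# ---------------------------------------------------------------------------

def omr_measures(rows: pd.DataFrame, schedule: StimulusSchedule | None = None
                 ) -> dict[str, float]:
    """Optomotor measures (R, G, B, FR, RGB) for one larva's feature rows."""
    return _single_larva_subset(rows, schedule, ["R", "G", "B", "FR", "RGB"])


def orientation_measures(rows: pd.DataFrame, schedule: StimulusSchedule | None = None
                         ) -> dict[str, float]:
    """Orientation measures (Or-R .. Or-RGB) for one larva's feature rows."""
    return _single_larva_subset(rows, schedule,
                                ["Or-R", "Or-G", "Or-B", "Or-FR", "Or-RGB"])


def stimulus_response_measures(rows: pd.DataFrame) -> dict[str, float]:
    """Acoustic-stimulus measures (St, Ex, Hab) for one larva's feature rows."""
    return _single_larva_subset(rows, None, ["St", "Ex", "Hab"])


def _single_larva_subset(rows: pd.DataFrame, schedule: StimulusSchedule | None,
                         names: list[str]) -> dict[str, float]:
    # standalone measures are defined regardless of the whole-recording exclusion
    feats = _to_arrays(rows)
    feats["frame"] = rows["frame"].to_numpy(float)[None, :] if "frame" in rows.columns \
        else np.arange(len(rows), dtype=float)[None, :]
    profile = profiles_from_arrays(feats, schedule, apply_exclusion=False)
    return {name: float(profile[name].iloc[0]) for name in names}


def larva_profile(rows: pd.DataFrame, schedule: StimulusSchedule | None = None,
                  expected_frames: int = 18 * FRAMES_PER_PERIOD) -> pd.Series:
    """The 25-parameter behavioral profile of a single larva.

    ``rows`` are the larva's feature-table rows in frame order.  Raises when
    the stream is shorter than the configured recording length.
    """
    if len(rows) < expected_frames:
        raise InputError(f"stream of {len(rows)} frames; expected {expected_frames}")
    feats = _to_arrays(rows)
    feats["frame"] = rows["frame"].to_numpy(float)[None, :]
    profile = profiles_from_arrays(feats, schedule).iloc[0]
    for key in ("plate_id", "well_id"):
        if key in rows.columns:
            profile[key] = rows[key].iloc[0]
    return profile


def profiles_from_table(table: pd.DataFrame, schedule: StimulusSchedule | None = None
                        ) -> pd.DataFrame:
    """Per-larva profiles for a full feature table (one row per well).

    The table must be well-major with equal-length frame streams, as produced
    by :func:`zlap.kinematics.build_feature_table`.
    """
    key = table["plate_id"].astype(str) + "/" + table["well_id"].astype(str)
    codes, uniques = pd.factorize(key)
    n_frames = len(table) // len(uniques)
    if len(table) != n_frames * len(uniques) or (
            np.diff(codes).min(initial=0) < 0):
        raise InputError("feature table is not well-major with equal stream lengths")
    feats = {
        c: table[c].to_numpy(dtype=float, na_value=np.nan).reshape(len(uniques), n_frames)
        for c in ["frame", "period", "valid", "moved", "scoot", "burst", "up",
                  "edge", "clockwise", "upward", "turn", "turn_abs"]
    }
    profiles = profiles_from_arrays(feats, schedule)
    ids = pd.DataFrame({"plate_id": [u.split("/", 1)[0] for u in uniques],
                        "well_id": [u.split("/", 1)[1] for u in uniques]})
    return pd.concat([ids, profiles.reset_index(drop=True)], axis=1)


def group_summary(profiles: pd.DataFrame, treatment_map: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment mean/sd/n of every parameter over non-excluded larvae.

    Null-aware: a larva whose OMR measure is null reduces that parameter's n.
    Returns a long DataFrame (treatment, parameter, mean, sd, n).
    """
    merged = profiles.merge(treatment_map[["plate_id", "well_id", "treatment"]],
                            on=["plate_id", "well_id"], how="left", validate="m:1")
    if merged["treatment"].isna().any():
        orphans = merged.loc[merged["treatment"].isna(), ["plate_id", "well_id"]]
        raise InputError(f"wells missing from treatment map: "
                         f"{orphans.to_records(index=False).tolist()[:5]}")
    alive = merged[~merged["excluded"].astype(bool)]
    records = []
    for treatment, grp in alive.groupby("treatment", sort=True):
        for param in PARAMETERS:
            vals = grp[param].dropna()
            records.append({
                "treatment": treatment, "parameter": param,
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                "n": int(len(vals)),
            })
    for treatment in treatment_map["treatment"].unique():
        if treatment not in set(alive["treatment"]):
            for param in PARAMETERS:
                records.append({"treatment": treatment, "parameter": param,
                                "mean": np.nan, "sd": np.nan, "n": 0})
    return pd.DataFrame.from_records(records)


def summary_means(summary: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long group summary into a treatment x parameter matrix of means."""
    return summary.pivot(index="treatment", columns="parameter", values="mean")[PARAMETERS]
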