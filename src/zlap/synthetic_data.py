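"""Synthetic plates, trajectories and screens with controlled phenotypes.

The generator emulates the standard assay: one larva per circular well
(radius 75 px), photographed every 6 s for 3 h (1800 frames), under the
18-period stimulus timeline.  A larva is a discrete-time random walker:

* per frame it moves with a probability modulated by the current stimulus —
  sound periods add a startle (20-s pulses) or excitability (1-s pulses)
  increment that decays within the period at the habituation rate;
* a moving step draws its length from the scoot or the burst distribution
  (uniform on (4, 18) and (22, 60) px — strictly inside the 3/20 px class
  boundaries, so classification of true steps is unambiguous);
* the heading carries von-Mises persistence noise plus a constant turn bias,
  and during moving-line periods is pulled toward the line direction with
  probability ``omr_gain`` (the optomotor response);
* the wall reflects (larvae cannot leave the well);
* the emitted pose places the eye midpoint 9 px rostral of the yolk, the
  eyes 6 px apart, adds Gaussian jitter, and drops the detection likelihood
  below the 0.5 validity threshold at rate ``likelihood_noise``.

Phenotype presets mirror the screen's reference pharmacology: calcineurin
inhibitors (CsA, FK506) show raised activity and acoustic excitability with
reduced optomotor/orientation responses and reduced habituation; the
DYRK1A-inhibitor phenotype (proINDY) is the near-opposite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import InputError
from .pose_io import POSE_COLUMNS, FRAMES_PER_PERIOD, StimulusSchedule, default_schedule
from .well_grid import WellCircle

WELL_RADIUS_PX = 75.0
WELL_PITCH_PX = 160.0
EYE_DISTANCE_PX = 9.0     # yolk -> eye midpoint
EYE_SEPARATION_PX = 6.0   # between the two eyes
WALL_MARGIN_PX = 12.0     # keeps the whole pose inside the well after reflection

N_FRAMES_DEFAULT = 18 * FRAMES_PER_PERIOD  # 1800

# the reference screen's group sizes
N_LARVAE_PER_GROUP = 48
N_DMSO_LARVAE = 844
N_COMPOUNDS = 190


@dataclass(frozen=True)
class PhenotypeParams:
    """Tunable movement/orientation statistics of one phenotype."""

    p_move: float = 0.15              # per-frame movement probability, no stimulus
    p_burst_given_move: float = 0.20  # long/fast swim fraction of moves
    scoot_range: tuple[float, float] = (4.0, 18.0)    # px per 6-s step
    burst_range: tuple[float, float] = (22.0, 60.0)   # px per 6-s step
    heading_kappa: float = 4.0        # von-Mises persistence concentration
    omr_gain: float = 0.25            # P(heading snaps toward the line direction)
    omr_kappa: float = 2.0            # concentration of the snapped heading
    startle_gain: float = 0.15        # movement increment, 20-s sound pulses
    excitability_gain: float = 0.30   # movement increment, 1-s sound pulses
    habituation_rate: float = 0.03    # per-frame decay of the sound response
    turn_bias: float = 0.0            # mean signed turn, degrees per frame
    edge_bias: float = 0.0            # P(heading snaps outward) per frame
    likelihood_noise: float = 0.02    # rate of sub-threshold pose confidence
    pose_noise_sd: float = 0.5        # px jitter on emitted coordinates

    def __post_init__(self) -> None:
        for name in ("p_move", "p_burst_given_move", "omr_gain", "startle_gain",
                     "excitability_gain", "edge_bias", "likelihood_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name}={v} outside [0, 1]")
        if min(self.scoot_range) < 0 or min(self.burst_range) < 0:
            raise InputError("step lengths must be >= 0")


#: phenotype presets used throughout the synthetic screens
PHENOTYPES: Mapping[str, PhenotypeParams] = {
    "control": PhenotypeParams(),
    # calcineurin-inhibitor-like: hyperactive, hyperexcitable, weak visual
    # responses, little habituation
    "csa_like": PhenotypeParams(p_move=0.30, p_burst_given_move=0.30,
                                omr_gain=0.05, excitability_gain=0.50,
                                habituation_rate=0.002),
    # near-opposite profile: hypoactive, strong visual responses, habituates fast
    "proindy_like": PhenotypeParams(p_move=0.06, p_burst_given_move=0.15,
                                    omr_gain=0.70, excitability_gain=0.10,
                                    habituation_rate=0.05),
}

#: reference treatments and their phenotypes, always present in a screen
REFERENCE_TREATMENTS: Mapping[str, str] = {
    "DMSO": "control",
    "EW": "control",
    "CsA": "csa_like",
    "FK506": "csa_like",
    "proINDY": "proindy_like",
    "CsA+proINDY": "csa_like",     # rescue combination; does not revert the profile
    "FK506+proINDY": "csa_like",
}


@dataclass
class SimulatedWell:
    """Ground truth and emitted poses for one simulated larva."""

    well: WellCircle
    phenotype: str
    truth_x: np.ndarray       # yolk, image coordinates
    truth_y: np.ndarray
    truth_heading_deg: np.ndarray  # y-up convention
    pose: pd.DataFrame        # canonical flat pose table (with jitter + likelihoods)


def _stimulus_drive(params_move: np.ndarray, startle: np.ndarray, excite: np.ndarray,
                    hab_rate: np.ndarray, schedule: StimulusSchedule,
                    n_frames: int) -> np.ndarray:
    """Per-larva, per-frame movement probability (n_larvae x n_frames)."""
    p = np.repeat(params_move[:, None], n_frames, axis=1)
    frames = np.arange(n_frames)
    periods = frames // FRAMES_PER_PERIOD + 1
    for period in np.unique(periods):
        if int(period) not in schedule.periods:
            continue
        stim = schedule.stimulus(int(period))
        if stim.kind != "sound":
            continue
        gain = startle if stim.interval_s and stim.interval_s >= 10 else excite
        cols = np.flatnonzero(periods == period)
        t_in = np.arange(len(cols))
        p[:, cols] += gain[:, None] * np.exp(-hab_rate[:, None] * t_in[None, :])
    return np.clip(p, 0.0, 1.0)


def _line_direction(schedule: StimulusSchedule, n_frames: int) -> np.ndarray:
    """Target heading (radians, y-up) per frame during line periods; NaN elsewhere."""
    frames = np.arange(n_frames)
    periods = frames // FRAMES_PER_PERIOD + 1
    target = np.full(n_frames, np.nan)
    for period in np.unique(periods):
        if int(period) not in schedule.periods:
            continue
        stim = schedule.stimulus(int(period))
        if stim.kind == "lines" and stim.direction in ("up", "down"):
            target[periods == period] = np.pi / 2 if stim.direction == "up" else -np.pi / 2
    return target


def _simulate_batch(
    params: list[PhenotypeParams],
    schedule: StimulusSchedule,
    n_frames: int,
    rng: np.random.Generator,
    well_radius: float = WELL_RADIUS_PX,
) -> dict[str, np.ndarray]:
    """Vectorized trajectory + pose emission for a batch of larvae.

    Returns well-centric ground truth (x, y y-up, heading) and the nine
    emitted pose arrays, each (n_larvae, n_frames).
    """
    n = len(params)
    get = lambda name: np.array([getattr(p, name) for p in params], dtype=float)

    p_move = _stimulus_drive(get("p_move"), get("startle_gain"),
                             get("excitability_gain"), get("habituation_rate"),
                             schedule, n_frames)
    target = _line_direction(schedule, n_frames)
    kappa = get("heading_kappa")
    omr_gain = get("omr_gain")
    omr_kappa = get("omr_kappa")
    edge_bias = get("edge_bias")
    turn_bias = np.radians(get("turn_bias"))
    p_burst = get("p_burst_given_move")
    sc_lo = np.array([p.scoot_range[0] for p in params])
    sc_hi = np.array([p.scoot_range[1] for p in params])
    bu_lo = np.array([p.burst_range[0] for p in params])
    bu_hi = np.array([p.burst_range[1] for p in params])

    r_max = well_radius - WALL_MARGIN_PX
    # start at a uniform position in the allowed disk, random heading
    theta0 = rng.uniform(0, 2 * np.pi, n)
    r0 = r_max * np.sqrt(rng.uniform(0, 1, n))
    x = r0 * np.cos(theta0)
    y = r0 * np.sin(theta0)
    heading = rng.uniform(-np.pi, np.pi, n)

    xs = np.empty((n, n_frames))
    ys = np.empty((n, n_frames))
    hs = np.empty((n, n_frames))
    for t in range(n_frames):
        heading = heading + rng.vonmises(turn_bias, kappa, n)
        if not np.isnan(target[t]):
            snap = rng.uniform(0, 1, n) < omr_gain
            if snap.any():
                heading[snap] = target[t] + rng.vonmises(
                    0.0, omr_kappa[snap], int(snap.sum()))
        drift = rng.uniform(0, 1, n) < edge_bias
        if drift.any():
            heading[drift] = np.arctan2(y[drift], x[drift]) + rng.vonmises(
                0.0, omr_kappa[drift], int(drift.sum()))
        moves = rng.uniform(0, 1, n) < p_move[:, t]
        bursts = rng.uniform(0, 1, n) < p_burst
        step = np.where(
            moves,
            np.where(bursts, rng.uniform(bu_lo, bu_hi), rng.uniform(sc_lo, sc_hi)),
            0.0,
        )
        x = x + step * np.cos(heading)
        y = y + step * np.sin(heading)
        # reflecting wall: fold the radius back inside r_max
        r = np.hypot(x, y)
        outside = r > r_max
        if outside.any():
            scale = (2 * r_max - r[outside]) / r[outside]
            scale = np.clip(scale, 0.0, None)
            x[outside] *= scale
            y[outside] *= scale
            heading[outside] = np.arctan2(y[outside], x[outside]) + np.pi + \
                rng.vonmises(0.0, 4.0, int(outside.sum()))
        heading = np.arctan2(np.sin(heading), np.cos(heading))
        xs[:, t] = x
        ys[:, t] = y
        hs[:, t] = heading
    return {"x": xs, "y": ys, "heading": hs}


def _emit_pose(
    truth: dict[str, np.ndarray],
    params: list[PhenotypeParams],
    wells: list[WellCircle],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Noisy three-point poses (image coordinates) from ground-truth trajectories."""
    xs, ys, hs = truth["x"], truth["y"], truth["heading"]
    n, n_frames = xs.shape
    cx = np.array([w.cx for w in wells])[:, None]
    cy = np.array([w.cy for w in wells])[:, None]
    sd = np.array([p.pose_noise_sd for p in params])[:, None]
    lnoise = np.array([p.likelihood_noise for p in params])[:, None]

    yolk_x = cx + xs
    yolk_y = cy - ys  # y-up -> image y-down
    mid_x = xs + EYE_DISTANCE_PX * np.cos(hs)
    mid_y = ys + EYE_DISTANCE_PX * np.sin(hs)
    # larva's left is heading rotated +90 degrees in y-up coordinates
    off_x = 0.5 * EYE_SEPARATION_PX * np.cos(hs + np.pi / 2)
    off_y = 0.5 * EYE_SEPARATION_PX * np.sin(hs + np.pi / 2)

    def jitter(shape):  # Gaussian pose-estimation error
        return rng.normal(0.0, 1.0, shape) * sd

    pose = {
        "x_yolk": yolk_x + jitter(xs.shape),
        "y_yolk": yolk_y + jitter(xs.shape),
        "x_left": cx + mid_x + off_x + jitter(xs.shape),
        "y_left": cy - (mid_y + off_y) + jitter(xs.shape),
        "x_right": cx + mid_x - off_x + jitter(xs.shape),
        "y_right": cy - (mid_y - off_y) + jitter(xs.shape),
    }
    for part in ("yolk", "left", "right"):
        base = rng.uniform(0.85, 1.0, (n, n_frames))
        low = rng.uniform(0.0, 0.45, (n, n_frames))
        dropped = rng.uniform(0, 1, (n, n_frames)) < lnoise
        pose[f"p_{part}"] = np.where(dropped, low, base)
    return pose


def _default_well(index: int = 0) -> WellCircle:
    row, col = divmod(index, 24)
    return WellCircle(
        cx=WELL_PITCH_PX / 2 + col * WELL_PITCH_PX,
        cy=WELL_PITCH_PX / 2 + row * WELL_PITCH_PX,
        radius=WELL_RADIUS_PX, row=row, col=col,
        well_id=f"{chr(ord('A') + row)}{col + 1}",
    )


def pose_arrays_to_table(pose: Mapping[str, np.ndarray], index: int) -> pd.DataFrame:
    """One well's slice of batch pose arrays as a canonical flat pose table."""
    n_frames = pose["x_yolk"].shape[1]
    data = {"frame": np.arange(n_frames)}
    for key in POSE_COLUMNS[1:]:
        data[key] = pose[key][index]
    return pd.DataFrame(data)


def simulate_trajectory(
    params: PhenotypeParams,
    schedule: StimulusSchedule | None = None,
    n_frames: int = N_FRAMES_DEFAULT,
    seed: int = 0,
    well: WellCircle | None = None,
    phenotype: str = "custom",
) -> SimulatedWell:
    """Simulate a single larva and emit its noisy pose stream."""
    if n_frames < 1:
        raise InputError("n_frames must be >= 1")
    schedule = schedule or default_schedule()
    well = well or _default_well()
    rng = np.random.default_rng(seed)
    truth = _simulate_batch([params], schedule, n_frames, rng, well.radius)
    pose = _emit_pose(truth, [params], [well], rng)
    return SimulatedWell(
        well=well,
        phenotype=phenotype,
        truth_x=well.cx + truth["x"][0],
        truth_y=well.cy - truth["y"][0],
        truth_heading_deg=np.degrees(truth["heading"][0]),
        pose=pose_arrays_to_table(pose, 0),
    )


@dataclass
class SimulatedScreen:
    """A whole synthetic screen: poses, layout, and ground-truth phenotypes."""

    wells: list[WellCircle]               # one per larva, plate-local geometry
    plate_ids: list[str]                  # aligned with wells
    pose: dict[str, np.ndarray]           # nine (n_larvae x n_frames) arrays
    treatment_map: pd.DataFrame           # plate_id, well_id, treatment, concentration_uM
    phenotype_of_treatment: dict[str, str]  # ground-truth labels
    schedule: StimulusSchedule

    def iter_pose_tables(self) -> Iterator[tuple[str, str, pd.DataFrame]]:
        for i, (plate, well) in enumerate(zip(self.plate_ids, self.wells)):
            yield plate, well.well_id, pose_arrays_to_table(self.pose, i)


def plan_screen(
    n_compounds: int = N_COMPOUNDS,
    phenotype_mix: Mapping[str, float] | None = None,
    n_larvae_per_group: int = N_LARVAE_PER_GROUP,
    n_control_larvae: int = N_DMSO_LARVAE,
    seed: int = 0,
    include_rescues: bool = True,
) -> list[tuple[str, str, int]]:
    """Treatment plan of a screen: (treatment, phenotype, n_larvae) triples.

    Always contains the reference treatments (CsA, FK506 — CsA-like;
    proINDY — opposite; EW — control; optionally the rescue combinations)
    plus an oversized DMSO vehicle group; library compounds draw their
    phenotype deterministically from ``phenotype_mix`` per seed.
    """
    mix = dict(phenotype_mix or {"control": 0.70, "csa_like": 0.15, "proindy_like": 0.15})
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise InputError("phenotype fractions must sum to 1")
    unknown = set(mix) - set(PHENOTYPES)
    if unknown:
        raise InputError(f"unknown phenotypes {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    treatments: list[tuple[str, str, int]] = []
    refs = dict(REFERENCE_TREATMENTS)
    if not include_rescues:
        refs = {k: v for k, v in refs.items() if "+" not in k}
    for name, phen in refs.items():
        n = n_control_larvae if name == "DMSO" else n_larvae_per_group
        treatments.append((name, phen, n))

    # deterministic phenotype counts per the mix, shuffled across compound ids
    counts = {p: int(round(f * n_compounds)) for p, f in mix.items()}
    drift = n_compounds - sum(counts.values())
    counts[max(mix, key=mix.get)] += drift
    assignment = [p for p, c in counts.items() for _ in range(c)]
    rng.shuffle(assignment)
    width = len(str(n_compounds))
    for i, phen in enumerate(assignment):
        treatments.append((f"drug_{i + 1:0{width}d}", phen, n_larvae_per_group))
    return treatments


def simulate_screen(
    n_compounds: int = N_COMPOUNDS,
    phenotype_mix: Mapping[str, float] | None = None,
    n_larvae_per_group: int = N_LARVAE_PER_GROUP,
    n_control_larvae: int = N_DMSO_LARVAE,
    seed: int = 0,
    n_frames: int = N_FRAMES_DEFAULT,
    schedule: StimulusSchedule | None = None,
    include_rescues: bool = True,
) -> SimulatedScreen:
    """Simulate a drug screen with known phenotype assignments.

    ``phenotype_mix`` gives the fraction of library compounds drawn from each
    phenotype (default 70 % control-like, 15 % CsA-like, 15 % opposite); see
    :func:`plan_screen` for the group structure.  Reproducible per seed.
    """
    schedule = schedule or default_schedule()
    rng = np.random.default_rng(seed)
    treatments = plan_screen(n_compounds, phenotype_mix, n_larvae_per_group,
                             n_control_larvae, seed, include_rescues)

    larvae_params: list[PhenotypeParams] = []
    records = []
    wells: list[WellCircle] = []
    plate_ids: list[str] = []
    per_plate = 96
    idx = 0
    for treatment, phen, n in treatments:
        for _ in range(n):
            plate, slot = divmod(idx, per_plate)
            row, col = divmod(slot, 12)
            well = WellCircle(
                cx=WELL_PITCH_PX / 2 + col * WELL_PITCH_PX,
                cy=WELL_PITCH_PX / 2 + row * WELL_PITCH_PX,
                radius=WELL_RADIUS_PX, row=row, col=col,
                well_id=f"{chr(ord('A') + row)}{col + 1}")
            wells.append(well)
            plate_ids.append(f"P{plate + 1}")
            larvae_params.append(PHENOTYPES[phen])
            records.append({"plate_id": f"P{plate + 1}", "well_id": well.well_id,
                            "treatment": treatment, "concentration_uM": 10.0})
            idx += 1

    truth = _simulate_batch(larvae_params, schedule, n_frames, rng)
    pose = _emit_pose(truth, larvae_params, wells, rng)
    return SimulatedScreen(
        wells=wells,
        plate_ids=plate_ids,
        pose=pose,
        treatment_map=pd.DataFrame.from_records(records),
        phenotype_of_treatment={t: p for t, p, _ in treatments},
        schedule=schedule,
    )


# ---------------------------------------------------------------------------
# plate rendering (end-to-end exercise of the well-segmentation stage)
# ---------------------------------------------------------------------------

def render_plate_frames(
    wells: list[SimulatedWell],
    layout: tuple[int, int],
    out_dir: str | Path,
    frames: list[int] | None = None,
    plate_id: str = "synthetic",
) -> list[Path]:
    """Render plate photographs of simulated wells and a ground-truth manifest.

    Wells are drawn as dark rings with a slightly shaded interior on a light
    background at the standard 160-px pitch; the larva appears as three dark
    blobs (two eyes, one yolk) at its ground-truth position.  Returns the
    written image paths; the manifest CSV holds well geometry and per-frame
    blob centers.
    """
    import imageio.v3 as iio

    n_rows, n_cols = layout
    if len(wells) > n_rows * n_cols:
        raise InputError(f"{len(wells)} wells exceed layout {n_rows}x{n_cols}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = frames if frames is not None else [0]

    height = int(n_rows * WELL_PITCH_PX)
    width = int(n_cols * WELL_PITCH_PX)
    yy, xx = np.mgrid[0:height, 0:width]
    paths = []
    manifest = []
    for frame in frames:
        img = np.full((height, width), 230, dtype=np.uint8)
        for i, sw in enumerate(wells):
            row, col = divmod(i, n_cols)
            cx = WELL_PITCH_PX / 2 + col * WELL_PITCH_PX
            cy = WELL_PITCH_PX / 2 + row * WELL_PITCH_PX
            r = sw.well.radius
            d2 = (xx - cx) ** 2 + (yy - cy) ** 2
            img[d2 <= r**2] = 210                      # well interior
            ring = (d2 >= (r - 2) ** 2) & (d2 <= (r + 2) ** 2)
            img[ring] = 40                             # well rim
            if frame < len(sw.truth_x):
                # larva blobs at ground truth, translated to this plate position
                lx = cx + (sw.truth_x[frame] - sw.well.cx)
                ly = cy + (sw.truth_y[frame] - sw.well.cy)
                h = np.radians(sw.truth_heading_deg[frame])
                mx, my = lx + EYE_DISTANCE_PX * np.cos(h), ly - EYE_DISTANCE_PX * np.sin(h)
                ex = 0.5 * EYE_SEPARATION_PX * np.cos(h + np.pi / 2)
                ey = 0.5 * EYE_SEPARATION_PX * np.sin(h + np.pi / 2)
                for bx, by, br, val in ((lx, ly, 3.0, 60), (mx + ex, my - ey, 2.0, 30),
                                        (mx - ex, my + ey, 2.0, 30)):
                    img[(xx - bx) ** 2 + (yy - by) ** 2 <= br**2] = val
                    manifest.append({"plate_id": plate_id, "frame": frame,
                                     "well_index": i, "row": row, "col": col,
                                     "cx": cx, "cy": cy, "radius": r,
                                     "blob_x": bx, "blob_y": by})
        path = out_dir / f"{plate_id}_{frame:04d}.png"
        iio.imwrite(path, img)
        paths.append(path)
    pd.DataFrame.from_records(manifest).to_csv(
        out_dir / f"{plate_id}_manifest.csv", index=False)
    return paths
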