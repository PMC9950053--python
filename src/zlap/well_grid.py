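"""Microplate well segmentation.

Plate photographs contain a lattice of circular wells (nominal inner diameter
7.15 mm, ~150 px at the standard imaging scale of ~48 um/px).  Wells are
located with a circular Hough transform on Canny edges, assigned row/column
grid identities by 1-D clustering of their center coordinates, and cropped
into square per-well images for downstream pose estimation.

Coordinate convention: image pixel coordinates, origin top-left, x right,
y down, 0-based.  Well-centric kinematics converts to y-up once, downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .errors import InputError, LayoutError

#: physical well geometry printed on the imaging rig: 7.15 mm inner diameter
#: maps to 150 px, i.e. ~48 um per pixel.
WELL_DIAMETER_MM = 7.15
WELL_DIAMETER_PX = 150
DEFAULT_MIN_DIST = 150
DEFAULT_MIN_RADIUS = 65
DEFAULT_MAX_RADIUS = 85


def microns_per_pixel(diameter_mm: float = WELL_DIAMETER_MM,
                      diameter_px: float = WELL_DIAMETER_PX) -> float:
    """Imaging scale in micrometers per pixel from the printed well geometry."""
    return diameter_mm * 1000.0 / diameter_px


@dataclass(frozen=True)
class PlateImage:
    """8-bit grayscale plate photograph."""

    pixels: np.ndarray
    plate_id: str = "plate"

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class WellCircle:
    """A detected well: center, radius, and (once assigned) its grid identity."""

    cx: float
    cy: float
    radius: float
    row: int | None = None
    col: int | None = None
    well_id: str | None = None


def _as_pixels(image: PlateImage | np.ndarray) -> np.ndarray:
    pixels = image.pixels if isinstance(image, PlateImage) else np.asarray(image)
    if pixels.ndim == 3:  # RGB -> luminance
        pixels = pixels[..., :3].mean(axis=2)
    if pixels.ndim != 2 or pixels.size == 0:
        raise InputError(f"expected a non-empty 2-D image, got shape {pixels.shape}")
    return pixels.astype(float)


def detect_wells(
    image: PlateImage | np.ndarray,
    min_radius: int = DEFAULT_MIN_RADIUS,
    max_radius: int = DEFAULT_MAX_RADIUS,
    min_dist: int = DEFAULT_MIN_DIST,
    *,
    radius_step: int = 2,
    canny_sigma: float = 2.0,
    accum_threshold: float = 0.4,
) -> list[WellCircle]:
    """Detect circular wells with a gradient (edge-based) circular Hough transform.

    Candidate circles are ranked by Hough accumulator response and kept
    greedily subject to a pairwise Euclidean center distance of at least
    ``min_dist``.  The number of detections is additionally capped at
    ``floor(image_area / min_dist**2)``, the densest lattice the spacing
    constraint admits.

    Returns an empty list when the image contains no circular gradients.
    """
    if not min_radius < max_radius:
        raise InputError("min_radius must be < max_radius")
    if min_dist <= 0:
        raise InputError("min_dist must be positive")
    pixels = _as_pixels(image)

    edges = canny(pixels / 255.0, sigma=canny_sigma)
    if not edges.any():
        return []
    radii = np.arange(min_radius, max_radius + 1, radius_step)
    hspaces = hough_circle(edges, radii)

    cap = int(pixels.shape[0] * pixels.shape[1] / float(min_dist) ** 2)
    if cap == 0:
        return []
    # over-collect candidates, then non-maximum suppress by Euclidean distance
    accums, cxs, cys, rs = hough_circle_peaks(
        hspaces, radii,
        total_num_peaks=4 * cap,
        threshold=accum_threshold * hspaces.max(),
    )
    kept: list[WellCircle] = []
    for _, cx, cy, r in sorted(zip(accums, cxs, cys, rs), key=lambda t: -t[0]):
        if len(kept) >= cap:
            break
        if all((cx - w.cx) ** 2 + (cy - w.cy) ** 2 >= min_dist**2 for w in kept):
            kept.append(WellCircle(cx=float(cx), cy=float(cy), radius=float(r)))
    return kept


def _cluster_1d(values: np.ndarray, gap: float) -> np.ndarray:
    """Assign cluster indices (sorted ascending) to 1-D values split at gaps > ``gap``."""
    order = np.argsort(values)
    labels = np.empty(len(values), dtype=int)
    current = 0
    labels[order[0]] = 0
    for prev, here in zip(order[:-1], order[1:]):
        if values[here] - values[prev] > gap:
            current += 1
        labels[here] = current
    return labels


def assign_grid_ids(circles: list[WellCircle], n_rows: int, n_cols: int) -> list[WellCircle]:
    """Sort detected circles into a row/column lattice and label them A1-style.

    Rows come from 1-D clustering of the center y coordinates with a gap
    threshold of half the median nearest-neighbor center distance (robust to
    center jitter well below half the well pitch); columns likewise on x.
    The assignment is deterministic for identical input.
    """
    if len(circles) > n_rows * n_cols:
        raise LayoutError(f"{len(circles)} circles exceed declared {n_rows}x{n_cols} layout")
    if not circles:
        return []
    if len(circles) == 1:
        c = circles[0]
        return [replace(c, row=0, col=0, well_id=_well_name(0, 0))]

    centers = np.array([[c.cx, c.cy] for c in circles])
    d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    gap = 0.5 * float(np.median(np.sqrt(d2.min(axis=1))))

    row_of = _cluster_1d(centers[:, 1], gap)
    col_of = _cluster_1d(centers[:, 0], gap)
    if row_of.max() + 1 > n_rows:
        raise LayoutError(f"detected {row_of.max() + 1} rows, declared {n_rows}")
    if col_of.max() + 1 > n_cols:
        raise LayoutError(f"detected {col_of.max() + 1} columns, declared {n_cols}")
    seen: set[tuple[int, int]] = set()
    out = []
    for c, r, k in zip(circles, row_of, col_of):
        if (int(r), int(k)) in seen:
            raise LayoutError(f"two circles assigned to grid cell ({r}, {k})")
        seen.add((int(r), int(k)))
        out.append(replace(c, row=int(r), col=int(k), well_id=_well_name(int(r), int(k))))
    return sorted(out, key=lambda c: (c.row, c.col))


def _well_name(row: int, col: int) -> str:
    """Row letter(s) + 1-based column, e.g. (0, 0) -> 'A1'."""
    letters = ""
    r = row
    while True:
        letters = chr(ord("A") + r % 26) + letters
        r = r // 26 - 1
        if r < 0:
            break
    return f"{letters}{col + 1}"


def crop_well(image: PlateImage | np.ndarray, circle: WellCircle, pad: int = 5) -> np.ndarray:
    """Square crop of side ``2*(radius+pad)`` centered on the well.

    Regions falling outside the source image are zero-filled, so the output
    shape is independent of the well position (clipping is defined behavior).
    """
    pixels = _as_pixels(image)
    half = int(round(circle.radius)) + pad
    side = 2 * half
    cx, cy = int(round(circle.cx)), int(round(circle.cy))
    out = np.zeros((side, side), dtype=pixels.dtype)
    y0, y1 = cy - half, cy + half
    x0, x1 = cx - half, cx + half
    sy0, sy1 = max(y0, 0), min(y1, pixels.shape[0])
    sx0, sx1 = max(x0, 0), min(x1, pixels.shape[1])
    if sy0 < sy1 and sx0 < sx1:
        out[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = pixels[sy0:sy1, sx0:sx1]
    return out


def load_image(path: str | Path, plate_id: str | None = None) -> PlateImage:
    """Read a PNG/TIFF raster as an 8-bit grayscale :class:`PlateImage`."""
    import imageio.v3 as iio

    path = Path(path)
    try:
        pixels = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read image {path}: {exc}") from exc
    pixels = np.asarray(pixels)
    if pixels.ndim == 3:
        pixels = pixels[..., :3].mean(axis=2)
    if pixels.size == 0:
        raise InputError(f"empty image: {path}")
    return PlateImage(pixels=pixels.astype(np.uint8), plate_id=plate_id or path.stem)


def write_well_manifest(wells: list[WellCircle], plate_id: str, path: str | Path) -> None:
    """Write the detected-well manifest CSV (plate_id, well_id, row, col, cx, cy, radius)."""
    import pandas as pd

    pd.DataFrame(
        [
            {"plate_id": plate_id, "well_id": w.well_id, "row": w.row, "col": w.col,
             "cx": w.cx, "cy": w.cy, "radius": w.radius}
            for w in wells
        ]
    ).to_csv(path, index=False)


def read_well_manifest(path: str | Path) -> dict[str, list[WellCircle]]:
    """Read a well manifest CSV back into per-plate :class:`WellCircle` lists."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"plate_id", "well_id", "row", "col", "cx", "cy", "radius"}
    if not required.issubset(df.columns):
        raise InputError(f"well manifest missing columns {sorted(required - set(df.columns))}")
    out: dict[str, list[WellCircle]] = {}
    for rec in df.itertuples(index=False):
        out.setdefault(str(rec.plate_id), []).append(
            WellCircle(cx=float(rec.cx), cy=float(rec.cy), radius=float(rec.radius),
                       row=int(rec.row), col=int(rec.col), well_id=str(rec.well_id))
        )
    return out
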