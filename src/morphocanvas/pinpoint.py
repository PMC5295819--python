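"""Per-cell PIN polarity quantification from two-channel images.

For each segmented cell a boundary band is extracted by subtracting the
disk-eroded cell mask from the mask itself (default radius 5 px); the cell's
polarity is the vector sum over band pixels of PIN intensity times the unit
vector from the mask centroid to the pixel.  Windowed vector fields sum cell
vectors per fixed image tile (default 30 x 30 px).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon as draw_polygon
from skimage.morphology import disk, erosion

__all__ = [
    "ImageStack",
    "CellSegmentation",
    "PolarityVector",
    "boundary_band",
    "cell_polarity",
    "window_average",
    "quantify_stack",
    "DEFAULT_BAND_RADIUS_PX",
    "DEFAULT_WINDOW_PX",
]

log = logging.getLogger(__name__)

DEFAULT_BAND_RADIUS_PX = 5
DEFAULT_WINDOW_PX = 30


@dataclass
class ImageStack:
    """Two-channel stack: PIN signal and wall stain, (nz, ny, nx) or (ny, nx)."""

    pin: np.ndarray
    wall: np.ndarray
    pixel_size: float = 1.0  # micrometres per pixel

    def __post_init__(self) -> None:
        self.pin = np.asarray(self.pin)
        self.wall = np.asarray(self.wall)
        if self.pin.shape != self.wall.shape:
            raise ValueError("PIN and wall channels must have the same shape")
        if np.any(self.pin < 0) or np.any(self.wall < 0):
            raise ValueError("intensities must be non-negative")

    def plane(self, z: int | None) -> np.ndarray:
        if self.pin.ndim == 2:
            return self.pin
        return self.pin[0 if z is None else z]


@dataclass
class CellSegmentation:
    """A cell's boundary polygon (pixel coordinates, x-y) and its plane."""

    id: int
    polygon: np.ndarray  # (k, 2) of (x, y)
    plane: int | None = None

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        poly = np.asarray(self.polygon, dtype=float)
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=shape)
        out = np.zeros(shape, dtype=bool)
        out[rr, cc] = True
        return out


@dataclass
class PolarityVector:
    cell_id: int
    vx: float
    vy: float
    plane: int | None = None

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.vx, self.vy))

    @property
    def angle(self) -> float:
        """Angle from the +x axis, in (-pi, pi]."""
        return float(np.arctan2(self.vy, self.vx))


def boundary_band(mask: np.ndarray, radius: int = DEFAULT_BAND_RADIUS_PX
                  ) -> np.ndarray:
    """Cell-boundary band: mask minus its disk-erosion (band subset of mask).

    A radius of 0 gives an empty band.  If erosion empties the mask the whole
    mask is returned with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return np.zeros_like(mask)
    eroded = erosion(mask, disk(radius)).astype(bool)
    if not eroded.any():
        warnings.warn("erosion emptied the mask; using whole mask as band")
        return mask.copy()
    return mask & ~eroded


def cell_polarity(pin_image: np.ndarray, mask: np.ndarray,
                  band: np.ndarray, cell_id: int = 0,
                  plane: int | None = None) -> PolarityVector:
    """Vector sum over band pixels of intensity times centroid-to-pixel unit
    vector.  The centroid is the binary mask centroid; pixels exactly at the
    centroid contribute zero."""
    if not band.any():
        raise ValueError("empty boundary band")
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    by, bx = np.nonzero(band)
    inten = np.asarray(pin_image, dtype=float)[by, bx]
    dx = bx - cx
    dy = by - cy
    norm = np.hypot(dx, dy)
    ok = norm > 1e-12
    vx = float(np.sum(inten[ok] * dx[ok] / norm[ok]))
    vy = float(np.sum(inten[ok] * dy[ok] / norm[ok]))
    return PolarityVector(cell_id, vx, vy, plane)


def window_average(
    vectors: list[PolarityVector] | np.ndarray,
    positions: np.ndarray,
    window: int = DEFAULT_WINDOW_PX,
    mode: str = "sum",
) -> dict[tuple[int, int], np.ndarray]:
    """Windowed vector field: per (ix, iy) tile, the sum of cell vectors whose
    centroid falls in that tile (tiling anchored at the image origin).

    ``mode='mean'`` optionally divides by the cell count per tile.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if len(vectors) and isinstance(vectors[0], PolarityVector):
        arr = np.array([[v.vx, v.vy] for v in vectors], dtype=float)
    else:
        arr = np.asarray(vectors, dtype=float).reshape(-1, 2)
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    field: dict[tuple[int, int], np.ndarray] = {}
    counts: dict[tuple[int, int], int] = {}
    for vec, pos in zip(arr, positions):
        key = (int(pos[0] // window), int(pos[1] // window))
        field[key] = field.get(key, np.zeros(2)) + vec
        counts[key] = counts.get(key, 0) + 1
    if mode == "mean":
        field = {k: v / counts[k] for k, v in field.items()}
    return field


def quantify_stack(
    stack: ImageStack,
    segmentations: list[CellSegmentation],
    radius: int = DEFAULT_BAND_RADIUS_PX,
    window: int = DEFAULT_WINDOW_PX,
) -> tuple[list[PolarityVector], dict[tuple[int, int], np.ndarray]]:
    """Quantify every segmented cell on its representative plane.

    Per-cell failures are logged and skipped; remaining cells are processed.
    Returns the per-cell polarity vectors and the windowed vector field.
    """
    shape = stack.pin.shape[-2:]
    vectors: list[PolarityVector] = []
    centroids: list[np.ndarray] = []
    for seg in segmentations:
        try:
            mask = seg.mask(shape)
            band = boundary_band(mask, radius)
            img = stack.plane(seg.plane)
            vec = cell_polarity(img, mask, band, cell_id=seg.id,
                                plane=seg.plane)
        except Exception as exc:  # keep going on per-cell failures
            log.warning("cell %s failed: %s", seg.id, exc)
            continue
        ys, xs = np.nonzero(mask)
        vectors.append(vec)
        centroids.append(np.array([xs.mean(), ys.mean()]))
    field = window_average(vectors, np.asarray(centroids).reshape(-1, 2),
                           window=window)
    return vectors, field
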