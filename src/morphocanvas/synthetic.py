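"""Synthetic ground-truth inputs: PIN image stacks with known polarity,
perturbed starting canvases, and initial cell grids.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

from .celldiv import CellComplex
from .mesh import Canvas, make_square_canvas
from .pinpoint import CellSegmentation, ImageStack

__all__ = [
    "SyntheticPinSpec",
    "gen_pin_stack",
    "gen_perturbed_sheet",
    "gen_cell_grid",
]


@dataclass
class SyntheticPinSpec:
    """Parameters of a synthetic two-channel PIN image.

    ``edge_signal_fraction`` of the per-cell boundary signal is concentrated
    on the boundary arc facing ``angle`` (the rest is spread uniformly);
    noise is Poisson on the signal plus Gaussian read noise of ``noise_sigma``.
    """

    n_cells: int = 25
    image_size: int = 300
    angle: float = 0.0              # radians, constant polarity field
    angle_mode: str = "constant"    # constant | convergent | channel
    edge_signal_fraction: float = 1.0
    edge_halfwidth_deg: float = 45.0
    signal_level: float = 200.0
    background: float = 5.0
    noise_sigma: float = 0.0
    poisson: bool = True
    band_px: int = 3
    seed: int = 0
    pixel_size: float = 0.3
    layout: str = "random"  # random | hex (jittered hexagonal lattice)
    jitter: float = 0.12    # hex-layout jitter, fraction of spacing

    def __post_init__(self) -> None:
        if not 0.0 <= self.edge_signal_fraction <= 1.0:
            raise ValueError("edge_signal_fraction must be in [0, 1]")
        if self.n_cells < 3:
            raise ValueError("need at least 3 cells for a Voronoi layout")


def _voronoi_cells(spec: SyntheticPinSpec) -> list[Polygon]:
    rng = np.random.default_rng(spec.seed)
    margin = 0.05 * spec.image_size
    if spec.layout == "hex":
        ncol = int(np.ceil(np.sqrt(spec.n_cells)))
        spacing = (spec.image_size - 2 * margin) / ncol
        pts = []
        i = 0
        while len(pts) < spec.n_cells:
            row, col = divmod(i, ncol)
            x = margin + (col + 0.25 + 0.5 * (row % 2)) * spacing
            y = margin + (row + 0.5) * spacing
            pts.append([x, y])
            i += 1
        pts = np.asarray(pts) + rng.normal(
            0.0, spec.jitter * spacing, size=(len(pts), 2))
        # snap to half-integer pixel phase so shared Voronoi edges fall on
        # integer coordinates and rasterise symmetrically
        pts = np.floor(pts) + 0.5
    else:
        pts = rng.uniform(margin, spec.image_size - margin,
                          size=(spec.n_cells, 2))
    # mirror points so every interior region is bounded
    mirrored = [pts]
    for axis, bound in ((0, 0.0), (0, spec.image_size),
                        (1, 0.0), (1, spec.image_size)):
        m = pts.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    frame = box(1, 1, spec.image_size - 2, spec.image_size - 2)
    polys = []
    for i in range(spec.n_cells):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            continue
        poly = Polygon(vor.vertices[region]).intersection(frame)
        if poly.is_empty or poly.geom_type != "Polygon" or poly.area < 20:
            continue
        polys.append(poly)
    return polys


def _cell_angle(spec: SyntheticPinSpec, centroid: np.ndarray) -> float:
    if spec.angle_mode == "constant":
        return spec.angle
    centre = np.array([spec.image_size / 2.0] * 2)
    if spec.angle_mode == "convergent":
        d = centre - centroid
        return float(np.arctan2(d[1], d[0]))
    if spec.angle_mode == "channel":
        # proximodistal in a central channel, pointing inward elsewhere
        if abs(centroid[0] - centre[0]) < 0.1 * spec.image_size:
            return np.pi / 2.0
        return 0.0 if centroid[0] < centre[0] else np.pi
    raise ValueError(f"unknown angle_mode {spec.angle_mode!r}")


def gen_pin_stack(spec: SyntheticPinSpec):
    """Generate a synthetic PIN/wall image pair with known per-cell polarity.

    Returns (stack, segmentations, true_angles) where ``true_angles`` maps
    cell id to the generating polarity angle.
    """
    from skimage.draw import polygon as draw_polygon

    n = spec.image_size
    pin = np.zeros((n, n), dtype=float)
    wall = np.zeros((n, n), dtype=float)
    rng = np.random.default_rng(spec.seed + 1)
    segs: list[CellSegmentation] = []
    true_angles: dict[int, float] = {}

    for cid, poly in enumerate(_voronoi_cells(spec)):
        coords = np.asarray(poly.exterior.coords)
        rr, cc = draw_polygon(coords[:, 1], coords[:, 0], shape=(n, n))
        mask = np.zeros((n, n), dtype=bool)
        mask[rr, cc] = True
        if mask.sum() < 20:
            continue
        from scipy.ndimage import distance_transform_edt

        # smooth boundary ring (distance-weighted) to avoid pixel-grid bias
        dist = distance_transform_edt(mask)
        sigma = max(spec.band_px / 2.0, 0.75)
        ring = np.where(mask,
                        np.exp(-0.5 * ((dist - sigma) / sigma) ** 2), 0.0)
        wall += 150.0 * ring
        ys, xs = np.nonzero(mask)
        cen = np.array([xs.mean(), ys.mean()])
        ang = _cell_angle(spec, cen)
        by, bx = np.nonzero(mask)
        theta = np.arctan2(by - cen[1], bx - cen[0])
        dang = np.angle(np.exp(1j * (theta - ang)))
        half = np.deg2rad(spec.edge_halfwidth_deg)
        facing = np.where(np.abs(dang) < half,
                          0.5 * (1.0 + np.cos(np.pi * dang / half)), 0.0)
        level = spec.signal_level * (
            (1.0 - spec.edge_signal_fraction) +
            spec.edge_signal_fraction * facing)
        pin[by, bx] += level * ring[by, bx]
        segs.append(CellSegmentation(cid, coords))
        true_angles[cid] = ang

    pin += spec.background
    if spec.poisson:
        pin = rng.poisson(np.maximum(pin, 0)).astype(float)
        wall = rng.poisson(np.maximum(wall, 0)).astype(float)
    if spec.noise_sigma > 0:
        pin = np.maximum(pin + rng.normal(0, spec.noise_sigma, pin.shape), 0)
        wall = np.maximum(
            wall + rng.normal(0, spec.noise_sigma, wall.shape), 0)
    stack = ImageStack(pin, wall, pixel_size=spec.pixel_size)
    return stack, segs, true_angles


def gen_perturbed_sheet(side: float, amplitude: float, seed: int,
                        resolution: float | None = None) -> Canvas:
    """Flat square canvas with seeded uniform z-noise (no initial curvature)."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    return make_square_canvas(side, resolution=resolution,
                              curvature_sagitta=0.0,
                              z_noise_amplitude=amplitude, seed=seed)


# Four starting cell geometries: square, elongated, oblique, irregular.
_CELL_SHAPES = {
    1: np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]),
    2: np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.8], [0.0, 1.8]]),
    3: np.array([[0.0, 0.0], [1.0, 0.35], [1.0, 1.35], [0.0, 1.0]]),
    4: np.array([[0.0, 0.1], [1.1, 0.0], [0.9, 1.0], [0.15, 1.25]]),
}


def gen_cell_grid(shape: int, n: int, size: float = 10.0) -> CellComplex:
    """Tile ``n`` cells (rounded up to a full grid) of one of the four
    starting geometries into a shared-wall cell complex."""
    if shape not in _CELL_SHAPES:
        raise ValueError("shape must be in 1..4")
    base = _CELL_SHAPES[shape] * size
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    dx = base[1] - base[0]
    dy = base[3] - base[0]
    verts: list[np.ndarray] = []
    index: dict[tuple[int, int], int] = {}

    def vid(point: np.ndarray) -> int:
        key = (round(float(point[0]) * 1e6), round(float(point[1]) * 1e6))
        if key not in index:
            index[key] = len(verts)
            verts.append(point)
        return index[key]

    cells = []
    count = 0
    for j in range(nrow):
        for i in range(ncol):
            if count >= n:
                break
            off = i * dx + j * dy
            loop = [vid(p + off) for p in base]
            cells.append(loop)
            count += 1
    return CellComplex(np.asarray(verts), cells)
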