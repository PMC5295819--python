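"""Cell-division patterns on the growing canvas.

Polygonal cells are passive material markers: their vertices move with the
canvas, and a cell whose area exceeds a threshold is divided along the
shortest wall through its centroid (then shortened slightly for more
realistic junction angles).  Wall birth times classify walls into age
classes (T0 original / T1 / T2) for comparison with wall-staining patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point, Polygon

from . import engine, mesh

__all__ = [
    "CellComplex",
    "advect_cells",
    "divide_cell",
    "divide_sweep",
    "run_cellfile_model",
    "orientation_lines",
    "wall_age_classes",
    "CELLFILE_PATTERNS",
]

# angle-to-axis classification bands (degrees) for growth-orientation lines
PARALLEL_MAX_DEG = 30.0
PERPENDICULAR_MIN_DEG = 60.0

# new walls are shortened by this fraction of their length
SHORTEN_FRACTION = 0.10

# brute-force chord search resolution (degrees)
_CHORD_STEP_DEG = 0.25


class CellGeometryError(ValueError):
    pass


@dataclass
class CellComplex:
    """Planar polygonal cells with birth-time-stamped walls.

    ``vertices`` is (k, 2); each cell is an ordered vertex-id loop; walls map
    sorted vertex pairs to their birth time.  Topology only changes by wall
    insertion: once created, a vertex keeps its relation to its neighbours.
    """

    vertices: np.ndarray
    cells: list[list[int]]
    walls: dict[tuple[int, int], float] = field(default_factory=dict)
    division_threshold: float | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if not self.walls:
            for loop in self.cells:
                for a, b in zip(loop, loop[1:] + loop[:1]):
                    self.walls.setdefault(_key(a, b), 0.0)
        if self.division_threshold is None:
            self.division_threshold = 2.0 * float(np.mean(self.cell_areas()))

    def polygon(self, ci: int) -> Polygon:
        return Polygon(self.vertices[self.cells[ci]])

    def cell_areas(self) -> np.ndarray:
        return np.array([self.polygon(i).area for i in range(len(self.cells))])

    def wall_segments(self):
        """Iterate (v0, v1, birth_time) with coordinates."""
        for (a, b), t in self.walls.items():
            yield self.vertices[a], self.vertices[b], t

    def adjacency(self) -> set[tuple[int, int]]:
        """Cell adjacency graph edges (pairs of cell indices sharing a wall)."""
        owner: dict[tuple[int, int], int] = {}
        adj = set()
        for ci, loop in enumerate(self.cells):
            for a, b in zip(loop, loop[1:] + loop[:1]):
                k = _key(a, b)
                if k in owner and owner[k] != ci:
                    adj.add((min(owner[k], ci), max(owner[k], ci)))
                owner[k] = ci
        return adj

    def copy(self) -> "CellComplex":
        return CellComplex(self.vertices.copy(),
                           [list(c) for c in self.cells],
                           dict(self.walls), self.division_threshold,
                           self.time)


def _key(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


# ----------------------------------------------------------------- advection


def advect_cells(cells: CellComplex, canvas_before: mesh.Canvas,
                 canvas_after: mesh.Canvas) -> CellComplex:
    """Move cell vertices with the canvas deformation (xy barycentric map).

    Vertices are located in the pre-step canvas by barycentric coordinates of
    the xy projection and re-emitted at the same barycentric position of the
    post-step canvas.  Points outside the mesh are mapped with their nearest
    triangle's affine map (with a warning from the caller's perspective this
    is a projection).
    """
    tris = canvas_before.triangles
    v0 = canvas_before.vertices[:, :2]
    v1 = canvas_after.vertices[:, :2]
    p = cells.vertices
    a = v0[tris[:, 0]]
    b = v0[tris[:, 1]]
    c = v0[tris[:, 2]]
    det = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - \
        (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    new_pts = np.empty_like(p)
    for i, pt in enumerate(p):
        w1 = ((b[:, 0] - pt[0]) * (c[:, 1] - pt[1]) -
              (c[:, 0] - pt[0]) * (b[:, 1] - pt[1])) / det
        w2 = ((c[:, 0] - pt[0]) * (a[:, 1] - pt[1]) -
              (a[:, 0] - pt[0]) * (c[:, 1] - pt[1])) / det
        w3 = 1.0 - w1 - w2
        inside = (w1 >= -1e-9) & (w2 >= -1e-9) & (w3 >= -1e-9)
        if np.any(inside):
            t = int(np.nonzero(inside)[0][0])
        else:  # outside: clamp to nearest triangle's barycentric coords
            t = int(np.argmin(np.minimum(np.minimum(w1, w2), w3) * -1))
            lo = np.clip([w1[t], w2[t], w3[t]], 0.0, None)
            s = lo.sum()
            w1 = np.full_like(w1, lo[0] / s)
            w2 = np.full_like(w2, lo[1] / s)
        tri = tris[t]
        new_pts[i] = (w1[t] * v1[tri[0]] + w2[t] * v1[tri[1]] +
                      (1.0 - w1[t] - w2[t]) * v1[tri[2]])
    out = cells.copy()
    out.vertices = new_pts
    return out


def transform_cells(cells: CellComplex, matrix: np.ndarray) -> CellComplex:
    """Apply a 2x2 linear map about the origin (affine growth shortcut)."""
    out = cells.copy()
    out.vertices = cells.vertices @ np.asarray(matrix).T
    return out


# ------------------------------------------------------------------ division


def shortest_centroid_chord(poly: Polygon,
                            step_deg: float = _CHORD_STEP_DEG):
    """Minimal-length chord through the centroid, fully interior to ``poly``.

    Scans chord orientations densely; ties break deterministically toward the
    smallest angle to the x-axis.  Returns (p0, p1, angle).
    """
    if not poly.is_valid or poly.area <= 0:
        raise CellGeometryError("non-simple polygon")
    anchor = poly.centroid
    if not poly.contains(anchor):
        # strongly non-convex cell: anchor the chord at an interior point
        anchor = poly.representative_point()
    cen = np.array([anchor.x, anchor.y])
    diam = 2.0 * np.sqrt(poly.bounds[2] ** 2 + poly.bounds[3] ** 2) + \
        2.0 * max(abs(v) for v in poly.bounds)
    best = None
    for ang in np.arange(0.0, 180.0, step_deg):
        rad = np.deg2rad(ang)
        d = np.array([np.cos(rad), np.sin(rad)])
        line = LineString([cen - diam * d, cen + diam * d])
        inter = poly.intersection(line)
        segs = []
        if inter.geom_type == "LineString":
            segs = [inter]
        elif inter.geom_type == "MultiLineString":
            segs = list(inter.geoms)
        seg = None
        for s in segs:  # keep the piece containing the anchor point
            if s.distance(anchor) < 1e-9:
                seg = s
                break
        if seg is None or seg.length <= 0:
            continue
        if best is None or seg.length < best[0] - 1e-12:
            coords = np.asarray(seg.coords)
            best = (seg.length, coords[0], coords[-1], ang)
    if best is None:
        raise CellGeometryError("no interior centroid chord found")
    return best[1], best[2], best[3]


def _insert_on_edge(cells: CellComplex, a: int, b: int,
                    point: np.ndarray) -> int:
    """Add a vertex on wall (a, b), splitting it in every cell that uses it."""
    new_id = len(cells.vertices)
    cells.vertices = np.vstack([cells.vertices, point[None, :]])
    birth = cells.walls.pop(_key(a, b))
    cells.walls[_key(a, new_id)] = birth
    cells.walls[_key(new_id, b)] = birth
    for loop in cells.cells:
        n = len(loop)
        for i in range(n):
            p, q = loop[i], loop[(i + 1) % n]
            if {p, q} == {a, b}:
                loop.insert(i + 1, new_id)
                break
    return new_id


def divide_cell(cells: CellComplex, ci: int,
                shorten: float = SHORTEN_FRACTION) -> tuple[int, int]:
    """Divide cell ``ci`` along the shortest centroid chord.

    The new wall passes through the centroid, is then shortened by sliding
    its endpoints along their host edges (total length reduction ``shorten``),
    and is stamped with the current time.  Returns the two daughter indices
    (the parent slot is reused).
    """
    loop = cells.cells[ci]
    poly = cells.polygon(ci)
    p0, p1, _ = shortest_centroid_chord(poly)
    pts = cells.vertices

    def locate(point):
        n = len(loop)
        best = (None, None, np.inf)
        for i in range(n):
            a, b = loop[i], loop[(i + 1) % n]
            seg = LineString([pts[a], pts[b]])
            d = seg.distance(Point(point))
            if d < best[2]:
                best = (a, b, d)
        return best[0], best[1]

    e0 = locate(p0)
    e1 = locate(p1)
    if set(e0) == set(e1):
        raise CellGeometryError("division chord endpoints on one edge")
    # shorten: slide each endpoint along its host edge toward reducing length
    p0s, p1s = _shorten_chord(pts, e0, e1, p0, p1, shorten)
    v0 = _insert_on_edge(cells, e0[0], e0[1], p0s)
    v1 = _insert_on_edge(cells, e1[0], e1[1], p1s)
    loop = cells.cells[ci]  # refreshed by insertions
    i0 = loop.index(v0)
    i1 = loop.index(v1)
    if i0 > i1:
        i0, i1 = i1, i0
    loop_a = loop[i0: i1 + 1]
    loop_b = loop[i1:] + loop[: i0 + 1]
    cells.walls[_key(v0, v1)] = cells.time
    cells.cells[ci] = loop_a
    cells.cells.append(loop_b)
    return ci, len(cells.cells) - 1


def _shorten_chord(pts, e0, e1, p0, p1, fraction):
    """Slide chord endpoints along their host edges to shrink the new wall."""
    if fraction <= 0:
        return p0, p1
    out = []
    other = [p1, p0]
    for (a, b), point, opp in zip((e0, e1), (p0, p1), other):
        ea, eb = pts[a], pts[b]
        edge = eb - ea
        elen = np.linalg.norm(edge)
        if elen < 1e-12:
            out.append(point)
            continue
        ehat = edge / elen
        t = float(np.dot(point - ea, ehat))
        wall = opp - point
        wn = np.linalg.norm(wall)
        if wn < 1e-12:
            out.append(point)
            continue
        # moving along +ehat changes wall length at rate -ehat.(wall/|wall|)
        rate = -float(np.dot(ehat, wall / wn))
        want = 0.5 * fraction * wn  # each endpoint takes half the reduction
        if abs(rate) < 1e-6:
            out.append(point)
            continue
        # bound the slide so daughters stay near the centroid split
        dt_slide = np.clip(want / rate, -2.0 * want, 2.0 * want)
        dt_slide = np.clip(dt_slide, -0.15 * elen, 0.15 * elen)
        margin = 0.05 * elen
        t_new = np.clip(t + dt_slide, margin, elen - margin)
        out.append(ea + t_new * ehat)
    return out[0], out[1]


def divide_sweep(cells: CellComplex,
                 shorten: float = SHORTEN_FRACTION) -> int:
    """Divide every cell above the area threshold (repeat until none left).

    Returns the number of divisions performed.  After the sweep no cell area
    exceeds twice the threshold.
    """
    count = 0
    guard = 0
    while guard < 10_000:
        guard += 1
        areas = cells.cell_areas()
        over = np.nonzero(areas > cells.division_threshold)[0]
        if len(over) == 0:
            return count
        divide_cell(cells, int(over[0]), shorten=shorten)
        count += 1
    raise CellGeometryError("division sweep did not terminate")


# -------------------------------------------------------- cell-file patterns

# printed specified-growth patterns for the cell-file simulations:
# 1 uniform isotropic; 2 high Kpar; 3 high Kpar during T1 then high Kper at T2
CELLFILE_PATTERNS = {
    1: {"T1": (0.05, 0.05), "T2": (0.05, 0.05)},
    2: {"T1": (0.08, 0.0), "T2": (0.08, 0.0)},
    3: {"T1": (0.1, 0.0), "T2": (0.0, 0.1)},
}


def wall_age_classes(cells: CellComplex, t1_start: float,
                     t2_start: float) -> dict[tuple[int, int], str]:
    """Classify walls by birth time: T0 (original), T1 or T2."""
    out = {}
    for k, birth in cells.walls.items():
        if birth < t1_start:
            out[k] = "T0"
        elif birth < t2_start:
            out[k] = "T1"
        else:
            out[k] = "T2"
    return out


def run_cellfile_model(
    pattern: int,
    cells: CellComplex | None = None,
    phase_hours: float = 12.0,
    dt: float = 1.0,
    polarity_axis: np.ndarray = (0.0, 1.0),
) -> tuple[CellComplex, dict[tuple[int, int], str]]:
    """Run a two-phase cell-file simulation on a uniformly growing canvas.

    The polarity axis is proximodistal (+y).  Growth is applied as the exact
    affine stretch of the uniform specified growth per step (the resultant of
    uniform growth on a free sheet); cells are advected and divided whenever
    their area exceeds the threshold.  Returns the final complex and wall age
    classes.
    """
    if pattern not in CELLFILE_PATTERNS:
        raise ValueError(f"unknown pattern {pattern}; choose 1, 2 or 3")
    if cells is None:
        from .synthetic import gen_cell_grid
        cells = gen_cell_grid(1, 9)
    cells = cells.copy()
    axis = np.asarray(polarity_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    perp = np.array([-axis[1], axis[0]])
    t1_start = 0.0
    t2_start = phase_hours
    for phase, (kpar, kper) in CELLFILE_PATTERNS[pattern].items():
        stretch = (np.exp(kpar * dt) * np.outer(axis, axis) +
                   np.exp(kper * dt) * np.outer(perp, perp))
        for _ in range(int(round(phase_hours / dt))):
            cells = transform_cells(cells, stretch)
            cells.time += dt
            divide_sweep(cells)
    classes = wall_age_classes(cells, t1_start + 1e-9, t2_start + 1e-9)
    return cells, classes


def orientation_lines(cells: CellComplex,
                      axis: np.ndarray = (0.0, 1.0),
                      min_birth: float = 0.0) -> list[dict]:
    """Growth-orientation lines from recent walls.

    Each wall born at or after ``min_birth`` yields a line perpendicular to
    the wall, classified by its angle to ``axis``: <= 30 deg parallel,
    >= 60 deg perpendicular, else diagonal.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    out = []
    for (a, b), birth in cells.walls.items():
        if birth < min_birth:
            continue
        w = cells.vertices[b] - cells.vertices[a]
        line = np.array([-w[1], w[0]])
        ln = np.linalg.norm(line)
        if ln < 1e-12:
            continue
        line /= ln
        ang = np.rad2deg(np.arccos(np.clip(abs(float(line @ axis)), 0, 1)))
        if ang <= PARALLEL_MAX_DEG:
            cls = "parallel"
        elif ang >= PERPENDICULAR_MIN_DEG:
            cls = "perpendicular"
        else:
            cls = "diagonal"
        out.append({"wall": (a, b), "birth": birth,
                    "angle": ang, "class": cls})
    return out


def wall_orientation_angles(cells: CellComplex,
                            min_birth: float = 0.0,
                            max_birth: float = np.inf) -> np.ndarray:
    """Axial wall orientations (radians in [0, pi)) for walls in a birth
    window."""
    angs = []
    for (a, b), birth in cells.walls.items():
        if not (min_birth <= birth < max_birth):
            continue
        w = cells.vertices[b] - cells.vertices[a]
        angs.append(np.arctan2(w[1], w[0]) % np.pi)
    return np.asarray(angs)


def circular_variance_axial(angles: np.ndarray) -> float:
    """Circular variance of axial data (angles doubled before averaging)."""
    if len(angles) == 0:
        return 1.0
    z = np.exp(2j * angles)
    return float(1.0 - abs(z.mean()))
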