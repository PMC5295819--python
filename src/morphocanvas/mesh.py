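"""Geometry of the growing tissue sheet.

The canvas is a triangulated midplane mesh with a scalar thickness field and,
per triangle, independent rest metrics for its two surfaces (A = +z side at
construction, B = -z side).  Rest metrics are stored as Gram matrices of the
triangle edge basis ``(e1, e2) = (v1 - v0, v2 - v0)``, which makes growth and
subdivision purely algebraic (no global parametrisation is needed).

Units: micrometres for lengths, hours for time (1 DAI = 24 h).
Axes: x = mediolateral, y = proximodistal (+y distal), z = adaxial-up.
"""

from __future__ import annotations

import csv
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Canvas",
    "Clone",
    "make_square_canvas",
    "make_strip_canvas",
    "induce_clones",
    "clone_stats",
    "remesh",
    "write_ply",
    "read_ply",
    "write_obj",
    "write_factor_csv",
    "read_factor_csv",
]

# Default target edge length as a fraction of the short dimension.
DEFAULT_RESOLUTION_FRAC = 1.0 / 30.0
# Default sagitta of the initial "slight curvature", fraction of short side.
DEFAULT_SAGITTA_FRAC = 0.01
# Default flat-start z-noise amplitude, fraction of side.
DEFAULT_NOISE_FRAC = 0.001
# Default thickness, fraction of short side.
DEFAULT_THICKNESS_FRAC = 0.03


class MeshError(ValueError):
    """Invalid canvas parameters or degenerate geometry."""


@dataclass
class Clone:
    """A marked material region (virtual sector) advected with the canvas."""

    id: int
    vertices: np.ndarray  # vertex indices
    elements: np.ndarray  # triangle indices
    induction_time: float
    initial_radius: float
    centre: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.initial_radius <= 0:
            raise MeshError("clone radius must be positive")


@dataclass
class Canvas:
    """Triangulated growing sheet with per-vertex fields and per-element state.

    Attributes
    ----------
    vertices : (n, 3) float array
        Midplane positions in micrometres.
    thickness : (n,) float array
        Sheet thickness at each vertex (> 0).
    triangles : (m, 3) int array
        Positively oriented (counter-clockwise seen from +z at construction).
    factors : dict of name -> (n,) array
        Identity/signal factor levels (dimensionless).
    rest_a, rest_b : (m, 2, 2) arrays
        Per-triangle rest Gram matrices of the edge basis for surfaces A / B.
    pol_mat_a, pol_mat_b : (m, 2) arrays
        Polarity direction in the triangle edge basis (material coordinates),
        per surface.  Realised 3-D directions are obtained via :meth:`polarity`.
    pol_defined_a, pol_defined_b : (m,) bool arrays
    frozen_a, frozen_b : (m,) bool arrays
        Frozen elements keep their material polarity when the polariser field
        changes.
    time : float
        Simulation time in hours.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    thickness: np.ndarray
    factors: dict[str, np.ndarray] = field(default_factory=dict)
    rest_a: np.ndarray | None = None
    rest_b: np.ndarray | None = None
    pol_mat_a: np.ndarray | None = None
    pol_mat_b: np.ndarray | None = None
    pol_defined_a: np.ndarray | None = None
    pol_defined_b: np.ndarray | None = None
    frozen_a: np.ndarray | None = None
    frozen_b: np.ndarray | None = None
    time: float = 0.0
    clones: list[Clone] = field(default_factory=list)
    pol: np.ndarray | None = None  # polariser concentration per vertex

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.thickness = np.asarray(self.thickness, dtype=float)
        m = len(self.triangles)
        if self.rest_a is None:
            g = self.current_gram()
            self.rest_a = g.copy()
            self.rest_b = g.copy()
        if self.pol_mat_a is None:
            self.pol_mat_a = np.zeros((m, 2))
            self.pol_mat_b = np.zeros((m, 2))
            self.pol_defined_a = np.zeros(m, dtype=bool)
            self.pol_defined_b = np.zeros(m, dtype=bool)
        if self.frozen_a is None:
            self.frozen_a = np.zeros(m, dtype=bool)
            self.frozen_b = np.zeros(m, dtype=bool)
        if np.any(self.thickness <= 0):
            raise MeshError("thickness must be positive everywhere")

    # ---------------------------------------------------------------- geometry

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def edges3(self) -> np.ndarray:
        """Per-triangle current edge matrix, shape (m, 3, 2): columns e1, e2."""
        v = self.vertices[self.triangles]
        e1 = v[:, 1] - v[:, 0]
        e2 = v[:, 2] - v[:, 0]
        return np.stack([e1, e2], axis=-1)

    def current_gram(self) -> np.ndarray:
        """Realised metric per triangle: Gram matrix of (e1, e2), (m, 2, 2)."""
        e = self.edges3()
        return np.einsum("mki,mkj->mij", e, e)

    def areas(self) -> np.ndarray:
        e = self.edges3()
        n = np.cross(e[:, :, 0], e[:, :, 1])
        return 0.5 * np.linalg.norm(n, axis=1)

    def normals(self) -> np.ndarray:
        e = self.edges3()
        n = np.cross(e[:, :, 0], e[:, :, 1])
        nn = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.maximum(nn, 1e-300)

    def total_area(self) -> float:
        return float(self.areas().sum())

    def rest_areas(self, surface: str = "a") -> np.ndarray:
        g = self.rest_a if surface == "a" else self.rest_b
        det = g[:, 0, 0] * g[:, 1, 1] - g[:, 0, 1] ** 2
        return 0.5 * np.sqrt(np.maximum(det, 0.0))

    def centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def bbox_extents(self) -> np.ndarray:
        """Axis-aligned bounding-box extents (3,)."""
        return self.vertices.max(axis=0) - self.vertices.min(axis=0)

    def element_thickness(self) -> np.ndarray:
        return self.thickness[self.triangles].mean(axis=1)

    def polarity(self, surface: str = "a") -> tuple[np.ndarray, np.ndarray]:
        """Realised per-element polarity for a surface.

        Returns (directions, defined): (m, 3) unit tangent vectors (zero rows
        where undefined) and the boolean defined mask.
        """
        mat = self.pol_mat_a if surface == "a" else self.pol_mat_b
        defined = self.pol_defined_a if surface == "a" else self.pol_defined_b
        e = self.edges3()
        d = np.einsum("mij,mj->mi", e, mat)
        norm = np.linalg.norm(d, axis=1, keepdims=True)
        ok = defined & (norm[:, 0] > 1e-300)
        out = np.where(ok[:, None], d / np.maximum(norm, 1e-300), 0.0)
        return out, ok

    def set_polarity_from_vectors(
        self, directions: np.ndarray, defined: np.ndarray, surface: str = "a",
        respect_frozen: bool = True,
    ) -> None:
        """Store realised tangent directions as material coordinates."""
        e = self.edges3()
        # least-squares material coords: m = (E^T E)^-1 E^T d
        g = np.einsum("mki,mkj->mij", e, e)
        rhs = np.einsum("mki,mk->mi", e, directions)
        mat = np.linalg.solve(g, rhs[..., None])[..., 0]
        frozen = self.frozen_a if surface == "a" else self.frozen_b
        upd = defined.copy()
        if respect_frozen:
            upd &= ~frozen
        if surface == "a":
            self.pol_mat_a[upd] = mat[upd]
            self.pol_defined_a[upd] = True
            self.pol_defined_a[~defined & ~frozen] = False
        else:
            self.pol_mat_b[upd] = mat[upd]
            self.pol_defined_b[upd] = True
            self.pol_defined_b[~defined & ~frozen] = False

    def copy(self) -> "Canvas":
        c = Canvas(
            vertices=self.vertices.copy(),
            triangles=self.triangles.copy(),
            thickness=self.thickness.copy(),
            factors={k: v.copy() for k, v in self.factors.items()},
            rest_a=self.rest_a.copy(),
            rest_b=self.rest_b.copy(),
            pol_mat_a=self.pol_mat_a.copy(),
            pol_mat_b=self.pol_mat_b.copy(),
            pol_defined_a=self.pol_defined_a.copy(),
            pol_defined_b=self.pol_defined_b.copy(),
            frozen_a=self.frozen_a.copy(),
            frozen_b=self.frozen_b.copy(),
            time=self.time,
            clones=[
                Clone(c_.id, c_.vertices.copy(), c_.elements.copy(),
                      c_.induction_time, c_.initial_radius,
                      None if c_.centre is None else c_.centre.copy())
                for c_ in self.clones
            ],
            pol=None if self.pol is None else self.pol.copy(),
        )
        return c

    def validate(self) -> None:
        if np.any(self.areas() <= 0):
            raise MeshError("degenerate triangle (area <= 0)")
        for g in (self.rest_a, self.rest_b):
            det = g[:, 0, 0] * g[:, 1, 1] - g[:, 0, 1] ** 2
            if np.any(det <= 0) or np.any(g[:, 0, 0] <= 0):
                raise MeshError("rest metric not positive definite")


# ------------------------------------------------------------------ builders


def _grid(nx: int, ny: int, lx: float, ly: float):
    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    tris = []
    for j in range(ny):
        for i in range(nx):
            v00 = j * (nx + 1) + i
            v10 = v00 + 1
            v01 = v00 + (nx + 1)
            v11 = v01 + 1
            # alternate diagonals for symmetry
            if (i + j) % 2 == 0:
                tris.append([v00, v10, v11])
                tris.append([v00, v11, v01])
            else:
                tris.append([v00, v10, v01])
                tris.append([v10, v11, v01])
    return verts, np.asarray(tris, dtype=np.int64)


def make_square_canvas(
    side: float,
    resolution: float | None = None,
    curvature_sagitta: float | None = None,
    z_noise_amplitude: float = 0.0,
    seed: int = 0,
    thickness: float | None = None,
) -> Canvas:
    """Build an initial square canvas, optionally domed and/or z-perturbed.

    ``curvature_sagitta`` is the height of the spherical-cap-like bulge at the
    centre (defaults to 1% of ``side``; pass 0 for a flat start).  Noise is
    uniform per-vertex z displacement in ``[-amp, amp]`` drawn from ``seed``.
    """
    if side <= 0:
        raise MeshError("side must be positive")
    if resolution is None:
        resolution = side * DEFAULT_RESOLUTION_FRAC
    if resolution <= 0 or resolution >= side:
        raise MeshError("resolution must be in (0, side)")
    if curvature_sagitta is None:
        curvature_sagitta = side * DEFAULT_SAGITTA_FRAC
    n = max(2, int(round(side / resolution)))
    verts, tris = _grid(n, n, side, side)
    if curvature_sagitta != 0.0:
        cx = cy = side / 2.0
        r2 = (verts[:, 0] - cx) ** 2 + (verts[:, 1] - cy) ** 2
        rmax2 = 2.0 * (side / 2.0) ** 2  # corner radius
        verts[:, 2] += curvature_sagitta * (1.0 - r2 / rmax2)
    if z_noise_amplitude > 0:
        rng = np.random.default_rng(seed)
        verts[:, 2] += rng.uniform(-z_noise_amplitude, z_noise_amplitude,
                                   size=len(verts))
    if thickness is None:
        thickness = side * DEFAULT_THICKNESS_FRAC
    return Canvas(verts, tris, np.full(len(verts), float(thickness)))


def strip_cap_profile(y: np.ndarray, height: float, sagitta: float) -> np.ndarray:
    """Analytic z-profile of the curved strip (abaxially convex for sag > 0)."""
    yc = height / 2.0
    return -sagitta * (1.0 - ((y - yc) / yc) ** 2)


def make_strip_canvas(
    width: float,
    height: float,
    curvature_sagitta: float | None = None,
    resolution: float | None = None,
    thickness: float | None = None,
) -> Canvas:
    """Build a rectangular strip canvas (long side = ``width`` along x).

    A positive sagitta curves the strip abaxially (bulge toward -z) across its
    short (proximodistal) dimension.
    """
    if width <= 0 or height <= 0:
        raise MeshError("width and height must be positive")
    short = min(width, height)
    if resolution is None:
        resolution = short * DEFAULT_RESOLUTION_FRAC
    if resolution <= 0:
        raise MeshError("resolution must be positive")
    if curvature_sagitta is None:
        curvature_sagitta = short * DEFAULT_SAGITTA_FRAC
    nx = max(2, int(round(width / resolution)))
    ny = max(2, int(round(height / resolution)))
    verts, tris = _grid(nx, ny, width, height)
    if curvature_sagitta != 0.0:
        verts[:, 2] += strip_cap_profile(verts[:, 1], height, curvature_sagitta)
    if thickness is None:
        thickness = short * DEFAULT_THICKNESS_FRAC
    return Canvas(verts, tris, np.full(len(verts), float(thickness)))


# -------------------------------------------------------------------- clones


def induce_clones(
    canvas: Canvas,
    time: float | None = None,
    radius: float = 10.0,
    spacing: float = 50.0,
) -> list[Clone]:
    """Mark a lattice of approximately circular material sectors.

    Clone centres sit on a square lattice with the given spacing; membership
    is by element centroid within ``radius`` of the centre at induction.
    """
    if radius >= spacing:
        raise MeshError("clone radius must be smaller than spacing (overlap)")
    if time is None:
        time = canvas.time
    lo = canvas.vertices.min(axis=0)
    hi = canvas.vertices.max(axis=0)
    xs = np.arange(lo[0] + spacing / 2, hi[0] - radius / 2, spacing)
    ys = np.arange(lo[1] + spacing / 2, hi[1] - radius / 2, spacing)
    cent = canvas.centroids()
    clones: list[Clone] = []
    cid = len(canvas.clones)
    for y in ys:
        for x in xs:
            d2 = (cent[:, 0] - x) ** 2 + (cent[:, 1] - y) ** 2
            elems = np.nonzero(d2 <= radius**2)[0]
            if len(elems) == 0:
                continue
            vids = np.unique(canvas.triangles[elems])
            clones.append(Clone(cid, vids, elems, float(time), radius,
                                centre=np.array([x, y, 0.0])))
            cid += 1
    canvas.clones.extend(clones)
    return clones


def clone_stats(canvas: Canvas, clone: Clone) -> dict[str, float]:
    """Area, principal axes and orientation of a clone.

    Axes are second-moment (standard-deviation) lengths of the area-weighted
    element centroids projected on the clone's best-fit plane; ``orientation``
    is the in-plane angle of the major axis in [0, pi), measured from the
    first plane axis (x for near-flat canvases).
    """
    if len(clone.elements) == 0:
        raise MeshError("empty clone")
    areas = canvas.areas()[clone.elements]
    pts = canvas.centroids()[clone.elements]
    area = float(areas.sum())
    w = areas / area
    mean = (pts * w[:, None]).sum(axis=0)
    x = pts - mean
    # best-fit plane; in-plane reference axis = projected global x (or y)
    cov3 = (x * w[:, None]).T @ x
    evals, evecs = np.linalg.eigh(cov3)
    normal = evecs[:, 0]
    ref = np.array([1.0, 0.0, 0.0])
    a1 = ref - (ref @ normal) * normal
    if np.linalg.norm(a1) < 1e-6:
        ref = np.array([0.0, 1.0, 0.0])
        a1 = ref - (ref @ normal) * normal
    a1 /= np.linalg.norm(a1)
    a2 = np.cross(normal, a1)
    plane = np.column_stack([a1, a2])
    p2 = x @ plane
    cov2 = (p2 * w[:, None]).T @ p2
    ev2, evec2 = np.linalg.eigh(cov2)
    major = 2.0 * float(np.sqrt(max(ev2[1], 0.0)))
    minor = 2.0 * float(np.sqrt(max(ev2[0], 0.0)))
    vmaj = evec2[:, 1]
    ang = float(np.arctan2(vmaj[1], vmaj[0])) % np.pi
    return {
        "area": area,
        "major_axis": major,
        "minor_axis": minor,
        "orientation": ang,
        "major_axis_vector": plane @ vmaj,  # 3-D direction (unit)
        "plane_normal": normal,
        "centroid": mean,
    }


# -------------------------------------------------------------------- remesh


def _edge_map(triangles: np.ndarray) -> dict[tuple[int, int], list[int]]:
    em: dict[tuple[int, int], list[int]] = {}
    for t, tri in enumerate(triangles):
        for a, b in ((0, 1), (1, 2), (2, 0)):
            key = (min(tri[a], tri[b]), max(tri[a], tri[b]))
            em.setdefault(key, []).append(t)
    return em


def remesh(canvas: Canvas, max_edge: float) -> Canvas:
    """Conforming longest-edge bisection until no edge exceeds ``max_edge``.

    Vertex fields are linearly interpolated at edge midpoints; child rest
    metrics are exact algebraic restrictions of the parent's, so geometry and
    integrated rest area are preserved.
    """
    if max_edge <= 0:
        raise MeshError("max_edge must be positive")
    out = canvas
    for _ in range(32):  # bounded refinement passes
        nxt = _bisect_pass(out, max_edge)
        if nxt is None:
            return out
        out = nxt
    return out


def _bisect_pass(canvas: Canvas, max_edge: float) -> Canvas | None:
    v = canvas.vertices
    tris = canvas.triangles
    # edge lengths
    def elen(i, j):
        return np.linalg.norm(v[i] - v[j])

    marked: set[tuple[int, int]] = set()
    for tri in tris:
        for a, b in ((0, 1), (1, 2), (2, 0)):
            i, j = int(tri[a]), int(tri[b])
            if elen(i, j) > max_edge:
                marked.add((min(i, j), max(i, j)))
    if not marked:
        return None
    # propagate: every triangle with a marked edge must have its longest edge
    # marked too (keeps bisection conforming)
    changed = True
    while changed:
        changed = False
        for tri in tris:
            keys = []
            lens = []
            for a, b in ((0, 1), (1, 2), (2, 0)):
                i, j = int(tri[a]), int(tri[b])
                keys.append((min(i, j), max(i, j)))
                lens.append(elen(i, j))
            if any(k in marked for k in keys):
                kmax = keys[int(np.argmax(lens))]
                if kmax not in marked:
                    marked.add(kmax)
                    changed = True

    # create midpoint vertices
    new_vertices = [v]
    midpoint_id: dict[tuple[int, int], int] = {}
    nv = len(v)
    factors = {k: [arr] for k, arr in canvas.factors.items()}
    thick = [canvas.thickness]
    pol = [canvas.pol] if canvas.pol is not None else None
    mids = []
    for (i, j) in sorted(marked):
        midpoint_id[(i, j)] = nv
        nv += 1
        mids.append((i, j))
    if mids:
        ii = np.array([m[0] for m in mids])
        jj = np.array([m[1] for m in mids])
        new_vertices.append(0.5 * (v[ii] + v[jj]))
        thick.append(0.5 * (canvas.thickness[ii] + canvas.thickness[jj]))
        for k, arr in canvas.factors.items():
            factors[k].append(0.5 * (arr[ii] + arr[jj]))
        if pol is not None:
            pol.append(0.5 * (canvas.pol[ii] + canvas.pol[jj]))
    verts = np.vstack(new_vertices)

    # realised polarity (3-D) so it can be re-derived on children
    pdir_a, pdef_a = canvas.polarity("a")
    pdir_b, pdef_b = canvas.polarity("b")

    new_tris: list[list[int]] = []
    new_rest_a: list[np.ndarray] = []
    new_rest_b: list[np.ndarray] = []
    parent_of: list[int] = []

    def restrict(g: np.ndarray, t_mat: np.ndarray) -> np.ndarray:
        return t_mat.T @ g @ t_mat

    for t, tri in enumerate(tris):
        i0, i1, i2 = (int(x) for x in tri)
        local = [(i0, i1), (i1, i2), (i2, i0)]
        keys = [(min(a, b), max(a, b)) for a, b in local]
        mk = [k in midpoint_id for k in keys]
        ga, gb = canvas.rest_a[t], canvas.rest_b[t]

        def emit(a, b, c, bary):
            """Append child triangle (a,b,c) with barycentric corner coords.

            ``bary`` gives each child corner in the parent's edge coordinates
            (u, w) with corner0=(0,0), corner1=(1,0), corner2=(0,1).
            """
            p0, p1, p2 = (np.asarray(p, dtype=float) for p in bary)
            t_mat = np.column_stack([p1 - p0, p2 - p0])
            new_tris.append([a, b, c])
            new_rest_a.append(restrict(ga, t_mat))
            new_rest_b.append(restrict(gb, t_mat))
            parent_of.append(t)

        b0, b1, b2 = (0.0, 0.0), (1.0, 0.0), (0.0, 1.0)
        bm = {0: (0.5, 0.0), 1: (0.5, 0.5), 2: (0.0, 0.5)}
        nmark = sum(mk)
        if nmark == 0:
            emit(i0, i1, i2, (b0, b1, b2))
            continue
        # split along the longest marked edge first, recurse once or twice
        corner = [i0, i1, i2]
        bcoord = [b0, b1, b2]

        def split(cn, bc, depth):
            trio = [(cn[0], cn[1]), (cn[1], cn[2]), (cn[2], cn[0])]
            ks = [(min(a, b), max(a, b)) for a, b in trio]
            present = [k for k in ks if k in midpoint_id]
            if not present or depth > 3:
                emit(cn[0], cn[1], cn[2], tuple(bc))
                return
            lens = [np.linalg.norm(verts[a] - verts[b]) if k in midpoint_id
                    else -1.0 for (a, b), k in zip(trio, ks)]
            s = int(np.argmax(lens))
            k = ks[s]
            mid = midpoint_id[k]
            mb = tuple(0.5 * (np.asarray(bc[s]) + np.asarray(bc[(s + 1) % 3])))
            # two children
            split([cn[s], mid, cn[(s + 2) % 3]],
                  [bc[s], mb, bc[(s + 2) % 3]], depth + 1)
            split([mid, cn[(s + 1) % 3], cn[(s + 2) % 3]],
                  [mb, bc[(s + 1) % 3], bc[(s + 2) % 3]], depth + 1)

        split(corner, bcoord, 0)

    new_canvas = Canvas(
        vertices=verts,
        triangles=np.asarray(new_tris, dtype=np.int64),
        thickness=np.concatenate(thick),
        factors={k: np.concatenate(a) for k, a in factors.items()},
        rest_a=np.asarray(new_rest_a),
        rest_b=np.asarray(new_rest_b),
        time=canvas.time,
        pol=np.concatenate(pol) if pol is not None else None,
    )
    parent = np.asarray(parent_of)
    # carry polarity: children inherit the parent's realised direction
    new_canvas.frozen_a = canvas.frozen_a[parent].copy()
    new_canvas.frozen_b = canvas.frozen_b[parent].copy()
    new_canvas.set_polarity_from_vectors(pdir_a[parent], pdef_a[parent], "a",
                                         respect_frozen=False)
    new_canvas.set_polarity_from_vectors(pdir_b[parent], pdef_b[parent], "b",
                                         respect_frozen=False)
    # clones: elements map to children of member elements
    inv: dict[int, list[int]] = {}
    for child, p in enumerate(parent_of):
        inv.setdefault(p, []).append(child)
    for cl in canvas.clones:
        elems = np.asarray(sorted(
            c for p in cl.elements for c in inv.get(int(p), [])), dtype=np.int64)
        vids = np.unique(new_canvas.triangles[elems]) if len(elems) else \
            np.empty(0, dtype=np.int64)
        new_canvas.clones.append(
            Clone(cl.id, vids, elems, cl.induction_time, cl.initial_radius,
                  cl.centre))
    return new_canvas


# ------------------------------------------------------------------------ IO


def write_ply(canvas: Canvas, path: str | Path, binary: bool = True) -> None:
    """Write the midplane mesh as PLY (binary little-endian by default)."""
    path = Path(path)
    n, m = canvas.n_vertices, canvas.n_triangles
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"element vertex {n}\n"
        "property float x\nproperty float y\nproperty float z\n"
        f"element face {m}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(canvas.vertices.astype("<f4").tobytes())
            for tri in canvas.triangles:
                fh.write(struct.pack("<Biii", 3, *map(int, tri)))
        else:
            for vtx in canvas.vertices:
                fh.write(f"{vtx[0]} {vtx[1]} {vtx[2]}\n".encode())
            for tri in canvas.triangles:
                fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n".encode())


def read_ply(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read vertices and faces from a PLY file written by :func:`write_ply`."""
    with open(path, "rb") as fh:
        data = fh.read()
    head_end = data.index(b"end_header\n") + len(b"end_header\n")
    header = data[:head_end].decode("ascii").splitlines()
    n = m = 0
    binary = False
    for line in header:
        if line.startswith("format binary_little_endian"):
            binary = True
        elif line.startswith("element vertex"):
            n = int(line.split()[-1])
        elif line.startswith("element face"):
            m = int(line.split()[-1])
    if binary:
        body = data[head_end:]
        verts = np.frombuffer(body[: n * 12], dtype="<f4").reshape(n, 3)
        faces = np.empty((m, 3), dtype=np.int64)
        off = n * 12
        for i in range(m):
            cnt, a, b, c = struct.unpack_from("<Biii", body, off)
            faces[i] = (a, b, c)
            off += 13
        return verts.astype(float), faces
    lines = data[head_end:].decode("ascii").split("\n")
    verts = np.array([[float(x) for x in ln.split()] for ln in lines[:n]])
    faces = np.array([[int(x) for x in ln.split()[1:4]]
                      for ln in lines[n: n + m]], dtype=np.int64)
    return verts, faces


def write_obj(canvas: Canvas, path: str | Path) -> None:
    with open(path, "w") as fh:
        for vtx in canvas.vertices:
            fh.write(f"v {vtx[0]} {vtx[1]} {vtx[2]}\n")
        for tri in canvas.triangles:
            fh.write(f"f {tri[0] + 1} {tri[1] + 1} {tri[2] + 1}\n")


def write_factor_csv(canvas: Canvas, path: str | Path) -> None:
    """Per-vertex factor levels keyed by vertex index (sidecar for meshes)."""
    names = sorted(canvas.factors)
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["vertex"] + names)
        for i in range(canvas.n_vertices):
            wr.writerow([i] + [repr(float(canvas.factors[k][i])) for k in names])


def read_factor_csv(path: str | Path) -> dict[str, np.ndarray]:
    with open(path, newline="") as fh:
        rd = csv.reader(fh)
        header = next(rd)
        names = header[1:]
        rows = [[float(x) for x in row[1:]] for row in rd]
    arr = np.asarray(rows)
    return {k: arr[:, i].copy() for i, k in enumerate(names)}
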