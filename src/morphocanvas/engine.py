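"""Turn specified growth into resultant deformation, and quantify conflict.

Mechanics: the canvas is a two-layer discrete shell.  Each triangle carries
independent rest metrics for its A (+z at construction) and B surfaces.  The
elastic energy is a St-Venant-Kirchhoff membrane term per surface (evaluated
against the realised midplane metric) plus a hinge bending term whose
preferred dihedral angles derive from the A/B rest-metric difference, so
differential surface growth induces spontaneous curvature.  Quasi-static
relaxation minimises this energy after every growth increment.

Only energy ratios matter for the quasi-static shapes; the modulus is 1 and
the Poisson-type coupling is 0.3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .mesh import Canvas

__all__ = [
    "ElasticParams",
    "derived_rates",
    "grow_rest_metrics",
    "relax",
    "step",
    "elastic_energy",
    "resultant_tensor",
    "conflict_report",
    "ResultantGrowth",
    "mean_curvature_sign",
]

# Display clamp for specified anisotropy (colour scale -1 .. +1).
KANISO_CLAMP = 1.0

# Orientation of the discrete dihedral relative to the continuum curvature
# convention used for the rest-metric difference (calibrated against an
# analytic paraboloid; see tests).
_THETA_SIGN = -1.0


@dataclass
class ElasticParams:
    modulus: float = 1.0
    nu: float = 0.3
    bending_scale: float = 1.0

    @property
    def mu(self) -> float:
        return self.modulus / (2.0 * (1.0 + self.nu))

    @property
    def lam(self) -> float:
        return self.modulus * self.nu / (1.0 - self.nu**2)


def derived_rates(kpar, kper) -> dict[str, np.ndarray]:
    """Specified anisotropy and areal rate: Kaniso = ln(Kpar/Kper) clamped to
    [-1, 1] for display; Karea = Kpar + Kper."""
    kpar = np.asarray(kpar, dtype=float)
    kper = np.asarray(kper, dtype=float)
    tiny = 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.maximum(kpar, tiny) / np.maximum(kper, tiny)
        kaniso = np.clip(np.log(ratio), -KANISO_CLAMP, KANISO_CLAMP)
    return {"Kaniso": kaniso, "Karea": kpar + kper}


# ------------------------------------------------------------------- algebra


def _chol2(g: np.ndarray) -> np.ndarray:
    """Vectorised lower Cholesky of (m, 2, 2) SPD matrices: g = L @ L.T."""
    a = g[:, 0, 0]
    b = g[:, 0, 1]
    c = g[:, 1, 1]
    sa = np.sqrt(a)
    out = np.zeros_like(g)
    out[:, 0, 0] = sa
    out[:, 1, 0] = b / sa
    out[:, 1, 1] = np.sqrt(np.maximum(c - b * b / a, 1e-300))
    return out


def _inv2(m: np.ndarray) -> np.ndarray:
    det = m[..., 0, 0] * m[..., 1, 1] - m[..., 0, 1] * m[..., 1, 0]
    out = np.empty_like(m)
    out[..., 0, 0] = m[..., 1, 1]
    out[..., 1, 1] = m[..., 0, 0]
    out[..., 0, 1] = -m[..., 0, 1]
    out[..., 1, 0] = -m[..., 1, 0]
    return out / det[..., None, None]


# ------------------------------------------------------------ hinge topology


def _build_hinges(triangles: np.ndarray) -> dict[str, np.ndarray]:
    """Interior edges with their two triangles and opposite vertices.

    For each hinge: v0, v1 (edge endpoints, as ordered CCW in t1), v2
    (opposite vertex in t1), v3 (opposite vertex in t2), t1, t2.
    """
    edge_owner: dict[tuple[int, int], tuple[int, int]] = {}
    rows = []
    for t, tri in enumerate(triangles):
        for k in range(3):
            a, b = int(tri[k]), int(tri[(k + 1) % 3])
            c = int(tri[(k + 2) % 3])
            key = (min(a, b), max(a, b))
            if key in edge_owner:
                (t1, v2, a1, b1) = edge_owner.pop(key)
                rows.append((a1, b1, v2, c, t1, t))
            else:
                edge_owner[key] = (t, c, a, b)
    if not rows:
        return {k: np.empty(0, dtype=np.int64)
                for k in ("v0", "v1", "v2", "v3", "t1", "t2")}
    arr = np.asarray(rows, dtype=np.int64)
    return {"v0": arr[:, 0], "v1": arr[:, 1], "v2": arr[:, 2],
            "v3": arr[:, 3], "t1": arr[:, 4], "t2": arr[:, 5]}


def dihedral_angles(x: np.ndarray, h: dict[str, np.ndarray]):
    """Signed dihedral angle per hinge, plus geometry reused by the gradient."""
    e = x[h["v1"]] - x[h["v0"]]
    n1 = np.cross(e, x[h["v2"]] - x[h["v0"]])
    n2 = np.cross(x[h["v3"]] - x[h["v0"]], e)
    elen = np.linalg.norm(e, axis=1)
    n1n = np.linalg.norm(n1, axis=1)
    n2n = np.linalg.norm(n2, axis=1)
    ehat = e / np.maximum(elen, 1e-300)[:, None]
    n1h = n1 / np.maximum(n1n, 1e-300)[:, None]
    n2h = n2 / np.maximum(n2n, 1e-300)[:, None]
    sin_t = np.einsum("ij,ij->i", np.cross(n1h, n2h), ehat)
    cos_t = np.einsum("ij,ij->i", n1h, n2h)
    theta = np.arctan2(sin_t, cos_t)
    return theta, (e, elen, ehat, n1, n1n, n2, n2n)


def _dihedral_grad_accum(x, h, dtheta, geom, grad):
    """Accumulate d(sum w_i * theta_i)/dx into grad, given per-hinge weights."""
    e, elen, ehat, n1, n1n, n2, n2n = geom
    inv_n1 = n1 / np.maximum(n1n, 1e-300)[:, None] ** 2 * \
        np.maximum(n1n, 1e-300)[:, None]  # == n1/|n1|^2 (kept explicit below)
    n1_f = n1 / np.maximum(n1n**2, 1e-300)[:, None]
    n2_f = n2 / np.maximum(n2n**2, 1e-300)[:, None]
    x0 = x[h["v0"]]
    x1 = x[h["v1"]]
    x2 = x[h["v2"]]
    x3 = x[h["v3"]]
    a0 = -np.einsum("ij,ij->i", x2 - x1, ehat)
    b0 = -np.einsum("ij,ij->i", x3 - x1, ehat)
    a1 = np.einsum("ij,ij->i", x2 - x0, ehat)
    b1 = np.einsum("ij,ij->i", x3 - x0, ehat)
    g0 = (a0[:, None] * n1_f + b0[:, None] * n2_f) * dtheta[:, None]
    g1 = (a1[:, None] * n1_f + b1[:, None] * n2_f) * dtheta[:, None]
    g2 = -elen[:, None] * n1_f * dtheta[:, None]
    g3 = -elen[:, None] * n2_f * dtheta[:, None]
    np.add.at(grad, h["v0"], g0)
    np.add.at(grad, h["v1"], g1)
    np.add.at(grad, h["v2"], g2)
    np.add.at(grad, h["v3"], g3)


# -------------------------------------------------------------------- energy


class _Elastic:
    """Precomputed elastic assembly for a fixed canvas topology/rest state."""

    def __init__(self, canvas: Canvas, params: ElasticParams):
        self.params = params
        self.tris = canvas.triangles
        self.n = canvas.n_vertices
        h_el = canvas.element_thickness()
        self.h_el = h_el
        self.linv_a = _inv2(_chol2(canvas.rest_a))
        self.linv_b = _inv2(_chol2(canvas.rest_b))
        self.area_a = canvas.rest_areas("a")
        self.area_b = canvas.rest_areas("b")
        self.w_a = self.area_a * h_el / 2.0
        self.w_b = self.area_b * h_el / 2.0

        self.hinges = _build_hinges(self.tris)
        self._bending_setup(canvas)

    def _bending_setup(self, canvas: Canvas) -> None:
        h = self.hinges
        if len(h["v0"]) == 0:
            self.k_hinge = np.empty(0)
            self.theta_bar = np.empty(0)
            return
        p = self.params
        abar = 0.5 * (canvas.rest_a + canvas.rest_b)
        bbar = (canvas.rest_b - canvas.rest_a) / \
            (2.0 * self.h_el[:, None, None])
        lbar = _chol2(abar)
        lbar_inv = _inv2(lbar)
        # b in rest-orthonormal coordinates
        bhat = np.einsum("mij,mjk,mlk->mil", lbar_inv, bbar, lbar_inv)
        det = abar[:, 0, 0] * abar[:, 1, 1] - abar[:, 0, 1] ** 2
        area_bar = 0.5 * np.sqrt(np.maximum(det, 1e-300))

        theta_bar = np.zeros(len(h["v0"]))
        spacing = np.zeros(len(h["v0"]))
        area_sum = np.zeros(len(h["v0"]))
        kappa = np.zeros(len(h["v0"]))
        for side, tkey in (("1", "t1"), ("2", "t2")):
            t = h[tkey]
            tri = self.tris[t]
            # material coords of the hinge edge in the triangle edge basis
            u = np.zeros((len(t), 2))
            for k, (va, vb) in enumerate(
                    ((0, 1), (1, 2), (2, 0))):
                basis = {(0, 1): (1.0, 0.0), (1, 2): (-1.0, 1.0),
                         (2, 0): (0.0, -1.0)}[(va, vb)]
                fwd = (tri[:, va] == h["v0"]) & (tri[:, vb] == h["v1"])
                rev = (tri[:, va] == h["v1"]) & (tri[:, vb] == h["v0"])
                u[fwd] = basis
                u[rev] = [-basis[0], -basis[1]]
            uhat = np.einsum("mji,mj->mi", lbar[t], u)  # L^T u
            ulen = np.linalg.norm(uhat, axis=1)
            uhat = uhat / np.maximum(ulen, 1e-300)[:, None]
            nhat = np.stack([-uhat[:, 1], uhat[:, 0]], axis=-1)
            kap = np.einsum("mi,mij,mj->m", nhat, bhat[t], nhat)
            hgt = 2.0 * area_bar[t] / np.maximum(ulen, 1e-300)
            kappa += 0.5 * kap
            spacing += hgt / 3.0
            area_sum += area_bar[t] / 3.0
        h_edge = 0.5 * (self.h_el[h["t1"]] + self.h_el[h["t2"]])
        dstiff = p.bending_scale * p.modulus * h_edge**3 / \
            (12.0 * (1.0 - p.nu**2))
        self.k_hinge = dstiff * area_sum / np.maximum(spacing, 1e-300) ** 2
        self.theta_bar = _THETA_SIGN * kappa * spacing

    # -- evaluation

    def energy_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        p = self.params
        tris = self.tris
        v = x[tris]
        e1 = v[:, 1] - v[:, 0]
        e2 = v[:, 2] - v[:, 0]
        emat = np.stack([e1, e2], axis=-1)  # (m, 3, 2)
        c = np.einsum("mki,mkj->mij", emat, emat)
        energy = 0.0
        grad = np.zeros_like(x)
        eye = np.eye(2)
        for linv, wgt in ((self.linv_a, self.w_a), (self.linv_b, self.w_b)):
            chat = np.einsum("mij,mjk,mlk->mil", linv, c, linv)
            strain = 0.5 * (chat - eye)
            tr = strain[:, 0, 0] + strain[:, 1, 1]
            sq = np.einsum("mij,mij->m", strain, strain)
            wdens = p.mu * sq + 0.5 * p.lam * tr**2
            energy += float(np.sum(wdens * wgt))
            dw_dstrain = 2.0 * p.mu * strain + \
                p.lam * tr[:, None, None] * eye
            dw_dc = 0.5 * np.einsum("mji,mjk,mkl->mil",
                                    linv, dw_dstrain, linv)
            ge = 2.0 * np.einsum("mki,mij->mkj", emat, dw_dc) * \
                wgt[:, None, None]
            g1 = ge[:, :, 0]
            g2 = ge[:, :, 1]
            np.add.at(grad, tris[:, 0], -(g1 + g2))
            np.add.at(grad, tris[:, 1], g1)
            np.add.at(grad, tris[:, 2], g2)

        if len(self.k_hinge):
            theta, geom = dihedral_angles(x, self.hinges)
            dth = theta - self.theta_bar
            energy += float(0.5 * np.sum(self.k_hinge * dth**2))
            _dihedral_grad_accum(x, self.hinges, self.k_hinge * dth,
                                 geom, grad)
        return energy, grad


def elastic_energy(canvas: Canvas,
                   params: ElasticParams | None = None) -> float:
    """Total elastic energy of the canvas in its current configuration."""
    params = params or ElasticParams()
    asm = _Elastic(canvas, params)
    e, _ = asm.energy_grad(canvas.vertices)
    return e


def relax(
    canvas: Canvas,
    tol: float = 1e-6,
    max_iter: int = 2000,
    params: ElasticParams | None = None,
) -> dict:
    """Quasi-static relaxation: minimise elastic energy over vertex positions.

    Uses L-BFGS with line search (energy is non-increasing across accepted
    iterates).  ``tol`` is the relative energy-change stopping criterion.
    Returns an info dict with the energy history; warns (and keeps the best
    state) on non-convergence.
    """
    params = params or ElasticParams()
    asm = _Elastic(canvas, params)
    x0 = canvas.vertices.ravel().copy()
    history: list[float] = []
    scale = max(canvas.total_area() * float(np.mean(canvas.thickness)), 1e-12)

    def fun(flat: np.ndarray):
        e, g = asm.energy_grad(flat.reshape(-1, 3))
        return e / scale, (g / scale).ravel()

    def cb(flat: np.ndarray):
        history.append(fun(flat)[0])

    res = minimize(fun, x0, jac=True, method="L-BFGS-B", callback=cb,
                   options={"maxiter": max_iter, "ftol": tol * 1e-3,
                            "gtol": 1e-10, "maxcor": 20})
    canvas.vertices = res.x.reshape(-1, 3)
    if not res.success and res.status != 1:  # status 1 = maxiter
        warnings.warn(f"relaxation did not converge: {res.message}")
    if res.status == 1:
        warnings.warn("relaxation stopped at max_iter; keeping best state")
    return {"energy": res.fun * scale, "n_iter": res.nit,
            "converged": bool(res.success),
            "history": [e * scale for e in history]}


# -------------------------------------------------------------------- growth


def grow_rest_metrics(canvas: Canvas, rates: dict[str, np.ndarray],
                      dt: float) -> Canvas:
    """Update rest metrics by exponential specified growth over ``dt`` hours.

    ``rates`` holds per-element arrays ``kpar_a, kper_a, kpar_b, kper_b`` and
    a per-vertex (or scalar) ``knor``.  Growth is applied as the stretch
    ``exp(dt*K)`` along the surface's polarity (Kpar) and perpendicular to it
    (Kper) in the rest configuration; thickness grows by ``exp(knor*dt)``.
    Elements with undefined polarity grow isotropically at the mean rate; if
    no polarity exists anywhere while growth is anisotropic, this is an error.
    """
    m = canvas.n_triangles
    for surf in ("a", "b"):
        kpar = np.broadcast_to(
            np.asarray(rates[f"kpar_{surf}"], dtype=float), (m,))
        kper = np.broadcast_to(
            np.asarray(rates[f"kper_{surf}"], dtype=float), (m,))
        g = canvas.rest_a if surf == "a" else canvas.rest_b
        mat = canvas.pol_mat_a if surf == "a" else canvas.pol_mat_b
        defined = (canvas.pol_defined_a if surf == "a"
                   else canvas.pol_defined_b)
        aniso = np.abs(kpar - kper) > 1e-12
        if np.any(aniso & ~defined):
            if not np.any(defined):
                bad = int(np.nonzero(aniso)[0][0])
                raise ValueError(
                    f"anisotropic specified growth but no polarity defined "
                    f"(element {bad}, surface {surf.upper()})")
            # isolated degenerate-gradient elements grow isotropically
            kmean = 0.5 * (kpar + kper)
            kpar = np.where(defined, kpar, kmean)
            kper = np.where(defined, kper, kmean)
        lmat = _chol2(g)
        what = np.einsum("mji,mj->mi", lmat, mat)  # L^T m
        nrm = np.linalg.norm(what, axis=1)
        ok = defined & (nrm > 1e-300)
        what = np.where(ok[:, None], what / np.maximum(nrm, 1e-300)[:, None],
                        np.array([1.0, 0.0]))
        ep = np.exp(2.0 * kpar * dt)
        eq = np.exp(2.0 * kper * dt)
        ww = np.einsum("mi,mj->mij", what, what)
        eye = np.eye(2)
        ghat = eq[:, None, None] * (eye - ww) + ep[:, None, None] * ww
        gnew = np.einsum("mij,mjk,mlk->mil", lmat, ghat, lmat)
        gnew = 0.5 * (gnew + np.swapaxes(gnew, 1, 2))
        if surf == "a":
            canvas.rest_a = gnew
        else:
            canvas.rest_b = gnew
    knor = np.asarray(rates.get("knor", 0.0), dtype=float)
    canvas.thickness = canvas.thickness * np.exp(
        np.broadcast_to(knor, (canvas.n_vertices,)) * dt)
    return canvas


def step(
    canvas: Canvas,
    model,
    dt: float = 1.0,
    params: ElasticParams | None = None,
    relax_tol: float = 1e-6,
    relax_max_iter: int = 800,
) -> Canvas:
    """Advance the simulation by ``dt``: events, polarity, growth, relaxation.

    ``model`` provides ``apply_events(canvas, t0, t1)``,
    ``update_polarity(canvas)`` and ``rates(canvas) -> dict``.
    """
    t0 = canvas.time
    t1 = t0 + dt
    model.apply_events(canvas, t0, t1)
    model.update_polarity(canvas)
    rates = model.rates(canvas)
    grow_rest_metrics(canvas, rates, dt)
    relax(canvas, tol=relax_tol, max_iter=relax_max_iter, params=params)
    canvas.time = t1
    return canvas


# --------------------------------------------------- growth-tensor analysis


@dataclass
class ResultantGrowth:
    """Strain/rotation decomposition of a deformation step for one element."""

    strain_rate: np.ndarray       # (2, 2) symmetric, in the t0 tangent basis
    rotation_rate: float          # total rotation magnitude, rad / h
    rotation_inplane: float       # rad / h
    rotation_outofplane: float    # rad / h
    deformation: np.ndarray = field(default=None)  # (3, 2) map, t0 coords


def _tangent_basis(e1: np.ndarray, e2: np.ndarray) -> np.ndarray:
    q1 = e1 / np.linalg.norm(e1)
    nrm = np.cross(e1, e2)
    nrm = nrm / np.linalg.norm(nrm)
    q2 = np.cross(nrm, q1)
    return np.column_stack([q1, q2, nrm])  # (3, 3), first two span tangent


def _sqrtm_spd2(m: np.ndarray) -> np.ndarray:
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    s = np.sqrt(max(det, 0.0))
    t = np.sqrt(max(m[0, 0] + m[1, 1] + 2.0 * s, 1e-300))
    return (m + s * np.eye(2)) / t


def _logm_spd2(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    return v @ np.diag(np.log(np.maximum(w, 1e-300))) @ v.T


def resultant_tensor(canvas0: Canvas, canvas1: Canvas, element: int,
                     dt: float) -> ResultantGrowth:
    """Polar-decompose the deformation of one element over a step.

    The deformation gradient maps the element's t0 tangent plane into 3-D;
    its symmetric factor gives the strain rate (log-stretch / dt) and its
    orthogonal factor the local rotation (in-plane + out-of-plane tilt).
    """
    tri0 = canvas0.triangles[element]
    tri1 = canvas1.triangles[element]
    v0 = canvas0.vertices[tri0]
    v1 = canvas1.vertices[tri1]
    e0 = np.stack([v0[1] - v0[0], v0[2] - v0[0]], axis=-1)  # (3, 2)
    e1 = np.stack([v1[1] - v1[0], v1[2] - v1[0]], axis=-1)
    if np.linalg.norm(np.cross(e0[:, 0], e0[:, 1])) < 1e-300:
        raise ValueError(f"degenerate element {element}")
    q0 = _tangent_basis(e0[:, 0], e0[:, 1])
    m0 = q0[:, :2].T @ e0  # (2, 2) coordinates of t0 edges in t0 basis
    if abs(np.linalg.det(m0)) < 1e-300:
        raise ValueError(f"degenerate element {element}")
    f3 = e1 @ np.linalg.inv(m0)  # (3, 2): t0 tangent coords -> 3-D
    c = f3.T @ f3
    u = _sqrtm_spd2(c)
    r3 = f3 @ np.linalg.inv(u)  # (3, 2) orthonormal columns
    strain_rate = _logm_spd2(u) / dt
    # full rotation taking the t0 frame (q0) to (r3, r3_normal)
    n1 = np.cross(r3[:, 0], r3[:, 1])
    rot = np.column_stack([r3, n1]) @ q0.T  # 3x3 rotation
    cos_tot = np.clip((np.trace(rot) - 1.0) / 2.0, -1.0, 1.0)
    total = float(np.arccos(cos_tot))
    cos_oop = np.clip(rot[2, 2] if False else float(n1 @ q0[:, 2]), -1.0, 1.0)
    oop = float(np.arccos(cos_oop))
    # in-plane part: rotation of tangent directions about the normal
    r2 = q0[:, :2].T @ r3
    inp = float(np.arctan2(r2[1, 0] - r2[0, 1], r2[0, 0] + r2[1, 1]))
    return ResultantGrowth(
        strain_rate=strain_rate,
        rotation_rate=total / dt,
        rotation_inplane=inp / dt,
        rotation_outofplane=oop / dt,
        deformation=f3,
    )


def specified_strain_rate(canvas: Canvas, element: int,
                          rates: dict[str, np.ndarray]) -> np.ndarray:
    """Specified (surface-averaged) strain-rate tensor of an element, in the
    same t0 tangent basis used by :func:`resultant_tensor`."""
    tri = canvas.triangles[element]
    v = canvas.vertices[tri]
    e0 = np.stack([v[1] - v[0], v[2] - v[0]], axis=-1)
    q0 = _tangent_basis(e0[:, 0], e0[:, 1])
    kpar = 0.5 * (np.atleast_1d(rates["kpar_a"])[
        min(element, np.size(rates["kpar_a"]) - 1)] +
        np.atleast_1d(rates["kpar_b"])[
        min(element, np.size(rates["kpar_b"]) - 1)])
    kper = 0.5 * (np.atleast_1d(rates["kper_a"])[
        min(element, np.size(rates["kper_a"]) - 1)] +
        np.atleast_1d(rates["kper_b"])[
        min(element, np.size(rates["kper_b"]) - 1)])
    dirs, ok = canvas.polarity("a")
    if ok[element]:
        p3 = dirs[element]
        p2 = q0[:, :2].T @ p3
        p2 = p2 / np.linalg.norm(p2)
    else:
        kmean = 0.5 * (kpar + kper)
        kpar = kper = kmean
        p2 = np.array([1.0, 0.0])
    pp = np.outer(p2, p2)
    return kpar * pp + kper * (np.eye(2) - pp)


def conflict_report(
    canvas0: Canvas,
    canvas1: Canvas,
    rates: dict[str, np.ndarray],
    dt: float,
) -> dict[str, np.ndarray]:
    """Per-element conflict summary over a completed step.

    residual strain = || resultant strain rate - specified strain rate ||_F;
    rotation magnitude >= 0; Kaniso / Karea from the specified rates.
    """
    m = canvas0.n_triangles
    residual = np.zeros(m)
    rotation = np.zeros(m)
    for el in range(m):
        res = resultant_tensor(canvas0, canvas1, el, dt)
        spec = specified_strain_rate(canvas0, el, rates)
        residual[el] = np.linalg.norm(res.strain_rate - spec)
        rotation[el] = res.rotation_rate
    kpar = 0.5 * (np.broadcast_to(rates["kpar_a"], (m,)) +
                  np.broadcast_to(rates["kpar_b"], (m,)))
    kper = 0.5 * (np.broadcast_to(rates["kper_a"], (m,)) +
                  np.broadcast_to(rates["kper_b"], (m,)))
    der = derived_rates(kpar, kper)
    return {
        "residual_strain_norm": residual,
        "rotation_magnitude": rotation,
        "Kaniso": der["Kaniso"],
        "Karea": der["Karea"],
    }


def mean_curvature_sign(canvas: Canvas) -> np.ndarray:
    """Per-interior-hinge sign of the dihedral (a proxy for mean-curvature
    sign; positive where the sheet is convex toward +z for upward normals)."""
    hinges = _build_hinges(canvas.triangles)
    theta, _ = dihedral_angles(canvas.vertices, hinges)
    return np.sign(theta)
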