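"""Executable catalogue of the tissue-conflict models.

Each entry bundles an initial-canvas recipe, declarative factor-domain
recipes, a polariser configuration, a phase schedule of growth-network
expression strings, scheduled events, and ablation variants.  Expression
strings are stored verbatim (modulo unicode operator normalisation) so they
serialise token-for-token.

Conventions: rates are fractional per hour; model times are hours
(1 DAI = 24 h).  The per-surface expressions are evaluated in the order
kparb, kpara, kperb, kpera, with earlier results available as variables.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field as dfield

import numpy as np

from . import engine, fields, mesh

__all__ = [
    "ModelConfig",
    "Phase",
    "get_model",
    "list_models",
    "ablate",
    "run_model",
    "AREAL_NORMALISATION_CONSTANT",
]

# multiplying factor of the no-areal-conflict normalisation (printed value)
AREAL_NORMALISATION_CONSTANT = 0.025

_RATE_ORDER = ("kparb", "kpara", "kperb", "kpera")


@dataclass
class Phase:
    t_start: float
    t_end: float
    exprs: dict[str, str]  # kparb/kpara/kperb/kpera (or kpar/kper) + knor

    def rate_exprs(self) -> dict[str, str]:
        out = dict(self.exprs)
        if "kpar" in out:
            out.setdefault("kparb", out["kpar"])
            out.setdefault("kpara", out["kpar"])
        if "kper" in out:
            out.setdefault("kperb", out["kper"])
            out.setdefault("kpera", out["kper"])
        return out


@dataclass
class ModelConfig:
    name: str
    canvas: dict
    factors: list[dict] = dfield(default_factory=list)
    polariser: dict | None = None
    phases: list[Phase] = dfield(default_factory=list)
    events: list[dict] = dfield(default_factory=list)
    ablations: dict[str, dict] = dfield(default_factory=dict)
    normalise_area: float | None = None
    isotropise: bool = False
    description: str = ""

    # ------------------------------------------------------------- validation

    def validate(self) -> None:
        names = {f["name"].lower() for f in self.factors}
        names |= set(_RATE_ORDER) | {"kpar", "kper"}
        for ph in self.phases:
            for expr in ph.rate_exprs().values():
                tree = fields.parse_expr(expr)
                for ref in _collect_vars(tree):
                    if ref.lower() not in names:
                        raise ValueError(
                            f"{self.name}: factor {ref!r} not defined")
        for a, b in zip(self.phases, self.phases[1:]):
            if abs(a.t_end - b.t_start) > 1e-9:
                raise ValueError(f"{self.name}: phases not contiguous")

    @property
    def t_start(self) -> float:
        return self.phases[0].t_start

    @property
    def t_end(self) -> float:
        return self.phases[-1].t_end

    # ------------------------------------------------------------------ build

    def build_canvas(self, resolution: float | None = None,
                     seed: int = 0) -> mesh.Canvas:
        spec = dict(self.canvas)
        kind = spec.pop("kind")
        if kind == "square":
            canvas = mesh.make_square_canvas(
                side=spec["side"], resolution=resolution,
                curvature_sagitta=spec.get("sagitta"),
                z_noise_amplitude=spec.get("noise", 0.0), seed=seed)
        elif kind == "strip":
            canvas = mesh.make_strip_canvas(
                width=spec["width"], height=spec["height"],
                curvature_sagitta=spec.get("sagitta"), resolution=resolution)
        else:
            raise ValueError(f"unknown canvas kind {kind!r}")
        canvas.time = self.t_start
        _setup_factors(canvas, self.factors)
        canvas.fired_events = set()  # type: ignore[attr-defined]
        if self.polariser is not None:
            self._polariser_state(canvas)
            self.update_polarity(canvas)
        return canvas

    def _polariser_state(self, canvas) -> fields.PolariserState:
        cfg = self.polariser or {}
        short = float(min(canvas.bbox_extents()[:2]))
        state = getattr(canvas, "_pol_state", None)
        if state is None:
            state = fields.PolariserState(
                production={cfg["production"]: 1.0} if "production" in cfg
                else {},
                degradation={cfg["degradation"]: 1.0} if "degradation" in cfg
                else {},
                fixed={k: v for k, v in cfg.get("fixed", {}).items()},
                diffusion_length=cfg.get("length_frac", 0.5) * short,
            )
            canvas._pol_state = state  # type: ignore[attr-defined]
        return state

    # ------------------------------------------- model protocol (engine.step)

    def apply_events(self, canvas, t0: float, t1: float) -> None:
        fired = getattr(canvas, "fired_events", None)
        if fired is None:
            fired = canvas.fired_events = set()  # type: ignore
        for i, ev in enumerate(self.events):
            if i in fired or not (t0 <= ev["t"] < t1):
                continue
            fired.add(i)
            kind = ev["kind"]
            if kind == "induce_clones":
                mesh.induce_clones(canvas, time=ev["t"],
                                   radius=ev.get("radius", 10.0),
                                   spacing=ev.get("spacing", 50.0))
            elif kind == "freeze_polarity":
                surf = ev.get("surface", "ab")
                if "a" in surf:
                    canvas.frozen_a[:] = True
                if "b" in surf:
                    canvas.frozen_b[:] = True
            elif kind == "add_sink":
                state = self._polariser_state(canvas)
                state.degradation[ev["factor"]] = ev.get("weight", 1.0)
            elif kind == "lock_channel":
                fields.lock_polarity_channel(
                    canvas, canvas.factors[ev["region"]],
                    surfaces=ev.get("surfaces", "ab"))
            elif kind == "set_polariser":
                state = self._polariser_state(canvas)
                if "production" in ev:
                    state.production = dict(ev["production"])
                if "degradation" in ev:
                    state.degradation = dict(ev["degradation"])
            else:
                raise ValueError(f"unknown event kind {kind!r}")

    def update_polarity(self, canvas) -> None:
        if self.polariser is None:
            return
        state = self._polariser_state(canvas)
        fields.update_polariser(canvas, state)

    def phase_at(self, t: float) -> Phase:
        for ph in self.phases:
            if ph.t_start - 1e-9 <= t < ph.t_end - 1e-9:
                return ph
        if abs(t - self.t_end) < 1e-6:
            return self.phases[-1]
        raise ValueError(f"{self.name}: no phase covers t={t}")

    def rate_fields(self, factor_levels: dict, t: float) -> dict[str, object]:
        """Evaluate the phase's expressions over arbitrary factor levels."""
        ph = self.phase_at(t)
        exprs = ph.rate_exprs()
        env = {k.lower(): v for k, v in factor_levels.items()}
        out: dict[str, object] = {}
        for key in _RATE_ORDER:
            val = fields.eval_expr(exprs[key], env)
            env[key] = val
            out[key] = val
        out["knor"] = fields.eval_expr(exprs.get("knor", "0"), env)
        return out

    def rates(self, canvas) -> dict[str, np.ndarray]:
        vals = self.rate_fields(canvas.factors, canvas.time)
        n = canvas.n_vertices
        tris = canvas.triangles

        def per_element(v) -> np.ndarray:
            arr = np.broadcast_to(np.asarray(v, dtype=float), (n,))
            return arr[tris].mean(axis=1)

        kpar_a = per_element(vals["kpara"])
        kper_a = per_element(vals["kpera"])
        kpar_b = per_element(vals["kparb"])
        kper_b = per_element(vals["kperb"])
        if self.isotropise:
            mean_a = 0.5 * (kpar_a + kper_a)
            mean_b = 0.5 * (kpar_b + kper_b)
            kpar_a = kper_a = mean_a
            kpar_b = kper_b = mean_b
        if self.normalise_area is not None:
            kpar_a, kper_a = _normalise(kpar_a, kper_a, self.normalise_area)
            kpar_b, kper_b = _normalise(kpar_b, kper_b, self.normalise_area)
        knor = np.broadcast_to(
            np.asarray(vals["knor"], dtype=float), (n,)).copy()
        return {"kpar_a": kpar_a, "kper_a": kper_a,
                "kpar_b": kpar_b, "kper_b": kper_b, "knor": knor}

    # --------------------------------------------------------- serialisation

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "canvas": self.canvas,
            "factors": self.factors,
            "polariser": self.polariser,
            "phases": [{"t_start": p.t_start, "t_end": p.t_end,
                        "exprs": p.exprs} for p in self.phases],
            "events": self.events,
            "ablations": self.ablations,
            "normalise_area": self.normalise_area,
            "isotropise": self.isotropise,
            "description": self.description,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["phases"] = [Phase(p["t_start"], p["t_end"], p["exprs"])
                       for p in d["phases"]]
        return cls(**d)


def _collect_vars(tree) -> set[str]:
    out = set()
    stack = [tree]
    while stack:
        node = stack.pop()
        if isinstance(node, fields.Var):
            out.add(node.name)
        for attr in ("left", "right", "arg", "amount", "value"):
            child = getattr(node, attr, None)
            if isinstance(child, fields.Expr):
                stack.append(child)
    return out


def _normalise(kpar: np.ndarray, kper: np.ndarray, c: float):
    """Printed areal normalisation: Kpar' = c*Kpar/Karea, Kper' = c*Kper/Karea;
    elements with Karea = 0 get c/2 each (flagged with a warning)."""
    karea = kpar + kper
    zero = np.abs(karea) < 1e-12
    if np.any(zero):
        warnings.warn(f"areal normalisation: {int(zero.sum())} points with "
                      "Karea=0 set to c/2 each")
    safe = np.where(zero, 1.0, karea)
    kpar2 = np.where(zero, c / 2.0, c * kpar / safe)
    kper2 = np.where(zero, c / 2.0, c * kper / safe)
    return kpar2, kper2


# ----------------------------------------------------------- factor recipes


def _setup_factors(canvas: mesh.Canvas, recipes: list[dict]) -> None:
    v = canvas.vertices
    lo = v.min(axis=0)
    ext = np.maximum(v.max(axis=0) - lo, 1e-12)
    x = (v[:, 0] - lo[0]) / ext[0]   # fractional coordinates
    y = (v[:, 1] - lo[1]) / ext[1]
    short = float(min(ext[0], ext[1]))

    def ensure_nonempty(arr, target_x=None, target_y=None):
        """Coarse meshes may miss a small region; include the nearest vertex."""
        if arr.sum() > 0:
            return arr
        d = np.zeros(len(v))
        if target_x is not None:
            d += (x - target_x) ** 2
        if target_y is not None:
            d += (y - target_y) ** 2
        arr[np.argmin(d)] = 1.0
        return arr

    for rec in recipes:
        kind = rec["kind"]
        name = rec["name"]
        if kind == "uniform":
            arr = np.full(len(v), float(rec.get("level", 1.0)))
        elif kind == "stripe":
            c = rec.get("center", 0.5)
            w = rec.get("width", 0.1)
            axis_x = rec.get("axis", "x") == "x"
            coord = x if axis_x else y
            arr = (np.abs(coord - c) <= w / 2).astype(float)
            arr = ensure_nonempty(arr, c if axis_x else None,
                                  None if axis_x else c)
        elif kind == "stripe_gauss":
            c = rec.get("center", 0.5)
            sigma = rec.get("sigma", 0.05)
            coord = x if rec.get("axis", "x") == "x" else y
            arr = np.exp(-((coord - c) / sigma) ** 2)
        elif kind == "halfplane":
            coord = x if rec.get("axis", "x") == "x" else y
            at = rec.get("at", 0.5)
            arr = ((coord > at) if rec.get("op", ">") == ">"
                   else (coord < at)).astype(float)
        elif kind == "band":
            coord = x if rec.get("axis", "x") == "x" else y
            arr = ((coord >= rec["lo"]) & (coord <= rec["hi"])).astype(float)
        elif kind == "radial_centre":
            r = np.hypot(x - 0.5, y - 0.5)
            arr = np.clip(1.0 - r / (0.5 * np.sqrt(2.0)), 0.0, 1.0)
        elif kind == "radial_edge":
            r = np.hypot(x - 0.5, y - 0.5)
            arr = 1.0 - np.clip(1.0 - r / (0.5 * np.sqrt(2.0)), 0.0, 1.0)
        elif kind == "disc":
            cx, cy = rec.get("center", (0.5, 0.5))
            arr = (np.hypot(x - cx, y - cy) <=
                   rec.get("radius", 0.1)).astype(float)
            arr = ensure_nonempty(arr, cx, cy)
        elif kind == "border":
            depth = rec.get("depth", 0.05)
            arr = ((x < depth) | (x > 1 - depth) |
                   (y < depth) | (y > 1 - depth)).astype(float)
        elif kind == "abs_band":  # |x - c| in (lo, hi)
            axis_x = rec.get("axis", "x") == "x"
            coord = x if axis_x else y
            c = rec.get("center", 0.5)
            d = np.abs(coord - c)
            arr = ((d > rec["lo"]) & (d <= rec["hi"])).astype(float)
            if rec["lo"] < 0:  # band containing the centre line
                arr = ensure_nonempty(arr, c if axis_x else None,
                                      None if axis_x else c)
        elif kind == "tent_plateau":
            # 0 at both edges of the axis, rising linearly to a plateau of 1
            # over the medial fraction
            coord = x if rec.get("axis", "x") == "x" else y
            d = np.abs(2.0 * coord - 1.0)  # 0 centre, 1 edges
            ramp = rec.get("ramp", 0.4)
            arr = np.clip((1.0 - d) / ramp, 0.0, 1.0)
        elif kind == "gauss_at":
            coord = x if rec.get("axis", "x") == "x" else y
            sigma = rec.get("sigma", 0.03)
            arr = np.zeros(len(v))
            for c in rec["positions"]:
                arr = np.maximum(arr, np.exp(-((coord - c) / sigma) ** 2))
        elif kind == "diffuse":
            length = rec.get("length_frac", 0.1) * short
            arr = fields.diffuse_signal(canvas, rec["source"], length)
        elif kind == "threshold":
            arr = (canvas.factors[rec["source"]] >
                   rec.get("level", 0.5)).astype(float)
        elif kind == "product":
            arr = np.ones(len(v))
            for src in rec["sources"]:
                arr = arr * canvas.factors[src]
        elif kind == "expr":
            arr = np.broadcast_to(np.asarray(
                fields.eval_expr(rec["expr"], canvas.factors), dtype=float),
                (len(v),)).copy()
        else:
            raise ValueError(f"unknown factor recipe {kind!r}")
        canvas.factors[name] = np.asarray(arr, dtype=float)


# ----------------------------------------------------------------- registry


def _square_base(side=100.0, sagitta=None, noise=0.0):
    return {"kind": "square", "side": side, "sagitta": sagitta,
            "noise": noise}


_CONVERGENT_POL = {"production": "ifoci", "degradation": "iborder",
                   "length_frac": 0.4}
_PARALLEL_POL = {"production": "ibottom", "fixed": {"itop": 0.0},
                 "length_frac": 0.6}

_SQUARE_FACTORS = [
    {"name": "ifoci", "kind": "disc", "center": (0.5, 0.5), "radius": 0.08},
    {"name": "iborder", "kind": "border", "depth": 0.06},
    {"name": "ibottom", "kind": "halfplane", "axis": "y", "op": "<",
     "at": 0.06},
    {"name": "itop", "kind": "halfplane", "axis": "y", "op": ">", "at": 0.94},
    {"name": "icentre", "kind": "radial_centre"},
    {"name": "iedge", "kind": "radial_edge"},
    {"name": "sjun", "kind": "stripe_gauss", "axis": "x", "center": 0.5,
     "sigma": 0.06},
    {"name": "srim", "kind": "stripe_gauss", "axis": "y", "center": 0.5,
     "sigma": 0.06},
    {"name": "ihalfside", "kind": "halfplane", "axis": "x", "op": "<",
     "at": 0.5},
    {"name": "idistalhalf", "kind": "halfplane", "axis": "y", "op": ">",
     "at": 0.5},
    {"name": "imargins", "kind": "abs_band", "axis": "x", "center": 0.5,
     "lo": 0.05, "hi": 0.25},
    {"name": "ichannel", "kind": "abs_band", "axis": "x", "center": 0.5,
     "lo": -1.0, "hi": 0.05},
    {"name": "iside", "kind": "abs_band", "axis": "x", "center": 0.5,
     "lo": 0.05, "hi": 0.35},
    {"name": "isinktop", "kind": "disc", "center": (0.5, 1.0),
     "radius": 0.12},
]

_WEDGE_FACTORS = [
    {"name": "isource", "kind": "halfplane", "axis": "y", "op": "<",
     "at": 0.05},
    {"name": "isink", "kind": "halfplane", "axis": "y", "op": ">",
     "at": 0.95},
    {"name": "iradl", "kind": "halfplane", "axis": "x", "op": "<",
     "at": 0.02},
    {"name": "iradr", "kind": "halfplane", "axis": "x", "op": ">",
     "at": 0.98},
    {"name": "irad", "kind": "expr", "expr": "clip(iradl + iradr)"},
    {"name": "srad", "kind": "diffuse", "source": "irad",
     "length_frac": 0.45},
    {"name": "ihinge", "kind": "threshold", "source": "srad", "level": 0.2},
    {"name": "idiv", "kind": "tent_plateau", "axis": "x", "ramp": 0.4},
    {"name": "iplt", "kind": "halfplane", "axis": "y", "op": "<", "at": 0.5},
    {"name": "iplx", "kind": "halfplane", "axis": "y", "op": "<", "at": 0.15},
    {"name": "irim", "kind": "band", "axis": "y", "lo": 0.5, "hi": 0.6},
    {"name": "srim", "kind": "diffuse", "source": "irim",
     "length_frac": 0.08},
    {"name": "ibrim", "kind": "threshold", "source": "srim", "level": 0.01},
    {"name": "ilip", "kind": "halfplane", "axis": "y", "op": ">", "at": 0.6},
    {"name": "ilif", "kind": "band", "axis": "y", "lo": 0.6, "hi": 0.8},
    {"name": "ilis", "kind": "halfplane", "axis": "y", "op": ">", "at": 0.8},
    {"name": "smed", "kind": "gauss_at", "axis": "x",
     "positions": [1 / 6, 3 / 6, 5 / 6], "sigma": 0.03},
    {"name": "slat", "kind": "gauss_at", "axis": "x",
     "positions": [0.0, 1 / 3, 2 / 3, 1.0], "sigma": 0.03},
    {"name": "ssec", "kind": "gauss_at", "axis": "x",
     "positions": [1 / 12, 3 / 12, 5 / 12, 7 / 12, 9 / 12, 11 / 12],
     "sigma": 0.02},
    {"name": "islat", "kind": "threshold", "source": "slat", "level": 0.5},
    {"name": "isinus", "kind": "expr", "expr": "islat * ilis"},
]

_WEDGE_POL = {"production": "isource", "degradation": "isink",
              "length_frac": 0.8}

# wedge thickness growth: 0.44 %/h as printed for the dome/wedge models
_WEDGE_KNOR = "0.0044"


def _phase(t0, t1, **exprs) -> Phase:
    return Phase(t0, t1, {k: v for k, v in exprs.items()})


def _build_registry() -> dict[str, ModelConfig]:
    reg: dict[str, ModelConfig] = {}

    def add(model: ModelConfig) -> None:
        reg[model.name] = model

    sq = _SQUARE_FACTORS

    # ---- uniform growth and the three elementary conflicts
    add(ModelConfig(
        name="fig1_isotropic",
        canvas=_square_base(),
        factors=sq,
        phases=[_phase(0, 120, kpar="0.03", kper="0.03", knor="0.044")],
        description="uniform isotropic growth",
    ))
    add(ModelConfig(
        name="fig1_anisotropic",
        canvas=_square_base(),
        factors=sq,
        polariser=_PARALLEL_POL,
        phases=[_phase(0, 120, kpar="0.03", kper="0.02", knor="0.044")],
        description="uniform anisotropic growth, proximodistal polarity",
    ))
    add(ModelConfig(
        name="fig1_surface",
        canvas=_square_base(),
        factors=sq,
        phases=[_phase(0, 120, kpara="0.06", kpera="0.06",
                       kparb="0.05", kperb="0.05", knor="0.044")],
        description="surface conflict with growth",
    ))
    add(ModelConfig(
        name="fig1_areal",
        canvas=_square_base(),
        factors=sq,
        phases=[_phase(0, 120, kpar="0.05+0.05*icentre",
                       kper="0.05+0.05*icentre", knor="0.044")],
        description="areal conflict with growth",
    ))
    add(ModelConfig(
        name="fig1_directional",
        canvas=_square_base(),
        factors=sq,
        polariser=_CONVERGENT_POL,
        phases=[_phase(0, 120, kpar="0.05", kper="0.02", knor="0.044")],
        description="convergent directional conflict",
    ))
    for suffix, base in (("areal_flat", "fig1_areal"),
                         ("directional_flat", "fig1_directional")):
        flat = copy.deepcopy(reg[base])
        flat.name = f"fig1s1_{suffix}"
        flat.canvas = _square_base(sagitta=0.0, noise=0.1)
        flat.description += ", flat noisy start"
        add(flat)

    # ---- orthogonal-domain directional/areal conflicts
    def sq_model(name, kpar, kper, pol=_CONVERGENT_POL, knor="0.044",
                 canvas=None, ablations=None, desc=""):
        add(ModelConfig(
            name=name, canvas=canvas or _square_base(), factors=sq,
            polariser=pol,
            phases=[_phase(0, 120, kpar=kpar, kper=kper, knor=knor)],
            ablations=ablations or {}, description=desc))

    sq_model(
        "fig6_orthogonal",
        "0.05+0.05*Sjun+0.05*Srim-0.2*Sjun*Srim",
        "0.05-0.05*Sjun-0.05*Srim+0.2*Sjun*Srim",
        ablations={"orthogonal": {"kpar": "0.05", "kper": "0.05"}},
        desc="orthogonal directional conflict, convergent field")
    sq_model(
        "fig6_T",
        "0.05+0.05*Sjun+0.05*Srim*ihalfside-0.1*Sjun*Srim",
        "0.05-0.05*Sjun-0.05*Srim*ihalfside+0.1*Sjun*Srim",
        desc="T-shaped directional conflict")
    sq_model(
        "fig6_L",
        "0.05+0.05*Sjun*idistalhalf+0.05*Srim*ihalfside-0.02*Sjun*Srim",
        "0.05-0.05*Sjun*idistalhalf-0.05*Srim*ihalfside+0.02*Sjun*Srim",
        desc="L-shaped directional conflict")
    sq_model(
        "fig6_I",
        "0.05+0.05*Sjun-0.1*Sjun*Srim",
        "0.05-0.05*Sjun+0.1*Sjun*Srim",
        desc="directional conflict for a vertical domain")
    sq_model(
        "fig6_one_arm",
        "0.05+0.05*Sjun*idistalhalf",
        "0.05-0.05*Sjun*idistalhalf",
        desc="directional conflict, upper half of the vertical domain")
    sq_model(
        "fig6_parallel",
        "0.05+0.05*Sjun-0.05*Srim",
        "0.05-0.05*Sjun+0.05*Srim",
        pol=_PARALLEL_POL,
        desc="orthogonal directional conflict in a parallel field")
    sq_model(
        "fig6_areal_orthogonal",
        "0.05+0.05*Sjun+0.05*Srim-0.02*Sjun*Srim",
        "0.05+0.05*Sjun+0.05*Srim-0.02*Sjun*Srim",
        pol=None,
        desc="areal conflict for an orthogonal domain")
    channel = ModelConfig(
        name="fig6_channel",
        canvas=_square_base(),
        factors=sq,
        polariser={"production": "ibottom", "degradation": "isinktop",
                   "length_frac": 0.6},
        phases=[_phase(0, 120,
                       kpar="0.05+0.05*Sjun+0.05*Srim*imargins"
                            "-0.075*Sjun*Srim",
                       kper="0.05-0.05*Srim*imargins-0.05*Sjun"
                            "+0.075*Sjun*Srim",
                       knor="0.044")],
        events=[
            {"t": 0.0, "kind": "lock_channel", "region": "ichannel"},
            {"t": 0.0, "kind": "set_polariser",
             "production": {"iside": 1.0},
             "degradation": {"isinktop": 1.0, "ichannel": 0.3}},
        ],
        description="orthogonal polarity field with a locked channel",
    )
    add(channel)

    # ---- combined conflicts
    sq_model(
        "fig6s1_directional_areal",
        "0.01+0.06*Sjun-0.12*Sjun*Srim",
        "0.01+0.06*Srim-0.12*Sjun*Srim",
        knor="0.01",
        desc="directional conflict with enhanced areal growth in the domains")
    add(ModelConfig(
        name="fig6s1_surface_directional",
        canvas=_square_base(),
        factors=sq,
        polariser=_CONVERGENT_POL,
        phases=[_phase(0, 120,
                       kpara="0.055+0.05*Sjun+0.05*Srim-0.2*Sjun*Srim",
                       kpera="0.055-0.05*Sjun-0.05*Srim+0.2*Sjun*Srim",
                       kparb="0.05+0.05*Sjun+0.05*Srim-0.2*Sjun*Srim",
                       kperb="0.05-0.05*Sjun-0.05*Srim+0.2*Sjun*Srim",
                       knor="0.044")],
        description="surface conflict combined with orthogonal directional "
                    "conflict (printed second Kparb read as Kperb)",
    ))
    add(ModelConfig(
        name="fig6s1_surface_areal",
        canvas=_square_base(sagitta=0.0, noise=0.1),
        factors=sq,
        phases=[_phase(0, 120,
                       kpara="0.03+0.025*icentre", kpera="0.03+0.025*icentre",
                       kparb="0.025+0.025*icentre",
                       kperb="0.025+0.025*icentre", knor="0.044")],
        description="surface plus areal conflict, flat noisy start",
    ))

    # ---- conflicts without overall growth (size-preserving)
    add(ModelConfig(
        name="fig7_surface",
        canvas=_square_base(),
        factors=sq,
        phases=[_phase(0, 120, kpara="0.005", kpera="0.005",
                       kparb="-0.005", kperb="-0.005", knor="0")],
        description="surface conflict without overall growth",
    ))
    add(ModelConfig(
        name="fig7_areal",
        canvas=_square_base(),
        factors=sq,
        phases=[_phase(0, 120, kpar="0.019-0.032*iedge",
                       kper="0.019-0.032*iedge", knor="0")],
        description="areal conflict without overall growth",
    ))
    add(ModelConfig(
        name="fig7_directional",
        canvas=_square_base(),
        factors=sq,
        polariser=_CONVERGENT_POL,
        phases=[_phase(0, 120, kpar="0.01", kper="-0.01", knor="0")],
        description="convergent directional conflict with contraction",
    ))
    add(ModelConfig(
        name="fig7_orthogonal_parallel",
        canvas=_square_base(),
        factors=sq,
        polariser=_PARALLEL_POL,
        phases=[_phase(0, 120, kpar="0.05*Sjun-0.05*Srim",
                       kper="0.05*Srim-0.05*Sjun", knor="0")],
        description="orthogonal directional conflict without overall growth",
    ))

    # ---- div domes and wild-type wedge (phases I and II)
    wedge_canvas = {"kind": "strip", "width": 1060.0, "height": 120.0,
                    "sagitta": None}
    div_phase1 = {
        "kparb": "0.02*inh(5,Srad)*pro(0.8,ilis)",
        "kpara": "Kparb*inh(0.5,(Srim>0.4)*inh(100,Srad))",
        "kperb": "0.005*inh(3,Srad)",
        "kpera": "Kperb",
        "knor": _WEDGE_KNOR,
    }
    div_phase2 = {
        "kparb": "0.012*inh(5,srad*pro(3,ilip))*inh(0.8,ilis)*inh(2,srim)"
                 "*pro(0.8,slat*ibrim)",
        "kpara": "Kparb*inh(0.5,(srim>0.4)*inh(100,srad))",
        "kperb": "0.012*inh(3,srad)*pro(2.5,srim)*inh(3,slat)*inh(3,smed)",
        "kpera": "Kperb",
        "knor": _WEDGE_KNOR,
    }
    add(ModelConfig(
        name="fig9_div_domes",
        canvas=wedge_canvas,
        factors=_WEDGE_FACTORS,
        polariser=_WEDGE_POL,
        phases=[Phase(240.0, 288.0, div_phase1),
                Phase(288.0, 576.0, div_phase2)],
        events=[{"t": 300.0, "kind": "induce_clones",
                 "radius": 10.0, "spacing": 60.0}],
        ablations={"orthogonal": {
            "phase2": {
                "kparb": "0.012*inh(5,srad*pro(3,ilip))*inh(0.8,ilis)",
                "kperb": "0.012*inh(3,srad)*inh(3,smed)",
            }}},
        description="div mutant domes, phase I + II",
    ))

    wt_phase1 = {
        "kparb": "0.02*inh(5,srad)*pro(0.8,ilis)*pro(1.5,idiv*ilif)"
                 "*pro(0.8,idiv*iplt*pro(0.3,iplx)*inh(5,isource))",
        "kpara": "Kparb*inh(3,srim*inh(10,smed)*inh(100,srad))",
        "kperb": "0.005*inh(3,srad)",
        "kpera": "Kperb",
        "knor": _WEDGE_KNOR,
    }
    wt_phase2 = {
        "kparb": "0.012*inh(5,Srad*pro(3,ilip))*pro(0.8,ilis)"
                 "*pro(0.5,idiv*ilif)"
                 "*pro(0.8,idiv*iplt*pro(0.3,iplx)*inh(5,isource))"
                 "*inh(2,Srim)*inh(0.2,idiv>0.95*Smed*ibrim)"
                 "*inh(50,Srad*ilis*pro(100,ihinge))*pro(0.8,Slat*ibrim)",
        "kpara": "Kparb*inh(3,idiv*Srim*inh(10,Smed)*inh(100,Srad))",
        "kperb": "0.012*inh(3,Srad)*pro(2.5,Srim*pro(0.5,idiv))"
                 "*inh(3,slat*inh(1,idiv>0.83)*ilif)"
                 "*inh(0.5,idiv>0.95*pro(1,4*Srim+1.5*ilis)*inh(100,iplx))"
                 "*inh(3,Smed*inh(10,iplt*idiv))"
                 "*inh(2,(1-idiv)*ilis*pro(2,isink)*inh(100,ihinge))"
                 "*pro(4.8,idiv*ilip*Ssec*inh(8,Srim))",
        "kpera": "Kperb*inh(0.5,idiv>0.95*ilip)",
        "knor": _WEDGE_KNOR,
    }
    add(ModelConfig(
        name="fig10_wt_wedge",
        canvas=wedge_canvas,
        factors=_WEDGE_FACTORS,
        polariser=_WEDGE_POL,
        phases=[Phase(240.0, 288.0, wt_phase1),
                Phase(288.0, 576.0, wt_phase2)],
        events=[
            {"t": 288.0, "kind": "freeze_polarity", "surface": "a"},
            {"t": 288.0, "kind": "add_sink", "factor": "isinus",
             "weight": 1.0},
            {"t": 300.0, "kind": "induce_clones",
             "radius": 10.0, "spacing": 60.0},
        ],
        ablations={"orthogonal": {
            "phase2": {
                "kparb": "0.012*inh(5,Srad*pro(3,ilip))*pro(0.8,ilis)"
                         "*pro(0.5,idiv*ilif)"
                         "*pro(0.8,idiv*iplt*pro(0.3,iplx)*inh(5,isource))"
                         "*inh(0.2,idiv>0.95*Smed*ibrim)"
                         "*inh(50,Srad*ilis*pro(100,ihinge))",
                "kperb": "0.012*inh(3,Srad)"
                         "*inh(0.5,idiv>0.95*pro(1,4*Srim+1.5*ilis)"
                         "*inh(100,iplx))"
                         "*inh(3,Smed*inh(10,iplt*idiv))"
                         "*inh(2,(1-idiv)*ilis*pro(2,isink)"
                         "*inh(100,ihinge))",
            }}},
        description="wild-type wedge, phase I + II",
    ))

    for model in reg.values():
        model.validate()
    return reg


_REGISTRY = _build_registry()


def list_models() -> list[str]:
    return sorted(_REGISTRY)


def get_model(name: str) -> ModelConfig:
    """A deep copy of a catalogue entry, safe to mutate."""
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown model {name!r}; catalogue: {', '.join(list_models())}")
    return copy.deepcopy(_REGISTRY[name])


def ablate(model: ModelConfig, conflict: str) -> ModelConfig:
    """Remove one conflict type from a model, per the printed ablations.

    surface: A/B expressions equalised (B copied to A).
    areal:   rates rescaled so Kpar'+Kper' equals the printed constant.
    directional: no polariser; growth isotropic at the mean rate.
    orthogonal: the model's stored orthogonal-interaction-free expressions.
    polarity_deflection: polariser-deflection events removed.
    """
    out = copy.deepcopy(model)
    out.name = f"{model.name}__no_{conflict}"
    if conflict == "surface":
        for ph in out.phases:
            exprs = ph.rate_exprs()
            ph.exprs = dict(exprs)
            ph.exprs["kpara"] = exprs["kparb"]
            ph.exprs["kpera"] = exprs["kperb"]
            ph.exprs.pop("kpar", None)
            ph.exprs.pop("kper", None)
    elif conflict == "areal":
        out.normalise_area = AREAL_NORMALISATION_CONSTANT
    elif conflict == "directional":
        out.polariser = None
        out.isotropise = True
        out.events = [e for e in out.events
                      if e["kind"] not in ("add_sink", "freeze_polarity",
                                           "lock_channel", "set_polariser")]
    elif conflict == "orthogonal":
        if "orthogonal" not in model.ablations:
            raise ValueError(
                f"orthogonal ablation is not meaningful for {model.name}")
        spec = model.ablations["orthogonal"]
        if "phase2" in spec:
            out.phases[-1].exprs.update(spec["phase2"])
        else:
            out.phases[0].exprs.update(spec)
    elif conflict == "polarity_deflection":
        out.events = [e for e in out.events
                      if e["kind"] not in ("add_sink", "freeze_polarity")]
    else:
        raise ValueError(f"unknown conflict {conflict!r}")
    out.validate()
    return out


def run_model(
    name: str | ModelConfig,
    resolution: float | None = None,
    seed: int = 0,
    t_end: float | None = None,
    dt: float = 1.0,
    relax_max_iter: int = 600,
    record_conflict: bool = True,
    clone_radius: float | None = None,
    clone_spacing: float | None = None,
):
    """Run a catalogue model and return trajectory summary data.

    Deterministic given the seed.  Returns a dict with the final canvas, the
    initial canvas, per-step area history and (optionally) the final-step
    conflict report.
    """
    model = get_model(name) if isinstance(name, str) else name
    canvas = model.build_canvas(resolution=resolution, seed=seed)
    if clone_radius is not None:
        mesh.induce_clones(canvas, radius=clone_radius,
                           spacing=clone_spacing or 3 * clone_radius)
    canvas0 = canvas.copy()
    if t_end is None:
        t_end = model.t_end
    areas = [canvas.total_area()]
    times = [canvas.time]
    n_steps = int(round((t_end - canvas.time) / dt))
    report = None
    prev = None
    for i in range(n_steps):
        if record_conflict and i == n_steps - 1:
            prev = canvas.copy()
        engine.step(canvas, model, dt, relax_max_iter=relax_max_iter)
        areas.append(canvas.total_area())
        times.append(canvas.time)
    if record_conflict and prev is not None:
        rates = model.rates(prev)
        report = engine.conflict_report(prev, canvas, rates, dt)
    return {
        "model": model,
        "canvas": canvas,
        "canvas0": canvas0,
        "areas": np.asarray(areas),
        "times": np.asarray(times),
        "conflict": report,
    }


def dump_model_json(model: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)


def load_model_json(path) -> ModelConfig:
    with open(path) as fh:
        return ModelConfig.from_dict(json.load(fh))
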