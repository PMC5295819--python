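"""Identity factors, diffusible signals, the polariser, and the growth-network
expression DSL.

The DSL covers the grammar used by the printed growth-regulatory equations:
numbers, factor names (case-insensitive), ``pro(x, f)``, ``inh(x, f)``,
products, sums/differences, threshold indicators ``f > c`` (which bind tighter
than products) and ``&`` (logical AND, between comparisons).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "pro",
    "inh",
    "Expr",
    "parse_expr",
    "eval_expr",
    "ExprError",
    "UnknownFactorError",
    "cotan_laplacian",
    "diffuse_signal",
    "PolariserState",
    "update_polariser",
    "lock_polarity_channel",
]


def pro(x, v):
    """Promotion multiplier: ``1 + x*v`` (>= 1 for admissible inputs)."""
    if np.any(np.asarray(x) < 0):
        raise ValueError("promotion amount must be non-negative")
    return 1.0 + np.asarray(x) * np.asarray(v)


def inh(x, v):
    """Inhibition multiplier: ``1 / (1 + x*v)`` (in (0, 1])."""
    if np.any(np.asarray(x) < 0):
        raise ValueError("inhibition amount must be non-negative")
    return 1.0 / (1.0 + np.asarray(x) * np.asarray(v))


# ------------------------------------------------------------------ DSL


class ExprError(ValueError):
    pass


class UnknownFactorError(ExprError):
    def __init__(self, name: str):
        super().__init__(f"unknown factor: {name!r}")
        self.name = name


class Expr:
    """Expression-tree node; subclasses implement eval and serialisation."""

    def __call__(self, env):
        return self.eval(env)

    def eval(self, env):  # pragma: no cover - abstract
        raise NotImplementedError

    def __str__(self):  # pragma: no cover - abstract
        raise NotImplementedError

    def __eq__(self, other):
        return type(self) is type(other) and self.__dict__ == other.__dict__

    def __hash__(self):
        return hash(str(self))


@dataclass(eq=False)
class Num(Expr):
    value: float

    def eval(self, env):
        return self.value

    def __str__(self):
        return repr(self.value) if self.value != int(self.value) \
            else str(int(self.value))


@dataclass(eq=False)
class Var(Expr):
    name: str

    def eval(self, env):
        key = self.name.lower()
        if key not in env:
            raise UnknownFactorError(self.name)
        return env[key]

    def __str__(self):
        return self.name


@dataclass(eq=False)
class BinOp(Expr):
    op: str
    left: Expr
    right: Expr

    _PREC = {"+": 1, "-": 1, "*": 2, "&": 3, ">": 4}

    def eval(self, env):
        a = self.left.eval(env)
        b = self.right.eval(env)
        if self.op == "+":
            return a + b
        if self.op == "-":
            return a - b
        if self.op == "*":
            return a * b
        if self.op == ">":
            return (np.asarray(a) > np.asarray(b)).astype(float)
        if self.op == "&":
            return ((np.asarray(a) != 0) & (np.asarray(b) != 0)).astype(float)
        raise ExprError(f"bad operator {self.op}")

    def _wrap(self, child):
        s = str(child)
        if isinstance(child, BinOp) and self._PREC[child.op] < self._PREC[self.op]:
            return f"({s})"
        return s

    def __str__(self):
        return f"{self._wrap(self.left)}{self.op}{self._wrap(self.right)}"


@dataclass(eq=False)
class Neg(Expr):
    arg: Expr

    def eval(self, env):
        return -self.arg.eval(env)

    def __str__(self):
        return f"-{self.arg}"


@dataclass(eq=False)
class Call(Expr):
    func: str  # 'pro' | 'inh' | 'clip'
    amount: Expr
    value: Expr | None = None

    def eval(self, env):
        if self.func == "clip":
            return np.maximum(self.amount.eval(env), 0.0)
        x = self.amount.eval(env)
        v = self.value.eval(env)
        return pro(x, v) if self.func == "pro" else inh(x, v)

    def __str__(self):
        if self.func == "clip":
            return f"clip({self.amount})"
        return f"{self.func}({self.amount},{self.value})"


_TOKEN = re.compile(
    r"\s*(?:(?P<num>\d+\.\d*|\.\d+|\d+)|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op>[-+*>&(),]))"
)


def _tokenize(text: str) -> list[tuple[str, str]]:
    # normalise unicode operators from printed equations
    text = (text.replace("∙", "*").replace("·", "*")
            .replace("−", "-").replace("–", "-"))
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            if text[pos:].strip() == "":
                break
            raise ExprError(f"cannot tokenise {text[pos:]!r}")
        pos = m.end()
        if m.lastgroup == "num":
            tokens.append(("num", m.group("num")))
        elif m.lastgroup == "name":
            tokens.append(("name", m.group("name")))
        else:
            tokens.append(("op", m.group("op")))
    tokens.append(("end", ""))
    return tokens


class _Parser:
    """Recursive descent.  Precedence (loose to tight): +/-, *, &, >."""

    def __init__(self, tokens):
        self.tokens = tokens
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, op):
        kind, val = self.next()
        if kind != "op" or val != op:
            raise ExprError(f"expected {op!r}, got {val!r}")

    def parse(self) -> Expr:
        e = self.sum()
        if self.peek()[0] != "end":
            raise ExprError(f"unexpected trailing token {self.peek()[1]!r}")
        return e

    def sum(self) -> Expr:
        # leading sign
        if self.peek() == ("op", "-"):
            self.next()
            e: Expr = Neg(self.product())
        else:
            e = self.product()
        while self.peek()[0] == "op" and self.peek()[1] in "+-":
            op = self.next()[1]
            e = BinOp(op, e, self.product())
        return e

    def product(self) -> Expr:
        e = self.andexpr()
        while self.peek() == ("op", "*"):
            self.next()
            e = BinOp("*", e, self.andexpr())
        return e

    def andexpr(self) -> Expr:
        e = self.comparison()
        while self.peek() == ("op", "&"):
            self.next()
            e = BinOp("&", e, self.comparison())
        return e

    def comparison(self) -> Expr:
        e = self.atom()
        if self.peek() == ("op", ">"):
            self.next()
            e = BinOp(">", e, self.atom())
        return e

    def atom(self) -> Expr:
        kind, val = self.next()
        if kind == "num":
            return Num(float(val))
        if kind == "name":
            if val.lower() in ("pro", "inh") and self.peek() == ("op", "("):
                self.next()
                amount = self.sum()
                self.expect(",")
                value = self.sum()
                self.expect(")")
                return Call(val.lower(), amount, value)
            if val.lower() == "clip" and self.peek() == ("op", "("):
                self.next()
                arg = self.sum()
                self.expect(")")
                return Call("clip", arg)
            return Var(val)
        if kind == "op" and val == "(":
            e = self.sum()
            self.expect(")")
            return e
        if kind == "op" and val == "-":
            return Neg(self.atom())
        raise ExprError(f"unexpected token {val!r}")


def parse_expr(text: str) -> Expr:
    """Parse a growth-network expression string into an expression tree."""
    return _Parser(_tokenize(text)).parse()


def eval_expr(expr: Expr | str, factor_levels: dict) -> np.ndarray | float:
    """Evaluate an expression pointwise over a mapping of factor levels.

    Factor-name lookup is case-insensitive.  Raises
    :class:`UnknownFactorError` naming any missing factor.
    """
    if isinstance(expr, str):
        expr = parse_expr(expr)
    env = {k.lower(): v for k, v in factor_levels.items()}
    return expr.eval(env)


# ------------------------------------------------------- diffusion on meshes


def cotan_laplacian(canvas) -> tuple[sp.csr_matrix, np.ndarray]:
    """Cotangent Laplacian (positive semidefinite) and lumped vertex areas."""
    v = canvas.vertices
    t = canvas.triangles
    n = len(v)
    ii, jj, ww = [], [], []
    mass = np.zeros(n)
    areas = canvas.areas()
    for k in range(3):
        a = t[:, k]
        b = t[:, (k + 1) % 3]
        c = t[:, (k + 2) % 3]
        u = v[b] - v[a]
        w = v[c] - v[a]
        cross = np.linalg.norm(np.cross(u, w), axis=1)
        cot = np.einsum("ij,ij->i", u, w) / np.maximum(cross, 1e-300)
        # cot at vertex a opposes edge (b, c)
        ii.extend([b, c])
        jj.extend([c, b])
        ww.extend([-0.5 * cot, -0.5 * cot])
    for k in range(3):
        mass += np.bincount(t[:, k], weights=areas / 3.0, minlength=n)
    ii = np.concatenate(ii)
    jj = np.concatenate(jj)
    ww = np.concatenate(ww)
    lap = sp.coo_matrix((ww, (ii, jj)), shape=(n, n)).tocsr()
    lap = lap - sp.diags(np.asarray(lap.sum(axis=1)).ravel())
    return lap.tocsr(), mass


def diffuse_signal(
    canvas,
    source_factor: str | np.ndarray,
    diffusion_length: float,
    mode: str = "steady",
) -> np.ndarray:
    """Steady-state diffusion-decay of a signal emitted by a source region.

    The source (factor level > 0.5) is clamped at 1; elsewhere the signal
    satisfies ``l^2 * laplace(u) = u`` so that on a one-dimensional strip the
    level decays as ``exp(-d / l)`` with distance ``d`` from the source.
    Output is normalised to [0, 1].
    """
    if isinstance(source_factor, str):
        src = canvas.factors[source_factor]
    else:
        src = np.asarray(source_factor, dtype=float)
    fixed = src > 0.5
    n = canvas.n_vertices
    if not np.any(fixed):
        warnings.warn("diffuse_signal: empty source region; returning zeros")
        return np.zeros(n)
    if not np.isfinite(diffusion_length):
        return np.ones(n)
    lap, mass = cotan_laplacian(canvas)
    big = sp.diags(mass) + diffusion_length**2 * lap
    free = ~fixed
    u = np.where(fixed, 1.0, 0.0)
    if np.any(free):
        a = big[free][:, free]
        rhs = -big[free][:, fixed] @ u[fixed]
        u[free] = spla.spsolve(a.tocsc(), rhs)
    u = np.clip(u, 0.0, 1.0)
    return u


# ----------------------------------------------------------------- polariser


@dataclass
class PolariserState:
    """Configuration and state of the diffusible polariser field.

    production / degradation map factor names to rate weights; ``fixed``
    maps factor names to clamped concentrations (Dirichlet sites).
    """

    production: dict[str, float] = field(default_factory=dict)
    degradation: dict[str, float] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)
    diffusion_length: float = 20.0
    base_decay: float = 0.05
    pol: np.ndarray | None = None


# elements whose gradient is below this fraction of the canvas mean are
# treated as having undefined polarity (isotropic growth there)
DEGENERATE_GRADIENT_FRAC = 1e-9


def _triangle_gradients(canvas, values: np.ndarray) -> np.ndarray:
    """Per-triangle tangent-plane gradient of a per-vertex scalar, (m, 3)."""
    e = canvas.edges3()  # (m, 3, 2)
    g = np.einsum("mki,mkj->mij", e, e)  # (m, 2, 2)
    tv = values[canvas.triangles]
    d = np.stack([tv[:, 1] - tv[:, 0], tv[:, 2] - tv[:, 0]], axis=-1)  # (m,2)
    coef = np.linalg.solve(g, d[..., None])[..., 0]
    return np.einsum("mij,mj->mi", e, coef)


def update_polariser(canvas, state: PolariserState, dt: float = 1.0):
    """Quasi-steady polariser update and polarity re-orientation.

    Solves the steady diffusion-production-degradation balance for POL, then
    sets per-element polarity (both surfaces) to the down-gradient direction
    (high POL at '+' organisers toward low POL at '-' organisers).  Frozen
    elements keep their stored material direction.
    """
    n = canvas.n_vertices

    def field_of(weights: dict[str, float]) -> np.ndarray:
        out = np.zeros(n)
        for name, w in weights.items():
            out = out + w * canvas.factors[name]
        return out

    prodf = field_of(state.production)
    degf = field_of(state.degradation)
    fixed_mask = np.zeros(n, dtype=bool)
    fixed_val = np.zeros(n)
    for name, level in state.fixed.items():
        sel = canvas.factors[name] > 0.5
        fixed_mask |= sel
        fixed_val[sel] = level

    if not (np.any(prodf > 0) or np.any(fixed_mask)):
        raise ValueError(
            "polariser needs at least one production or fixed site")

    lap, mass = cotan_laplacian(canvas)
    decay = state.base_decay + degf
    a_mat = sp.diags(mass * decay) + \
        state.base_decay * state.diffusion_length**2 * lap
    rhs = mass * prodf
    u = np.zeros(n)
    free = ~fixed_mask
    u[fixed_mask] = fixed_val[fixed_mask]
    if np.any(free):
        sub = a_mat[free][:, free]
        b = rhs[free] - a_mat[free][:, fixed_mask] @ u[fixed_mask]
        u[free] = spla.spsolve(sub.tocsc(), b)
    u = np.maximum(u, 0.0)
    state.pol = u
    canvas.pol = u

    grad = _triangle_gradients(canvas, u)
    norm = np.linalg.norm(grad, axis=1)
    thresh = DEGENERATE_GRADIENT_FRAC * max(norm.mean(), 1e-300)
    defined = norm > thresh
    dirs = np.where(defined[:, None],
                    -grad / np.maximum(norm[:, None], 1e-300), 0.0)
    canvas.set_polarity_from_vectors(dirs, defined, "a")
    canvas.set_polarity_from_vectors(dirs, defined, "b")
    return state


def lock_polarity_channel(canvas, region: np.ndarray,
                          surfaces: str = "ab") -> None:
    """Freeze polarity of elements whose centroid lies in a region mask.

    ``region`` is a per-vertex or per-element boolean mask.  Frozen elements
    keep their current material polarity; an empty region is a no-op.
    """
    region = np.asarray(region)
    if region.dtype != bool:
        region = region > 0.5
    if region.shape[0] == canvas.n_vertices:
        elem = region[canvas.triangles].all(axis=1)
    else:
        elem = region
    if not np.any(elem):
        return
    if "a" in surfaces:
        canvas.frozen_a[elem] = True
    if "b" in surfaces:
        canvas.frozen_b[elem] = True


def unlock_polarity(canvas, surfaces: str = "ab") -> None:
    if "a" in surfaces:
        canvas.frozen_a[:] = False
    if "b" in surfaces:
        canvas.frozen_b[:] = False
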