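"""Reaction systems and morphogen-gradient families.

Every model is a small set of ODEs (optionally with diffusion) in which one
or two morphogen profiles act as spatially varying bifurcation parameters.
Concentrations are nondimensional throughout; positions are absolute
coordinates on ``[0, L]`` (helpers report fractions of ``L`` where useful).

Families
--------
``toggle1``
    Two mutually repressive species; species 1 is activated by a single
    morphogen gradient.  No diffusion (the classic cell-autonomous switch).
``toggle2``
    The same switch with each species activated by its own morphogen
    (typically antiparallel gradients) and per-species diffusivities.
``hb``
    Hunchback driven by a Bicoid-style gradient plus Hb self-activation,
    with Hb diffusion.  Quantitative runs require externally supplied
    parameter values.
``scalar``
    A one-species cubic bistable reaction ``u (1 - u) (u - alpha(x))`` whose
    traveling-front speed has the closed form ``(1 - 2 alpha) sqrt(D / 2)``;
    it serves as the analytic oracle for front-speed code.
"""

from __future__ import annotations

import io
import math
import tomllib
from dataclasses import dataclass, replace
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "HillParams",
    "ToggleParams",
    "HbParams",
    "ScalarBistableParams",
    "GradientSpec",
    "Model",
    "hill_response",
    "eval_gradient",
    "build_model",
    "load_config",
    "dump_config",
]

GradientKind = Literal["static_exp", "emerging", "decaying", "bcd", "tabulated"]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HillParams:
    """Half-max concentration ``K`` and Hill coefficient ``n`` (both > 0)."""

    K: float
    n: float

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ValueError(f"Hill K must be positive, got {self.K}")
        if not self.n > 0:
            raise ValueError(f"Hill n must be positive, got {self.n}")


@dataclass(frozen=True)
class ToggleParams:
    """Mutually repressive two-gene switch.

    ``a1``/``a2`` are maximal production rates, ``beta`` the (shared) decay
    rate, ``act``/``rep`` the activating and repressing Hill functions, and
    ``D1``/``D2`` the product diffusivities (0 for the cell-autonomous case).
    """

    a1: float
    a2: float
    beta: float
    act: HillParams
    rep: HillParams
    D1: float = 0.0
    D2: float = 0.0

    def __post_init__(self) -> None:
        if min(self.a1, self.a2, self.D1, self.D2) < 0:
            raise ValueError("rates and diffusivities must be nonnegative")
        if not self.beta > 0:
            raise ValueError("beta must be positive")

    @property
    def umax(self) -> float:
        """Upper bound ``max(a1, a2) / beta`` on attainable concentrations."""
        return max(self.a1, self.a2) / self.beta


@dataclass(frozen=True)
class HbParams:
    """Hunchback/Bicoid regulatory parameters (all positive)."""

    alpha_b: float
    alpha_h: float
    b0: float
    h0: float
    nb: float
    nh: float
    beta: float
    D: float

    def __post_init__(self) -> None:
        vals = (self.alpha_b, self.alpha_h, self.b0, self.h0,
                self.nb, self.nh, self.beta, self.D)
        if any(v <= 0 for v in vals):
            raise ValueError("all Hb parameters must be positive")

    @property
    def umax(self) -> float:
        return (self.alpha_b + self.alpha_h) / self.beta


@dataclass(frozen=True)
class ScalarBistableParams:
    """Cubic bistable reaction with position-dependent threshold alpha(x).

    ``alpha_field`` may be a plain float, a callable of x, or a tabulated
    GradientSpec; bistability requires values in (0, 1).
    """

    D: float
    alpha_field: float | Callable[[np.ndarray], np.ndarray] | "GradientSpec"

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("diffusivity must be nonnegative")

    def alpha(self, x):
        if isinstance(self.alpha_field, GradientSpec):
            return eval_gradient(self.alpha_field, 0.0, x)
        if callable(self.alpha_field):
            return np.asarray(self.alpha_field(np.asarray(x, dtype=float)))
        return np.full_like(np.asarray(x, dtype=float), float(self.alpha_field))

    @property
    def umax(self) -> float:
        return 1.0


@dataclass(frozen=True)
class GradientSpec:
    """A morphogen profile family evaluable at (t, x).

    kinds
    -----
    - ``static_exp``:  b exp(-|x - source| / lam)
    - ``emerging``:    b exp(-x/lam) (1 - exp(-gamma t)), growing from zero
    - ``decaying``:    b exp(-x/lam - gamma t)
    - ``bcd``:         bm exp(-x/lam - omega0 (max(t, t0) - t0))
    - ``tabulated``:   linear interpolation of (x, value) pairs, flat
      extrapolation at the ends

    ``source`` places the origin of a static exponential (0 = anterior by
    default; ``source = L`` yields the antiparallel partner gradient).
    """

    kind: GradientKind
    b: float = 1.0
    lam: float = 1.0
    gamma: float = 0.0
    bm: float = 1.0
    omega0: float = 0.0
    t0: float = 0.0
    source: float = 0.0
    table: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("static_exp", "emerging", "decaying", "bcd", "tabulated"):
            raise ValueError(f"unknown gradient kind {self.kind!r}")
        if self.kind == "tabulated":
            if not self.table or len(self.table) < 2:
                raise ValueError("tabulated gradient needs >= 2 (x, value) pairs")
            xs = [p[0] for p in self.table]
            if any(b <= a for a, b in zip(xs, xs[1:])):
                raise ValueError("tabulated x values must be strictly increasing")
        else:
            if self.b <= 0 or self.bm <= 0 or self.lam <= 0:
                raise ValueError("b, bm and lam must be positive")
            if self.gamma < 0 or self.omega0 < 0:
                raise ValueError("gamma and omega0 must be nonnegative")

    def __call__(self, t, x):
        return eval_gradient(self, t, x)

    def final(self) -> "GradientSpec":
        """The t -> infinity static profile of an emerging gradient."""
        if self.kind != "emerging":
            raise ValueError("final() is defined for emerging gradients")
        return GradientSpec(kind="static_exp", b=self.b, lam=self.lam,
                            source=self.source)

    def frozen_at(self, t: float) -> "GradientSpec":
        """A static (tabulation-free where possible) snapshot at time t."""
        if self.kind in ("static_exp", "tabulated"):
            return self
        if self.kind == "emerging":
            amp = self.b * (1.0 - math.exp(-self.gamma * t))
            if amp <= 0:
                # identically-zero profile; encode as a flat table
                return GradientSpec(kind="tabulated",
                                    table=((0.0, 0.0), (1e12, 0.0)))
            return GradientSpec(kind="static_exp", b=amp, lam=self.lam,
                                source=self.source)
        if self.kind == "decaying":
            return GradientSpec(kind="static_exp",
                                b=self.b * math.exp(-self.gamma * t),
                                lam=self.lam, source=self.source)
        # bcd
        amp = self.bm * math.exp(-self.omega0 * (max(t, self.t0) - self.t0))
        return GradientSpec(kind="static_exp", b=amp, lam=self.lam,
                            source=self.source)


def hill_response(y, p: HillParams, mode: Literal["activate", "repress"]):
    """Activating or repressing Hill response in [0, 1].

    ``activate``: (y/K)^n / (1 + (y/K)^n);  ``repress``: 1 / (1 + (y/K)^n).
    Monotone in y; accepts scalars or arrays (y >= 0).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("hill_response requires nonnegative concentrations")
    r = (y / p.K) ** p.n
    if mode == "activate":
        out = r / (1.0 + r)
    elif mode == "repress":
        out = 1.0 / (1.0 + r)
    else:
        raise ValueError(f"unknown Hill mode {mode!r}")
    return out if out.ndim else float(out)


def eval_gradient(g: GradientSpec, t, x):
    """Morphogen concentration of ``g`` at time(s) t and position(s) x."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    if g.kind == "tabulated":
        xs = np.array([p[0] for p in g.table])
        vs = np.array([p[1] for p in g.table])
        if np.any(x < xs[0] - 1e-12) or np.any(x > xs[-1] + 1e-12):
            raise ValueError("position outside tabulated gradient range")
        out = np.interp(x, xs, vs)
        return float(out) if scalar else out

    d = np.abs(x - g.source)
    if g.kind == "static_exp":
        out = g.b * np.exp(-d / g.lam)
    elif g.kind == "emerging":
        out = g.b * np.exp(-d / g.lam) * (1.0 - np.exp(-g.gamma * np.asarray(t)))
    elif g.kind == "decaying":
        out = g.b * np.exp(-d / g.lam - g.gamma * np.asarray(t))
    else:  # bcd
        tt = np.maximum(np.asarray(t, dtype=float), g.t0) - g.t0
        out = g.bm * np.exp(-d / g.lam - g.omega0 * tt)
    out = np.asarray(out)
    return float(out) if scalar and out.ndim == 0 else out


# ---------------------------------------------------------------------------
# the Model container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Model:
    """A reaction system on [0, L] with per-species diffusivities.

    ``rhs(t, x, u)`` evaluates the reaction term; ``x`` may be a scalar or a
    length-M array and ``u`` has shape ``(n_species,)`` or ``(n_species, M)``.
    """

    n_species: int
    rhs: Callable
    diffusivities: tuple[float, ...]
    L: float
    gradients: tuple[GradientSpec, ...]
    params: object
    tag: str

    def __post_init__(self) -> None:
        if len(self.diffusivities) != self.n_species:
            raise ValueError("one diffusivity per species is required")

    def frozen_rhs(self, t: float) -> Callable:
        """The autonomous reaction term g(x, u) with time frozen at t."""
        rhs = self.rhs

        def f(x, u):
            return rhs(t, x, u)

        return f

    def local_rhs(self, t: float, x: float) -> Callable:
        """The local (single position, frozen time) ODE right-hand side f(u)."""
        rhs = self.rhs

        def f(u):
            return rhs(t, x, u)

        return f

    def with_diffusivities(self, diffusivities: Sequence[float]) -> "Model":
        return replace(self, diffusivities=tuple(float(d) for d in diffusivities))

    @property
    def umax(self) -> float:
        """Scale of the attainable concentration box (used to seed searches)."""
        return getattr(self.params, "umax", 1.0)


def _toggle1_rhs(p: ToggleParams, g: GradientSpec):
    # Hill inputs are clipped at 0: adaptive steppers may overshoot slightly
    # below zero, and the response is defined for nonnegative concentrations.
    def rhs(t, x, u):
        u = np.asarray(u, dtype=float)
        u1, u2 = u[0], u[1]
        a = eval_gradient(g, t, x)
        du1 = p.a1 * hill_response(a, p.act, "activate") \
            * hill_response(np.maximum(u2, 0.0), p.rep, "repress") - p.beta * u1
        du2 = p.a2 * hill_response(np.maximum(u1, 0.0), p.rep, "repress") \
            - p.beta * u2
        return np.stack(np.broadcast_arrays(du1, du2))

    return rhs


def _toggle2_rhs(p: ToggleParams, g1: GradientSpec, g2: GradientSpec):
    def rhs(t, x, u):
        u = np.asarray(u, dtype=float)
        u1, u2 = u[0], u[1]
        a1 = eval_gradient(g1, t, x)
        a2 = eval_gradient(g2, t, x)
        du1 = p.a1 * hill_response(a1, p.act, "activate") \
            * hill_response(np.maximum(u2, 0.0), p.rep, "repress") - p.beta * u1
        du2 = p.a2 * hill_response(a2, p.act, "activate") \
            * hill_response(np.maximum(u1, 0.0), p.rep, "repress") - p.beta * u2
        return np.stack(np.broadcast_arrays(du1, du2))

    return rhs


def _hb_rhs(p: HbParams, g: GradientSpec):
    def rhs(t, x, u):
        u = np.asarray(u, dtype=float)
        h = u[0]
        b = eval_gradient(g, t, x)
        rb = (np.asarray(b, dtype=float) / p.b0) ** p.nb
        rh = (np.maximum(h, 0.0) / p.h0) ** p.nh
        f = (p.alpha_b * rb + p.alpha_h * rh) / (1.0 + rb + rh)
        dh = f - p.beta * h
        return np.asarray(dh)[None] if np.ndim(dh) else np.array([dh])

    return rhs


def _scalar_rhs(p: ScalarBistableParams):
    def rhs(t, x, u):
        u = np.asarray(u, dtype=float)
        v = u[0]
        a = p.alpha(x)
        dv = v * (1.0 - v) * (v - a)
        return np.asarray(dv)[None] if np.ndim(dv) else np.array([dv])

    return rhs


def build_model(family: str, params, gradients=(), L: float = 1.0) -> Model:
    """Wire a parameter set and gradient(s) into an evaluable Model.

    ``gradients`` must contain exactly one profile for ``toggle1``/``hb``,
    two for ``toggle2`` and none for ``scalar`` (whose threshold field lives
    in the parameters).
    """
    gradients = tuple(gradients)
    if family == "toggle1":
        if len(gradients) != 1:
            raise ValueError("toggle1 takes exactly one gradient")
        if not isinstance(params, ToggleParams):
            raise TypeError("toggle1 requires ToggleParams")
        return Model(2, _toggle1_rhs(params, gradients[0]),
                     (params.D1, params.D2), L, gradients, params, "toggle1")
    if family == "toggle2":
        if len(gradients) != 2:
            raise ValueError("toggle2 takes exactly two gradients")
        if not isinstance(params, ToggleParams):
            raise TypeError("toggle2 requires ToggleParams")
        return Model(2, _toggle2_rhs(params, *gradients),
                     (params.D1, params.D2), L, gradients, params, "toggle2")
    if family == "hb":
        if len(gradients) != 1:
            raise ValueError("hb takes exactly one gradient")
        if not isinstance(params, HbParams):
            raise TypeError("hb requires HbParams")
        return Model(1, _hb_rhs(params, gradients[0]),
                     (params.D,), L, gradients, params, "hb")
    if family == "scalar":
        if len(gradients) != 0:
            raise ValueError("scalar model takes no separate gradient "
                             "(alpha_field lives in the parameters)")
        if not isinstance(params, ScalarBistableParams):
            raise TypeError("scalar requires ScalarBistableParams")
        return Model(1, _scalar_rhs(params), (params.D,), L, (), params, "scalar")
    raise ValueError(f"unknown model family {family!r}")


# ---------------------------------------------------------------------------
# flat TOML configuration I/O
# ---------------------------------------------------------------------------

_GRADIENT_KEYS = ("kind", "b", "lam", "gamma", "bm", "omega0", "t0", "source")


def _gradient_from_dict(d: dict) -> GradientSpec:
    kw = {k: d[k] for k in _GRADIENT_KEYS if k in d}
    if "table" in d:
        kw["table"] = tuple((float(a), float(b)) for a, b in d["table"])
    return GradientSpec(**kw)


def _gradient_to_dict(g: GradientSpec) -> dict:
    d: dict = {"kind": g.kind}
    if g.kind == "tabulated":
        d["table"] = [list(p) for p in g.table]
        return d
    d.update(b=g.b, lam=g.lam, source=g.source)
    if g.kind in ("emerging", "decaying"):
        d["gamma"] = g.gamma
    if g.kind == "bcd":
        d.update(bm=g.bm, omega0=g.omega0, t0=g.t0)
    return d


def load_config(source) -> Model:
    """Read a Model from a flat TOML config (path, bytes or file object).

    Exactly one model-family section (``[toggle1]``, ``[toggle2]``, ``[hb]``,
    ``[scalar]``) must be present, plus ``[gradient]`` (or ``[gradient1]`` /
    ``[gradient2]`` for toggle2) and an optional top-level ``L``.
    """
    if isinstance(source, (str, bytes)):
        if isinstance(source, str):
            with open(source, "rb") as fh:
                cfg = tomllib.load(fh)
        else:
            cfg = tomllib.load(io.BytesIO(source))
    else:
        cfg = tomllib.load(source)

    families = [f for f in ("toggle1", "toggle2", "hb", "scalar") if f in cfg]
    if len(families) != 1:
        raise ValueError(
            f"config must contain exactly one model-family section, found {families}")
    family = families[0]
    sec = dict(cfg[family])
    L = float(cfg.get("L", 1.0))

    if family in ("toggle1", "toggle2"):
        params = ToggleParams(
            a1=float(sec["a1"]), a2=float(sec["a2"]), beta=float(sec["beta"]),
            act=HillParams(K=float(sec["K_a"]), n=float(sec["n_a"])),
            rep=HillParams(K=float(sec["K_r"]), n=float(sec["n_r"])),
            D1=float(sec.get("D1", 0.0)), D2=float(sec.get("D2", 0.0)))
        if family == "toggle1":
            grads = (_gradient_from_dict(cfg["gradient"]),)
        else:
            grads = (_gradient_from_dict(cfg["gradient1"]),
                     _gradient_from_dict(cfg["gradient2"]))
    elif family == "hb":
        params = HbParams(**{k: float(sec[k]) for k in
                             ("alpha_b", "alpha_h", "b0", "h0",
                              "nb", "nh", "beta", "D")})
        grads = (_gradient_from_dict(cfg["gradient"]),)
    else:
        if "alpha_table" in sec:
            af = GradientSpec(kind="tabulated",
                              table=tuple((float(a), float(b))
                                          for a, b in sec["alpha_table"]))
        else:
            af = float(sec["alpha"])
        params = ScalarBistableParams(D=float(sec["D"]), alpha_field=af)
        grads = ()
    return build_model(family, params, grads, L)


def _toml_value(v) -> str:
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    if isinstance(v, float) and v == int(v) and abs(v) < 1e15:
        return f"{v:.1f}"
    return repr(v)


def dump_config(m: Model) -> str:
    """Serialize a Model back to flat TOML text (inverse of load_config)."""
    lines = [f"L = {_toml_value(float(m.L))}", ""]

    def emit(section: str, d: dict) -> None:
        lines.append(f"[{section}]")
        for k, v in d.items():
            if isinstance(v, (int, float)) and not isinstance(v, bool):
                v = float(v)
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")

    p = m.params
    if m.tag in ("toggle1", "toggle2"):
        emit(m.tag, dict(a1=p.a1, a2=p.a2, beta=p.beta,
                         K_a=p.act.K, n_a=p.act.n, K_r=p.rep.K, n_r=p.rep.n,
                         D1=p.D1, D2=p.D2))
        if m.tag == "toggle1":
            emit("gradient", _gradient_to_dict(m.gradients[0]))
        else:
            emit("gradient1", _gradient_to_dict(m.gradients[0]))
            emit("gradient2", _gradient_to_dict(m.gradients[1]))
    elif m.tag == "hb":
        emit("hb", dict(alpha_b=p.alpha_b, alpha_h=p.alpha_h, b0=p.b0,
                        h0=p.h0, nb=p.nb, nh=p.nh, beta=p.beta, D=p.D))
        emit("gradient", _gradient_to_dict(m.gradients[0]))
    elif m.tag == "scalar":
        d: dict = {"D": p.D}
        if isinstance(p.alpha_field, GradientSpec):
            d["alpha_table"] = [list(pair) for pair in p.alpha_field.table]
        elif callable(p.alpha_field):
            raise ValueError("callable alpha_field cannot be serialized; "
                             "tabulate it first")
        else:
            d["alpha"] = float(p.alpha_field)
        emit("scalar", d)
    else:
        raise ValueError(f"cannot serialize model tag {m.tag!r}")
    return "\n".join(lines)
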