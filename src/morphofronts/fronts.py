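"""Local front velocities and the reduced boundary-position ODE.

In a bistable reaction-diffusion system whose bifurcation parameters vary
in space, the gene-expression boundary behaves locally like the traveling
front of the spatially homogeneous companion system with parameters frozen
at their local values.  This module measures that local front velocity
c(x), assembles it into a velocity-vs-position map, integrates the reduced
boundary ODE dw/dt = c(w + eps), and finds localization points where c
crosses zero (attracting when the crossing is from positive to negative
with increasing x, so that fronts converge onto it from both sides).

For the scalar cubic model u (1 - u) (u - alpha) the traveling-front speed
has the closed form c = (1 - 2 alpha) sqrt(D / 2), used both as a fast path
and as the analytic oracle for the numeric measurement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import local_dynamics as ld
from .models import Model
from .rd_solver import Grid, integrate_rd, _crossings

__all__ = ["VelocityMap", "FrontApprox", "NoFrontError",
           "frozen_front_speed", "scalar_front_speed", "velocity_map",
           "ode_boundary", "localization_points"]


class NoFrontError(ValueError):
    """Raised when a traveling front is requested at monostable parameters."""


@dataclass(frozen=True)
class VelocityMap:
    """Signed local front velocity on the bistable part of the axis.

    c > 0 means the high-species-1 domain expands toward larger x.  Values
    between nodes are obtained by monotone piecewise-linear interpolation;
    ``extrapolated`` flags entries inferred near a bifurcation rather than
    simulated (front speeds diverge in cost there).
    """

    abscissa: np.ndarray
    c: np.ndarray
    t: float = 0.0
    extrapolated: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.abscissa) < 2:
            raise ValueError("velocity map needs at least two entries")
        if np.any(np.diff(self.abscissa) <= 0):
            raise ValueError("abscissa must be strictly increasing")
        if not np.all(np.isfinite(self.c)):
            raise ValueError("velocities must be finite")

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.abscissa[0]), float(self.abscissa[-1])

    def __call__(self, x):
        return np.interp(x, self.abscissa, self.c)


@dataclass
class FrontApprox:
    """Reduced-ODE boundary trajectory w(t)."""

    ts: np.ndarray
    w: np.ndarray
    eps: float
    w0: float
    truncated: bool = False  # halted at the edge of the bistable domain


def scalar_front_speed(alpha: float, D: float) -> float:
    """Closed-form traveling-front speed of the cubic bistable reaction."""
    return (1.0 - 2.0 * alpha) * math.sqrt(D / 2.0)


def _measure_front_speed(companion: Model, u_high: np.ndarray,
                         u_low: np.ndarray, u_unstable: np.ndarray,
                         sigma_loc: float, *, rel_change: float = 0.01,
                         max_doublings: int = 4) -> float:
    """Fit the speed of the traveling front of a homogeneous bistable system.

    A step initial condition between the two stable states is integrated on
    an auxiliary domain of >= 40 front widths; boundary positions (crossings
    of the unstable species-1 level) over the last 75% of the run are fit by
    least squares.  The time window doubles until the fitted speed changes
    by < 1% (the domain is enlarged whenever the front nears an edge).
    """
    D_max = max(max(companion.diffusivities), 1e-300)
    width = math.sqrt(D_max / sigma_loc)
    ref = float(u_unstable[0])

    T = 6.0 / sigma_loc
    n_widths = 40.0
    c_prev = None
    for _ in range(max_doublings + 1):
        L_aux = max(n_widths * width, 8.0 * width)
        # keep the expected traversal well inside the domain
        if c_prev is not None:
            L_aux = max(L_aux, 4.0 * abs(c_prev) * T + 20.0 * width)
        N = int(max(200, min(900, L_aux / (width / 8.0)))) | 1
        grid = Grid(N=N, L=L_aux)
        companion_aux = replace(companion, L=L_aux)
        ic = np.where(grid.xs[None, :] < 0.5 * L_aux,
                      u_high[:, None], u_low[:, None])
        sol = integrate_rd(companion_aux, ic, (0.0, T), grid,
                           n_out=80, rtol=1e-7, atol=1e-10)
        xs = grid.xs
        pos = np.full(len(sol.ts), np.nan)
        prev = 0.5 * L_aux
        for i in range(len(sol.ts)):
            cr = _crossings(xs, sol.fields[0, i] - ref)
            if cr.size:
                prev = cr[np.argmin(np.abs(cr - prev))]
                pos[i] = prev
        keep = sol.ts >= 0.25 * T
        tt, pp = sol.ts[keep], pos[keep]
        ok = np.isfinite(pp)
        tt, pp = tt[ok], pp[ok]
        if len(tt) < 5 or np.min(pp) < 5 * width or np.max(pp) > L_aux - 5 * width:
            # front left the measurable window: enlarge and retry
            n_widths *= 2.0
            continue
        A = np.vstack([tt, np.ones_like(tt)]).T
        (c_fit, _), res, *_ = np.linalg.lstsq(A, pp, rcond=None)
        ss_tot = np.sum((pp - pp.mean()) ** 2)
        r2 = 1.0 - (res[0] / ss_tot if res.size and ss_tot > 0 else 0.0)
        # only meaningful when the front actually moved a measurable distance
        if np.ptp(pp) > 0.5 * width and r2 < 0.999:
            warnings.warn(f"front-speed regression R^2 = {r2:.5f} < 0.999; "
                          "speed estimate may not be converged", stacklevel=2)
        scale = max(abs(c_fit), 1e-3 * sigma_loc * width)
        if c_prev is not None and abs(c_fit - c_prev) < rel_change * scale:
            return float(c_fit)
        c_prev = c_fit
        T *= 2.0
    return float(c_prev)


def frozen_front_speed(m: Model, x: float, t: float = 0.0, *,
                       method: str = "auto") -> float:
    """Local front velocity c at position x with parameters frozen at time t.

    ``method='auto'`` uses the closed form for the scalar cubic family and a
    traveling-wave simulation otherwise; 'analytic' and 'simulate' force one
    route (the pair provides an internal cross-check).  Raises NoFrontError
    at monostable parameters.
    """
    if method not in ("auto", "analytic", "simulate"):
        raise ValueError(f"unknown method {method!r}")
    if m.tag == "scalar" and method in ("auto", "analytic"):
        a = float(m.params.alpha(np.asarray(x, dtype=float)))
        if not 0.0 < a < 1.0:
            raise NoFrontError(f"scalar model monostable at x={x} (alpha={a})")
        return scalar_front_speed(a, m.params.D)
    if method == "analytic":
        raise ValueError(f"no analytic front speed for family {m.tag!r}")

    fps = ld.find_fixed_points(m, float(x), t)
    mid = ld.species1_midpoint(m)
    if ld.classify_portrait(fps, mid) != "bistable":
        raise NoFrontError(f"parameters at x={x}, t={t} are not bistable")
    stable = sorted((fp for fp in fps if fp.stable), key=lambda fp: fp.state[0])
    unstable = [fp for fp in fps if not fp.stable]
    u_low, u_high = stable[0].state, stable[-1].state
    u_uns = min(unstable, key=lambda fp: abs(fp.leading_rate)).state
    sigma_loc = min(abs(fp.leading_rate) for fp in stable)

    frozen_rhs = m.rhs

    def companion_rhs(_t, _xi, u):
        return frozen_rhs(t, x, u)

    companion = Model(n_species=m.n_species, rhs=companion_rhs,
                      diffusivities=m.diffusivities, L=1.0, gradients=(),
                      params=m.params, tag=f"{m.tag}_frozen")
    return _measure_front_speed(companion, u_high, u_low, u_uns, sigma_loc)


def velocity_map(m: Model, xs: np.ndarray, t: float = 0.0, *,
                 scan: ld.BifurcationScan | None = None,
                 edge_margin_frac: float = 0.01,
                 method: str = "auto",
                 cache: dict | None = None) -> VelocityMap:
    """Local front velocity over the bistable grid positions.

    The speed is computed once per distinct frozen parameter value (keyed on
    the local morphogen concentrations) and mapped back to x.  Entries
    within ``edge_margin_frac * L`` of a bifurcation endpoint are linearly
    extrapolated from their neighbors rather than simulated, and flagged.
    Monostable positions are simply absent from the map.
    """
    xs = np.asarray(xs, dtype=float)
    if scan is None:
        scan = ld.scan_axis(m, t, xs)
    bist = scan.bistable_mask()
    keep = [i for i, x in enumerate(xs) if bist[i]]
    if len(keep) < 2:
        raise NoFrontError("fewer than two bistable grid positions")

    margin = edge_margin_frac * m.L
    near_bif = np.zeros(len(xs), dtype=bool)
    for x_end, interior in ((scan.x_a, scan.x_crit is not None or scan.x_a > xs[0]),
                            (scan.x_p, scan.x_p < xs[-1])):
        if x_end is not None and interior:
            near_bif |= np.abs(xs - x_end) < margin

    if cache is None:
        cache = {}

    def param_key(x):
        vals = tuple(round(float(g(t, x)), 12) for g in m.gradients)
        if m.tag == "scalar":
            vals = (round(float(m.params.alpha(np.asarray(x))), 12),)
        return vals

    abscissa, cs, flags = [], [], []
    for i in keep:
        x = float(xs[i])
        if near_bif[i]:
            abscissa.append(x)
            cs.append(np.nan)
            flags.append(True)
            continue
        key = param_key(x)
        if key not in cache:
            cache[key] = frozen_front_speed(m, x, t, method=method)
        abscissa.append(x)
        cs.append(cache[key])
        flags.append(False)

    abscissa = np.asarray(abscissa)
    cs = np.asarray(cs, dtype=float)
    flags = np.asarray(flags)
    good = ~flags
    if good.sum() < 2:
        raise NoFrontError("too few simulated velocity entries")
    if flags.any():
        # linear extrapolation from the two nearest simulated entries
        fit_x, fit_c = abscissa[good], cs[good]
        for j in np.flatnonzero(flags):
            order = np.argsort(np.abs(fit_x - abscissa[j]))[:2]
            x0, x1 = fit_x[order]
            c0, c1 = fit_c[order]
            cs[j] = c0 + (c1 - c0) * (abscissa[j] - x0) / (x1 - x0)
    return VelocityMap(abscissa=abscissa, c=cs, t=t, extrapolated=flags)


def ode_boundary(vm, w0: float, eps: float, t_span: tuple[float, float], *,
                 n_out: int = 200, rtol: float = 1e-8,
                 atol: float = 1e-10) -> FrontApprox:
    """Integrate the reduced boundary ODE dw/dt = c(w + eps).

    ``vm`` is a VelocityMap, or a callable c(t, x) for time-varying
    gradients (e.g. built from instantaneous maps on a refresh schedule).
    Integration halts cleanly when w + eps leaves the map's bistable domain
    (the returned trajectory is truncated and flagged).
    """
    if isinstance(vm, VelocityMap):
        lo, hi = vm.domain
        if not lo <= w0 + eps <= hi:
            raise ValueError("w0 + eps outside the velocity map's domain")

        def c_of(t, w):
            return float(vm(w + eps))

        def edge(t, y):
            w = y[0] + eps
            return min(w - lo, hi - w)
        edge.terminal = True
        events = [edge]
    else:
        def c_of(t, w):
            return float(vm(t, w + eps))
        events = None

    t_eval = np.linspace(t_span[0], t_span[1], n_out + 1)
    sol = solve_ivp(lambda t, y: [c_of(t, y[0])], t_span, [float(w0)],
                    t_eval=t_eval, events=events, rtol=rtol, atol=atol,
                    method="RK45")
    truncated = bool(events and sol.t_events[0].size)
    return FrontApprox(ts=sol.t, w=sol.y[0], eps=float(eps), w0=float(w0),
                       truncated=truncated)


def localization_points(vm: VelocityMap) -> list[tuple[float, str]]:
    """Zero crossings of c(x) with their stability.

    Returns (x_l, 'attracting'|'repelling') pairs; a crossing is attracting
    when c passes from positive to negative with increasing x, so that
    fronts on both sides propagate toward it.  Empty when c never changes
    sign.
    """
    xs, cs = vm.abscissa, vm.c
    out: list[tuple[float, str]] = []
    for i in range(len(xs) - 1):
        if cs[i] == 0.0:
            kind = "attracting" if (i > 0 and cs[i - 1] > 0 > cs[i + 1]) \
                else "repelling"
            out.append((float(xs[i]), kind))
            continue
        if cs[i] * cs[i + 1] < 0:
            root = brentq(lambda x: float(vm(x)), xs[i], xs[i + 1],
                          xtol=1e-12 * max(1.0, xs[-1]))
            kind = "attracting" if cs[i] > 0 else "repelling"
            out.append((float(root), kind))
    return out
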