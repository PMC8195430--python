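"""Instantaneous (frozen-time) local dynamics along the axis.

For a model whose morphogen profile acts as a spatially varying bifurcation
parameter, this module answers: what are the fixed points of the local
no-diffusion dynamics at position x and frozen time t, are they stable, is
the position mono- or bistable, where are the bistable-interval endpoints
``x_a``/``x_p`` and the monostable-to-bistable transition ``x_crit``, which
attractor does a given initial condition reach, and how fast is the slowest
local convergence (the rate sigma entering kappa = gamma / sigma).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .models import Model

__all__ = [
    "FixedPoint",
    "LocalPortrait",
    "BifurcationScan",
    "find_fixed_points",
    "classify_portrait",
    "scan_axis",
    "critical_parameter",
    "basin_label",
    "basin_labels",
    "sigma_and_kappa",
]

#: eigenvalue magnitudes below this are treated as marginal (bifurcation)
MARGINAL_RATE = 1e-8

#: default position tolerance for interval-endpoint bisection, as fraction of L
POSITION_RTOL = 1e-4


@dataclass(frozen=True)
class FixedPoint:
    """A root of the local reaction term with its linear stability."""

    state: np.ndarray
    stability: str  # "stable" | "unstable" | "saddle"
    leading_rate: float  # max real part of Jacobian eigenvalues (1/time)

    @property
    def stable(self) -> bool:
        return self.stability == "stable"


@dataclass(frozen=True)
class LocalPortrait:
    x: float
    t: float
    fixed_points: tuple[FixedPoint, ...]
    classification: str  # "mono_high" | "mono_low" | "bistable"


@dataclass
class BifurcationScan:
    """Per-position classification plus refined interval endpoints.

    ``u_low``/``u_high``/``u_unstable`` hold full state vectors (NaN where a
    branch is absent) with shape (len(xs), n_species); they back the boundary
    extraction and basin labeling downstream.
    """

    xs: np.ndarray
    classes: list[str]
    x_a: float | None
    x_p: float | None
    x_crit: float | None
    u_low: np.ndarray = field(default=None, repr=False)
    u_high: np.ndarray = field(default=None, repr=False)
    u_unstable: np.ndarray = field(default=None, repr=False)
    t: float = 0.0

    @property
    def has_bistable(self) -> bool:
        return self.x_a is not None

    @property
    def width(self) -> float:
        if not self.has_bistable:
            raise ValueError("scan has no bistable interval")
        return self.x_p - self.x_a

    def bistable_mask(self) -> np.ndarray:
        return np.array([c == "bistable" for c in self.classes])

    def to_frame(self):
        """Tabular view (one row per grid position) for plotting/serialization."""
        import pandas as pd

        ns = self.u_low.shape[1]
        data = {"x": self.xs, "class": self.classes}
        for j in range(ns):
            data[f"u_low_{j + 1}"] = self.u_low[:, j]
            data[f"u_high_{j + 1}"] = self.u_high[:, j]
            data[f"u_unstable_{j + 1}"] = self.u_unstable[:, j]
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# fixed points
# ---------------------------------------------------------------------------


def _seed_grid(n_species: int, umax: float) -> np.ndarray:
    """Log-spaced seeds spanning the attainable box [0, umax]^n."""
    if n_species == 1:
        pts = np.concatenate(([0.0], np.geomspace(1e-3 * umax, umax, 15)))
        return pts[:, None]
    per_axis = np.concatenate(([0.0], np.geomspace(1e-3 * umax, umax, 7)))
    grids = np.meshgrid(*([per_axis] * n_species), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def _batch_jacobian(f: Callable, u: np.ndarray, eps_scale: float) -> np.ndarray:
    """Central-difference Jacobians for a batch of states.

    ``u`` has shape (M, n); returns (M, n, n) with J[m, i, j] = df_i/du_j.
    ``f`` maps (n, M) -> (n, M).
    """
    m, n = u.shape
    J = np.empty((m, n, n))
    for j in range(n):
        h = eps_scale * np.maximum(1.0, np.abs(u[:, j]))
        up = u.copy()
        um = u.copy()
        up[:, j] += h
        um[:, j] = np.maximum(um[:, j] - h, 0.0)  # stay in the domain of f
        denom = up[:, j] - um[:, j]
        J[:, :, j] = ((f(up.T) - f(um.T)) / denom).T
    return J


def find_fixed_points(m: Model, x: float, t: float,
                      seeds: np.ndarray | None = None,
                      ftol: float = 1e-10,
                      merge_tol: float = 1e-6) -> list[FixedPoint]:
    """Fixed points of the frozen local dynamics at (x, t).

    A damped Newton iteration is run from every seed of a log-spaced grid
    spanning the attainable box simultaneously; converged roots are merged
    within ``merge_tol`` (relative to the box scale) and classified by the
    eigenvalues of a finite-difference Jacobian.  Points with a marginal
    leading eigenvalue (|Re| < 1e-8) are classified unstable with a warning.
    """
    f_local = m.local_rhs(t, x)
    n = m.n_species
    umax = max(m.umax, 1e-12)
    if seeds is None:
        seeds = _seed_grid(n, umax)
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))

    def fbatch(u):  # u: (n, M) -> (n, M)
        out = np.asarray(f_local(u), dtype=float)
        return out.reshape(n, -1)

    u = seeds.copy()
    scale = max(1.0, umax)
    for _ in range(80):
        r = fbatch(u.T).T  # (M, n)
        J = _batch_jacobian(fbatch, u, 1e-7)
        try:
            step = np.linalg.solve(J, r[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(Ji, ri, rcond=None)[0]
                             for Ji, ri in zip(J, r)])
        # damp: cap the step at half the box scale to avoid wild excursions
        norms = np.max(np.abs(step), axis=1)
        damp = np.minimum(1.0, 0.5 * scale / np.maximum(norms, 1e-300))
        u = u - step * damp[:, None]
        u = np.clip(u, 0.0, 10.0 * scale)
        if np.all(np.max(np.abs(r), axis=1) < ftol):
            break

    res = np.max(np.abs(fbatch(u.T).T), axis=1)
    ok = res < max(ftol, 1e-9)
    roots = u[ok]
    if roots.size == 0:
        warnings.warn(f"no fixed point found at x={x}, t={t} "
                      "(degenerate parameters?)", stacklevel=2)
        return []

    # merge duplicates
    merged: list[np.ndarray] = []
    tol = merge_tol * scale
    for r_ in roots:
        if not any(np.max(np.abs(r_ - q)) < tol for q in merged):
            merged.append(r_)

    out: list[FixedPoint] = []
    for state in merged:
        J = _batch_jacobian(fbatch, state[None], 1e-7)[0]
        eig = np.linalg.eigvals(J)
        lead = float(np.max(eig.real))
        if abs(lead) < MARGINAL_RATE:
            warnings.warn(
                f"marginal fixed point at x={x}, t={t}: leading rate "
                f"{lead:.2e}; classifying unstable", stacklevel=2)
            stability = "unstable"
        elif lead < 0:
            stability = "stable"
        else:
            n_pos = int(np.sum(eig.real > 0))
            stability = "saddle" if 0 < n_pos < len(eig) else "unstable"
        out.append(FixedPoint(state=state, stability=stability,
                              leading_rate=lead))
    out.sort(key=lambda fp: fp.state[0])
    return out


def species1_midpoint(m: Model) -> float:
    """Midpoint of the attainable species-1 range, the high/low divider."""
    p = m.params
    if m.tag in ("toggle1", "toggle2"):
        return 0.5 * p.a1 / p.beta
    if m.tag == "hb":
        return 0.5 * (p.alpha_b + p.alpha_h) / p.beta
    return 0.5 * m.umax


def classify_portrait(fps: Sequence[FixedPoint],
                      midpoint: float = 0.5) -> str:
    """'mono_high' / 'mono_low' / 'bistable' from a fixed-point list.

    With a single stable point, high vs. low is decided by comparing its
    species-1 value to ``midpoint`` (half the attainable species-1 range for
    the built-in families).  More than two stable points is unsupported.
    """
    stable = [fp for fp in fps if fp.stable]
    if len(stable) == 2:
        return "bistable"
    if len(stable) > 2:
        raise ValueError(f"unsupported topology: {len(stable)} stable points")
    if len(stable) == 0:
        raise ValueError("no stable fixed point (degenerate parameters)")
    return "mono_high" if stable[0].state[0] >= midpoint else "mono_low"


def portrait(m: Model, x: float, t: float) -> LocalPortrait:
    fps = find_fixed_points(m, x, t)
    cls = classify_portrait(fps, species1_midpoint(m))
    return LocalPortrait(x=float(x), t=float(t),
                         fixed_points=tuple(fps), classification=cls)


# ---------------------------------------------------------------------------
# axis scan
# ---------------------------------------------------------------------------


def _branch_rows(m: Model, fps: Sequence[FixedPoint]):
    """(u_low, u_high, u_unstable) state rows; NaN where a branch is absent."""
    n = m.n_species
    low = np.full(n, np.nan)
    high = np.full(n, np.nan)
    uns = np.full(n, np.nan)
    stable = sorted((fp for fp in fps if fp.stable), key=lambda fp: fp.state[0])
    unstable = [fp for fp in fps if not fp.stable]
    if len(stable) == 1:
        mid = species1_midpoint(m)
        if stable[0].state[0] >= mid:
            high = stable[0].state
        else:
            low = stable[0].state
    elif len(stable) >= 2:
        low = stable[0].state
        high = stable[-1].state
    if unstable:
        # the separatrix-defining middle point: closest to the stable midgap
        uns = min(unstable, key=lambda fp: abs(fp.leading_rate)).state
    return low, high, uns


def scan_axis(m: Model, t: float, xs: np.ndarray,
              position_tol: float | None = None) -> BifurcationScan:
    """Classify every grid position and refine the bistable endpoints.

    ``x_a`` / ``x_p`` are located by bisection between adjacent grid cells of
    differing class, to ``position_tol`` (default 1e-4 L).  ``x_crit`` is the
    monostable-to-bistable transition on the anterior side, when present.
    With several bistable blocks the largest is reported (and a warning
    raised); the per-position classification list is always complete.
    """
    xs = np.asarray(xs, dtype=float)
    if np.any(np.diff(xs) <= 0):
        raise ValueError("xs must be sorted ascending")
    if position_tol is None:
        position_tol = POSITION_RTOL * m.L

    mid = species1_midpoint(m)
    classes: list[str] = []
    n = m.n_species
    u_low = np.empty((len(xs), n))
    u_high = np.empty((len(xs), n))
    u_uns = np.empty((len(xs), n))
    for i, x in enumerate(xs):
        fps = find_fixed_points(m, float(x), t)
        classes.append(classify_portrait(fps, mid))
        u_low[i], u_high[i], u_uns[i] = _branch_rows(m, fps)

    def class_at(x: float) -> str:
        return classify_portrait(find_fixed_points(m, x, t), mid)

    def refine(lo: float, hi: float, lo_cls: str, hi_cls: str) -> float:
        """Bisect the transition between positions of differing class."""
        while hi - lo > position_tol:
            mid_x = 0.5 * (lo + hi)
            c = class_at(mid_x)
            if c == lo_cls:
                lo = mid_x
            else:
                hi = mid_x
        return 0.5 * (lo + hi)

    bist = np.array([c == "bistable" for c in classes])
    if not bist.any():
        return BifurcationScan(xs=xs, classes=classes, x_a=None, x_p=None,
                               x_crit=None, u_low=u_low, u_high=u_high,
                               u_unstable=u_uns, t=t)

    # contiguous bistable blocks
    idx = np.flatnonzero(bist)
    blocks = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    if len(blocks) > 1:
        warnings.warn(f"{len(blocks)} disjoint bistable blocks; reporting "
                      "endpoints of the largest", stacklevel=2)
    block = max(blocks, key=len)
    i0, i1 = block[0], block[-1]

    if i0 == 0:
        x_a = float(xs[0])
        anterior_cls = None
    else:
        anterior_cls = classes[i0 - 1]
        x_a = refine(xs[i0 - 1], xs[i0], anterior_cls, "bistable")
    if i1 == len(xs) - 1:
        x_p = float(xs[-1])
    else:
        x_p = refine(xs[i1], xs[i1 + 1], "bistable", classes[i1 + 1])

    x_crit = x_a if anterior_cls in ("mono_high", "mono_low") else None
    return BifurcationScan(xs=xs, classes=classes, x_a=x_a, x_p=x_p,
                           x_crit=x_crit, u_low=u_low, u_high=u_high,
                           u_unstable=u_uns, t=t)


def critical_parameter(classify: Callable[[float], str],
                       lo: float, hi: float, tol: float = 1e-6) -> float:
    """Bisect a scalar bifurcation parameter to its critical value.

    ``classify(theta)`` must return a classification string; the two interval
    endpoints must classify differently ('bistable' on exactly one side).
    """
    c_lo, c_hi = classify(lo), classify(hi)
    if (c_lo == "bistable") == (c_hi == "bistable"):
        raise ValueError(
            f"classification does not change over [{lo}, {hi}]: "
            f"{c_lo!r} at both ends of the bistability test")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if (classify(mid) == "bistable") == (c_lo == "bistable"):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# basins
# ---------------------------------------------------------------------------


def _relax_to_attractors(f: Callable, states: np.ndarray,
                         attractors: list[np.ndarray],
                         sigma_local: float,
                         radius_rtol: float = 1e-4,
                         cap_factor: float = 50.0) -> np.ndarray:
    """Integrate a batch of states under du/dt = f(u) until each is within a
    convergence radius of an attractor; returns the attractor index per state
    (-1 where the time cap was hit first)."""
    from scipy.integrate import solve_ivp

    states = np.array(states, dtype=float)
    n_states, n = states.shape
    radii = np.array([radius_rtol * max(1.0, np.max(np.abs(a)))
                      for a in attractors])
    labels = np.full(n_states, -1, dtype=int)

    def assign(u):
        for k, (a, r) in enumerate(zip(attractors, radii)):
            d = np.max(np.abs(u - a), axis=1)
            newly = (labels == -1) & (d < r)
            labels[newly] = k

    assign(states)
    t_cap = cap_factor / sigma_local
    t = 0.0
    chunk = t_cap / 10.0
    y = states
    while t < t_cap and np.any(labels == -1):
        live = labels == -1
        y_live = y[live]

        def rhs(_t, yy):
            u = yy.reshape(-1, n).T
            return np.asarray(f(u)).reshape(n, -1).T.ravel()

        sol = solve_ivp(rhs, (0.0, chunk), y_live.ravel(),
                        method="RK45", rtol=1e-8, atol=1e-10)
        y_new = sol.y[:, -1].reshape(-1, n)
        y[live] = y_new
        t += chunk
        assign(y)
    return labels


def basin_labels(m: Model, x: float, t: float,
                 ics: np.ndarray) -> list[str]:
    """Attractor labels ('high'/'low'/'indeterminate') for a batch of
    initial conditions under the frozen no-diffusion dynamics at (x, t)."""
    fps = find_fixed_points(m, x, t)
    stable = sorted((fp for fp in fps if fp.stable), key=lambda fp: fp.state[0])
    if not stable:
        raise ValueError(f"no stable fixed point at x={x}, t={t}")
    if len(stable) == 1:
        mid = species1_midpoint(m)
        name = "high" if stable[0].state[0] >= mid else "low"
        return [name] * len(np.atleast_2d(ics))
    if len(stable) > 2:
        raise ValueError("unsupported topology: >2 stable points")
    # two attractors: high/low is relative (sorted by species-1 value)
    names = ["low", "high"]
    sigma_local = min(abs(fp.leading_rate) for fp in stable)
    f = m.local_rhs(t, x)
    ics = np.atleast_2d(np.asarray(ics, dtype=float))
    idx = _relax_to_attractors(f, ics, [fp.state for fp in stable],
                               sigma_local)
    return [names[i] if i >= 0 else "indeterminate" for i in idx]


def basin_label(m: Model, x: float, t: float, ic: np.ndarray) -> str:
    """Single-initial-condition convenience wrapper around basin_labels."""
    return basin_labels(m, x, t, np.atleast_2d(ic))[0]


# ---------------------------------------------------------------------------
# timescales
# ---------------------------------------------------------------------------


def sigma_and_kappa(m: Model, gamma: float, t: float | None = None,
                    n_grid: int = 41) -> tuple[float, float]:
    """Slowest bistable convergence rate sigma and the ratio kappa = gamma/sigma.

    sigma is the minimum of |leading eigenvalue| over both stable fixed
    points at every bistable position of the frozen profile.  By default the
    profile is the t -> infinity limit (emerging gradients); for gradients
    without a nontrivial final profile (e.g. decaying) pass the time ``t`` at
    which to freeze, typically 0.
    """
    if t is None:
        if m.gradients and m.gradients[0].kind == "emerging":
            from .models import build_model

            frozen = build_model(m.tag, m.params, (m.gradients[0].final(),),
                                 m.L)
        elif m.gradients and m.gradients[0].kind in ("decaying", "bcd"):
            raise ValueError(
                "gradient has no nontrivial t->infinity profile; pass the "
                "freeze time t explicitly (typically t=0)")
        else:
            frozen = m
        t_eval = 0.0
    else:
        frozen = m
        t_eval = float(t)

    xs = np.linspace(0.0, m.L, n_grid)
    mid = species1_midpoint(m)
    sigma = np.inf
    found = False
    for x in xs:
        fps = find_fixed_points(frozen, float(x), t_eval)
        if classify_portrait(fps, mid) != "bistable":
            continue
        found = True
        for fp in fps:
            if fp.stable:
                sigma = min(sigma, abs(fp.leading_rate))
    if not found:
        raise ValueError("no bistable position on the frozen profile; "
                         "sigma is undefined")
    return float(sigma), float(gamma) / float(sigma)
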