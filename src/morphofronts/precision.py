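"""Boundary precision and reproducibility metrics.

Given an ensemble of initial conditions (cell-to-cell variation within one
embryo, or uniform-but-variable conditions across embryos -- the arithmetic
is identical, only the reading differs), the tight bounds (x~a, x~p) locate
the guaranteed-high and guaranteed-low flanks of the final bistable
interval, and

    R = (x~p - x~a) / (x_p - x_a)

is the fraction of the bistable interval over which the outcome is not
guaranteed: R = 0 means a precise (fully reproducible) boundary.  Two
experiment protocols produce R under dynamic gradients: boundary formation
while a gradient emerges, and the "sweep" in which an established gradient
decays, converting irregular bistable territory into monostable territory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import local_dynamics as ld
from .models import GradientSpec, Model, build_model

__all__ = [
    "ICEnsemble",
    "PrecisionResult",
    "tight_bounds",
    "irregularity_R",
    "irregularity_at_time",
    "emergence_experiment",
    "sweep_experiment",
    "readout_time_for_shift",
]

#: relaxation is declared converged when max |du/dt| drops below this
RELAX_RATE_TOL = 1e-8
#: and is capped at this many multiples of the slowest local timescale
RELAX_CAP = 100.0


@dataclass(frozen=True)
class ICEnsemble:
    """A set of nonnegative initial states, with its generating seed.

    ``interpretation`` records whether members represent cells within one
    embryo (precision reading) or whole embryos (reproducibility reading);
    every computation treats both identically.
    """

    states: np.ndarray  # (n_members, n_species)
    interpretation: str = "cells_within_embryo"
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "states",
                           np.atleast_2d(np.asarray(self.states, dtype=float)))
        if np.any(self.states < 0):
            raise ValueError("initial conditions must be nonnegative")
        if self.interpretation not in ("cells_within_embryo", "embryos"):
            raise ValueError(f"unknown interpretation {self.interpretation!r}")

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class PrecisionResult:
    """Tight bounds and irregularity metrics for one protocol run."""

    x_tilde_a: float
    x_tilde_p: float
    R: float
    x_a: float
    x_p: float
    t_f: float | None = None
    kappa: float | None = None
    R_t: np.ndarray | None = None
    indeterminate: bool = False  # any basin label hit the time cap
    swept: bool = False  # whole domain monostable at readout
    fields: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# bounds and metrics
# ---------------------------------------------------------------------------


def _bounds_from_predicates(all_high: Callable[[float], bool],
                            none_high: Callable[[float], bool],
                            x_a: float, x_p: float,
                            tol: float) -> tuple[float, float]:
    """Bisect the tight bounds on [x_a, x_p] given monotone predicates.

    ``all_high(x)`` is True where the basin at x still contains every
    ensemble member; under basin nesting it holds on a prefix [x_a, x~a].
    ``none_high(x)`` holds on a suffix [x~p, x_p].  Endpoint checks at
    x_a + tol and x_p - tol pin degenerate cases (boundary at an interval
    end) exactly to the endpoint.
    """
    lo, hi = x_a, x_p
    if all_high(min(x_p - tol, x_p)):
        xa_t = x_p
    elif not all_high(x_a + tol):
        xa_t = x_a
    else:
        a, b = x_a + tol, x_p - tol
        while b - a > tol:
            mid = 0.5 * (a + b)
            if all_high(mid):
                a = mid
            else:
                b = mid
        xa_t = 0.5 * (a + b)

    if none_high(x_a + tol):
        xp_t = x_a
    elif not none_high(x_p - tol):
        xp_t = x_p
    else:
        a, b = x_a + tol, x_p - tol
        while b - a > tol:
            mid = 0.5 * (a + b)
            if none_high(mid):
                b = mid
            else:
                a = mid
        xp_t = 0.5 * (a + b)
    return xa_t, max(xp_t, xa_t)


def tight_bounds(m: Model, scan: ld.BifurcationScan, ens: ICEnsemble,
                 t: float = 0.0,
                 position_tol: float | None = None) -> tuple[float, float]:
    """Tight bounds (x~a, x~p) of the possibly-irregular region.

    x~a is the largest x in the bistable interval whose high basin contains
    every ensemble member; x~p the smallest x whose high basin contains
    none.  Basin membership comes from integrating the frozen local
    dynamics; nesting of basins along a monotone gradient makes both
    predicates monotone, so bisection applies.  Indeterminate labels widen
    the bounds conservatively (counted outside the basin for x~a, inside
    for x~p).
    """
    if not scan.has_bistable:
        raise ValueError("scan has no bistable interval")
    if position_tol is None:
        position_tol = ld.POSITION_RTOL * m.L
    flagged = {"indeterminate": False}

    def labels_at(x: float) -> list[str]:
        labs = ld.basin_labels(m, x, t, ens.states)
        if "indeterminate" in labs:
            flagged["indeterminate"] = True
        return labs

    def all_high(x: float) -> bool:
        return all(lab == "high" for lab in labels_at(x))

    def none_high(x: float) -> bool:
        return all(lab == "low" for lab in labels_at(x))

    xa_t, xp_t = _bounds_from_predicates(all_high, none_high,
                                         scan.x_a, scan.x_p, position_tol)
    if flagged["indeterminate"]:
        warnings.warn("indeterminate basin labels widened the tight bounds",
                      stacklevel=2)
    return xa_t, xp_t


def irregularity_R(bounds: tuple[float, float],
                   scan: ld.BifurcationScan) -> float:
    """R = (x~p - x~a) / (x_p - x_a), the irregular fraction in [0, 1]."""
    if not scan.has_bistable or scan.width <= 0:
        raise ValueError("degenerate bistable interval: R undefined")
    xa_t, xp_t = bounds
    return (xp_t - xa_t) / scan.width


def irregularity_at_time(R: float, scan_t: ld.BifurcationScan,
                         scan_tf: ld.BifurcationScan) -> float:
    """Rescale R to the bistable width at an earlier time t:
    R_t = [width(t_f) / width(t)] * R."""
    if not scan_t.has_bistable or scan_t.width <= 0:
        raise ValueError("zero-width bistable interval at t: R_t undefined")
    return (scan_tf.width / scan_t.width) * R


# ---------------------------------------------------------------------------
# shared machinery for the two protocols
# ---------------------------------------------------------------------------


def _integrate_ensemble(m: Model, xs: np.ndarray, states: np.ndarray,
                        t0: float, t1: float, *, rtol=1e-8, atol=1e-10):
    """Integrate every ensemble member at every position under the
    time-dependent local dynamics; returns final states (n_ics, nx, ns)."""
    n_ics, ns = states.shape
    nx = len(xs)
    xs_rep = np.repeat(xs, n_ics)  # (nx * n_ics,)
    y0 = np.tile(states, (nx, 1))  # (nx * n_ics, ns)
    rhs = m.rhs

    def f(t, y):
        u = y.reshape(-1, ns).T  # (ns, nx * n_ics)
        return np.asarray(rhs(t, xs_rep, u)).reshape(ns, -1).T.ravel()

    sol = solve_ivp(f, (t0, t1), y0.ravel(), method="RK45",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ensemble integration failed: {sol.message}")
    return sol.y[:, -1].reshape(nx, n_ics, ns).transpose(1, 0, 2)


def _relax_frozen(m_frozen: Model, xs: np.ndarray, states, t_frozen: float,
                  sigma: float, *, rtol=1e-8, atol=1e-10):
    """Relax states (n_ics, nx, ns) under the frozen dynamics until the
    largest rate of change falls below RELAX_RATE_TOL (capped)."""
    n_ics, nx, ns = states.shape
    xs_rep = np.repeat(xs, n_ics)
    y = states.transpose(1, 0, 2).reshape(-1, ns)
    rhs = m_frozen.rhs

    def f(_t, yy):
        u = yy.reshape(-1, ns).T
        return np.asarray(rhs(t_frozen, xs_rep, u)).reshape(ns, -1).T.ravel()

    t_cap = RELAX_CAP / sigma
    chunk = t_cap / 10.0
    t = 0.0
    yflat = y.ravel()
    while t < t_cap:
        rate = np.max(np.abs(f(0.0, yflat)))
        if rate < RELAX_RATE_TOL:
            break
        sol = solve_ivp(f, (0.0, chunk), yflat, method="RK45",
                        rtol=rtol, atol=atol)
        yflat = sol.y[:, -1]
        t += chunk
    return yflat.reshape(nx, n_ics, ns).transpose(1, 0, 2)


def _label_final_states(scan: ld.BifurcationScan, final: np.ndarray,
                        midpoint: float) -> np.ndarray:
    """Label relaxed states high/low by the nearest stable branch.

    ``final`` has shape (n_ics, nx, ns) aligned with scan.xs; returns a
    boolean high-matrix (n_ics, nx).  At monostable positions the class
    decides the label outright.
    """
    n_ics, nx, ns = final.shape
    high = np.zeros((n_ics, nx), dtype=bool)
    for i in range(nx):
        cls = scan.classes[i]
        if cls == "mono_high":
            high[:, i] = True
        elif cls == "mono_low":
            high[:, i] = False
        else:
            d_hi = np.max(np.abs(final[:, i, :] - scan.u_high[i]), axis=1)
            d_lo = np.max(np.abs(final[:, i, :] - scan.u_low[i]), axis=1)
            high[:, i] = d_hi < d_lo
    return high


def _bounds_from_protocol(label_fn: Callable[[float], np.ndarray],
                          scan: ld.BifurcationScan,
                          tol: float) -> tuple[float, float]:
    """Tight bounds where labels come from re-running a protocol at x."""

    def all_high(x: float) -> bool:
        return bool(np.all(label_fn(x)))

    def none_high(x: float) -> bool:
        return bool(np.all(~label_fn(x)))

    return _bounds_from_predicates(all_high, none_high,
                                   scan.x_a, scan.x_p, tol)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------


def emergence_experiment(m: Model, ens: ICEnsemble,
                         kappa_targets: Sequence[float],
                         n_positions: int = 100,
                         *, emergence_decades: float = 9.0,
                         store_fields: bool = True,
                         rtol: float = 1e-8) -> list[PrecisionResult]:
    """Boundary formation while the gradient grows from zero (Fig-2 style).

    For each target kappa the emergence rate is set to gamma = kappa * sigma
    (sigma from Jacobian eigenvalues on the final profile); every ensemble
    member is integrated at every one of ``n_positions`` grid positions
    through the emergence phase and then relaxed on the final static
    profile.  kappa = inf is the static-gradient control.  R is measured
    against the final-profile bistability scan, with the tight bounds
    refined by re-running the protocol at bisection positions.
    """
    g = m.gradients[0]
    if g.kind != "emerging":
        raise ValueError("emergence_experiment needs an emerging gradient")
    final_model = build_model(m.tag, m.params, (g.final(),), m.L)
    sigma, _ = ld.sigma_and_kappa(m, 0.0)
    xs = np.linspace(0.0, m.L, n_positions)
    scan = ld.scan_axis(final_model, 0.0, xs)
    if not scan.has_bistable:
        raise ValueError("final profile has no bistable region")
    mid = ld.species1_midpoint(m)
    tol = ld.POSITION_RTOL * m.L

    results = []
    for kappa in kappa_targets:
        if np.isinf(kappa):
            run_model = final_model
            t_emerge = 0.0
        else:
            gamma = kappa * sigma
            gk = GradientSpec(kind="emerging", b=g.b, lam=g.lam, gamma=gamma,
                              source=g.source)
            run_model = build_model(m.tag, m.params, (gk,), m.L)
            # amplitude within e^-decades of final once t exceeds this
            t_emerge = emergence_decades / gamma

        def protocol_states(xq: np.ndarray) -> np.ndarray:
            """Relaxed final states (n_ics, len(xq), ns) of the protocol."""
            if t_emerge > 0:
                states = _integrate_ensemble(run_model, xq, ens.states,
                                             0.0, t_emerge, rtol=rtol)
            else:
                states = np.broadcast_to(
                    ens.states[:, None, :],
                    (len(ens), len(xq), m.n_species)).copy()
            return _relax_frozen(final_model, xq, states, 0.0, sigma,
                                 rtol=rtol)

        final_states = protocol_states(xs) if store_fields else None

        def label_fn(x: float) -> np.ndarray:
            xq = np.array([x])
            sub = _subscan(scan, xq, final_model, mid)
            return _label_final_states(sub, protocol_states(xq), mid)[:, 0]

        xa_t, xp_t = _bounds_from_protocol(label_fn, scan, tol)
        R = irregularity_R((xa_t, xp_t), scan)
        results.append(PrecisionResult(
            x_tilde_a=xa_t, x_tilde_p=xp_t, R=R, x_a=scan.x_a, x_p=scan.x_p,
            kappa=float(kappa), fields=final_states))
    return results


def _subscan(scan: ld.BifurcationScan, xq: np.ndarray, model: Model,
             midpoint: float) -> ld.BifurcationScan:
    """A scan restricted to query positions (classified fresh off-grid)."""
    if xq is scan.xs or (len(xq) == len(scan.xs)
                        and np.array_equal(xq, scan.xs)):
        return scan
    classes = []
    n = model.n_species
    u_low = np.empty((len(xq), n))
    u_high = np.empty((len(xq), n))
    u_uns = np.empty((len(xq), n))
    for i, x in enumerate(xq):
        fps = ld.find_fixed_points(model, float(x), scan.t)
        classes.append(ld.classify_portrait(fps, midpoint))
        u_low[i], u_high[i], u_uns[i] = ld._branch_rows(model, fps)
    return ld.BifurcationScan(xs=np.asarray(xq), classes=classes,
                              x_a=scan.x_a, x_p=scan.x_p, x_crit=scan.x_crit,
                              u_low=u_low, u_high=u_high, u_unstable=u_uns,
                              t=scan.t)


def sweep_experiment(m: Model, ens: ICEnsemble, t_f: float,
                     n_positions: int = 100, *,
                     compute_R_t: bool = False,
                     rtol: float = 1e-8) -> PrecisionResult:
    """Precision enhancement by gradient decay (Fig-3 style).

    The morphogen decays from t = 0 to the readout time t_f; the profile is
    then held fixed and every cell relaxes to steady state.  R is computed
    against the bistability scan of the frozen (t = t_f) profile.  If decay
    has made the whole domain monostable the boundary has been fully swept:
    R is reported as 0 with the ``swept`` flag set.
    """
    g = m.gradients[0]
    if g.kind not in ("decaying", "bcd"):
        raise ValueError("sweep_experiment needs a decaying gradient")
    frozen_model = build_model(m.tag, m.params, (g.frozen_at(t_f),), m.L)
    xs = np.linspace(0.0, m.L, n_positions)
    scan_tf = ld.scan_axis(frozen_model, 0.0, xs)
    mid = ld.species1_midpoint(m)
    tol = ld.POSITION_RTOL * m.L

    if not scan_tf.has_bistable:
        return PrecisionResult(x_tilde_a=np.nan, x_tilde_p=np.nan, R=0.0,
                               x_a=np.nan, x_p=np.nan, t_f=t_f, swept=True)

    sigma_tf = np.inf
    for x in scan_tf.xs[scan_tf.bistable_mask()]:
        for fp in ld.find_fixed_points(frozen_model, float(x), 0.0):
            if fp.stable:
                sigma_tf = min(sigma_tf, abs(fp.leading_rate))

    def run_at(xq: np.ndarray) -> np.ndarray:
        states = _integrate_ensemble(m, xq, ens.states, 0.0, t_f, rtol=rtol)
        states = _relax_frozen(frozen_model, xq, states, 0.0, sigma_tf,
                               rtol=rtol)
        sub = _subscan(scan_tf, xq, frozen_model, mid)
        return _label_final_states(sub, states, mid)

    def label_fn(x: float) -> np.ndarray:
        return run_at(np.array([x]))[:, 0]

    xa_t, xp_t = _bounds_from_protocol(label_fn, scan_tf, tol)
    R = irregularity_R((xa_t, xp_t), scan_tf)
    R_t = None
    if compute_R_t:
        ts = np.linspace(0.0, t_f, 11)
        vals = []
        for tq in ts:
            frozen_q = build_model(m.tag, m.params, (g.frozen_at(tq),), m.L)
            scan_q = ld.scan_axis(frozen_q, 0.0, xs)
            vals.append(irregularity_at_time(R, scan_q, scan_tf)
                        if scan_q.has_bistable else np.nan)
        R_t = np.column_stack([ts, vals])
    return PrecisionResult(x_tilde_a=xa_t, x_tilde_p=xp_t, R=R,
                           x_a=scan_tf.x_a, x_p=scan_tf.x_p, t_f=t_f,
                           R_t=R_t)


def readout_time_for_shift(g: GradientSpec, delta: float, *,
                           numeric: bool = False,
                           level: float | None = None) -> float:
    """Readout time t_f at which the decaying profile's level sets have
    shifted anteriorly by ``delta``.

    For the exponential decaying gradient the level sets move at speed
    lambda * gamma, so t_f = delta / (lambda * gamma).  ``numeric=True``
    root-finds the same time from the trajectory of the position holding a
    fixed concentration ``level`` (any level gives the same answer for an
    exponential profile) and is exposed for non-exponential profiles.
    """
    if g.kind != "decaying":
        raise ValueError("readout_time_for_shift needs a decaying gradient")
    if g.gamma <= 0:
        raise ValueError("gamma = 0: the profile never shifts (no finite t_f)")
    if delta <= 0:
        raise ValueError("shift must be positive")
    if not numeric:
        return delta / (g.lam * g.gamma)

    from scipy.optimize import brentq

    c = level if level is not None else g.b * np.exp(-1.0)
    # position of the level set at t = 0
    x0 = -g.lam * np.log(c / g.b)

    def moved(t):
        return float(g(t, max(x0 - delta, 0.0))) - c

    t_hi = 10.0 * delta / (g.lam * g.gamma)
    return brentq(moved, 0.0, t_hi, xtol=1e-12)
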