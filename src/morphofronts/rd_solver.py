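"""Method-of-lines integration of the reaction-diffusion systems.

Space is discretized on a node-centered grid with a second-order central
Laplacian; no-flux (zero-gradient) boundaries are imposed through mirrored
ghost nodes.  Time integration uses SciPy's stiff-capable LSODA with a
banded Jacobian structure (species are interleaved per node, so the band
width equals the species count).  Species with zero diffusivity reduce
exactly to independent per-node reaction ODEs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .local_dynamics import BifurcationScan
from .models import Model

__all__ = ["Grid", "PDESolution", "BoundaryTrajectory",
           "integrate_rd", "extract_boundary"]


@dataclass(frozen=True)
class Grid:
    """Node-centered spatial grid: x_i = i dx, endpoints included."""

    N: int
    L: float

    def __post_init__(self) -> None:
        if self.N < 16:
            raise ValueError("grid needs at least 16 nodes")
        if self.L <= 0:
            raise ValueError("domain length must be positive")

    @property
    def dx(self) -> float:
        return self.L / (self.N - 1)

    @property
    def xs(self) -> np.ndarray:
        return np.linspace(0.0, self.L, self.N)


@dataclass
class PDESolution:
    """Solution fields with shape (n_species, n_times, N)."""

    ts: np.ndarray
    grid: Grid
    fields: np.ndarray

    def species(self, j: int) -> np.ndarray:
        return self.fields[j]

    def final_state(self) -> np.ndarray:
        """State profile at the last output time, shape (n_species, N)."""
        return self.fields[:, -1, :]

    def to_frame(self):
        """Long-format table (t, x, species, value)."""
        import pandas as pd

        ns, nt, N = self.fields.shape
        t = np.repeat(self.ts, N)
        x = np.tile(self.grid.xs, nt)
        frames = []
        for j in range(ns):
            frames.append(pd.DataFrame({
                "t": t, "x": x, "species": j + 1,
                "value": self.fields[j].ravel()}))
        return pd.concat(frames, ignore_index=True)


@dataclass
class BoundaryTrajectory:
    """Boundary position over time (NaN before the front has formed)."""

    ts: np.ndarray
    w: np.ndarray
    t_form: float | None
    width: np.ndarray

    def formed(self) -> np.ndarray:
        """Mask of output times at/after front formation with a defined w."""
        if self.t_form is None:
            return np.zeros_like(self.ts, dtype=bool)
        return (self.ts >= self.t_form) & np.isfinite(self.w)


def _laplacian(u: np.ndarray, dx: float) -> np.ndarray:
    """Central second difference with mirrored ghost nodes (no flux)."""
    lap = np.empty_like(u)
    lap[:, 1:-1] = (u[:, 2:] - 2.0 * u[:, 1:-1] + u[:, :-2])
    lap[:, 0] = 2.0 * (u[:, 1] - u[:, 0])
    lap[:, -1] = 2.0 * (u[:, -2] - u[:, -1])
    return lap / (dx * dx)


def integrate_rd(m: Model, ic_profile: np.ndarray, t_span: tuple[float, float],
                 grid: Grid, *, n_out: int = 200, t_eval=None,
                 method: str = "LSODA", rtol: float = 1e-6,
                 atol: float = 1e-9, max_step: float = np.inf) -> PDESolution:
    """Integrate the reaction-diffusion system on ``grid`` over ``t_span``.

    ``ic_profile`` has shape (n_species, N).  Time-varying gradients are
    evaluated inside the right-hand side at solver time (non-autonomous
    integration).  Output is returned at ``t_eval`` or at ``n_out`` evenly
    spaced times.  Raises on integrator failure or nonfinite state; values
    below -1e-9 trigger a diagnostic warning but are never clipped.
    """
    ic = np.asarray(ic_profile, dtype=float)
    ns = m.n_species
    if ic.shape != (ns, grid.N):
        raise ValueError(f"ic_profile must have shape ({ns}, {grid.N})")
    if np.any(ic < 0):
        raise ValueError("ic_profile must be nonnegative")

    xs = grid.xs
    dx = grid.dx
    D = np.asarray(m.diffusivities, dtype=float)[:, None]
    rhs_react = m.rhs

    def rhs(t, y):
        u = y.reshape(grid.N, ns).T
        du = np.asarray(rhs_react(t, xs, u), dtype=float).reshape(ns, grid.N)
        if np.any(D != 0.0):
            du = du + D * _laplacian(u, dx)
        return du.T.ravel()

    if t_eval is None:
        t_eval = np.linspace(t_span[0], t_span[1], n_out + 1)
    options = {}
    if method in ("LSODA", "BDF", "Radau") and np.any(D != 0.0):
        if method == "LSODA":
            options = {"lband": ns, "uband": ns}
        else:
            from scipy.sparse import diags

            k = ns
            N_tot = grid.N * ns
            offs = list(range(-k, k + 1))
            options = {"jac_sparsity": diags(
                [np.ones(N_tot - abs(o)) for o in offs], offs)}

    sol = solve_ivp(rhs, t_span, ic.T.ravel(), method=method, t_eval=t_eval,
                    rtol=rtol, atol=atol, max_step=max_step, **options)
    if not sol.success:
        raise RuntimeError(
            f"RD integration failed at t={sol.t[-1] if sol.t.size else t_span[0]}:"
            f" {sol.message}")
    fields = sol.y.T.reshape(len(sol.t), grid.N, ns).transpose(2, 0, 1)
    if not np.all(np.isfinite(fields)):
        raise RuntimeError("nonfinite values in RD solution")
    if np.min(fields) < -1e-9:
        warnings.warn(f"RD solution dips to {np.min(fields):.3e} < -1e-9; "
                      "consider tighter tolerances", stacklevel=2)
    return PDESolution(ts=np.asarray(sol.t), grid=grid, fields=fields)


# ---------------------------------------------------------------------------
# boundary extraction
# ---------------------------------------------------------------------------


def _reference_curve(scan: BifurcationScan, xs: np.ndarray,
                     species: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ref, lo, hi) arrays on ``xs``.

    In the bistable interval the reference is the local unstable steady
    state; in monostable stretches it falls back to the midpoint of the
    stable branches at the nearest bistable position.  lo/hi are the local
    (or nearest-bistable) stable-branch values used for width levels.
    """
    if not scan.has_bistable:
        raise ValueError("scan has no bistable interval; supply an explicit "
                         "reference level instead")
    bist = scan.bistable_mask()
    bist_idx = np.flatnonzero(bist)
    sxs = scan.xs

    uns = scan.u_unstable[:, species]
    low = scan.u_low[:, species]
    high = scan.u_high[:, species]

    # nearest bistable scan index for every requested x
    nearest = bist_idx[np.argmin(
        np.abs(xs[:, None] - sxs[bist_idx][None, :]), axis=1)]
    lo = np.interp(xs, sxs[bist_idx], low[bist_idx])
    hi = np.interp(xs, sxs[bist_idx], high[bist_idx])

    ref = np.where(
        (xs >= scan.x_a) & (xs <= scan.x_p),
        np.interp(xs, sxs[bist_idx], uns[bist_idx]),
        0.5 * (low[nearest] + high[nearest]))
    return ref, lo, hi


def _crossings(xs: np.ndarray, d: np.ndarray) -> np.ndarray:
    """x positions where d changes sign, linearly interpolated."""
    s = np.sign(d)
    s[s == 0] = 1
    idx = np.flatnonzero(s[:-1] != s[1:])
    if idx.size == 0:
        return np.empty(0)
    x0, x1 = xs[idx], xs[idx + 1]
    d0, d1 = d[idx], d[idx + 1]
    return x0 - d0 * (x1 - x0) / (d1 - d0)


def extract_boundary(sol: PDESolution, scan: BifurcationScan,
                     species: int = 0,
                     reference=None) -> BoundaryTrajectory:
    """Boundary position per output time.

    The boundary is the crossing of the species field with the local
    unstable-steady-state curve (midpoint of the stable branches outside the
    bistable interval, or an explicit ``reference`` level/array).  With
    several crossings the one nearest the previous position is kept
    (continuity).  ``width`` is the distance between the 10% and 90% levels
    of the local high-low span around the boundary.

    ``t_form`` is the first time a crossing lies inside the bistable
    interval *and* the profile around it actually connects the two stable
    branches (attains 95% of the local span on one side and 5% on the
    other within a few boundary widths).  The second condition guards
    against spurious crossings of not-yet-developed profiles -- a flat
    initial condition can intersect the spatially varying unstable branch
    without any front existing yet.
    """
    xs = sol.grid.xs
    if reference is None:
        ref, lo, hi = _reference_curve(scan, xs, species)
    else:
        ref = np.broadcast_to(np.asarray(reference, dtype=float), xs.shape)
        lo = np.full_like(xs, np.nan)
        hi = np.full_like(xs, np.nan)

    field = sol.species(species)
    nt = len(sol.ts)
    w = np.full(nt, np.nan)
    width = np.full(nt, np.nan)
    t_form = None
    prev = None
    for i in range(nt):
        d = field[i] - ref
        cr = _crossings(xs, d)
        if cr.size == 0:
            continue
        pos = cr[np.argmin(np.abs(cr - prev))] if prev is not None else cr[0]
        w[i] = pos
        prev = pos
        # 10-90% width of the local span, measured at the crossing's levels
        developed = False
        if np.isfinite(lo).any():
            lo_b = np.interp(pos, xs, lo)
            hi_b = np.interp(pos, xs, hi)
            span = hi_b - lo_b
            if span > 0:
                c10 = _crossings(xs, field[i] - (lo_b + 0.1 * span))
                c90 = _crossings(xs, field[i] - (lo_b + 0.9 * span))
                if c10.size and c90.size:
                    x10 = c10[np.argmin(np.abs(c10 - pos))]
                    x90 = c90[np.argmin(np.abs(c90 - pos))]
                    width[i] = abs(x10 - x90)
                # front exists once the profile spans both stable branches
                # in a neighborhood of the crossing
                wd = width[i] if np.isfinite(width[i]) else 0.1 * sol.grid.L
                near = (xs > pos - 5 * wd) & (xs < pos + 5 * wd)
                if near.any():
                    fn = field[i][near]
                    developed = (fn.max() >= lo_b + 0.95 * span
                                 and fn.min() <= lo_b + 0.05 * span)
        else:
            developed = True  # explicit reference: no branch data to check
        if (t_form is None and developed and scan is not None
                and scan.has_bistable
                and scan.x_a - 1e-12 <= pos <= scan.x_p + 1e-12):
            t_form = float(sol.ts[i])
    return BoundaryTrajectory(ts=sol.ts, w=w, t_form=t_form, width=width)
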