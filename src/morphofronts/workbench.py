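"""Scenario presets, fixtures, and table I/O.

Each preset wires a model, grid, ensemble and protocol into a reproducible
bundle: (config, seed) determines every numeric output exactly.

Preset parameter notes
----------------------
``fig2_emergence`` / ``fig3_sweep`` use a single-gradient toggle whose
parameters were chosen (and are frozen here) to produce the canonical
mono_high -> bistable -> mono_low class sequence on x in [0, 1] with a
bistable band covering roughly a third of the axis; the ensemble box
[0, 0.2 umax]^2 clusters initial conditions near the origin while straddling
the basin boundary over part of the band, so the static control has R > 0.

``fig5_localization`` uses the symmetric two-morphogen toggle (a = 1.7,
beta = 0.35, n = 2, K_a = 0.75, K_r = 1, D1 = D2 = 1) with antiparallel
exponential gradients crossing mid-domain; domain length and gradient decay
were chosen so the bistable band spans ~20% of the axis and is about nine
front widths wide, keeping the propagating boundary far from both the
domain edges and the band edges.

``hb_yang`` (the Hunchback/Bicoid system) deliberately ships no numeric
defaults: quantitative parameter values come from the published Hb-Bcd
model of Yang et al. and must be supplied by the user as a TOML file
(``write_hb_template`` emits a blank template).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import local_dynamics as ld
from . import fronts as fr
from . import precision as pr
from . import rd_solver as rd
from .models import (GradientSpec, HbParams, HillParams, Model,
                     ScalarBistableParams, ToggleParams, build_model)

__all__ = ["ScenarioConfig", "ScenarioBundle", "RunRecord",
           "make_ic_ensemble", "scenario", "write_hb_template",
           "write_table", "read_table", "run_and_record", "SCENARIO_NAMES"]

SCENARIO_NAMES = ("fig2_emergence", "fig3_sweep", "fig5_localization",
                  "fig6_stripes", "hb_yang")

# frozen fixture parameters for the single-gradient toggle presets
TOGGLE1_FIXTURE = dict(a1=3.0, a2=1.0, beta=1.0, K_a=0.3, n_a=2.0,
                       K_r=0.4, n_r=3.0, b=1.0, lam=0.3, L=1.0)

# frozen fixture parameters for the antiparallel-gradient toggle preset
FIG5_FIXTURE = dict(a=1.7, beta=0.35, K_a=0.75, n_a=2.0, K_r=1.0, n_r=2.0,
                    D1=1.0, D2=1.0, b=5.0, lam=60.0, L=150.0)

# frozen fixture parameters for the scalar multi-localization preset
FIG6_FIXTURE = dict(D=0.1, alpha_mid=0.5, alpha_amp=0.4, n_stripes=3,
                    L=40.0, u0=0.3)


def make_ic_ensemble(n: int, box: Sequence[tuple[float, float]],
                     seed: int | None = None,
                     interpretation: str = "cells_within_embryo"
                     ) -> pr.ICEnsemble:
    """Uniform random initial conditions within a per-species box.

    ``box`` lists (low, high) per species; identical (n, box, seed) calls
    return identical ensembles.  A degenerate box (low == high) yields
    uniform initial conditions.
    """
    if n < 1:
        raise ValueError("ensemble needs at least one member")
    box = [(float(lo), float(hi)) for lo, hi in box]
    for lo, hi in box:
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid box bounds ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    states = np.column_stack([rng.uniform(lo, hi, n) for lo, hi in box])
    return pr.ICEnsemble(states=states, seed=seed,
                         interpretation=interpretation)


@dataclass
class ScenarioConfig:
    """Declarative description of a preset experiment.

    ``overrides`` replaces individual fixture values (flat keys as in the
    fixture dicts above); ensemble, grid and protocol settings have
    name-specific defaults.  ``hb_params_file`` is mandatory for
    ``hb_yang``.
    """

    name: str
    seed: int = 0
    n_ics: int = 50
    ic_box_frac: float = 0.2  # ensemble box upper edge as fraction of umax
    n_positions: int = 100
    grid_n: int = 601
    kappas: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, float("inf"))
    shift: float | None = None  # boundary shift Delta for the sweep (abs.)
    t_f: float | None = None
    eps: float = 0.0
    t_end: float | None = None
    n_seeds: int = 10
    overrides: dict = field(default_factory=dict)
    hb_params_file: str | None = None

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}; "
                             f"choose from {SCENARIO_NAMES}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kappas"] = ["inf" if np.isinf(k) else k for k in self.kappas]
        return d


@dataclass
class ScenarioBundle:
    """A fully wired experiment: invoke ``run()`` to reproduce it."""

    config: ScenarioConfig
    model: Model | None
    grid: rd.Grid | None
    ensemble: pr.ICEnsemble | None
    run: Callable[[], dict]


@dataclass
class RunRecord:
    """Provenance for one invocation (serialized next to its outputs)."""

    config: dict
    seed: int | None
    version: str
    outputs: list[str]
    wall_time_s: float

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str) + "\n")


# ---------------------------------------------------------------------------
# preset construction
# ---------------------------------------------------------------------------


def _toggle1_model(fx: dict, kind: str, gamma: float = 1.0) -> Model:
    p = ToggleParams(a1=fx["a1"], a2=fx["a2"], beta=fx["beta"],
                     act=HillParams(fx["K_a"], fx["n_a"]),
                     rep=HillParams(fx["K_r"], fx["n_r"]))
    g = GradientSpec(kind=kind, b=fx["b"], lam=fx["lam"], gamma=gamma)
    return build_model("toggle1", p, (g,), fx["L"])


def _fig5_model(fx: dict) -> Model:
    p = ToggleParams(a1=fx["a"], a2=fx["a"], beta=fx["beta"],
                     act=HillParams(fx["K_a"], fx["n_a"]),
                     rep=HillParams(fx["K_r"], fx["n_r"]),
                     D1=fx["D1"], D2=fx["D2"])
    g1 = GradientSpec(kind="static_exp", b=fx["b"], lam=fx["lam"], source=0.0)
    g2 = GradientSpec(kind="static_exp", b=fx["b"], lam=fx["lam"],
                      source=fx["L"])
    return build_model("toggle2", p, (g1, g2), fx["L"])


def _fig6_model(fx: dict) -> Model:
    k = fx["n_stripes"]
    L = fx["L"]

    def alpha(x):
        return fx["alpha_mid"] - fx["alpha_amp"] * np.cos(
            2.0 * np.pi * k * np.asarray(x) / L)

    p = ScalarBistableParams(D=fx["D"], alpha_field=alpha)
    return build_model("scalar", p, (), L)


def step_front_ic(scan: ld.BifurcationScan, grid: rd.Grid,
                  band_frac: float = 0.8) -> tuple[np.ndarray, float]:
    """A preformed-front initial profile: local high branch anterior of a
    position inside the bistable band, local low branch posterior.

    Returns (ic_profile, x0).  Branch values are taken from the scan (which
    must share the grid's positions); NaN branch entries (monostable
    stretches lacking that branch) fall back to the single available state.
    """
    if not scan.has_bistable:
        raise ValueError("scan has no bistable interval")
    x0 = scan.x_a + band_frac * (scan.x_p - scan.x_a)
    hi = np.where(np.isnan(scan.u_high), scan.u_low, scan.u_high).T
    lo = np.where(np.isnan(scan.u_low), scan.u_high, scan.u_low).T
    ic = np.where(grid.xs[None, :] < x0, hi, lo)
    return np.ascontiguousarray(ic), float(x0)


def _run_fig2(cfg: ScenarioConfig, m: Model, ens: pr.ICEnsemble) -> dict:
    results = pr.emergence_experiment(m, ens, list(cfg.kappas),
                                      n_positions=cfg.n_positions,
                                      store_fields=True)
    return {"results": results,
            "table": pd.DataFrame([
                {"kappa": r.kappa, "seed": ens.seed,
                 "x_tilde_a": r.x_tilde_a, "x_tilde_p": r.x_tilde_p,
                 "R": r.R} for r in results])}


def _run_fig3(cfg: ScenarioConfig, fx: dict) -> dict:
    delta = cfg.shift if cfg.shift is not None else 0.05 * fx["L"]
    sigma, _ = ld.sigma_and_kappa(
        _toggle1_model(fx, "decaying", gamma=1.0), 1.0, t=0.0)
    rows = []
    results: dict = {}
    box_hi = cfg.ic_box_frac * fx["a1"] / fx["beta"]
    for kappa in cfg.kappas:
        if np.isinf(kappa):
            continue
        gamma = kappa * sigma
        m = _toggle1_model(fx, "decaying", gamma=gamma)
        t_f = (cfg.t_f if cfg.t_f is not None
               else pr.readout_time_for_shift(m.gradients[0], delta))
        per_seed = []
        for j in range(cfg.n_seeds):
            ens = make_ic_ensemble(cfg.n_ics, [(0.0, box_hi)] * 2,
                                   seed=cfg.seed * 1000 + j)
            res = pr.sweep_experiment(m, ens, t_f,
                                      n_positions=cfg.n_positions)
            per_seed.append(res)
            rows.append({"kappa": kappa, "seed": ens.seed,
                         "x_tilde_a": res.x_tilde_a,
                         "x_tilde_p": res.x_tilde_p, "R": res.R,
                         "t_f": t_f})
        results[kappa] = per_seed
    return {"results": results, "sigma": sigma, "delta": delta,
            "table": pd.DataFrame(rows)}


def _run_fig5(cfg: ScenarioConfig, m: Model, fx: dict) -> dict:
    grid = rd.Grid(N=cfg.grid_n, L=fx["L"])
    t_end = cfg.t_end if cfg.t_end is not None else 1200.0
    scan = ld.scan_axis(m, 0.0, grid.xs)
    ic, _x0 = step_front_ic(scan, grid)
    sol = rd.integrate_rd(m, ic, (0.0, t_end), grid, n_out=300)
    traj = rd.extract_boundary(sol, scan)

    xs_map = np.linspace(scan.x_a - 2.0, scan.x_p + 2.0, 101)
    vm = fr.velocity_map(m, xs_map, 0.0,
                         scan=ld.scan_axis(m, 0.0, xs_map))
    locs = fr.localization_points(vm)

    mask = traj.formed()
    t0, w0 = float(traj.ts[mask][0]), float(traj.w[mask][0])
    approx = fr.ode_boundary(vm, w0, cfg.eps, (t0, t_end), n_out=600)
    w_ode = np.interp(traj.ts[mask], approx.ts, approx.w)
    err = np.abs(w_ode - traj.w[mask]) / fx["L"] * 100.0
    return {"scan": scan, "solution": sol, "trajectory": traj,
            "velocity_map": vm, "localization": locs, "approx": approx,
            "max_err_pct": float(err.max()),
            "table": pd.DataFrame({"t": traj.ts[mask], "w_pde": traj.w[mask],
                                   "w_ode": w_ode, "err_pct": err})}


def _run_fig6(cfg: ScenarioConfig, m: Model, fx: dict) -> dict:
    grid = rd.Grid(N=cfg.grid_n, L=fx["L"])
    t_end = cfg.t_end if cfg.t_end is not None else 150.0
    ic = np.full((1, grid.N), fx["u0"])
    sol = rd.integrate_rd(m, ic, (0.0, t_end), grid, n_out=150)
    xs_map = np.linspace(0.0, fx["L"], 161)
    scan = ld.scan_axis(m, 0.0, xs_map)
    vm = fr.velocity_map(m, xs_map, 0.0, scan=scan)
    locs = fr.localization_points(vm)
    return {"solution": sol, "velocity_map": vm, "localization": locs,
            "scan": scan, "table": sol.to_frame()}


def _load_hb(path: str) -> tuple[HbParams, GradientSpec, float]:
    import tomllib

    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    sec = cfg.get("hb", {})
    missing = [k for k in ("alpha_b", "alpha_h", "b0", "h0", "nb", "nh",
                           "beta", "D") if sec.get(k) in (None, "")]
    gsec = cfg.get("gradient", {})
    missing += [f"gradient.{k}" for k in ("bm", "lam", "omega0", "t0")
                if gsec.get(k) in (None, "")]
    if missing:
        raise ValueError(
            "Hb scenario parameter file is incomplete (missing: "
            + ", ".join(missing) + "). Quantitative values come from the "
            "published Hb-Bcd model of Yang et al.; fill in the template "
            "from that source.")
    p = HbParams(**{k: float(sec[k]) for k in ("alpha_b", "alpha_h", "b0",
                                               "h0", "nb", "nh", "beta", "D")})
    g = GradientSpec(kind="bcd", bm=float(gsec["bm"]), lam=float(gsec["lam"]),
                     omega0=float(gsec["omega0"]), t0=float(gsec["t0"]))
    return p, g, float(cfg.get("L", 1.0))


def write_hb_template(path) -> None:
    """Emit a blank Hb parameter template (no numeric defaults on purpose:
    values must come from the published Hb-Bcd model of Yang et al.)."""
    Path(path).write_text(
        "# Hunchback/Bicoid model parameters.\n"
        "# Fill every field from the published Hb-Bcd model (Yang et al.);\n"
        "# this package deliberately ships no numeric guesses.\n"
        'L = ""          # domain length (embryo length, same units as lam)\n'
        "\n[hb]\n"
        'alpha_b = ""    # maximal Bcd-driven Hb production\n'
        'alpha_h = ""    # maximal Hb self-activated production\n'
        'b0 = ""         # Bcd half-max concentration\n'
        'h0 = ""         # Hb half-max concentration\n'
        'nb = ""         # Bcd Hill coefficient\n'
        'nh = ""         # Hb Hill coefficient\n'
        'beta = ""       # Hb decay rate\n'
        'D = ""          # Hb diffusivity\n'
        "\n[gradient]\n"
        'bm = ""         # Bcd amplitude\n'
        'lam = ""        # Bcd length constant\n'
        'omega0 = ""     # Bcd temporal decay rate\n'
        't0 = ""         # onset time of Bcd decay\n')


def _run_hb(cfg: ScenarioConfig) -> dict:
    if not cfg.hb_params_file:
        raise ValueError(
            "the hb_yang scenario requires a parameter file: quantitative "
            "values come from the published Hb-Bcd model of Yang et al. and "
            "are not bundled; write a template with write_hb_template() and "
            "fill it from that source.")
    p, g, L = _load_hb(cfg.hb_params_file)
    grid = rd.Grid(N=cfg.grid_n, L=L)
    t_end = cfg.t_end if cfg.t_end is not None else 600.0
    out: dict = {}
    for variant in ("wt", "stau", "bcd1.0"):
        gv = g if variant != "bcd1.0" else dataclasses.replace(g, bm=0.5 * g.bm)
        m = build_model("hb", p, (gv,), L)
        scan = ld.scan_axis(m, 0.0, grid.xs)
        if variant == "stau":
            # homogeneous ic just inside the low basin of the posterior
            level = (np.nanmin(scan.u_unstable[:, 0]) * 0.9
                     if np.isfinite(scan.u_unstable).any() else 0.0)
            ic = np.full((1, grid.N), max(level, 0.0))
        else:
            # ic is itself a reduced-magnitude boundary profile
            prof = 0.5 * np.nanmax(scan.u_high[:, 0]) * np.exp(
                -grid.xs / (0.25 * L))
            ic = prof[None, :]
        sol = rd.integrate_rd(m, ic, (0.0, t_end), grid, n_out=200)
        traj = rd.extract_boundary(sol, scan)
        out[variant] = {"scan": scan, "solution": sol, "trajectory": traj}

    # critical Bcd level of the frozen no-diffusion system
    def classify(bval: float) -> str:
        gsc = GradientSpec(kind="tabulated", table=((0.0, bval), (L, bval)))
        mm = build_model("hb", p, (gsc,), L)
        return ld.classify_portrait(ld.find_fixed_points(mm, 0.0, 0.0),
                                    ld.species1_midpoint(mm))

    try:
        out["b_crit"] = ld.critical_parameter(classify, 0.0, float(g.bm))
    except ValueError:
        out["b_crit"] = None
    return out


def scenario(cfg: ScenarioConfig) -> ScenarioBundle:
    """Wire a preset into a bundle whose ``run()`` reproduces it."""
    if cfg.name == "fig2_emergence":
        fx = {**TOGGLE1_FIXTURE, **cfg.overrides}
        m = _toggle1_model(fx, "emerging")
        box = [(0.0, cfg.ic_box_frac * fx["a1"] / fx["beta"])] * 2
        ens = make_ic_ensemble(cfg.n_ics, box, seed=cfg.seed)
        return ScenarioBundle(cfg, m, None, ens,
                              lambda: _run_fig2(cfg, m, ens))
    if cfg.name == "fig3_sweep":
        fx = {**TOGGLE1_FIXTURE, **cfg.overrides}
        m = _toggle1_model(fx, "decaying")
        return ScenarioBundle(cfg, m, None, None, lambda: _run_fig3(cfg, fx))
    if cfg.name == "fig5_localization":
        fx = {**FIG5_FIXTURE, **cfg.overrides}
        m = _fig5_model(fx)
        grid = rd.Grid(N=cfg.grid_n, L=fx["L"])
        return ScenarioBundle(cfg, m, grid, None,
                              lambda: _run_fig5(cfg, m, fx))
    if cfg.name == "fig6_stripes":
        fx = {**FIG6_FIXTURE, **cfg.overrides}
        m = _fig6_model(fx)
        grid = rd.Grid(N=cfg.grid_n, L=fx["L"])
        return ScenarioBundle(cfg, m, grid, None,
                              lambda: _run_fig6(cfg, m, fx))
    # hb_yang
    return ScenarioBundle(cfg, None, None, None, lambda: _run_hb(cfg))


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path, units: dict | None = None) -> None:
    """TSV with commented header lines naming columns and units."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# columns: " + "\t".join(df.columns) + "\n")
        if units:
            fh.write("# units: " + "\t".join(
                str(units.get(c, "-")) for c in df.columns) + "\n")
        df.to_csv(fh, sep="\t", index=False, header=False,
                  float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        header = None
        for line in fh:
            if line.startswith("# columns:"):
                header = line[len("# columns:"):].split()
            elif not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if header:
        df.columns = header
    return df


def run_and_record(cfg: ScenarioConfig, out_dir) -> dict:
    """Execute a scenario, write its tables and a RunRecord, return results."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    bundle = scenario(cfg)
    results = bundle.run()
    outputs = []
    if "table" in results:
        p = out_dir / f"{cfg.name}.tsv"
        write_table(results["table"], p)
        outputs.append(str(p))
    if "velocity_map" in results:
        vm = results["velocity_map"]
        p = out_dir / f"{cfg.name}_velocity.tsv"
        write_table(pd.DataFrame({"x": vm.abscissa, "c": vm.c}),
                    p, units={"x": "length", "c": "length/time"})
        outputs.append(str(p))
    if "trajectory" in results:
        tr = results["trajectory"]
        p = out_dir / f"{cfg.name}_boundary.tsv"
        write_table(pd.DataFrame({"t": tr.ts, "w": tr.w, "width": tr.width}),
                    p, units={"t": "time", "w": "length", "width": "length"})
        outputs.append(str(p))
    rec = RunRecord(config=cfg.to_dict(), seed=cfg.seed, version=__version__,
                    outputs=outputs, wall_time_s=time.time() - t0)
    rec.write(out_dir / f"{cfg.name}_run.json")
    results["record"] = rec
    return results
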