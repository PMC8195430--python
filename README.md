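# morphofronts

Simulation and analysis of **bistable gene-expression boundaries** read out
from (possibly time-varying) **morphogen gradients**.

In early development, a graded morphogen concentration α(x) acts as a
spatially varying bifurcation parameter for the genetic network inside each
cell/nucleus. For a mutually repressive toggle switch

    du1/dt = a1·h_a(α(x)) h_r(u2) − β u1
    du2/dt = a2·h_r(u1) − β u2,     h_a(y) = (y/K_a)^n / (1 + (y/K_a)^n),
                                    h_r(y) = 1 / (1 + (y/K_r)^n),

the axis splits into a monostable-high anterior, a bistable band
[x_a, x_p], and a monostable-low posterior. Where the dynamics are
bistable, the fate of a cell depends on its initial condition — which is
exactly where boundary *precision* (within an embryo) and
*reproducibility* (across embryos) are decided. This package implements:

- **Instantaneous bifurcation scans** along the axis: fixed points,
  stability, mono/bistable classification, refined interval endpoints
  `x_a`, `x_p`, `x_crit`.
- **The irregularity ratio** `R = (x̃_p − x̃_a) / (x_p − x_a)`, where
  `x̃_a` is the largest x whose high basin of attraction contains *every*
  member of an initial-condition ensemble and `x̃_p` the smallest x whose
  high basin contains *none*. R = 0 means a precise (fully reproducible)
  boundary; R = 1 means the whole bistable band is up for grabs. The same
  arithmetic reads as precision (cell-to-cell variation) or reproducibility
  (embryo-to-embryo variation).
- **Dynamic-gradient protocols**: boundary formation under an *emerging*
  gradient `α(t,x) = b e^{−x/λ}(1 − e^{−γt})` and precision enhancement
  under a *decaying* gradient `α(t,x) = b e^{−x/λ−γt}` that sweeps
  irregular bistable territory into monostable territory. The controlling
  parameter is `κ = γ/σ`, the gradient rate over the slowest network
  relaxation rate in the bistable band.
- **Reaction–diffusion solves** (method of lines, no-flux boundaries) for
  diffusive gene products, where the boundary becomes a **propagating
  front** whose local speed is the traveling-front speed `c(x)` of the
  spatially homogeneous companion system frozen at x.
- **The reduced boundary ODE** `dw/dt = c(w + ε)`, which collapses the PDE
  to a single scalar equation for the boundary position once a front has
  formed, and **front localization points** `x_l` where `c(x_l) = 0` —
  with antiparallel gradients the boundary parks where α1(x_l) = α2(x_l),
  independent of initial conditions and robust to domain rescaling.
- Model systems: single- and two-gradient toggle switches, the
  Hunchback–Bicoid system (user-supplied parameters), and a scalar cubic
  bistable reaction `u(1−u)(u−α(x))` whose analytic wave speed
  `c = (1 − 2α)√(D/2)` serves as the oracle for the numeric front-speed
  machinery.

## Worked example

```python
import numpy as np
import morphofronts as mf

# single-gradient toggle with an emerging morphogen gradient
p = mf.ToggleParams(a1=3, a2=1, beta=1,
                    act=mf.HillParams(0.3, 2), rep=mf.HillParams(0.4, 3))
g = mf.GradientSpec(kind="emerging", b=1.0, lam=0.3, gamma=1.0)
m = mf.build_model("toggle1", p, (g,), L=1.0)

ens = mf.ICEnsemble(np.random.default_rng(7).uniform(0, 0.6, (50, 2)))
for r in mf.emergence_experiment(m, ens, [0.01, 10.0, np.inf],
                                 n_positions=100, store_fields=False):
    print(f"kappa={r.kappa:>5}: R={r.R:.3f}")
```

prints

```
kappa= 0.01: R=0.000
kappa= 10.0: R=0.876
kappa=  inf: R=0.864
```

i.e. a gradient that emerges quasi-statically (κ = 0.01) erases all
sensitivity to the scattered initial conditions (R = 0), while a fast
gradient (κ = 10) or the static control (κ = ∞) leaves most of the
bistable band irregular. (That κ = 10 slightly exceeds the static control
is a property of this particular ensemble, not noise.)

On the diffusive side:

```python
m = mf.build_model("scalar", mf.ScalarBistableParams(D=0.1, alpha_field=0.1),
                   (), L=30.0)
print(mf.frozen_front_speed(m, 15.0, method="simulate"))   # 0.17869
print(mf.scalar_front_speed(0.1, 0.1))                     # 0.17889
```

and the antiparallel-gradient scenario from the command line:

```bash
morphofronts scenario fig5_localization --out out/
# max |w_ODE - w_PDE| = 0.374% of L
# localization point x_l=75 (attracting)
```

The boundary propagates to the gradient crossing at x = L/2 = 75 no matter
the initial condition, and the one-variable ODE tracks the full PDE
boundary to a fraction of a percent of the domain length.

The `morphofronts` CLI exposes `scan`, `simulate`, `precision`, `velocity`,
`approx` and `scenario` subcommands; all outputs are TSV tables with
commented headers plus a JSON run record, and identical (config, seed)
invocations are byte-identical.

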