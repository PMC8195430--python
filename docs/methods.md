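# Methods

This note documents the models, metrics and numerical choices behind
`morphofronts`, in the order a user meets them: local (no-diffusion)
dynamics and the precision metric first, then diffusive fronts and the
reduced boundary ODE.

## Models and gradients

All model families share the structure *reaction term + morphogen input*,
with concentrations nondimensional and the axis coordinate x ∈ [0, L]
(x = 0 is anterior, where the primary morphogen is highest; positions are
reported both in absolute units and as fractions of L).

- **toggle1** — two mutually repressive genes; species 1 is activated by a
  single morphogen through an activating Hill function, repression is a
  shared repressing Hill function. Carries no diffusivities: it is the
  cell-autonomous part of the theory, where each position evolves
  independently.
- **toggle2** — the same switch with each species activated by its own
  morphogen and per-species diffusivities D1, D2; used with antiparallel
  exponential gradients for front localization.
- **hb** — Hunchback driven by Bicoid plus Hb self-activation through a
  shared-denominator regulatory function, with Hb decay and diffusion.
  Quantitative work requires the parameter values of the published
  Hb–Bcd model (Yang et al.); the package ships a blank template rather
  than numeric guesses, and the Hb scenario refuses to run without a
  completed file.
- **scalar** — the cubic bistable reaction u(1−u)(u−α(x)) with diffusion.
  Its traveling front connecting u = 1 to u = 0 has the exact speed
  c = (1 − 2α)√(D/2), which makes it the analytic oracle for every piece
  of front machinery. The cubic is a canonical choice made for that
  closed form; no claim is made that it matches any particular published
  one-dimensional model.

Gradient families: static exponential b·e^(−|x−source|/λ) (`source = L`
gives the antiparallel partner), emerging b·e^(−x/λ)(1 − e^(−γt)),
decaying b·e^(−x/λ−γt), a Bicoid-style profile with decay onset at t0,
and tabulated profiles (linear interpolation, flat extrapolation).
Non-tabulated profiles are strictly decreasing in x, which is what makes
basins of attraction nested along the axis (used heavily below).

Inside right-hand sides, Hill inputs are clamped at zero: adaptive
steppers may probe slightly negative states, and the response functions
are defined for nonnegative concentrations. Nonnegativity itself is never
enforced by clipping (see solver notes).

## Instantaneous portraits and the axis scan

Freezing time in a time-dependent system yields its instantaneous phase
portrait at (t, x). Fixed points are found by a multi-start damped Newton
iteration run simultaneously from a log-spaced seed grid spanning the
attainable box [0, a_max/β]^n (8×8 seeds for two species, 16 for one),
with finite-difference Jacobians, duplicate merging at 1e−6 of the box
scale, and stability from Jacobian eigenvalues. A leading eigenvalue with
|Re| < 1e−8 is treated as marginal and classified unstable with a
warning, so bifurcation points cannot silently masquerade as attractors.

Classification: two stable points → bistable; one stable point → high or
low by comparing its species-1 value to half the attainable species-1
range. Within a bistable pair, high/low is *relative* (larger species-1
value), since the high branch can sit below the global midpoint deep in
the band. The axis scan classifies a grid, then bisects each transition
between neighboring cells of different class to 1e−4·L, giving x_a, x_p
and (when the anterior neighbor is monostable) x_crit.

σ, the slowest relaxation rate in the bistable band, is the minimum of
|leading eigenvalue| over both stable states at every bistable position
of the frozen profile; κ = γ/σ compares the gradient's rate to it. For
emerging gradients the frozen profile is the t → ∞ limit; a decaying
gradient has no nontrivial limit, so the caller must freeze at a finite
time (the sweep protocol uses t = 0). Since σ comes from Jacobian
eigenvalues, reported κ values are implementation-defined up to that
choice of convergence-rate definition; a test cross-checks the
eigenvalue against the decay exponent fitted from a simulated
log-distance-to-attractor curve.

## Basins, tight bounds and R

Basin membership at (x, t) is decided by integrating the frozen local
dynamics until the state is within a convergence radius of a stable fixed
point — 1e−4 in max-norm relative to the attractor's scale — with a time
cap of 50/σ_local. A capped, unconverged trajectory is labeled
*indeterminate* and treated conservatively: outside the basin when
computing x̃_a, inside it when computing x̃_p, so indeterminacy can only
widen the irregular region.

For an ensemble of initial conditions, x̃_a is the largest x in [x_a, x_p]
whose high basin contains every member, x̃_p the smallest x whose high
basin contains none, and R = (x̃_p − x̃_a)/(x_p − x_a). Monotone gradients
nest the basins (B_{x2} ⊂ B_{x1} for x1 < x2), so both predicates are
monotone in x and the bounds are found by bisection over the full
ensemble, to the same 1e−4·L tolerance. The endpoints are probed first at
x_a + tol and x_p − tol: when the predicate already fails (holds) there,
the bound is pinned exactly to the interval endpoint, so degenerate cases
— every member low throughout the band, for instance — give R = 0
exactly rather than a tolerance-sized remnant. Ensemble membership is
tested in full at every bisection point; member-wise basins of a
two-species system are not totally ordered, so no "extreme member"
shortcut is assumed beyond the nesting of the basins themselves.

The same computation serves two readings: members as cells within one
embryo (precision) or as whole embryos with uniform initial conditions
(reproducibility). Nothing in the arithmetic distinguishes them; the
ensemble carries an interpretation tag for reporting only.

## The two dynamic-gradient protocols

**Emergence.** The gradient grows from zero; γ is set per target κ as
γ = κσ. Every ensemble member is integrated at every grid position
through the emergence phase (to t = 9/γ, by which the profile amplitude
is within b·e^(−9) ≈ 1.2e−4·b of final), then relaxed on the final static
profile until the largest |du/dt| falls below 1e−8, capped at 100/σ.
Final states are labeled by the nearest stable branch of the final-profile
scan; R is computed against that scan, with the tight bounds refined by
re-running the full protocol at bisection positions. κ = ∞ is the static
control (no emergence phase). With a monostable start and κ ≪ 1 the
variation in initial conditions is washed out before bistability appears
anywhere, so R = 0.

**Decay sweep.** The profile decays from an established gradient for a
readout time t_f, is then held fixed, and all cells relax; R is computed
against the frozen-profile scan. Since level sets of the decaying
exponential move anteriorly at speed λγ, matching a boundary shift Δ
across different κ means t_f = Δ/(λγ) (the default shift is 0.05·L; a
numeric root-find on the level-set trajectory is provided for
non-exponential profiles and agrees with the closed form to 1e−6
relative). R_t rescales R by the ratio of bistable widths at t_f and t.
If decay has made the whole domain monostable the boundary was fully
swept: R is reported as 0 with an explicit flag.

## Reaction–diffusion solver

Method of lines on a node-centered grid (default N = 601 for the
localization scenario, i.e. dx = 0.25 length units ≈ 0.17% of L), with a
second-order central Laplacian and no-flux boundaries via mirrored ghost
nodes (u_{−1} = u_1). Time integration is LSODA with a banded Jacobian —
species are interleaved per node, so the bandwidth equals the species
count — at rtol 1e−6, atol 1e−9. Zero-diffusivity species reduce exactly
to per-node reaction ODEs (verified against independent per-node
integration to 1e−6 max-norm). Time-varying gradients are evaluated
inside the right-hand side at solver time, never pre-tabulated. Values
below −1e−9 trigger a diagnostic warning but are never clipped: clipping
would mask solver error.

**Boundary extraction.** The boundary is the crossing of the tracked
species with the local unstable-branch curve from the scan, linearly
interpolated between nodes; in monostable stretches the reference falls
back to the midpoint of the stable branches at the nearest bistable
position (a documented convention — no principled boundary definition
exists there). With several crossings the one nearest the previous
position is kept. Boundary width is the distance between the 10% and 90%
levels of the local high–low span. The front is considered *formed*
(t_form) at the first time a crossing lies inside the bistable interval
**and** the profile around it spans both stable branches (reaches 95% of
the local span on one side and 5% on the other within ±5 boundary
widths). The second condition matters: a flat, not-yet-developed profile
can intersect the spatially varying unstable branch without any front
existing, and the reduced ODE below describes formed fronts only.

## Local front velocity and the reduced ODE

The local front velocity c(x) is the speed of the traveling front of the
spatially homogeneous companion system with parameters frozen at their
(t, x) values; c > 0 means the high-species-1 domain expands toward
larger x. It is measured by integrating a step initial condition between
the two stable states on an auxiliary domain of at least 40 front widths
(width estimated as √(D_max/σ_local), resolution ≈ 8 nodes per width),
discarding the first 25% of the run, and least-squares fitting the
extracted boundary positions; the time window doubles until the fitted
speed changes by < 1%, the domain is enlarged whenever the front nears an
edge, and a fit with R² < 0.999 over a meaningful displacement raises a
convergence warning. For the scalar family the closed form is used
directly (the simulation route remains available and is cross-checked
against it to 2% in the tests).

The velocity map computes c once per distinct frozen parameter value
(keyed on the local morphogen concentrations) and maps it back to x over
the bistable grid positions; map entries within 1%·L of a bifurcation
endpoint are linearly extrapolated from their neighbors rather than
simulated (front speeds near the saddle-node are expensive and divergent
in cost) and flagged as such. Between entries the map interpolates
piecewise-linearly.

The boundary ODE dw/dt = c(w + ε) is integrated adaptively and halts
cleanly (flagged) if w + ε leaves the bistable domain. ε defaults to 0
for equal diffusivities; it is treated as an absolute length when set.
Localization points are sign-change roots of the interpolated map,
attracting when c passes + → − with increasing x so fronts converge onto
them from both sides; with unequal diffusivities the attracting root
shifts toward lower concentration of the morphogen activating the
faster-diffusing species.

## Scenario defaults and what they probe

Published figures behind the scenario presets do not print every
parameter, so the presets freeze documented choices:

- **toggle1 fixture** (emergence and sweep): a1 = 3, a2 = 1, β = 1,
  K_a = 0.3, n_a = 2, K_r = 0.4, n_r = 3, gradient b = 1, λ = 0.3 on
  L = 1. Chosen by a coarse parameter scan for the canonical
  mono_high → bistable → mono_low sequence with a bistable band covering
  ≈ 37% of the axis (x_a ≈ 0.154, x_p ≈ 0.536, σ ≈ 0.193). The default
  ensemble draws uniformly from [0, 0.2·a1/β]² ("clustered near the
  origin"); that box straddles the basin boundary over part of the band,
  so the static control has R ≈ 0.86 and the protocols have something to
  improve on.
- **fig5 localization fixture**: a = 1.7, β = 0.35, n = 2, K_a = 0.75,
  K_r = 1, D1 = D2 = 1 with antiparallel exponentials b = 5, λ = 60 on
  L = 150. The Hill parameters fix the intrinsic scales — 10–90% front
  width ≈ 8.2 length units, and a ≈ 0.19-unit offset between the standing
  front's midpoint and the saddle value that the extraction convention
  crosses — so the gradient/domain choice puts those scales in the
  reduced-ODE's validity regime: band width ≈ 31.7 (≈ 4 front widths,
  21% of L), crossing at L/2. The ODE-accuracy run starts from a
  preformed step between the local branches at 80% of the band, because
  the reduced ODE models a formed front; starting from a homogeneous
  state, the first ≈ 1.5 relaxation times are front *development* (the
  width tightens from ≈ 14 to 8.2), which is outside the approximation by
  construction. Homogeneous initial conditions are used for the
  localization-invariance checks, where only the steady state matters.
- **fig6 stripes**: scalar model, D = 0.1, α(x) = 0.5 − 0.4·cos(2πkx/L),
  so α sweeps [0.1, 0.9] and crosses the balance level ½ at 2k points;
  opposing fronts from a homogeneous start converge onto them, refining a
  stripe pattern.

## What the synthetic ensembles do and do not emulate

Initial-condition ensembles are uniform draws in a box — a deliberate
worst-case stand-in for "variation left behind by upstream processes".
They carry no spatial correlation between neighboring cells, no
correlation between species, and no heavy tails; gene expression itself
is deterministic (no transcriptional noise, no mRNA/protein two-stage
kinetics, no delays). Consequently, passing tests show that the
*deterministic basin geometry* behaves as claimed under these ensembles;
they say nothing about stochastic switching between basins, which real
nuclei exhibit and which would leave residual irregularity at any κ.

## Known limitations

- The reduced boundary ODE has no formal error bound; ε is a heuristic
  correction and the default ε = 0 is only appropriate for equal
  diffusivities well inside the bistable band. Near band edges the front
  straddles the bifurcation and the approximation degrades.
- The boundary-position convention (unstable-branch crossing) differs
  from the standing front's symmetry point by a small parameter-dependent
  offset; it is the same convention on both sides of every comparison
  made here, but absolute positions carry that offset.
- Everything spatial is one-dimensional. Patterns on higher-dimensional
  domains whose parameters vary along a single axis are equivalent to
  their 1-D cross-sections, which is the only sense in which 2-D examples
  are covered.
- The solver grid is uniform; no adaptivity in space. Fronts much
  narrower than ≈ 6 nodes will pin numerically.
- `basin_label` and the scans assume at most two stable states; richer
  multistability raises an explicit unsupported-topology error rather
  than guessing.
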