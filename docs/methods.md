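# Methods

## The model

`photodyn` implements a deliberately small dynamic model of leaf-level
photosynthesis for greenhouse crops (parameterised here for tomato,
*Solanum lycopersicum*) under naturally fluctuating irradiance.  Two
ordinary differential equations carry the dynamics; everything else is
algebraic.

**States.**

* `g_tc` — total conductance of the leaf surface to CO₂ diffusion
  (stomata plus boundary layer), mol m⁻² s⁻¹.
* `c_i` — CO₂ mole fraction in the intercellular air space,
  µmol mol⁻¹.

**Inputs** (drivers, measured or synthesised): irradiance `I`
(µmol m⁻² s⁻¹), leaf temperature `T_l` (K), and ambient CO₂ `c_a`
(µmol mol⁻¹).

**Stomatal kinetics.**  `g_tc` relaxes exponentially toward a
steady-state target `G(I, c_a)`:

    dg_tc/dt = (G − g_tc)/k_u   if G ≥ g_tc   (opening)
    dg_tc/dt = (G − g_tc)/k_d   otherwise      (closing)

with two distinct time constants, because stomata of leaves under
natural fluctuating light open faster than they close (`k_u` = 179.4 s
and `k_d` = 830.3 s in the default set).  Conditioning on `G ≥ g_tc`
is equivalent to conditioning on the sign of the derivative itself
since both time constants are positive; the right-hand side is
continuous at the switch, so no event handling is needed.  The target
is modelled as saturating-linear, `G = min(g_min + αI, g_max)`, with
one `(g_min, g_max, α)` triple per ambient-CO₂ regime (400 and
800 ppm by default; an arbitrary `c_a` snaps to the nearest regime).
The saturating-linear shape is the simplest form consistent with the
three parameters that define each regime; it is a design choice of
this package.

**CO₂ mass balance.**  `c_i` obeys

    dc_i/dt = (R·T_l/(d·P_a)) · [ g_tc(c_a − c_i) + R_d − A_gross(c_i) ]

where `d` is an effective leaf thickness (10⁻⁴ m), `P_a` atmospheric
pressure, and `A_gross = min(W_c, W_j)(1 − Γ*/c_i)` the
Farquhar–von Caemmerer–Berry (FvCB) gross assimilation with

    W_c = V_cmax · c_i / (c_i + K_c (1 + O_i/K_o))      (Rubisco-limited)
    W_j = J(I) / (4 + 8 Γ*/c_i)                          (transport-limited)
    J(I) = [J_max + θI − sqrt((J_max + θI)² − 4 J_max γ θI)] / (2γ)

`Γ*`, `K_c`, `K_o` follow Arrhenius responses
`exp(c − ΔH_a/(R₁ T_l))`.  The triose-phosphate limitation, finite
mesophyll conductance (so `c_c = c_i`), RuBP-pool dynamics and Rubisco
activation kinetics are intentionally excluded: the model assumes
Rubisco stays activated through light fluctuations.

**Output.**  Net assimilation is read off Fick's law,
`A_n = g_tc (c_a − c_i)`, so predicting the two states is sufficient.
The per-step limitation flag records which of `W_c`/`W_j` is smaller
(`W_c` on exact ties — a deterministic convention with no physical
content).

**Units.**  The mixed gas-exchange convention is used throughout:
conductances in mol m⁻² s⁻¹; `c_i`, `c_a`, `K_c`, `Γ*` in µmol mol⁻¹;
`K_o` and `O_i` in kPa; rates in µmol m⁻² s⁻¹.  With these units
Fick's law yields µmol m⁻² s⁻¹ directly.

## Numerics

The `c_i` equation is stiff relative to the 2 s logging cadence: its
effective relaxation rate is roughly `(R·T_l/(d·P_a))·g_tc ≈ 50 s⁻¹`,
i.e. `c_i` tracks its quasi-equilibrium within ~0.1 s.  Three
integration modes are provided and cross-checked against each other:

* **fast** (default): under zero-order-hold inputs the stomatal
  equation is linear with constant coefficients inside each sampling
  interval and never overshoots its target, so it is advanced by its
  exact exponential solution (the active time constant cannot change
  mid-interval).  The `c_i` balance is advanced with 10 backward-Euler
  substeps per interval, each solved by a safeguarded Newton iteration
  (the Newton residual is strictly monotone in `c_i`, so a maintained
  bracket plus bisection fallback is globally convergent).  Backward
  Euler is L-stable: large substeps damp exactly onto the
  quasi-equilibrium branch that the true solution follows.
* **bdf**: `scipy.integrate.solve_ivp` with the BDF method over the
  full right-hand side, `max_step` equal to the sampling interval so
  held-input discontinuities are not skipped.  Used as an independent
  reference; agreement with the fast mode is ~10⁻⁵ µmol mol⁻¹ in
  `c_i` on step-response tests (contract: 10⁻³).
* **qss**: the `c_i` balance is solved algebraically at every step.
  Agreement with full integration is < 10⁻³ µmol m⁻² s⁻¹ in `A_n` on
  greenhouse-style traces (contract: 0.1).

`c_i` is floored at 10⁻⁶ µmol mol⁻¹ with a warning (the `Γ*/c_i` term
is singular at zero); input interpolation defaults to zero-order hold
because instrument logs are samples of held conditions, with a linear
mode selectable.  The fast inner loops are compiled with numba.

## Parameter estimation

The three dynamic parameters `(k_u, k_d, c₃)` — `c₃` scales the
Arrhenius response of `K_c` and effectively rescales `V_cmax`'s
operating point — are estimated by minimising

    O = Σ [0.2 (g_tc − g_tc,m)² + 0.2 (c_i − c_i,m)² + 0.6 (A_n − A_n,m)²] / N

with the simulation initialised from the first measured record.  The
weights favour `A_n`.  Note the objective mixes raw squared residuals
of series with very different magnitudes (`g_tc` ~0.2, `c_i` ~300,
`A_n` ~15), so the `c_i` term dominates unless `c_i` is fitted
tightly; this literal form is the package default, and a
variance-normalised variant is available behind an explicit flag.

The optimiser is `scipy.optimize.differential_evolution` — a seeded,
bounded, population-based global method with a total population of
300 candidate triples (any method of this class is adequate here; the
optimum, not the optimiser, is the contract), followed by an L-BFGS-B
polish.  Default bounds: `k_u ∈ [10, 1000] s`, `k_d ∈ [50, 3000] s`,
`c₃ ∈ [37.5, 38.5]`.  A simulation failure inside the objective
returns `+inf` with a logged cause so the global search survives
pathological candidates.  Fits are deterministic given the seed.

**Profile likelihood.**  For each grid value of the profiled
parameter the remaining two are re-optimised (Nelder–Mead within the
bounds, warm-started sweeping outward from the global estimate).  The
95% interval is where the profile stays below

    O_min · (1 + F₀.₉₅(1, N−3)/(N−3)),

the standard likelihood-ratio threshold for a weighted-SSE objective
with three free parameters; the quantile and level are arguments, so
the rule is swappable.  Crossings are located by linear interpolation
between grid points; a profile that never crosses on one side flags
that endpoint as open and logs a warning.

**Goodness of fit.**  `RMSE = sqrt(Σ(x − x_m)²/N)` (the rooted form —
its magnitude, not the unrooted sum, is what matches per-channel
residual scales) and `R² = 1 − SS_res/SS_tot` per channel.

## A-priori steady-state calibration

* **A/ci curves** (`fit_aci`): over the Rubisco-limited region
  (default `c_i ≤ 300 µmol mol⁻¹`, configurable and logged),
  `A_n = V_cmax (c_i − Γ*)/(c_i + K_c(1 + O_i/K_o)) − R_d` is linear
  in `(V_cmax, R_d)` and solved by ordinary least squares.  Measured
  `c_i` is the abscissa; points above the cut never enter the fit.
* **Light-response curves** (`fit_light_response`): the full
  steady-state model with `(V_cmax, R_d)` fixed is fitted for
  `(J_max, θ, γ)` by bounded nonlinear least squares (`γ ∈ (0, 1]`,
  `θ > 0`), using each curve's concurrent `c_i` readings.  Curves
  from both CO₂ regimes should be pooled: at 400 ppm the
  high-irradiance points are Rubisco-limited, which leaves `J_max`
  weakly identified from that regime alone.  Whether to fit or fix
  `γ` is genuinely open; it is fitted here, with bounds.
* **Conductance targets** (`fit_stomatal_target`): the
  saturating-linear form is fitted per CO₂ regime; constant data
  degenerate gracefully to `α ≈ 0`, `g_min ≈ g_max`.

Replicates are fitted individually (reported as per-replicate
diagnostics plus across-replicate spread) and pooled; the pooled fit
is the headline estimate, matching how single published values per
parameter arise from replicated campaigns.

## Synthetic data

The generator exists so the whole pipeline is testable without any
measured series; it emulates the *statistical shape* of the study
conditions, not any particular day:

* **greenhouse_day** (default 6 h at 2 s): a low-pass-filtered random
  walk confined to a 200–400 µmol m⁻² s⁻¹ baseline band, plus three
  smooth sin²-envelope excursions (30–70 min, 105–170 min, and from
  335 min) whose largest is pinned to a 1193 µmol m⁻² s⁻¹ daily
  maximum.  Leaf temperature drifts sinusoidally around 296 K
  (±1.5 K) with a small smoothed coupling to irradiance; `c_a` is
  held constant.
* **chamber_fluctuating**: a square wave between 50 and
  500 µmol m⁻² s⁻¹ switching every minute — step-rich and therefore
  the most informative cheap trace for the stomatal time constants.
* Steady-state designs reproduce the calibration protocols: the CO₂
  sequence (400, 300, 200, 100, 50, 400, 400, 500, 600, 800, 1000,
  1200 ppm at saturating light, 8 replicates) and the irradiance
  sequence (0–1200 µmol m⁻² s⁻¹ in 9 steps, 6 replicates per CO₂
  regime), evaluated through the model's own steady-state solver.

Measurement noise is independent Gaussian per channel with defaults
`σ_An = 0.5 µmol m⁻² s⁻¹`, `σ_gtc = 0.005 mol m⁻² s⁻¹`,
`σ_ci = 3 µmol mol⁻¹` — plausible infrared-gas-analyser magnitudes
chosen as fixture settings, not instrument claims.  What the
generator does **not** reproduce: autocorrelated or heteroscedastic
instrument error, chamber boundary-layer artefacts, slow drifts in
leaf physiology (photoinhibition, circadian effects), or the exact
spectral content of real sky irradiance.  Passing recovery tests
therefore demonstrate correctness and identifiability of the
machinery under the stated noise model, not performance on real
leaves.

## Problem sizes and defaults

The parameter-recovery experiment uses the full six-hour, 2 s trace
(N = 10 801) with the population-300 global search; it completes in a
few minutes on one core thanks to the compiled fast path.  Property
and replication tests use one-hour chamber traces (N = 1801) and
population 45, which the recovery-median study shows is already
sufficient for ~3% median accuracy on `k_u`; these sizes are the
package's test defaults, chosen to keep the suite quick while leaving
the science unchanged.  The global fit's iteration cap (40
generations) relies on the final gradient polish for refinement;
convergence is typically declared by the population-spread criterion
well before the cap.

## Known limitations

* `J(I)` is instantaneous: the gradual post-shadefleck induction of
  electron transport is not modelled.
* Leaf temperature is an input; there is no energy balance.
* The `G(I, c_a)` target form and the 300 µmol mol⁻¹ A/ci partition
  are reconstructions of choices that published work often leaves in
  supplements; both are configurable.
* The two-regime stomatal target is a lookup, not a continuous
  response surface in `c_a`.
* Parameters are leaf- and cultivar-specific; transferring the model
  to another crop requires redoing both calibrations.
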