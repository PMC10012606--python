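# Methods

## Model and assumptions

The choroid plexus (ChP) luminal membrane is idealized as a flat sheet
bearing a homogeneous lawn of cylindrical microvilli.  The repeating
inter-microvillar space — the functional unit (FU) — is mapped to a
straight cylindrical channel via the hydraulic diameter of the unit-cell
cross-section (square cell of side p = 1/√σ minus four quarter-cylinders of
radius r_mv).  Two caveats of that mapping are worth knowing: the formula
d(p, r_mv) is *not* monotone in r_mv near r_mv = 0 (a vanishingly thin pin
raises d slightly above p, up to ≈ 1.015 p at r_mv ≈ 0.067 p) and d < p is
only guaranteed for r_mv > 0.137 p.  Both properties hold comfortably in
the anatomical regime (r_mv/p ≈ 0.32 at the table means), which is where
the property tests assert them.

Inside the channel, steady solute transport (diffusion, advection, lateral
membrane source) is coupled to osmotic water entry proportional to the
local excess osmolality C − C₀.  The assumptions inherited from the
standing-gradient tradition: steady state, 1D (radial uniformity), dilute
ideal osmosis with reflection coefficient 1, constant D and L_p, rigid
geometry, no hydrostatic pressure contribution.

Solute flux is not a free parameter.  Assuming all solutes leaving the
ventricles originate in the inter-microvillar spaces, the organ-total
injection equals ρ·Q_meas·C₀; dividing by N FUs and the FU wall area gives
the baseline areal flux φ₀ = ρ·Q_meas·C₀/(N(πd·l_mv + πd²/4)).  The πd²/4
share — what would physically enter through the channel base, which the 1D
model must keep impermeable — is rerouted through the first d/2 of the side
wall at a boost factor 1.5 (the base-to-side area ratio of that section).
By construction the lateral integral identity ∫φ dA = ρ·Q_meas·C₀/N holds
to machine precision, and tests pin it there.  If a sampled FU is shorter
than d/2 the boost region is clamped to the full length and φ₀ recomputed
to preserve the identity; such draws are flagged.

The tip does not open into well-mixed CSF but into a protected pool of
depth l_prot — stagnant CSF between the macroscopic ChP folds, where only
production-driven flow moves solutes.  Balancing convection against
back-diffusion across the pool yields the tip condition
D(1 − e^{u·l_prot/D})·C′ = u(C − C₀).  As printed this is identically 0 = 0
at u = 0, so the solver evaluates the equivalent regularized form
C − C₀ + l_prot·g(x)·C′ = 0 with x = u·l_prot/D and g(x) = expm1(x)/x
(series below 1e−8): identical for u ≠ 0, smooth in the unknowns (exact
Jacobians for the Newton iteration), and reducing exactly to the Robin
form C − C₀ + l_prot·C′ = 0 as u → 0 and to C(l_mv) = C₀ at l_prot = 0.

## Parameters

| name   | meaning                          | units       | default (mean ± SD)  |
|--------|----------------------------------|-------------|----------------------|
| l_mv   | microvillus length               | µm          | 2.0 ± 0.33           |
| r_mv   | microvillus radius               | µm          | 0.09 ± 0.01          |
| σ      | microvilli surface density       | 1/µm²       | 12.5 ± 1.83          |
| A_app  | apparent luminal area            | cm²         | 3.66 ± 0.35 (logN)   |
| l_prot | protected length                 | µm          | 77.5 ± 19.4, [0,155] |
| D      | solute (Na⁺) diffusivity in CSF  | cm²/s       | 1.15e−5 ± 1.3e−6     |
| C₀     | bulk CSF osmolality              | Osm         | 0.307 ± 0.006        |
| L_p    | luminal water permeability       | cm/(s·Osm)  | 1.44e−5 ± 6.42e−6 (logN) |
| ρ      | CSF density                      | g/mL        | 1.00 ± 2e−4          |
| Q_meas | measured CSF production          | µL/min      | 6.8 ± 0.3            |

These marginals are the study conditions; they encode the spread of the
underlying measurement literature and are not tuning knobs.  Directly
measured quantities are normal, truncated at zero (negligible mass — every
mean sits > 5 SD above zero).  A_app and L_p are derived rather than
measured and must be positively supported; with only their first two
moments available they are represented by moment-matched lognormals
(positive support, right skew plausible for a permeability).  The true
shapes being unavailable, this surrogate choice is the main source of
uncertainty on the headline ratio, plausibly at the percent level.  The
protected length is a normal centred on the conservative upper-limit
estimate 77.5 µm and truncated symmetrically to [0, 155] µm (truncated
inverse-CDF sampling, no clipping), so its realized mean is exactly
77.5 µm.  Marginals are sampled independently; no correlation structure is
asserted by the sources.  The three fixed verification cases bracket the
production distribution at zero protected length; the "high" case's
diffusion coefficient is taken as 1.08e−5 cm²/s (its printed exponent is
inconsistent with its siblings and with the resulting production rate).

Internally everything is CGS (cm, s, g, Osm); µm/cm²/µL·min⁻¹ inputs are
converted once at construction.  N = σ·A_app is kept real-valued — it is a
density product that only ever scales per-FU fluxes, not a census.

## Numerics

The BVP is solved in nondimensional form with state (c, c′, v): lengths by
l_mv, concentration elevation by Cs = (4φ₀l²/(ρdD))·(1 + l_prot/l_mv),
velocity by the matching osmotic scale.  Folding the protected-pool
amplification (1 + l_prot/l_mv) into Cs keeps the unknowns O(1); without
it, the collocation residual estimate hits its roundoff floor near the
default tolerance and mesh refinement feeds on itself.

The collocation solver (`scipy.integrate.solve_bvp`, 4th order) gets
analytic ODE and boundary Jacobians, an initial mesh of 48 uniform nodes
plus knots resolving the flux transition, tolerance 1e−8, and the exact
diffusion-only solution as the initial guess — in the physiological,
weakly nonlinear regime it converges in one or two Newton iterations
(~2 ms per solve).  The piecewise-constant flux step is represented as a
symmetric linear ramp of half-width 2% of the distance to the nearest
break or domain edge: the collocation residual estimator assumes a
continuous right-hand side, and a sharp step at a node poisons the
adjacent element's residual no matter how fine the mesh.  The ramp
preserves the flux integral (hence mass closure) exactly and changes
production by < 1e−4 relative.  On non-convergence the solver ramps the
water permeability geometrically from 1e−2·L_p (then 1e−4·L_p), re-using
each converged solution — needed only in strongly convective regimes such
as the legacy verification channel (tip Péclet ≈ 13).  Failures after
continuation are flagged per sample, never silent NaNs; the Monte-Carlo
driver hard-errors if more than 1% of samples fail.  Geometrically
infeasible draws (σπr_mv² ≥ 1) are rejected and logged, not clipped, to
avoid biasing the production distribution.

Diagnostics computed per solve: relative solute-mass closure (tip
advective+diffusive outflux vs lateral injection, typically ~1e−12),
relative water balance (u(l_mv) vs the integral of osmotic influx,
~1e−14), and the tip Péclet number u(l_mv)·l_prot/D.

## Small-Péclet closed form

Dropping the convective terms and linearizing the tip condition makes the
problem quadrature, giving for the boosted piecewise flux (â = a/l_mv)

u(l) = (16 L_p φ₀/(ρd²D))·l³·[1/3 + â/4 − â³/12 + (l_prot/l)(1 + â/2)],

exactly linear in L_p, Q_meas and l_prot.  Validation against the full
solver shows it is accurate to < 2% at zero protected length but is an
*upper bound* that overshoots by ≈ 10% at the table means with
l_prot = 77.5 µm: the linearization drops the dilution term C·du/dz, and
the protected pool amplifies the concentration scale ~40-fold, making that
term an O(10%) sink.  Two consequences worth stating plainly: the
production–protected-length relation of the full model is monotone but
slightly concave (R² ≈ 0.9965 against a straight line over 0–155 µm,
confirmed by an independent finite-difference solver), and the same effect
pulls the probabilistic mean from the ≈ 10.8% of measured production the
linear estimate would suggest down to ≈ 9.7% — below the 10% mark.

## Uncertainty propagation

`scipy.stats.qmc.LatinHypercube` supplies the stratified unit design
(exactly one draw per equal-probability interval of every marginal);
inverse CDFs of the (truncated) marginals map it to parameter space.  The
default analysis size is n = 20,000, a reduced-scale design: the
sampling-independence study shows successive mean changes < 0.1% from
n = 2,500 upward, so the full-scale n = 200,000 run changes nothing at the
reported precision and the reduced size keeps the suite and the
reproduction script inside minutes on one CPU.  The whole pipeline
(sample → solve → summarize) is bitwise-reproducible at fixed seed.

## Verification

* Legacy channel: the solver reproduces the classic secretory-channel
  configuration (prescribed d, step flux over the first 10%, no protected
  pool): hypertonic closed end (C(0) ≈ 0.41 Osm) relaxing monotonically to
  0.3 Osm, velocity monotone increasing, emergent fluid near-isotonic.
* Independent oracle: a second-order finite-difference discretization with
  damped Picard coupling (10⁴ uniform nodes, banded solves; shares no code
  or formulation with the collocation path) agrees with the collocation
  result to 0.05% on the legacy channel and ~1e−5 on physiological cases.
* Deterministic benchmarks: the three bracketing parameter sets yield
  0.0025, 0.0068 and 0.0109 µL/min.

## What the generator does and does not emulate

The sampling module realizes exactly the statistical structure the
analysis assumes: independent marginals with the stated means, SDs and
truncations.  It does not emulate parameter correlations (e.g. between
microvillar density and radius), spatial heterogeneity of the ChP surface,
temporal variation of production, or the unknown true shapes of the two
derived-parameter distributions.  Passing tests therefore demonstrate
faithful propagation of the stated uncertainty model — not that this
uncertainty model exhausts biological reality.

## Known limitations

* Strictly 1D: circumferential diffusion and the finite active-surface
  fraction of a real FU are absent; a 3D treatment predicts lower
  production still, so the 1D result is best read as an upper bound.
* ChP motion (cardiac/respiratory) would disturb both the gradients and
  the protected pools; the model is rigid and steady, again favouring the
  mechanism.
* The protected length is an anatomical upper limit, not an effective
  hydrodynamic one.
* Lognormal surrogates for A_app and L_p are a two-moment approximation.

All of these biases push in the same direction: the computed
standing-gradient production is an upper limit, strengthening rather than
weakening the conclusion that the mechanism cannot account for measured
CSF production.
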