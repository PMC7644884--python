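# Methods

## Model and assumptions

`avdsim` simulates osmotic water balance of a single animal cell whose
actomyosin cortex exerts an excess hydrostatic pressure *S* on the
cytoplasm. The state is (V, N): cell volume and total intracellular
osmolyte amount. Water crosses the membrane down the combined
hydrostatic/osmotic driving force (S − ΔC), osmolytes leave through open
channels down (S + ΔC) — the gradient term plus the pressure assist —
with ΔC = N/V − C₀. Both driving forces are kept in equivalent
concentration units (pressure divided by RT), so a single pair of
permeabilities P_w and P_i (cm/s) closes the system.

Deliberate simplifications, inherited from the model being implemented:

- no membrane potential or electroneutrality bookkeeping; P_i and C₀ are
  cumulative, species-agnostic parameters;
- S, A and P_w are constant in time within a schedule segment;
- the osmolyte flux takes the hydrostatic assist term exactly as
  written, (S + ΔC) A P_i, without a mechanistic channel model.

The quasi-steady closed forms additionally assume C₀ ≫ S and drop terms
quadratic in the small quantities (ΔC, S). Constructing a parameter set
with S/C₀ > 0.05 emits a `RegimeWarning` rather than an error, because
the formulas remain evaluable and the warning marks where they degrade
to first-order accuracy.

Two numerical regimes are worth knowing about:

- **Sign of the quasi-steady ΔC.** When P_i > C₀ ρ P_w (true at the
  reference parameter set), ΔC* is negative: osmolyte efflux outruns the
  concentrating effect of water loss, and the steady intracellular
  osmolarity sits slightly *below* the medium. The value is reported
  as-is with a regime note; it is a property of the model, not a bug.
- **Validity horizon.** With constant A the quasi-steady dV/dt is
  constant, so a high-pressure cell would eventually shrink without
  bound. Real cells lose ~10–20 %. The integrator therefore carries a
  terminal stop at V = 0.5·V₀ (configurable) and flags trajectories
  that hit it; downstream consumers (the population simulator) treat a
  stop before the observation time as an excluded cell.

## Parameters, units, defaults

Internal computation is entirely in cm/g/s/mol. The CLI/config boundary
accepts µm, Pa and mOsm/L and converts once on the way in.

| symbol | meaning | unit | default | why |
|---|---|---|---|---|
| r | cell radius | cm | 5·10⁻⁴ | typical ~10 µm-diameter epithelial cell |
| C₀ | medium osmolarity | mol/cm³ | 10⁻⁴ | reference value of the worked example |
| S | cortical pressure | Pa | 1000 | within the reported tens-to-thousands-Pa range of intracellular pressure |
| P_i | osmolyte permeability | cm/s | 10⁻⁵ | literature value for K⁺ in resting membrane |
| P_w | water permeability | cm/s | 2·10⁻³ | typical reported osmotic water permeability |
| ρ | molar volume of water | cm³/mol | 18 | physical constant |
| RT | pressure↔concentration | Pa·L/mol | 2.5·10⁶ | rounded value at 300 K |

`rt_mode="paper_rounded"` (default) uses the rounded RT so that the
worked-example numbers reproduce digit for digit; `"exact"` uses R·T
(2.4943·10⁶ Pa·L/mol at 300 K, ≈0.23 % smaller). Shrinkage rates are
signed (negative = volume decrease) in the API; the CLI additionally
prints the magnitude as "% per hour".

`area_mode="constant"` holds A at 4πr₀² — the assumption under which the
closed forms are exact and the default everywhere. `"sphere_coupled"`
(A = (36π)^⅓ V^⅔) is provided as a clearly-labelled extension beyond the
constant-area model.

## Integration

The workhorse state is (V, N) because N is conserved *exactly* when
P_i = 0, making the channel-blockade limit a conservation law rather
than a numerical accident. The mathematically equivalent (V, ΔC) system
is implemented as `integrate_delta_c` purely as a cross-check; tests
verify trajectory agreement (≤10⁻⁶ relative) and the pointwise identity
of its right-hand side with the chain rule of the flux form.

ΔC relaxes with time constant τ = (r/3)/(P_i + C₀ ρ P_w) ≈ 12 s at
default parameters, while volume drains over hours — a ~10³ timescale
separation. The default integrator is `scipy.integrate.solve_ivp` with
LSODA, rtol 10⁻⁸ and per-variable atol scaled to 10⁻¹²·(V₀, N₀); output
grids are geometrically refined near each segment start so the fast
transient is resolved. Schedules (pressure steps, channel blockade) are
piecewise-constant with the solver restarted at each breakpoint; this
handles discontinuities exactly without event root-finding. A pressure
step at t = 0 on an equilibrated cell (ΔC(0) = 0) is the default
scenario; ramps can be approximated by multi-segment schedules.

Quasi-steady-state detection declares onset at the first sample from
which |dΔC/dt| stays below tol·|ΔC_ref|/τ (tol = 0.01, ΔC_ref the final
gradient) and reports the median ΔC thereafter; absence of a plateau
raises rather than defaulting.

## Synthetic populations

The population generator emulates a two-arm water-content assay: a
treated arm in which apoptosis induction raises S, and a control arm in
which depolymerizing the actin cortex removes the pressure entirely —
modeled as S = 0 with all permeabilities unchanged, since the mechanism
under test attributes the loss to cytoskeletal pressure. Cells draw
parameters independently (lognormal for positive rate-like parameters;
truncated normal and point-mass families also available), are integrated
individually to the observation time (3 h), and receive additive
Gaussian measurement noise on the percent-water-loss scale, matching the
mean ± SEM reporting convention of such assays. Cells are assigned
round-robin to 3 replicate labels; replicate effects are zero by
default.

Default calibration, fixed once from the reported group summaries
(treated 4.2 % ± 0.15 SEM, n = 45; control 0.00 ± 0.03 SEM, n = 31):

- measurement noise sd = 0.03·√31 ≈ 0.167 percentage points, shared by
  both arms (the control arm's scatter is measurement-only);
- treated biological variability: the remaining treated-arm variance
  implies a per-cell sd of √((0.15²·45) − 0.167²) ≈ 0.99 points, i.e. a
  coefficient of variation of 0.235 on the loss, carried entirely by a
  lognormal pressure distribution with σ_log = √ln(1 + 0.235²) ≈ 0.232;
- treated pressure median 29.8 Pa, so that the mean pressure
  (29.8·e^{σ²/2} ≈ 30.6 Pa) yields a mean 3-h loss of 4.2 % through the
  forward model (the loss is linear in S to ~1 %).

Note the calibrated per-cell pressures (~30 Pa) are much smaller than
the 1000 Pa of the deliberately generous feasibility estimate; both lie
inside the physiological tens-to-thousands-Pa range.

What the generator does *not* emulate: replicate (batch) effects,
correlated parameters within a cell, apoptosis commitment timing,
fragmentation as an alternative volume-loss route, or the optics of the
water-content measurement. Passing tests therefore show that the
*pipeline* recovers what this idealized population encodes — not that
real MDCK measurements behave this way.

Reproducibility: each `PopulationSpec` seed is split via
`numpy.random.SeedSequence.spawn` into independent parameter-sampling
and measurement-noise streams; identical (spec, seed) pairs give
bit-identical tables.

## Statistics

The two-arm comparison is Welch's unequal-variance t test computed from
summary statistics: t = (m₁ − m₂)/√(sem₁² + sem₂²) with
Welch–Satterthwaite degrees of freedom. Welch is the default because the
two arms' SEMs differ five-fold; the pooled Student form is available
via `equal_var=True`. p values are two-sided (sidedness is a
convention, immaterial at t ≈ 27). Tests cross-check the summary-stat
path against `scipy.stats.ttest_ind` on raw values.

`fit_pressure` estimates only S by bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective) against the
forward ODE; P_i, P_w and S are jointly poorly identifiable from a
single volume trace because the quasi-steady rate depends on them only
through the product/ratio combination in the rate formula, so
multi-parameter fitting is intentionally not offered. Uncertainty is a
local Jacobian-based standard error, not a bootstrap.

## Problem sizes

The test suite and acceptance script run everything at the scales the
analyses need and nothing larger: single-cell integrations of 10²–10³
output samples, populations of 45 + 31 cells, 100 seeded replications
for the power check, 20 seeds for noisy pressure recovery, and 100
random parameter sets for the monotonicity properties.

## Known limitations

- Constant-A linearity means long-horizon trajectories are only
  meaningful up to modest volume loss; the 0.5·V₀ stop is a guard, not
  a prediction.
- The model has no volume set-point or feedback; it describes the
  dehydration phase only.
- The osmolyte is a single effective species; ion-specific predictions
  (which channel, which ion) are out of scope.
- `detect_qss` assumes constant parameters; scheduled runs must be
  analyzed segment-wise.
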