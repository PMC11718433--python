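# Methods

## Scope and model

`pelletox` analyses the oxygen supply of submerged filamentous-fungal
pellets — dense, near-spherical hyphal aggregates several hundred µm in
radius.  Three data streams meet on a common radial coordinate:

1. **3D morphology**: binarized voxel images of freeze-dried pellets,
   reduced to a radial hyphal fraction ch(r) — the volume fraction of
   hyphal material in 15 µm concentric shells around a 50 µm central
   sphere at the mass centre — plus sphericity and axis-ratio shape
   metrics.
2. **Oxygen microprofiles**: Clark-type microelectrode depth profiles
   (10 µm steps, ≥ 3 replicates averaged), entering the pellet from the
   saturated bulk (6.7 mg L⁻¹ at 37 °C).
3. **A mechanistic model**: the radially symmetric reaction–diffusion
   balance

   ∂c/∂t = (1/r²) ∂/∂r [ D_eff(r) r² ∂c/∂r ] − q(c, ch)

   with hindered diffusivity D_eff = D_bulk (1 − ch)ᵃ and Monod-type
   consumption.  Two consumption laws are implemented:
   *growth-only*, q = (ρ_h/Y_X/O₂) · c/(K_XO + c) · µ_max · ch, and
   *growth + maintenance*, which floors the growth term at zero below a
   critical concentration c_crit and adds a separate maintenance Monod
   term m_O₂,max · ρ_h · c/(K_MO + c) · ch.  The floor is a physical
   necessity: the printed growth term would otherwise turn negative below
   c_crit.

Parameters (defaults in `KineticParams`): D_bulk = 8.7·10⁻⁶ m² h⁻¹,
a = 1.76, ρ_h = 150 kg m⁻³, Y_X/O₂ = 2.77, K_XO = 2.5·10⁻⁵ kg m⁻³,
µ_max = 0.16 h⁻¹ (0.24 h⁻¹ for the hyperbranching strain),
m_O₂,max = 7.2·10⁻³ kg kg⁻¹ h⁻¹, K_MO = 1.5·10⁻⁵ kg m⁻³,
c_crit = 10⁻⁵ kg m⁻³.  Internally everything runs in the hour-based
system these values are tabulated in (m, h, kg m⁻³); concentrations
cross module boundaries in mg L⁻¹ (1 mg L⁻¹ = 10⁻³ kg m⁻³) and lengths
in µm.

## Pseudo-steady state and the simulation clock

Growth (doubling time ln 2/µ_max ≈ 3–4 h) is far slower than oxygen
transport and uptake, so ch is frozen during a simulation and the steady
oxygen profile is what the model predicts for a measurement
(`characteristic_times` reports the three scales).  The steady state is
obtained by transient integration from a uniform initial condition at
the surface concentration, with a zero-flux symmetry condition at r = 0
and a Dirichlet condition at the border (the measured maximum
concentration c_max).

One subtlety deserves emphasis: with hour-based parameters the
simulation clock's natural unit is the hour, and this package follows
the field convention of labelling that clock in "seconds" — "steady
within milliseconds, horizon 2 s" describes the solver time axis, on
which draining a 500 µm pellet from saturation takes ~10⁻² units.  The
steady-state criterion is a maximum concentration change below 10⁻⁶ of
the surface value per 10⁻³ clock units, checked continuously by event
detection; `SimResult.time_to_steady` records the first time it holds
(~0.04 for the reference scenario, comfortably inside the 2-unit
horizon).

## Discretization and numerics

Space is discretized on 100 uniform nodes (configurable) with a
conservative second-order finite-volume scheme: fluxes
D_eff r² Δc/Δr are evaluated on cell faces with face-averaged ch, cell
volumes are exact spherical shells, and the centre cell needs no special
treatment of the r = 0 singularity.  The semi-discrete system is stiff
and is integrated with LSODA using an analytic tridiagonal Jacobian;
complex-valued sensitivity runs (below) use BDF with the same Jacobian
in sparse form, as LSODA is real-only.  Tolerances: relative 10⁻⁶,
absolute 10⁻⁹·c_surface.

Because the scheme is conservative, the discrete steady state satisfies
an exact mass balance: the flux through the outermost interior face plus
the sink in the surface half-cell equals the cell-volume quadrature of
consumption.  `flux_balance` exposes both sides; they agree to solver
tolerance at steady state.  (A derivative-based surface flux is *not*
used for this check: with the default parameters the Thiele modulus is
~30, the concentration boundary layer spans a few grid cells, and a
one-sided 3-point derivative carries an O((φ·Δr/R)²) ≈ 3–5% error that
says nothing about the solver.)  Correctness is certified against the
closed-form first-order-kinetics sphere solution
c(r) = c_s (R/r) sinh(φ r/R)/sinh φ: maximum relative error is < 1% at
100 nodes and < 0.25% at 200, confirming second-order convergence.

## Border detection and alignment

Microprofiles carry no reference to the pellet centre, so the border is
the shared fixed point: on the oxygen side the depth at which the mean
profile reaches 95% of its maximum (scanning from the deep end outward,
linearly interpolated); on the image side the radius at which ch drops
to 0.005 (not 0, to suppress single protruding hyphae).  Shell fractions
are anchored at shell mid-radii for the cutoff interpolation — a bin
average estimates ch at the bin centre — which keeps the detected border
within half a shell width (≤ 7.5 µm) of a sharp pellet edge.  Aligning
both borders maps depth d to radius r_border − (d − d_border); samples
mapping past the centre are discarded with a warning.

The 95% rule has a known systematic on profiles that sit exactly at the
plateau up to the border (as ideal synthetic profiles do): the
interpolated crossing lands a few µm *inside* the true border
(offset ≈ step · 0.05·c_max / first-step drop, ~5 µm at default
steepness).  The border radius itself is still recovered exactly on
lattice-aligned pellets, but the few-µm shift of all sample positions
biases end-to-end yield fits low by ~15%.  Estimation studies therefore
use `gen_aligned_pellet`, which maps depths to radii with the
generator's exact knowledge of the border; the full border-rule path is
validated separately for border recovery (±10 µm) and concentration
preservation.

## Supply metrics

*Penetration depth* is the thickness of the outer layer with oxygen
above a zero threshold (default 0.05 mg L⁻¹, ≈ 1% of saturation — real
sensors never read exactly zero), scanning the aligned profile from the
centre outward with linear interpolation.  The *active part percentage*
(APP) is the hyphal volume inside that layer as a share of the total
hyphal volume inside the border, computed with exact spherical-shell
volumes and pro-rated partial bins; for uniform ch it reduces to
100·(1 − ((R − d)/R)³).  Maximum gradients of oxygen and ch use central
second-order finite differences on the unsmoothed mean profile,
restricted to the supplied layer.

## Parameter estimation and model selection

Per pellet, free parameters of the consumption law (typically the yield
Y_X/O₂ alone) are estimated by bounded trust-region-reflective least
squares on the residuals y_exp − y_sim at each measured radius inside
the border, in mg L⁻¹.  Multistart (default 50 log-uniform start points
within the bounds, seeded; c_crit linear-uniform since its lower bound
is 0) guards against local minima; every start's objective is recorded
and the best kept.  Bounds bracket the literature values by ≥ 10×:
Y_X/O₂ ∈ [0.1, 30], m_O₂,max ∈ [10⁻⁵, 0.1], K_XO, K_MO ∈ [10⁻⁷, 10⁻³],
c_crit ∈ [0, 10⁻⁴] (kg, m, h units).  Scripts and tests use 2–5 starts
with a per-start evaluation cap for these 1–2 parameter problems; the
multistart-dominance and noiseless-recovery tests support that the
reduced setting finds the same optimum.

Jacobians use complex-step differentiation (step 10⁻²⁰) through the
transient solver when the forward map is analytic in the free
parameters — true for the growth-only law — and central finite
differences for the maintenance law, whose max(c − c_crit, 0) floor
breaks analyticity.  On smooth points both agree to a relative 10⁻⁵.

Goodness of fit is the mean absolute error (MAE) in mg L⁻¹.  Candidate
models (consumption law × free-parameter set) are ranked by the
small-sample corrected Akaike criterion
AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n − k − 1) with k = n_free + 1 (the
residual variance counts as a parameter); ties favour fewer parameters.
Strain comparisons use classic one-way ANOVA (α = 0.05).

## Synthetic data: what it emulates and what it does not

No pellet dataset is deposited, so a seeded generator supplies every
test input:

- **ch(r)**: logistic core-to-rim transition over a configurable rim
  width, times a linear taper to zero over the last 8 µm; shell values
  are volume-weighted bin averages.  Preset radii lie on the 50 + 15k µm
  lattice so the border rule recovers them exactly.
- **Oxygen profiles**: the forward model sampled at 10 µm from the
  border inward, a 100 µm plateau at the surface concentration
  prepended, i.i.d. Gaussian noise truncated at zero per replicate
  (default 3).  Default noise: 0.02 mg L⁻¹, typical of Clark-type
  microelectrodes; recovery studies use 0.1 mg L⁻¹ as their stated
  condition.
- **Phantoms**: binary voxel images (2 µm synthetic voxels; real
  tomograms are 1 µm) in which each voxel is foreground with probability
  equal to its shell's target fraction; ellipsoids rescale distances
  anisotropically.

Two presets define strain-typical conditions.  The hyperbranching
preset has the denser outer rim (ch 0.15 → 0.40, µ_max 0.24 h⁻¹,
R = 455 µm); the regular preset is flatter (0.30 → 0.25, µ_max
0.16 h⁻¹, R = 500 µm).  Rim fractions were set from the zero-order
penetration estimate √(2 D_eff c_s/q_max) so the supplied layer lands at
the strain-typical thickness (~230 µm regular, ~150 µm hyperbranching);
both fall inside the reported 90–290 µm range with the literature
parameter set.

What the generator does **not** emulate: the external mass-transfer
boundary layer (profiles plateau sharply at the border, which is what
makes the 95%-border systematic above visible), tomographic artefacts,
hypha-scale structure (tips, septa), suction-induced distortion at the
pellet centre, and sensor drift.  Passing tests therefore demonstrate
the pipeline's internal consistency and the solver's correctness, not
robustness to those real-data effects.

The zero-truncation of sensor noise has one further consequence worth
knowing: over a large anoxic core the *mean* of truncated noise is a
positive floor (≈ 0.04 mg L⁻¹ at sd 0.1) that no consumption model can
reproduce, and the extra maintenance parameter partially absorbs it,
distorting AICc comparisons for reasons unrelated to kinetics.  The
model-selection study therefore uses pellets whose steady profile stays
positive everywhere (R = 245 µm, uniform ch 0.15), where the i.i.d.
noise premise of the comparison holds.  This mirrors the practical
observation that only the oxygen-positive region carries information
for parameter identification.

## Degenerate inputs and tie-breaks

Constant oxygen profiles (no decline anywhere) put the border at the
deepest sample with a warning — every sample is equivalently "outside".
Profiles entirely below the zero threshold give penetration depth 0 with
a warning.  Shells wholly below the 0.005 cutoff, empty images,
constant-intensity images, and sub-minimal sample counts raise errors.
ch is clamped to 0.999 on simulation grids so the diffusivity never
vanishes.  Solver failures inside multistart produce large penalty
residuals instead of aborting the fit; a fit fails only if every start
fails.

## Known limitations

- 1D spherical symmetry: non-spherical pellets are flagged
  (axis ratio < 0.7 or sphericity < 0.95) and excluded from cohort
  means, not modelled.
- ρ_h = 150 kg m⁻³ is a dry-weight density applied to a wet-volume
  fraction; the literature value is used as printed.
- The end-to-end yield bias of the 95%-border rule (~15% low on
  plateau-type profiles) is inherent to that border definition, not to
  the estimator; real profiles smoothed by an external boundary layer
  are expected to sit closer to the rule's assumptions.
- Convection, product formation, multi-substrate coupling and full-3D
  simulation on voxel geometries are out of scope.
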