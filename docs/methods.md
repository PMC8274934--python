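# Methods

## The neck model

We model the pre-fission geometry as an axisymmetric cylindrical membrane
neck of radius R and length L joining two planar sheets, with a uniform
FisB surface density φ in the neck in equilibrium with a background
density φ₀ on the sheets. The free energy, in thermal units
(k_BT, nm, nm⁻²), is

    F(R, φ) = 2πRL [ κ/(2R²) + γ + φ ln(φ/φ₀) + a V_LJ(R) φ² + U(φ) ]
              − 2πR² γ,

with V_LJ(r) = (σ/r)¹² − (σ/r)⁶. The terms are: Helfrich bending of the
cylindrical wall (H = 1/R), membrane tension over the neck surface,
ideal translational entropy of the proteins, a trans homo-oligomerization
energy across the neck lumen (strength a, per squared density), and a
crowding penalty

    U(φ) = ε (φ³ − φ_rmax³)² / (4 φ_rmax⁶)   for φ ≥ φ_rmax, else 0,

which is zero up to the close-packing onset
φ_rmax = 2^(2/3)/(3^(3/2) σ_cis²) (a triangular lattice at the spacing
r_max = 2^(1/6) σ_cis of the in-plane repulsion minimum) and rises
steeply but smoothly (C¹) above it. The final −2πR²γ accounts for the
disc of sheet membrane (one per sheet) replaced as the neck widens; it is
why tension alone favours an ever-wider neck, and why the open neck is
the R → ∞ state rather than a finite-radius minimum.

Assumptions worth keeping in mind: the neck is a perfect cylinder
(no catenoid/unduloid shapes, no boundary corrections), φ is uniform, the
proteins have no curvature preference, and the treatment is strictly
equilibrium — no membrane fluctuations, hydrodynamics or fission
kinetics.

### Stationarity conditions and the two force-balance variants

∂F/∂φ = 0 gives the density condition

    1 + ln(φ/φ₀) + 2aφ V_LJ(R) + U′(φ) = 0            (per k_BT)

and ∂F/∂R = 0 the radius condition. The package implements the radius
condition in two variants. The `printed` variant,

    γ_eff − κ/(2R²) + aφ² [6(σ/R)⁶ − 12(σ/R)¹²] − 2γR/L = 0,
    γ_eff = γ + φ ln(φ/φ₀) + U(φ),

is the published algebraic form. The `variational` variant is the exact
derivative of the implemented F divided by 2πL; it differs by an
additive aφ²V_LJ(R) term (the product-rule contribution of the
interaction energy density to d(R·aV_LJφ²)/dR). Whether the omission in
the printed form is a deliberate simplification is not decidable from
the available material, so both are first-class and tested; `printed` is
the default for fidelity, and at the reference parameters they give
R = 2.775 vs 2.820 nm — the same physics. The two variants are verified
against each other symbolically (their difference equals aφ²V_LJ) and
the variational one against central finite differences of F.

### Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| κ | bending modulus | 20 | k_BT |
| γ | membrane tension | 1e-4 N/m → 0.0243 | k_BT nm⁻² |
| σ | trans LJ length scale | 2.47 | nm |
| σ_cis | in-plane LJ length scale | 2.47 | nm |
| ε | crowding energy scale | 32.78 | k_BT nm⁻² |
| a | trans interaction strength | 1e4 | k_BT nm² |
| φ₀ | background FisB density | 100 µm⁻² → 1e-4 | nm⁻² |
| L | neck length | 40 | nm |
| T | temperature (conversions only) | 298 | K |

φ_rmax is derived from σ_cis (0.0501 nm⁻² ≈ 5×10⁴ µm⁻² at 2.47 nm)
unless explicitly overridden. Laboratory units (N/m, µm⁻²) are converted
at T; the temperature itself is a convention — the sources quote γ in
N/m without stating T, so 298 K is fixed as the default.

### Solver

The density condition is solved exactly at fixed R: the residual is
scanned on a 256-point log grid in φ ∈ (0, 10 φ_rmax] and each sign
change is polished with Brent's method. Because the residual → −∞ as
φ → 0, roots alternate stable/unstable; the stable ones are free-energy
minima in φ. Up to two stable branches exist — a dilute branch near
φ₀/e and a crowded branch near φ_rmax.

The radius condition is then a 1D root find along each stable branch
φ(R): g(R) = radius residual at (R, φ(R)) is scanned on a 256-point log
grid over R ∈ [σ, 200 nm] and negative-to-positive crossings (free-energy
minima along the branch) are polished with Brent's method. The
lowest-energy crossing is the reported equilibrium; no crossing on any
branch means the neck is open. Scanning the branches separately matters:
near the critical interaction strength the crowded cluster is metastable
relative to the dilute state at the same radius, yet it is precisely the
state whose existence defines a "closed" neck. Selecting densities by
free-energy comparison alone would tie the open/closed transition to the
L-free density equation and make the critical strength exactly
independent of neck length; branch-resolved scanning recovers the weak,
strictly monotone L-dependence carried by the sheet-tension term −2γR/L
(a_critical = 383.1, 381.7, 381.1, 380.8 k_BT nm² for L = 20, 30, 40,
60 nm at otherwise-reference parameters). Because that dependence is a
few parts per thousand, `find_critical_a` bisects (geometrically) to a
relative tolerance of 1e-5 by default.

An independent brute-force oracle, `minimize_free_energy_grid`, takes
the argmin of F on a log-log (R, φ) grid (default 160×160 over
R ∈ [σ, 50 nm], φ ∈ [1e-3 φ₀, 10 φ_rmax]) followed by three levels of
local grid zooming. The R ceiling of 50 nm is deliberate: well above any
closed radius (which sits near r_max ≈ 2.8 nm), but below the radius at
which the unbounded open branch (−2πR²γ) undercuts the closed minimum
and a global argmin would stop being the physically relevant local one.
An argmin on the R edge is classified open. The solver and the oracle
agree within 2% in R over randomized parameter neighbourhoods (seeded
test).

Degenerate inputs: non-positive R, φ or parameters raise domain errors;
an unknown variant or a degenerate grid raises a configuration error; a
missing open/closed sign change in the critical-strength bracket raises
an explicit no-transition error, distinct from numerical failure.

## Nucleation-time estimator

Independent diffusing proteins give a Poisson-distributed neck occupancy
with mean 2πRLφ₀; the waiting time for n to co-occupy the neck is
estimated as τ · P(N ≥ n)⁻¹ with τ = L²/D the diffusive correlation
time. The tail is summed term-by-term whenever n > mean (the complement
of the CDF would cancel catastrophically at small means; the sum is
exact to machine precision and is verified against `scipy.stats.poisson.sf`).
`infer_critical_n` picks the n whose waiting time is nearest an observed
delay on a log scale, since the times span decades; a delay shorter than
τ returns n = 1 with a warning flag. R, φ₀ and D are explicit inputs
with no hidden defaults in the CLI — the monomer-vs-cluster diffusivity
choice materially changes τ and is the caller's to make. With
R = 6 nm, L = 40 nm, D = 2800 nm²/s, the mean occupancy is 0.030 at
φ₀ = 20 µm⁻² and 0.151 at 100 µm⁻²; an hour-scale delay then maps to a
critical cluster of 2–3 proteins, and the same cluster size nucleates in
under a minute at native expression. The exact integer inferred depends
on the geometric prefactors and the D assigned to monomers, so it is
reported as a consistency estimate, not a sharp constant.

## Tracking and diffusion

MSD uses the overlapping time-averaged estimator (all displacement pairs
per delay within each track, then an unweighted mean across tracks); a
non-overlapping variant is available. Tracks must be uniformly sampled
(frame intervals within 1% of the ensemble median; violations are
reported per track). The diffusion fit is ordinary least squares of
MSD = 4DΔt through the origin over delays ≤ 25 s, the 2D projection
convention; the 95% CI comes from the slope's t-based standard error and
R² is computed against the constrained model. A free-intercept mode
exists for data with static localization noise but is not the default —
the generator's localization noise defaults to zero, matching the
near-ideal linearity of the measured curves this emulates.

The asymmetry statistic builds the 2×2 gyration tensor
⟨xᵢxⱼ⟩ − ⟨xᵢ⟩⟨xⱼ⟩ and returns −ln(1 − (R₁²−R₂²)²/(R₁²+R₂²)²) from the
eigenvalues R₁² ≥ R₂². The logarithm base is taken natural (the source
formula leaves it unstated). Exactly collinear tracks saturate the
contrast at 1 and are capped at 746 with a degeneracy flag; an
all-points-identical track is undefined and raises.

## Copy-number calibration and labeling efficiency

The calibration is a least-squares line through the origin (slope in au
per fluorophore; R² reported against the constrained model), matching
the way the imaging standards are analysed; heteroscedasticity is
ignored. Spot intensities are sums over 6×6-pixel boxes minus a
same-size background box chosen by the caller on cluster-free membrane —
background selection is deliberately not automated. Copies are reported
as real numbers; rounding is presentation.

Labeling efficiency is the binomial MLE p̂ = (total steps)/(n_sites ×
n_traces) for i.i.d. Binomial(n_sites, p) step counts, with a 95%
profile-likelihood CI (likelihood-ratio inversion against χ²₁), which
stays sensible at boundary-adjacent p̂ where Wald intervals collapse; at
an exact boundary the interval is one-sided. A histogram least-squares
fit was considered and rejected as strictly less efficient for the same
model.

## Binding isotherms

Titrations are fitted to f_b = [L]/([L]+K_d) by unweighted nonlinear
least squares in log₁₀ K_d (affinities span decades; positivity is
automatic). Requirements: ≥ 4 points spanning ≥ 1 decade; bound
fractions outside [0,1] by ≤ 0.05 are clipped with a warning, larger
excursions are errors; all-saturated data are unidentifiable. The model
assumes total lipid ≫ bound protein.

The 95% CI is a symmetric studentized bootstrap (bootstrap-t) from case
resampling: each of the (default 1000) resample refits is studentized by
its own Gauss-Newton standard error, and the interval is
θ̂ ± se(θ̂)·q₀.₉₅(|T|). Two details matter for calibration. First,
percentile-type intervals systematically undercover here (measured
~88–89% at 95% nominal) because a titration has only a handful of
informative points near K_d and case resampling perturbs how many are
present; studentization corrects most of this. Second, the standard
error is taken from the SSE-profile curvature over a ±0.2-decade span
rather than a minimal stencil: resamples that lose informative points
have locally flat profiles, and a CI-scale span keeps their standard
errors (and hence T) stable. The refits are evaluated on a shared
log₁₀ K_d grid with parabolic refinement, keeping the whole bootstrap
vectorized. Measured coverage under the synthetic study conditions
(13 log-spaced concentrations over 1e-8–1e-4 M, Gaussian noise sd 0.05)
is ~93% pooled over 1200 independent datasets.

Charge density is Σ mole_fraction × |charge| per lipid; 30% cardiolipin
(two charges) equals 60% PG or PS (one charge) exactly.

## Synthetic data

Generators draw from per-stage RNG streams derived from
(seed, stage name) via hashed `SeedSequence`s, so regenerating one kind
of fixture never perturbs another, and all outputs are bit-reproducible
per seed. Defaults are the study conditions: 24 tracks × 250 one-second
frames at D = 2800 nm²/s (DMC) or 28 nm²/s (ISEP); titrations of 13
log-spaced concentrations over 1e-8–1e-4 M with Gaussian noise sd 0.05,
clipped to [0,1]; calibration standards of {4, 20, 40, 56, 80} copies
at 29.56 au/copy with 10% multiplicative noise, ten replicates per
level; 100 cluster spots of 40 emitters over an additive per-spot
background; 200 five-site bleaching standards at labeling probability
0.80.

What the generators do *not* emulate — and hence what passing tests do
not demonstrate about real data: spot detection and linking errors,
motion blur and localization noise (off by default), bleaching within a
trace, cell-surface curvature distorting 2D projections of motion,
titration replicate structure and pipetting error correlations, and any
deviation of real binding from the ideal Langmuir form. The tests show
the estimators recover known ground truth under the stated statistical
models, at the stated sample sizes.

## Problem sizes

The default suite and the analysis scripts use the study-scale sizes
directly (24–25 tracks × 250 frames; 50-seed diffusion replication;
100-replicate × 1000-resample binding studies; 100×200 bleaching
standards; 20 randomized parameter sets for the solver/oracle
comparison), chosen so a full run completes in about a minute for the
heaviest study while keeping Monte Carlo error well inside the asserted
tolerances.

## Known limitations

- The equilibrium model says nothing about fission dynamics, rates, or
  the post-nucleation growth of the cluster; the nucleation estimate is
  a scaling argument, not a first-passage calculation with absorbing
  boundaries.
- The printed/variational discrepancy in the radius condition is left
  open by design; conclusions that depend on which variant is used
  (none found at the reference parameters) should be treated with care.
- At extreme interaction strengths (a ≳ 10⁶ k_BT nm²) the finite
  crowding penalty lets φ rise well above φ_rmax and the equilibrium
  radius dips fractionally below r_max; the close-packing picture
  applies to the physically relevant a range around the transition.
- Copy-number conversion inherits the calibration's multiplicative
  noise floor (~2% on the slope at the default design); labeling
  near-boundary efficiencies make the binomial CI one-sided.
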