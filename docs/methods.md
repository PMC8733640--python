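# Methods

This note documents the models, conventions and numerical choices behind
`cornea-emod`, in the order data flows through the pipeline: air-puff
model, shell mechanics, synthetic examinations, extraction, statistics,
classifier.

## Air-puff model

The jet is idealised as a time-varying uniform pressure on a disc of
radius `rp` centred on the apex; the apex force is `f(t) = p(t) π rp²`
(kPa × mm² = mN, so the unit system is closed). The temporal profile is a
baseline-subtracted Gaussian: the Gaussian tail value at t = 0 is removed
and the profile renormalised, so the pulse starts at exactly zero, peaks
at `peak_pressure` (default 9.5 kPa) at `peak_time` (15 ms) and decays to
zero again before the end of the 32 ms window; `pulse_halfwidth` (6 ms) is
the half-width at half-maximum of the underlying Gaussian. These defaults
are conventions chosen to place simulated deformations in the
physiological range (peak deformation ≈ 1.0–1.3 mm across groups); the
true instrument profile is proprietary and all parameters are
config-overridable. Pressures are kPa internally; mmHg is accepted at I/O
boundaries with 1 mmHg = 0.133322 kPa.

The default frame convention is 140 frames over 32 ms across an 8 mm
chord — a public device convention, not a measured fact.

## Shell mechanics

The cornea is a thin shallow spherical shell of mid-surface radius
`R − t/2`, thickness `t`, Poisson ratio ν = 0.49 (nearly incompressible
soft tissue; overridable). The modulus is obtained from the
force–displacement slope `S` by

    E = S (R − t/2) √(12(1 − ν²)) / (π t (1 − c₁ μ²)),
    μ = rp [12(1 − ν²) / ((R − t/2)² t²)]^(1/4).

Three conventions deserve explicit statement:

* **Term grouping and units.** The grouping above, with slope in mN/mm and
  lengths in mm and the right-hand side read as kPa, is fixed in a single
  function (`shell._modulus_kpa`) so it can be swapped. It was chosen
  because group-mean healthy inputs then land in the 0.1–1 MPa decade
  reported for in-vivo corneal moduli. Read literally the expression has
  dimensions of force/length; the kPa reading is therefore a documented
  unit convention of this implementation, isolated at one boundary.
* **The correction coefficient c₁.** The linear Reissner shallow shell
  under normal load is equivalent to a flat plate on a Winkler foundation
  of modulus `Et/R²`; for a uniform disc load of dimensionless radius μ
  the centre deflection has the closed form `w(0) = (p/k)(1 + μ ker′(μ))`
  (Kelvin function `ker`). Writing the normalised apex stiffness
  `S(μ) = (πμ²/8)/(1 + μ ker′(μ))` (disc-load stiffness over point-load
  stiffness at equal resultant, `S(0) = 1`), we define
  `c₁(μ) = (1 − S(μ))/μ²`, so that `1 − c₁μ²` equals `S(μ)` exactly.
  `S > 1` — a spread load deflects the apex less than a point load —
  hence c₁ < 0. The coefficient varies logarithmically at small μ; below
  μ = 10⁻⁵ it is evaluated at that floor (the correction factor is 1 to
  machine precision there regardless). `compute_c1` accepts an override
  callable so an alternative shell solution can be substituted without
  touching the inversion.
* **Validation.** `disc_load_stiffness_fd` solves the same bending problem
  by a conservative cell-centred finite-difference discretisation of the
  axisymmetric biharmonic operator (clamped far edge at ≥ 25 decay
  lengths, boundary load cell weighted by its covered area fraction, the
  point-load reference applied to the innermost cell). It shares no code
  with the Kelvin closed form and agrees with it to better than 0.01%
  across the validity band μ ≤ 5; μ beyond that raises a quality flag on
  results.

`forward_stiffness` inverts the relation algebraically through the same
grouping function, so modulus → slope → modulus round trips are exact to
floating point.

## Synthetic cohorts

Subject-level variables are drawn per group from truncated normal
distributions. CCT, R, bIOP, true modulus E, SP-A1 and ARTh use published
group means and SDs (healthy / FFKC / KC: CCT 534.5±34.6 / 522.8±39.5 /
462.8±51.8 μm; R 7.75±0.92 / 6.94±0.95 / 5.36±1.01 mm; bIOP 15.3±2.0 /
14.6±1.8 / 14.3±2.5 mmHg; E 0.35±0.04 / 0.30±0.08 / 0.16±0.04 MPa;
SP-A1 93.3±14.5 / 79.6±14.1 / 41.6±13.5; ARTh 451±113 / 400±98 /
193±110). Truncation bounds are the type invariants (e.g. R ∈ [4, 10] mm,
CCT ∈ [300, 700] μm, bIOP ∈ [5, 40] mmHg); because truncating an
off-centre normal shifts its mean (the KC curvature radius has its lower
bound only ~1.3 SD below the mean), the underlying location is solved
numerically so the *truncated* mean equals the stated target, keeping
5000-subject sample means within 2% of the targets. The tomographic
features B.Ele.Th, Kmax and Pachymin have no published distributions; the
defaults are made-up, clinically plausible group-separated normals
(healthy 4±3 μm / 43.5±1.5 D / 528±35 μm; FFKC 8±4 / 45.0±1.8 / 505±40;
KC 35±15 / 55±6 / 438±50) whose only role is to give the classifier
group-informative inputs. Default cohort sizes are 50/36/50
(healthy/FFKC/KC), matching the study design this generator emulates.
E and bIOP are drawn independently by default; an empirical E–IOP
correlation exists in vivo but no generative relation is available, so
none is imposed.

## Forward examination model

For a subject with true modulus E the apex deformation is

    δ(t) = softclip( f(t) / k ),   k = forward_stiffness(E, geometry, rp),

where the softclip is exactly the identity up to a knee (0.5 mm, above
the 0.2–0.4 mm analysis window) and approaches a saturation amplitude
`DA_max` (1.45 mm) exponentially with continuous first derivative. The
exact linearity below the knee is deliberate: it makes the noiseless
simulate → extract → invert loop an identity, so any recovery error seen
in tests is attributable to the estimator, not the phantom. `DA_max` was
chosen so that group-mean subjects produce peak deformations near the
published group values (≈ 1.05 / 1.08 / 1.26 mm for healthy / FFKC / KC).

The spatial profile is a Gaussian bump of width w = 2.0 mm *truncated to
zero* at the whole-eye-motion peripheral zone (cutoff 3.5 mm) and
renormalised to unit apex value. The truncation matters: a pure Gaussian
leaks ≈ 22% of the apex deformation into |x| ≥ 3.5 mm, which would bias
the peripheral eye-motion estimator by ≈ 17% and with it every downstream
stiffness. Whole-eye motion is a quadratic drift `a t²`
(a = 10⁻⁴ mm/ms²) applied to the entire profile; elevation noise is
i.i.d. Gaussian per sample with σ = 2 μm. Every examination embeds its
noiseless deformation series, stiffness, applanation instants (computed
with the same central-zone curvature definition the extractor uses),
eye-motion coefficient and noise σ, so extraction error never requires
re-simulation.

The optional rasteriser renders each frame as a bright band of
configurable thickness with additive noise and records the pixel
geometry; `detect_edge` recovers the curve per column as the
intensity-weighted centroid around the brightest pixel (sub-pixel
accurate, < 0.5 px noiseless, median ≤ 1 px at default noise).

## Extraction

* **Whole-eye motion**: mean elevation change (vs frame 0) over
  |x| ≥ 3.5 mm; deformation = apex elevation change − that series. With
  the compact deformation bump this estimator is unbiased; injected
  quadratic drifts cancel exactly.
* **Applanation events**: per-frame quadratic fit over the central
  |x| ≤ 1 mm; curvature = 2× the quadratic coefficient; A1T/A2T are the
  first (loading) and last (recovery) zero crossings, localised sub-frame
  by linear interpolation. The device's true flatness criterion is not
  public; this fitting-zone convention is documented and configurable.
  A1V/A2V are central-difference velocities of the deformation series
  interpolated at those instants (A1V > 0, A2V < 0 by the inward/outward
  sign convention). HCT/DA are the time and value of the deformation
  maximum; PD is the distance between the two surface crests flanking the
  apex at the HCT frame (ties toward larger |x|).
* **Stiffness**: OLS slope of force on deformation restricted to loading
  samples with δ ∈ [0.2, 0.4] mm; fewer than 3 in-window samples raises a
  subject-level quality error (reported as a QC exclusion, never a silent
  drop).
* **Effective puff radius**: at the A1T frame, half-width of the
  contiguous zone whose (lightly smoothed) elevation stays within 8 μm of
  the apex elevation. A depth criterion is used instead of a pointwise
  curvature threshold because 2 μm column noise dominates per-column
  second derivatives; zones narrower than 0.5 mm (an undeformed arc
  always yields ≈ √(2R·tol) ≈ 0.35 mm) trigger fallback to the
  configured default with a warning flag.

## Statistics

Normality uses the Lilliefors-corrected one-sample K–S test (parameters
estimated from the sample; plain K–S p-values would be conservative —
common statistical packages apply the same correction). Agreement reports
bias, 95% limits of agreement (bias ± 1.96 SD of differences), the paired
t-test, ICC(2,1) (two-way random, absolute agreement, single measures —
the standard two-device form; the form name is recorded in the output)
and the concordance correlation coefficient in its population-moment
form. One-way ANOVA is computed from the explicit sum-of-squares
decomposition (SST = SSB + SSW is asserted as an invariant) with Fisher
LSD pairwise t-tests on the pooled within-group mean square. ROC analysis
is empirical with trapezoidal AUC (equal to the Mann–Whitney pair count
with ties at 1/2); score orientation is auto-chosen so AUC ≥ 0.5 and
recorded; cutoffs maximise the Youden index with ties broken toward
higher specificity. Correlated AUCs on identical subjects are compared
with the DeLong placement-value construction (two-sided normal test).
Raw p-values are reported throughout; no multiplicity correction is
applied beyond LSD.

## Classifier

A 12–5–1 feed-forward network (tanh hidden, linear output) regresses the
group code healthy = 1, FFKC = 0, KC = −1 from A1T, A1V, A2T, A2V, SP-A1,
PD, DA, ARTh, B.Ele.Th, Kmax, Pachymin and E. Training minimises MSE with
Levenberg–Marquardt (damped Gauss–Newton on the analytic residual
Jacobian; λ scaled ×10 on rejection, ÷10 on acceptance), stopping at MSE
≤ 0.005 or 1000 iterations; plain gradient descent with learning rate
0.01 is available as a fallback optimizer. Features are z-scored with
statistics fitted on the training split only; the 70/30 split is
stratified by group with largest-remainder allocation so each group's
training share is within one subject of 70%. Weight initialisation is
uniform [−0.5, 0.5] scaled by 1/√fan-in from a seeded generator;
(data, config, seed) fully determine the model. Continuous predictions
are thresholded at ±0.5 consistently with the coding (value > 0.5 → the
group coded 1); values exactly at ±0.5 fall to the middle group. One
published figure caption assigns the thresholds in the opposite order to
its own coding; this implementation keeps coding and thresholds mutually
consistent rather than guessing intent.

## Reproducibility and problem sizes

One master seed drives everything: the cohort generator derives
per-subject simulation seeds from it, so any single subject is
reproducible in isolation from its cohort row. Default problem sizes —
chosen as the package's own test-scale conventions — are 50/36/50
cohorts, 50 repetitions per cell in recovery experiments, 10–20 seeded
cohorts in discrimination summaries, and n = 3000 radial cells in the
finite-difference shell oracle.

## What the synthetic data do and do not show

The generator reproduces the *statistical structure* of the published
group tables (means/SDs of geometry, pressure and modulus, group-coded
auxiliary features) and the *physical structure* the extractor assumes
(quasi-static force balance, compact deformation bump, rigid eye motion,
i.i.d. elevation noise). It does not model corneal viscoelasticity or
damping (the deformation is in phase with the force; HCT sits at the
force peak rather than ~2 ms after it as in vivo), spatially correlated
speckle noise, posterior-surface dynamics, IOP–deformation coupling, or
tear-film/eyelid artefacts. Passing tests therefore demonstrate that the
estimators are correct and well-conditioned under the stated model, and
that group separations consistent in location with published AUCs emerge
from the calibrated distributions — not that the pipeline reproduces any
clinical cohort's numbers. A1T/A2T group separations in particular are
weaker here than in vivo because the simulated applanation time is driven
almost entirely by stiffness rather than by IOP.

## Known limitations

* The c₁ derivation assumes an infinite shallow shell (no limbal boundary)
  and a clamped far field; both are standard for this geometry but
  untested against finite-cornea FE models here.
* The kPa reading of the modulus relation is a convention (see above);
  absolute E values inherit it, though all *relative* comparisons (group
  contrasts, AUCs, recovery errors) are invariant to it.
* The device's SP-A1 definition involves proprietary pressure calibration;
  the extracted SPA1 here follows the printed formula
  (adjusted pressure at A1 − bIOP)/deflection and is not numerically
  comparable to device output. Cohort-level SP-A1 features are therefore
  drawn from the published distributions instead.
* QC exclusions (never-applanating or window-unreachable subjects) are
  rare (< 1% at defaults) but group-dependent; exclusion counts are
  reported in every study summary.
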