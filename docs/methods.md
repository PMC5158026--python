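# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `tubemech`.  Units throughout:
µm, µN, MPa and seconds — a mutually consistent system
(1 MPa = 1 µN/µm²) in which membrane tensions and stiffnesses come out
directly in N/m.

## The measurement and its processing

A cellular force microscope drives a force sensor toward the tube at
constant stage speed (2 µm/s), loads to a 5 µN maximum and retracts.  The
stage displacement `z` is shared between sample indentation `δ` and the
sensor's own elastic deflection: `z = z0 + δ + F/k_sensor` (two springs in
series).  Processing a raw `(t, z, F)` record involves three steps.

**Contact detection.**  A baseline line is fitted to the early approach
(removing offset and the weak capillary slope) and contact is declared at
the first run of ≥ 5 samples exceeding 5 baseline standard deviations.
Two refinements make this robust in regimes where the naive rule fails:

* the baseline window, nominally the first 20% of the approach, is capped
  below a crude estimate of the force rise and then *refitted* strictly
  before the detected contact.  For very compliant tubes (≈ 0.2 N/m) the
  indentation depth dominates the approach and a fixed-fraction window
  would otherwise swallow the beginning of the force rise — contaminating
  the baseline slope and biasing the recovered stiffness by up to −15%;
* the contact coordinate `z0` is refined to sub-sample resolution by
  intersecting a line fitted to the early force rise with the baseline.
  On synthetic curves with 10 nN force noise this locates `z0` to ≈ 5 nm
  (about one 4 nm sample), versus several samples for a walk-back rule.

**Sensor cancellation.**  `δ = (z − z0) − F/k_sensor`, with the fitted
baseline line subtracted from the force.  On noiseless, curvature-free
synthetic curves this inverts the generator's series-spring construction
exactly (tested to < 0.1% across sensor/sample stiffness ratios 0.5–50).
The curve splits into loading and unloading at the global force maximum.

**Apparent stiffness.**  Ordinary least-squares slope of `F` against `δ`
restricted to the maximum-load region, `F ≥ (1 − w) F_max`, with
`w = 0.2` by default.  The window width is a configuration parameter: the
"region of maximum load" is a definition, not a measurement, and the
sensitivity of the result to `w` is itself of interest.  Statistics are
pooled per indentation (n tubes, m indentations, one distribution), and
the growing/non-growing comparison uses a two-sided permutation test on
the difference of means with add-one correction — the stiffness
distributions are strongly right-skewed (mean > median), so a t-test's
normality assumption is unattractive.

## The synthetic cohort generator

The study's raw recordings are unavailable, so cohorts are generated with
known truth and the pipeline is validated by parameter recovery.  The
generator emulates:

* **Tube geometry.**  Diameters i.i.d. truncated-normal (17.4 ± 2.5 µm for
  lily, 4.9 ± 0.7 µm for Arabidopsis; truncation at zero is negligible as
  mean > 3 sd).  Wall thickness uniform on 0.1–0.3 µm and turgor uniform
  on 0.1–0.4 MPa by default — values in the range reported for lily pollen
  tubes; both are configurable and carried per tube.
* **Truth stiffness (empirical mode).**  A lognormal is the natural
  two-parameter family for a positive, right-skewed quantity, and its
  parameters are fixed exactly by the printed mean and median:
  `exp(µ) = median`, `σ² = 2 ln(mean/median)`.  The loading marginal of
  the growing group uses (2.20, 1.73) N/m.  Hysteresis is modeled by a
  second, correlated lognormal (Gaussian copula, ρ = 0.8 on the log scale)
  for unloading, clipped from below at the loading value:
  `k_unload = max(k_load, k')`.  The clip enforces the observed hysteresis
  direction for every tube — note that *no* coupling of the two printed
  marginals can do this exactly, because the printed loading σ exceeds the
  unloading σ and the marginal survival curves cross in the upper tail.
  The location parameter of `k'` is therefore calibrated (closed-form mean
  of a bivariate-lognormal maximum, plus scalar root finding) so the mean
  of the clipped unloading distribution equals the printed 3.28 N/m
  exactly.  Groups printed without medians (non-growing: means
  0.69/1.67 N/m) reuse the growing group's log-scale σ per phase with
  `µ = ln(mean) − σ²/2`.
* **Curve shape.**  In contact the sample force follows the quadratic
  family `F(δ) = k_e δ (1 + β δ/δ_max)`, with β = 0.1 by default (β = 0
  gives an exactly linear ramp used by the closed-form tests).  The truth
  value attached to a tube is *defined* as the apparent stiffness in the
  maximum-load window — the quantity the instrument pipeline reports — so
  the generator rescales the linear coefficient `k_e` by the analytic
  window factor of the quadratic (1.18 at β = 0.1, w = 0.2 on loading;
  1.02 on unloading, whose window sits at the start of the retraction).
  Unloading follows the analogous quadratic from the turning point,
  reaching zero contact force at a positive residual indentation.
* **Instrument effects.**  Series sensor spring (default 10 N/m, recorded
  in the manifest so processing can cancel it), additive Gaussian force
  noise (default sd 10 nN), a capillary background slope (default 1% of
  the group's median stiffness, two orders below the sample stiffness),
  and a 100 µm stage-travel limit (a typical piezo-stage range; the
  5 µN load is unreachable within travel for tubes below ≈ 0.06 N/m, and
  cohort synthesis records any skipped curves in the manifest).
* **Apex softening.**  Near the hemispherical tip the indentation axis is
  not normal to the wall; only the cos²φ projection of the reaction acts
  along the sensor axis, with `cos φ = min(distance/R, 1)`.  Apex-mode
  cohorts place indentations at 4–14 µm from the tip so that the distance
  bins straddle the dome gradient; shank-mode cohorts use 50–150 µm
  (attenuation exactly 1), matching the convention that "shank" means
  ≥ 50 µm from the tip.

Everything is driven by one integer seed through a `SeedSequence` tree;
fixed seed ⇒ bit-identical cohorts and byte-identical output files.

What the generator does *not* emulate — and hence what recovery tests do
not show about real data: drift and hydrodynamic artifacts, viscoelastic
rate dependence (the two phases have static truth values), spatial
heterogeneity of the wall along the shank, adhesion on retraction, and any
deviation of real hysteresis from the lognormal-pair model.

A note on cohort-size effects: at the printed design (19 tubes, ~7
indentations each) the pooled statistics are clustered — indentations of
one tube share its truth.  The pooled mean then carries ≈ 0.4 N/m of
between-cohort spread, and the pooled *median* of so few effective values
is slightly upward-biased for a lognormal (≈ +2% at n = 19).  Recovery
experiments therefore average over seed replicates and quote the
between-replicate standard error.

## The shell forward model

The tube shank is modeled as a thin-walled, linear-elastic circular
cylinder under internal pressure, indented by a uniform pressure patch of
radius `a = 0.4 µm` (the tip radius) at mid-length.  On the developed
surface (axial `x`, circumferential arc `s = Rθ`) the linearized
Donnell shallow-shell equations with an Airy stress function φ read

    D ∇⁴w − (1/R) φ_xx − N_x w_xx − N_θ w_ss = q(x, s)
    ∇⁴φ + (E t / R) w_xx = 0

with bending rigidity `D = E t³ / 12(1 − ν²)` and pressure pretensions
`N_θ = pR`, `N_x = pR/2`.  Eliminating φ mode-by-mode for a simply
supported cylinder (`w = Σ w_mn sin(λ_m x) cos(n θ)`, `λ_m = mπ/L`) gives
the modal stiffness

    K_mn = D κ⁴ + E t λ_m⁴ / (R² κ⁴) + N_x λ_m² + N_θ (n/R)²,
    κ² = λ_m² + (n/R)²

— bending, membrane stretching, and pretension.  The patch load
contributes `q_mn ∝ J₁(κa)/κ`, only odd `m` reach the center, and the
apparent stiffness is `k = F / w(center)`.

**Numerics.**  The series is evaluated vectorized over an (m, n) grid up
to a truncation wavenumber κ_max that resolves both the patch (6/a) and
the bending boundary layer (12/√(Rt)); κ_max is doubled until the center
deflection changes by < 10⁻⁴ relative (non-convergence raises, never
returns silently).  The truncation ladder is quantized and the mode
geometry cached, so inversion sweeps reuse it across (E, t, p) changes.
Defaults: ν = 0.3 (not printed for the wall; configurable), L = 20 R
(simply supported ends; the L-sensitivity between 10 R and 40 R is below
1%, tested).  With p = 0 the operator is exactly linear in E (verified to
10⁻⁶), and k is strictly increasing in E, t and p on physiological scans;
the diameter trend is reported but not asserted.

**Independent oracle.**  The same two coupled PDEs are discretized by
second-order finite differences on the developed surface and solved as one
sparse LU system (fields w and φ stacked).  Symmetry about the load
meridian and the mid-length plane reduces the domain to a quarter
(mirror-image second differences; quarter-vs-full equivalence is tested to
10⁻⁸).  The grid spacing must satisfy `h ≤ min(a/2, √(Rt)/4)` — at least
four cells across the patch diameter and the boundary layer — and halving
h moves the answer by < 2%.  Across a 3 × 3 × 3 grid over
E ∈ [20, 400] MPa, t ∈ [0.1, 0.3] µm, p ∈ [0.1, 0.4] MPa at the lily
diameter, the two solvers agree to 0.35% worst-case (the acceptance bound
is 5%).  The oracle exists purely for verification; the Fourier solver is
the production path.

## Inversion

`k_model` is continuous and strictly increasing in E at fixed (t, p, d),
so `invert_E` brackets on E ∈ [1, 1000] MPa and runs Brent's method
(relative tolerance 10⁻⁴; forward-then-invert round trips recover E to
< 1% across a Latin hypercube of the physiological box).  Targets outside
the attainable stiffness interval — e.g. a soft target under high turgor,
where the pressure floor alone exceeds it — are reported as incompatible
geometry, not raised.

`compatible_set` grids (t, p, d) (default 10³ over wall 0.1–0.3 µm, turgor
0.1–0.4 MPa, diameter mean ± 2 sd = 12.4–22.4 µm), inverts at every node,
and keeps bracket-endpoint moduli when they still match the target within
the 10% relative tolerance ("similar stiffness" needs an explicit
tolerance; 10% is the default and configurable).  At the growing-group
mean loading stiffness of 2.20 N/m the compatible moduli span
1–659 MPa — far more than the order-of-magnitude spread that motivates
reporting a range rather than a point value.  The endpoints themselves are
model-dependent (a linearized shell, a particular parameter box) and are
reported informatively; the robust, asserted property is
`E_max/E_min ≥ 10`.  Only the loading phase is inverted.

## Known limitations

* The shell model is geometrically linear; at 5 µN the real indentation
  depth is comparable to the tube radius and the true response stiffens.
  The reported `k_model` is the small-deflection slope about the
  pressurized state, so compatible-modulus *endpoints* should be read as
  model-conditional.
* The apical dome is handled only through the cos² contact-angle
  projection in the generator; the forward model covers the cylindrical
  shank, and inversion of apex-region stiffness is out of scope.
* Wall anisotropy, layering and viscoelastic constitutive behavior are not
  modeled; loading/unloading separation is the only concession to
  rate-dependence, mirroring the measurement convention.
* The empirical-mode answer key defines truth as the windowed apparent
  stiffness at the generator's calibration window (w = 0.2); analysing
  such cohorts at a very different w introduces a small, analytically
  predictable offset.
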