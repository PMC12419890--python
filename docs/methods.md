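# Methods

## Model

The steady-state force to cut a thin sheet is modelled as an energy balance:
cut advance d*x* creates crack surface *t*·d*x* at cost *G*c·*t*·d*x*, giving
the sharp-blade lower bound *F* ≥ *G*c·*t*.  A blunt edge adds near-tip
dissipation d*U*loss ≈ *C*·σc·*R*·*t*·d*x*, so

F_f = Gc·t·(1 + Ω),   Ω = C·σc·R/Gc.

Assumptions: thin-sheet cutting (bending/buckling negligible), steady-state
propagation (initiation excluded), rate independence (cutting-speed effects
of order 20% per threefold speed change are ignored), and a single
characteristic tool length *R*.  σc is identified with the ultimate tensile
strength by default; it is a plain field on `MaterialProperties`, so a yield
stress or modulus can be substituted where more appropriate.  *C* is treated
as a constant; its possible dependence on friction and strain stiffening is
deliberately not modelled.

Key parameters and defaults:

| parameter | default | units | meaning |
|---|---|---|---|
| `C` | 2.0 | – | contact constant of order unity |
| `omega_sharp_threshold` | 0.05 | – | largest Ω at which measured forces are indistinguishable from Gc·t |
| `Gc`, `sigma_c`, `E` | per material | J m⁻², Pa, Pa | sheet characterization (means ± sd) |

Regime classification is strict at the threshold: Ω exactly at the cutoff is
`transitional`, Ω ≥ 1 is `geometry_dominated`.  The critical radius — the
largest *R* that elevates the predicted force by at most a tolerance τ — is
the inversion R = τ·Gc/(C·σc); for a median tropical leaf with σc = 3 MPa
and Gc = 400 J m⁻² the 5% criterion gives R ≈ 3.3 µm.

Uncertainty propagation is first-order Gaussian with independent errors
(no covariance terms); the propagated sd of Gc·t is verified against a
10⁵-draw Monte Carlo in the tests.

Reference materials shipped with the package (tensile + pure-shear
characterization, mean ± sd): 4:1 PDMS (E 4.1 ± 0.3 MPa, Gc 98 ± 9 J m⁻²,
σc 6.0 ± 2 MPa), 10:1 PDMS (1.6 ± 0.3 MPa, 197 ± 25 J m⁻², 5.5 ± 2 MPa) and
Japanese laurel lamina (31 ± 4 MPa, 746 ± 210 J m⁻², 1.63 ± 0.3 MPa).

## Trace processing

Each trial has two passes at constant stage speed (default 0.3 mm s⁻¹,
5 mm travel): first pass through intact sheet (plateau = total cutting force
*F*c), second pass through the open cut (plateau = spacing force *F*s);
fracture force *F*f = *F*c − *F*s.  Displacement is time × stage speed unless
an explicit displacement column is supplied, which takes precedence.

Steady-state extraction averages a fixed 2 mm displacement window.  The
exact post-peak settling rule is a package decision (deterministic, exposed
in the API):

1. the cut-initiation peak is the global force maximum (first pass only);
2. settling is the first post-peak sample whose 5-sample rolling median lies
   within `settle_fraction` (default 10%) of the trailing median (median
   force over the final 2 mm);
3. the averaging window starts a `guard_length` (default 0.4 mm) of travel
   later.  The guard matters: when settling triggers, the decaying
   initiation transient can still be at up to 10% of the plateau, and
   averaging from that point biases the plateau estimate by ~0.5%; the guard
   suppresses the remnant by e^(−guard/settle-scale) to ≲ 0.01%, below the
   noise floor of the window mean.

The second-pass window is pinned to the same displacement interval as the
first-pass window, keeping *F*c and *F*s comparable.  Trials with less than
2 mm of post-settling travel raise an "insufficient steady state" error and
are excluded by the pipeline with a reason code.  Negative fracture forces
(Fs > Fc) are flagged, never clipped — discarding is a pipeline-level policy.
Lamina-thickness correction rescales all three forces by t̄/t₁; it is
applied only to substrates tagged biological, errors on double application,
and inverts exactly with the `force=True` override.

## Edge geometry

Definitions: the wedge angle is the interior angle between two lines fitted
along the straight flanks of the tip cross-section; the edge radius is the
radius of the smallest circle tangent to both flank lines that fits entirely
within the material cross-section.

Automation decisions (all in `FlankFitConfig`):

- **Straight-flank criterion.** A vertex is straight when the summed turning
  angle across a 10 px arc-length window is below 2°.  The window is
  measured in arc length, not vertex count: at the 0.5 px discretization a
  gentle tip arc turns only ~0.5°/vertex, so a per-vertex threshold cannot
  separate arcs from flanks, whereas a 10 px window accumulates 10/R
  radians on an arc and flags it curved for any radius up to ~280 px.  The
  two longest straight runs are the flanks, each fitted by total least
  squares (SVD); the apex is their intersection.  Fewer than two runs →
  "no flanks" error; flanks within 1° of parallel → degenerate-geometry
  error.
- **Containment test.** The open contour is closed by the straight segment
  joining its endpoints (the bounding cut edge).  A candidate circle of
  radius r has its centre on the interior bisector at distance r/sin(γ)
  from the apex (γ = half wedge angle), which enforces exact bitangency;
  it fits when the centre lies inside the polygon and its distance to every
  boundary segment is ≥ r − 0.01 px (the slack absorbs the sagitta of the
  discretized arc and floating-point tangency).
- **Search.** Containment is monotone in r for wedge-plus-tangent-arc tips
  (verified by a property test), so the smallest contained radius is found
  by bracketing on a 64-point log grid followed by bisection to 0.05 px.
  A brute-force 0.1 px upward grid search serves as the independent oracle
  in the tests.

Estimates are exactly scale-equivariant (the solve runs in pixel space) and
rotation/translation invariant to within the bisection tolerance.  Radii
below the pixel scale are reported at the resolution floor (≤ 2 px).

## Material characterization

Engineering stress/strain throughout.  Young's modulus is the least-squares
slope over a fixed strain window (default 0–5%) — deterministic, no knee
detection; narrow the window for stiff, low-strength materials whose linear
region ends earlier.  UTS is the maximum stress.  Tearing energy uses the
pure-shear relation Gc = W(λc)·h₀ with W the trapezoid-integrated strain
energy density of the unnotched twin up to the critical stretch of the
notched twin — for the pure-shear geometry the energy release rate is
independent of crack length, making this product exact.  Replicates are
pooled as mean ± sample sd; a single replicate yields sd 0 with a warning.
Plant-tissue anisotropy and heterogeneity are not modelled.

## Allometry

Scaling exponents are OLS slopes on log₁₀–log₁₀ axes (the field's
convention; not standardized major axis), with 95% t-intervals on the slope.
Group contrasts are ratios of means with seeded percentile-bootstrap
intervals (default 2000 resamples).  Repeated-measures ANCOVA-style
inference is out of scope; the pipeline emits tidy tables for external
statistical software.

## Synthetic data

The generator emulates the study conditions: 15 workers per group with body
masses evenly spaced in log₁₀ over 1.9–55.5 mg (callows) and 2.3–54.8 mg
(foragers); pristine edge radii size-invariant, truncated-normal with mean
162 nm and sd 120 nm; worn radii following R = a·m^(−0.87) with lognormal
scatter (sd 0.4 dex — an assumption, the true wear distribution at a given
mass being unknown), clamped to 89–11712 nm.  The power-law prefactor maps
the log-midpoint of the mass range to the log-midpoint of the radius range;
the deterministic line cannot span the full observed radius range (the mass
range raised to 0.87 spans a factor ~19, the radii a factor ~132), so the
scatter supplies the tails.

Traces: plateau levels satisfy the model exactly (Ff = Gc·t·(1+Ω));
spacing fractions are drawn uniformly in a configurable band (12–22% for
pseudoleaf profiles, 9–14% for plant profiles); additive Gaussian noise
(default sd 1 mN) on both passes; the initiation peak is a linear ramp to
1.33× the plateau with 0.1 mm exponential settling — an invented shape whose
parameters matter only through the plateau statistics.  Sheet thicknesses
scatter 5% about their 200/400 µm nominals.  Sampling: 300 Hz at
0.3 mm s⁻¹ (≈ 2000 samples per 2 mm window).

Stress–strain records have exact initial slope E and exact peak σc
(piecewise linear/monotone-Hermite construction with the section boundaries
on the strain grid); pure-shear pairs are built so the zero-noise tearing
energy equals the material's Gc exactly.  Stress noise is multiplicative
(sensor error scaling with signal).

What the generator does **not** emulate: leaf veins and spatial
heterogeneity, abrasion physics of wear, cut-initiation mechanics, rate
dependence, sensor drift.  Passing tests therefore demonstrate that the
pipeline recovers known ground truth under the study's idealized conditions,
not that it is robust to every artefact of real micrographs or real force
traces.

## Pipeline policies

Thickness correction only for biological substrates (pseudoleaf variation
< 5%); repeats averaged per blade before group summaries (a deterministic
substitute for repeated-measures modelling, applied after correction);
every exclusion carries a reason code (head/epoxy contact, fixation
failure, blade damage, short steady state) and is reported, never imputed.
The parameter-recovery regression Ff/t = Gc + C·σc·R pools both groups per
material, using the per-trial measured thickness.

## Problem sizes and tolerances in the shipped tests

Simulated studies run 2 groups × 15 workers × 4 sheet types (120 trials,
seconds on one core); the edge-geometry validation sweeps 50 contours over
radii 89–11712 nm and angles 30–93° at 30–70 px target radius; coverage
checks use 500 seeded replicates of small regressions.  Recovery tolerances:
edge radius 2%, wedge angle 0.5°, tearing energy 5%, C·σc 10%, plateau bias
< 1%.

## Known limitations

- The flank detector assumes the contour runs flank → tip → flank and that
  the tip arc radius is below ~280 px at the chosen scale; pick the image
  scale so the expected radius is tens of pixels.
- Contour extraction from real SEM micrographs (thresholding, segmentation)
  is out of scope; inputs are ordered point lists.
- The critical-radius formula inverts the model exactly; published
  rule-of-thumb radii for "sharp enough" blades depend on the choice of σc
  and can differ from this inversion by small integer factors.
- Energy terms beyond fracture and near-tip dissipation (bending,
  plasticity, far-field friction) are subsumed in the spacing force rather
  than modelled.
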