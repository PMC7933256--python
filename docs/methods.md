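# Methods

`atriamorph` quantifies left-atrial (LA) shape remodeling from a closed
triangulated surface of the segmented atrium.  This note documents the
measurement model, its tunable parameters, the synthetic-atrium generator the
tests rely on, and the numerical choices behind both.

## The measurement chain

Given a closed surface (mm coordinates) and three landmark groups — the
pulmonary-vein (PV) ostia centroids, the left-atrial-appendage (LAA) ostium,
and an inferior reference point such as the mitral annulus centre — one
`AtrialShapeModel.fit()` call runs:

1. **Best-fit sphere (ICP).**  A sphere is registered to the surface by
   iterative closest point: each vertex is matched with its closest point on
   the current sphere, then centre and scale are re-estimated as the
   similarity transform minimising the summed squared mismatch (for a sphere
   the template's rotation is pure gauge, so centre + scale are the only
   effective parameters).  The iteration starts from the area-weighted
   centroid and mean radial distance and stops when both the centre shift
   and the radius change fall below 1e-10 of the current radius (≤ 200
   iterations).  The relative stopping rule keeps the fit — and everything
   derived from it — invariant under uniform rescaling of the input.  On
   zero-residual data the fixed point coincides with the direct algebraic
   least-squares sphere (`fit_sphere_algebraic`, the independent oracle used
   in testing); on noisy data it is the orthogonal-distance least-squares
   sphere, which differs from the algebraic estimator at order σ²/AR.
   The fitted radius is the **average radius AR** (mm).

2. **Signed radial deviation and protrusion exclusion.**  Each vertex gets
   `d_i = |v_i − c| − AR`, measured along the ray from the sphere centre:
   positive is outward/convex, negative inward/concave.  Vertices with
   `d_i > +10 mm` are excluded — PV stumps and the appendage protrude
   outward, atrial wall does not — and carry no weight in any surface
   statistic.  An `absolute` mode (|d_i| > threshold) is available.  By
   default the sphere is then refit on the included vertices until the
   exclusion mask stabilises (at most 2 passes, configurable 0–5): a tall
   protrusion pulls the all-vertex fit enough to shift S by ~0.2 mm, and the
   sphere is meant to describe the atrial body, not its protrusions.
   Setting `refit_passes: 0` restores the fit-once behaviour.

3. **Mean deviation and sphericity.**  `S` is the area-weighted mean of
   |d_i| over included vertices (barycentric vertex areas; area weighting
   makes S mesh-resolution invariant, an unweighted option exists).  The
   absolute value is deliberate: the signed mean is ~0 near the least-squares
   optimum by construction, which would make every atrium look perfectly
   spherical.  Sphericity is `LAS = 1 − S/AR`, stored as a fraction and
   printed as percent; 1 means a perfect sphere.

4. **Anatomical frame and six-segment partition.**  The superior axis ẑ
   points from the inferior reference to the sphere centre; the posterior
   axis p̂ is the PV-centroid direction orthogonalised to ẑ; the lateral
   axis is ±(ẑ × p̂) with the sign fixed so the LAA ostium has positive
   lateral and negative posterior coordinates (the LAA is anterolateral; the
   sign flip mirrors the azimuth when the export chirality requires it).
   Vertices are binned by polar angle θ (from ẑ) and azimuth φ (from p̂
   toward the lateral axis): θ < 45° roof; 45–105°: posterior (|φ| < 60°),
   septum (φ ≤ 0 side) or lateral (φ > 0 side); θ ≥ 105°:
   inferior-posterior (|φ| < 90°), inferior septum (φ ≤ 0) or lateral
   (φ > 0).  No published boundary definition exists for these segments, so
   the four band angles are configuration values (`BandConfig`), not
   constants; the defaults above are the package's choice.  Excluded
   vertices keep the label `excluded`.

5. **Segmental wall deviation.**  `D_seg` is the *signed* area-weighted mean
   of d_i over the segment's included vertices — signed, because inward
   (concave) remodeling of e.g. the posterior wall must appear as a negative
   D.  The area-weighted combination of the six D values reproduces the
   whole-surface signed mean (a consistency identity asserted in tests).
   A segment with zero included area reports NaN with a warning.

6. **Volumes and asymmetry.**  The total volume LAV comes from the
   divergence theorem (mm³ → mL in exactly one place).  The cutting plane is
   oriented parallel to the posterior wall — the total-least-squares plane
   through the posterior-segment vertices — and positioned on the segment
   between the PV-ostia centroid and the LAA ostium (interpolation factor
   `plane_offset`, default 0.5 = midpoint), normal toward the LAA.  Clipping
   splits LAV into anterior LA-A and posterior LA-P; the asymmetry index is
   `ASI = LA-A / LAV`.  Clipped part-volumes are computed by clipping each
   triangle against the plane and summing signed tetrahedra referenced to a
   point *on* the plane, so the planar caps contribute exactly zero volume:
   conservation LA-A + LA-P = LAV holds to machine precision for any plane,
   and no cap triangulation is ever constructed.

Deterministic throughout: identical inputs and configuration give
byte-identical outputs; every metrics record carries the configuration
digest, software version and input checksums.

## Tunable parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `exclusion_threshold` | 10 | mm | outward deviation beyond which a vertex is a protrusion |
| `exclusion_mode` | `outward` | — | `outward` (d > t) or `absolute` (|d| > t) |
| `refit_passes` | 2 | — | refit-on-included iterations (0 disables) |
| `area_weighted` | true | — | barycentric-area weights in S and D |
| `plane_offset` | 0.5 | — | cutting-plane position between PV centroid (0) and LAA (1) |
| `BandConfig.roof_polar` | 45 | deg | roof / mid-zone boundary |
| `BandConfig.inferior_polar` | 105 | deg | mid / inferior boundary |
| `BandConfig.posterior_half_width` | 60 | deg | posterior band half-width |
| `BandConfig.inferior_posterior_half_width` | 90 | deg | inferior-posterior half-width |
| `stats.alpha` | 0.05 | — | two-tailed significance level |
| `stats.welch` | false | — | Welch instead of pooled-variance t |
| `stats.bh_correction` | false | — | Benjamini–Hochberg adjusted p-values |

## Cohort statistics

`lva_association_analysis` takes a per-patient table (LAV, LA-A, LA-P, ASI,
AR, S, LAS, six D values, six binary low-voltage labels and their count) and
emits three labelled families: Spearman correlations of every metric against
the low-voltage segment count; the pairwise Spearman grid among D values and
against LAV/ASI/LAS; and the "extended low voltage" group contrast — count
= 6 versus counts 1–3 (0, 4, 5 are outside the contrast) — per segment with
an equal-variance Student t by default.  All p-values are two-tailed and
uncorrected by default.  Spearman uses average ranks; its p-value is an
exact permutation probability for n ≤ 10 (full enumeration, vectorised in
chunks) and the Student-t approximation above.  Wilcoxon tests use the
exact null for combined n ≤ 12 and the continuity-corrected normal
approximation otherwise; chi-square is Pearson's without continuity
correction (Yates by flag).  A Kolmogorov–Smirnov normality screen exists
as a descriptive flag only — it never switches a test.  Degenerate requests
(constant vectors, groups smaller than 2) become not-computable rows, not
exceptions.  Classical test machinery (t, chi-square, Pearson p, exact
Wilcoxon nulls, large-sample approximations) is delegated to scipy behind
this module's interface.

## The synthetic-atrium generator

No public atrial-mesh datasets accompany this method, so the generator is
the test bed.  One atrium is an icosphere (default radius 32 mm,
subdivision 4 ≈ 2562 vertices) displaced radially by:

* **six segment bumps** — smoothed indicators of the six segments (full
  amplitude inside, raised-cosine decay over 25° outside), signed mm;
* **anterolateral elongation** — a quadrupolar term
  `e·(u_x² − 0.5·u_y² − 0.8·u_z²)` emulating the non-uniform dilation of an
  atrium constrained posteriorly by the spine and superiorly/inferiorly by
  its connections; a similarity sphere fit cannot absorb a quadrupole, so
  this is the component that survives into the deviation map;
* **Gaussian radial noise** (σ, default 0 for single atria, 0.3 mm in
  cohorts) and optional **PV/LAA stubs**: cylinder-like outward protrusions
  (height 15 mm, plateau core with an 8° raised-cosine edge) that exercise
  the >10 mm exclusion rule.

Landmarks (4 PV ostia posteriorly, LAA anterolaterally, inferior reference
below the pole) are emitted consistently with the frame the bumps were
painted in.

**Fit-adjusted ground truth.**  The best-fit sphere absorbs the monopole
(mean inflation) and dipole (translation-like) parts of any radial
deformation, so raw bump amplitudes are *not* what the pipeline should
recover.  The generator predicts the sphere the fit will settle on — linear
monopole+dipole projection polished to the weighted orthogonal
least-squares fixed point (the linearisation alone underestimates the
radius by O(|centre shift|²/AR) once the dipole is strong) — and recomputes
deviations, frame and segment labels around that predicted centre, because
segment means are sensitive to boundary migration.  This truth is accurate
to ≲0.1 mm for per-segment amplitudes within about ±5 mm under 0.3 mm
noise (the regime of the recovery tests); in the extreme-severity tail of
the cohort distribution the truth-vs-pipeline gap can reach ~1 mm (area
weighting on the deformed mesh and higher-order fit nonlinearity), so
tests assert tight agreement only inside the validated regime.

**Cohorts.**  Each patient draws a latent remodeling severity
s ~ Gamma(4, 1/4) (mean 1, SD 0.5) that scales the whole deformation field:
elongation s·(4 ± 0.8) mm and bump profile s·((−2, −2, −4, +3, +3, 0) ± 0.8)
mm, base radius 32 ± 4 mm.  Per-segment low-voltage labels are
Bernoulli(logistic(−1.5 + 2.0·|D_seg|)) on the *fit-adjusted* deviation —
the deformation the pipeline can observe — independently across segments
given the deformations.  The severity factor is what couples deformation to
the label count, mirroring the clinical picture that more remodeled atria
carry more fibrotic substrate.  The resulting cohorts show inward roof and
posterior walls, outward inferior and lateral walls, a near-neutral septum,
per-segment label prevalences of roughly 0.3–0.5 and counts spanning 0–6.
The generator reproduces the *sign structure and association direction* of
remodeled cohorts; it does not target any published segment-mean magnitudes,
and clinical covariates, wall thickness, CT noise and real PV anatomy are
all outside its scope — passing tests certify the measurement chain and the
statistics, not anatomical realism.

All randomness derives from one master seed through
`numpy.random.SeedSequence` with the patient index as spawn key: adding a
patient never perturbs earlier patients, and the same seed is bitwise
reproducible.

**Fast path for calibration studies.**  The type-I-error and power
properties of the association analysis need tens of thousands of synthetic
patients (1000 null cohorts of 24; 200 effect cohorts of 100).  For these,
`generate_cohort(..., meshes=False)` emits the metrics table directly from
the generator's fit-adjusted truth — the properties concern the
deformation → label → statistics chain, and the mesh stage is exercised
separately by the geometry tests.  Measured at the defaults: type-I
rejection ≈ 0.04–0.05 (within binomial 99% bounds of 0.05), lateral-wall
power 100%.

## Numerical choices and edge cases

* Vertices closer than 1e-9 mm are merged on load (STL duplicates vertices
  per facet); degenerate zero-area faces are dropped; inverted winding is
  repaired by flipping all faces once when the signed volume is negative.
* Non-watertight meshes load with a warning; volume operations refuse them.
* Plane fitting is total least squares via SVD; collinear inputs (second
  singular value ≤ 1e-12 of the first) are rejected.
* The algebraic sphere fit solves the linear system from expanding
  |p − c|² = r²; coplanar inputs are rejected by a rank check.
* Ties in Spearman use average ranks; the exact permutation p includes the
  observed permutation (never returns 0).
* Paired t with zero-variance nonzero differences raises (degenerate);
  all-zero differences return t = 0, p = 1.
* Signed-rank Wilcoxon drops zero differences and raises if none remain.
* The per-segment D of an empty segment is NaN (missing), with a warning.
* Problem sizes in the default test run — icosphere subdivisions 3–4,
  cohorts of 4–100 patients, 100-atrium recovery studies, 1000 + 200
  calibration cohorts on the fast path — were chosen so the full suite and
  the acceptance script each complete in a few minutes on one CPU.

## Known limitations

* Segment boundaries are a configuration convention; absolute segmental
  values are only comparable under a fixed `BandConfig`.
* LAV is the volume of the supplied closed mesh, nothing more; PV/LAA
  trimming conventions upstream change it.
* The ICP and algebraic sphere fits agree exactly only on zero-residual
  data; on noisy surfaces they differ at O(σ²/AR), far below anatomical
  effect sizes but visible at strict tolerances.
* The exclusion rule removes outward protrusions only (default); inward
  artifacts (e.g. over-segmented mitral funnel) are not detected.
* The generator's deformations are radial displacement fields; real
  remodeling also bends and thickens the wall, which no radial field
  represents.
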