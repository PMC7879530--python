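# Methods

## Measurement model

The package evaluates a plan/post-operative pair of distal-radius surface
models through three named articular reference points — the radial styloid
process (P₁) and the volar (P₂) and dorsal (P₃) edges of the sigmoid notch —
plus one auxiliary frame landmark (the base of the sigmoid notch). All
coordinates are millimetres.

**Anatomical frame.** Measurements are expressed in a right-handed frame
derived from the *preoperative plan* model only: y = long axis of the radius
(proximal +), z = projection of the notch-base → styloid line onto the plane
⊥ y (radial +), x = y × z (palmar +), origin at the intersection of the long
axis with the distal articular surface. Using the plan frame for both states
means the post-operative triad is judged in exactly the coordinates the plan
was drawn in; no second frame is derived from the (possibly imperfectly
reduced) post-operative anatomy.

The long axis is fitted on the intact shaft: the vertex cloud's principal
direction initialises the axis, the shaft band (default the 35%–95% fraction
of the extent toward the proximal end) is cut into 25 cross-sections, and a
least-squares line through the section centroids is iterated to convergence
(<1e-8 rad). The proximal sign is resolved by metaphyseal flare: the end
quarter with the larger near-maximum cross-sectional radius is distal. For a
shape without a flare the sign falls back to a deterministic convention, and
callers can pass an explicit proximal hint. The origin is the most distal
intersection of the axis line with the surface (vectorised Möller–Trumbore
over all faces).

**Side convention.** The palmar/proximal/radial-positive triple is
right-handed only for a right wrist. Left-sided input is reflected across
the plane through the origin perpendicular to the raw radial direction
before the frame is built; the mirror plane is stored on the frame and
applied inside every world→frame conversion, so left and right wrists yield
sign-compatible metrics.

**Registration.** The post-operative scene is registered onto the plan scene
using only vertices of the intact proximal shaft (frame y ≥ cutoff, default
20 mm). The solver is trimmed point-to-point ICP: nearest-neighbour
correspondences (scipy cKDTree), the worst 10% dropped, closed-form SVD
(Kabsch) inner solve with determinant correction, stop when the trimmed RMS
changes by <1e-6 mm (max 200 iterations; non-convergence is flagged, never
silently accepted). Initialisation is centroid + principal-axes alignment
with the four-fold eigenvector sign ambiguity resolved by nearest-neighbour
RMS. This initialisation matters: with a plain identity start, ICP between
two identically sampled surfaces can settle into a sampling-aligned local
minimum one angular grid step (~6.5°) off about the shaft axis.

**Metrics.** With both triads in the plan frame: dᵢ = ‖Pᵢᵖˡᵃⁿ − Pᵢᵖᵒˢᵗ‖,
d_bary = distance between triangle centroids, plane area =
½‖(P₂−P₁)×(P₃−P₁)‖, volar tilt = arctan((y₂−y₃)/|x₂−x₃|) (sagittal
projection; positive when the dorsal edge is more distal, i.e. normal palmar
tilt), radial inclination = arctan((y₂−y₁)/|z₁−z₂|) (coronal projection;
positive when the styloid is more distal). The angle sign conventions are
fixed so that anatomically normal wrists score positive on both; the
projection-plane reading of "a line perpendicular to the longitudinal axis"
is the standard radiographic interpretation and is used throughout. Both
angles are measured from reference-point lines, not from fitted articular
surfaces.

## Statistics

- Shapiro–Wilk per metric (delegated to scipy; n must be 3–5000 and
  non-constant).
- One-way within-subject RM-ANOVA over (d₁, d₂, d₃, d_bary): classical
  sums-of-squares decomposition, F = MS_cond/MS_error with df (k−1),
  (k−1)(n−1). Whether the barycenter distance belongs in the same family as
  the three vertex distances is a design choice; analysing all four together
  with post-hoc contrasts directly supports the barycenter-vs-vertex
  comparison of interest.
- Post-hoc: all pairwise paired-t contrasts, Holm-corrected by default
  (Bonferroni available).
- Plane area: two-sided paired t (post vs plan).
- ICC: Shrout–Fleiss single-measure forms computed from the two-way mean
  squares — ICC(1,1), ICC(2,1) absolute agreement, ICC(3,1) consistency —
  with F-based p-values and 95% CIs (Satterthwaite approximation for
  ICC(2,1)). The selected default is ICC(2,1): plan-vs-outcome agreement is
  an absolute-agreement question. All three forms are always reported.
  Degenerate variance structures (e.g. a zero-noise cohort) surface as
  explicit diagnostics rather than numbers.
- α = 0.05, two-sided, throughout.

## Synthetic cohorts

The generator replaces patient CT data and defines the validation conditions.

**Template.** Fixed landmark coordinates chosen to satisfy simultaneously the
cohort-mean landmark magnitudes (‖P₁‖ ≈ 14.4, ‖P₂‖ ≈ 16.9, ‖P₃‖ ≈ 13.6 mm),
their anatomical octants (P₁ radial-dorsal-distal, P₂ ulnar-palmar-proximal,
P₃ ulnar-dorsal-proximal), and the articular angles (volar tilt ≈ 10.9°,
radial inclination ≈ 20.5°). Configurable tolerance bands are validated at
template construction; an unsatisfiable band raises an error naming it.

**Mesh.** A stylised bone, not a realistic radius: an elliptic shaft tube
along +y (semi-axes 9 × 11 mm) with a 0.85 proximal taper, a metaphyseal
flare to a 17.5 mm rim, and a distal articular cap built as a thin-plate
height field passing exactly through the origin, all landmarks, and the rim.
Only the properties the pipeline consumes are faithful: a well-defined long
axis (cross-section centroids exactly on y), an identifiable azimuth (the
ellipse breaks rotational symmetry) and polarity (the taper breaks
end-to-end symmetry — a uniform tube sampled on a uniform angular grid is
*exactly* self-congruent under a 180° flip, which trimmed ICP will happily
find), a cap through the origin, and landmarks on the surface (≤0.5 mm).

**Noise model.** Between-subject variation and plan-to-post reduction error
are iid per-axis Gaussian displacements of each landmark (σ_between = 1.6 mm,
matching the printed between-subject SDs of the landmark magnitudes;
σ_error = 2.0/1.5958 ≈ 1.253 mm). The error calibration uses the chi(3) law:
a per-axis σ gives mean displacement σ·2√(2/π), so the default reproduces
the ≈2 mm per-point error scale. An optional systematic offset models a
directional reduction bias and defaults to zero — the clinical data hint at
a small volar-tilt bias but do not constrain its direction, so none is
imposed. The same law predicts the barycenter advantage: the centroid of
three independently perturbed points has mean displacement smaller by 1/√3.
Each post-operative scene is finally moved by a random rigid transform
(rotation ≤15°, translation ≤10 mm, both uniform in magnitude, isotropic in
direction), recorded as ground truth. One rng seeded once drives the whole
cohort stream, so identical (config, seed) gives byte-identical output files.

**What the generator does not emulate** — and therefore what passing tests do
not show about real data: fracture fragments and comminution (displacement is
applied directly to reference points; the evaluation method never touches
fragments), realistic cortical geometry, segmentation error from CT,
correlated or anisotropic marking error, and observer variability in landmark
placement. In particular, real between-subject variation is strongly
correlated across landmarks (bone size and shape), whereas the generator
perturbs each landmark independently; σ_between is therefore calibrated to
the landmark-magnitude SDs, and the resulting per-case *angle* variance
(SD ≈ 10°) overstates the clinical one (≈5°). Cohort angle means and ICCs
consequently scatter more between seeds than a real cohort would. Conclusions about the *pipeline* (frame stability, registration
exactness on intact geometry, statistical calibration) transfer; conclusions
about clinical effect sizes do not.

## Numerical choices and scaled-down sizes

- Frame axes re-orthonormalised by SVD; orthonormality enforced to 1e-9,
  right-handedness det = +1 ± 1e-9.
- ICP: tol 1e-6 mm RMS change, max 200 iterations, trim fraction 0.1.
- Mesh resolution default 2 mm edge length (~2900 vertices), enough for
  sub-0.5 mm landmark-to-surface distance and exact registration recovery
  while keeping a 63-case cohort run in seconds.
- Validation sizes: 63-case cohorts (study size) for end-to-end runs; the
  multi-cohort statistical checks (100 cohorts) run at landmark level using
  the recorded ground-truth transform as an exact-registration surrogate,
  registration exactness being established separately (recovery to <1e-5 °
  and <1e-12 mm in 200 mesh trials).
- Degenerate inputs fail loudly with typed exceptions: collinear point sets,
  empty shaft bands, axes missing the surface, zero-variance statistics,
  landmark files with missing names (the error names the missing landmark).

## Known limitations

- Point-to-point ICP assumes near-congruent intact regions; it is not robust
  to large missing regions or to shafts shorter than the masked band.
- The ICC(2,1) confidence interval uses the standard Satterthwaite
  approximation; coverage is validated at n = 63 but will degrade for very
  small cohorts (a warning fires below n = 5).
- Ulnar variance, articular step-off and gap are out of scope: they are not
  functions of the three reference points.
- The stylised bone cannot probe how the frame responds to anatomical
  pathologies (severe dorsal comminution, pre-existing deformity).
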