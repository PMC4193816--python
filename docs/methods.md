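# Methods

This note documents the models, numerical choices and limitations behind
`aortacalc`, in the order data flows through the pipeline.

## The phantom: what it emulates and what it does not

The synthetic CT aorta is a constant-diameter blood-pool tube — a vertical
ascending cylinder, a toroidal arch lying in a vertical plane, and a vertical
descending cylinder — rasterized into an axial-slice HU grid (default
512×512 in-plane at 0.5 mm, 2.5 mm slices, matching a ~250 mm field of view
non-contrast cardiac acquisition). Defaults: lumen 40 HU (unenhanced blood),
background −100 HU (mediastinal fat) with optional Gaussian noise, arch
radius 30 mm, lumen diameter 30 mm (a per-part triple is accepted).
Calcifications are uniform-HU cuboids or ellipsoids placed tangent to the
lumen surface (wall calcium); cuboid faces are half-open so an extent of
k pixels rasterizes to exactly k voxel centres, which makes hand-computable
scoring examples exact.

Two deliberate departures from the obvious textbook values:

* **Background −100 HU, not 0.** The lumen-membership rule used by the
  tracker (±60 HU of the seed-patch median) needs lumen/background contrast
  larger than the tolerance; blood (40) against water-equivalent tissue (0)
  would be indistinguishable under that rule. Fat-dominated mediastinum is
  the realistic high-contrast neighbour of the aorta on non-contrast CT.
* **Noise is applied to background only.** Lumen and lesion voxels keep
  their nominal HU so that scores computed from the written volume equal the
  analytic per-lesion values exactly; boundary contrast — what the tracker
  actually depends on — is still noisy.

What the phantom does **not** model: aortic wall thickness (lumen only),
vessel taper, beam hardening, gating artifacts, the spine and ribs (a
synthetic distant blob stands in for them in the validation tests), and
anatomical tortuosity beyond the single-plane arch. Passing tests therefore
demonstrate correctness of the geometry/scoring machinery, not robustness to
every real-scan artifact.

The ground truth carries the exact parametric centerline (piecewise
line–arc–line), per-segment arc lengths, and per-lesion Agatston scores
computed by an independent per-voxel oracle (analytic containment mask →
threshold at 130 HU → per-slice area × density weight). The oracle shares
nothing with the detection pipeline except the volume itself.

## Centerline tracking

Cross-sections are measured by a maximal inscribed circle: the radius grows
in 0.25 mm steps while ≥ 95% of 72 perimeter samples stay lumen-like
(|HU − seed-patch median| ≤ 60), alternating with recentring to the centroid
of the lumen-like perimeter samples, until the centre moves < 0.05 mm (max
50 iterations). Two refinements resolve degeneracies of that classical
scheme:

* **Region-centroid recentring.** In an oblique cut of a tube the
  cross-section is elongated and the maximal inscribed circle is non-unique
  (it can slide along the long axis); iterated over planes this turns into a
  systematic drift. The centroid of the connected lumen-like region around
  the circle (capped at 3 radii) is the section centre of an elliptical cut
  and is therefore used as the final centre.
* **Half-maximum radius.** The grow-and-stop radius is quantized and biased
  by edge digitisation. The reported radius is the median over the 72 rays
  of the half-maximum edge crossing (profile midway between lumen reference
  and local outside value, sub-sampled at 0.05 px), the standard
  full-width-half-maximum convention of vessel sizing. On digital disks this
  recovers the radius to ~0.02 mm.

A seed is accepted only if its 5×5-patch median lies in (−50, 129) HU —
an unenhanced blood-pool plausibility gate that turns background seeds into
errors rather than runaway circles.

Tracking: axial slices are tracked downward from each seed (the descending
aorta from `C_D`, the ascending extension to the coronary ostium level from
`C_A`), each circle centre seeding the slice below. The arch is swept by
oblique planes whose normals advance in 2° steps from the axial direction at
`C_A` through 240° (121 planes, endpoint inclusive), rotating about the
horizontal axis through the seed midpoint. Each plane is positioned by
advancing the previous circle centre with the semitoroidal path increment
(initial major radius = half the seed chord); anchoring the sweep to the
found centres keeps the cut on the vessel even when the real arch is not a
torus centred on the seed midpoint. Where the sweep beyond 180° overlaps the
axial descending track, the point whose plane is more perpendicular to the
local tangent is kept (for a near-vertical descending aorta: the axial one).

The merged polyline then gets a perpendicularity correction: positions are
smoothed (5-point moving average), tangents estimated by arc-length-aware
finite differences, every cross-section re-resliced orthogonal to its
tangent and re-inscribed. Two passes are run — the first fixes positions
(hence tangents), the second re-measures diameters; further passes are a
no-op within tolerance. Re-inscription failures keep the prior estimate with
a warning. On noise-free phantoms at acquisition resolution this yields
median centerline error ~0.01 in-plane voxels (max ~0.5) and median diameter
error < 0.1 voxel; the residual worst-case diameter error (~1 voxel) comes
from axial partial volume in oblique sections, not from the correction.

Oblique reslicing itself is plain trilinear interpolation on a centred
square window (default 80 mm at the in-plane voxel pitch); out-of-grid
positions read a −2000 HU sentinel. An axis-aligned window reproduces the
axial slice bit-exactly.

## Segments

Boundaries, proximal→distal: the LMCA projection (start), the seed-pair
axial level on the ascending limb (1|2), the RSA projection (2|3), the LSA
projection (3|4), the CS axial level projected onto the descending limb
(4|5), and the distal terminus. Landmarks project to the nearest centerline
point (ties → proximal; a > 5 cm distance warns). Intervals are half-open and
closed proximally, so an arc length exactly on a boundary belongs to the
distal segment. The 1|2 and 4|5 rules make segments 1 and 5 coincide with
standard cardiac-scan coverage, which is the operative definition of
"standard TAC" throughout. The ascending/descending limb split for
axial-level boundaries is at the arch apex (most superior point).

## Lesions

Candidates are 26-connected 3-D components of voxels ≥ 130 HU whose maximal
single-slice area is ≥ 1 mm² (the classical operational minimum). A 3-D
component definition avoids counting one plaque once per slice; reported
lesion counts are therefore 3-D object counts. Manual per-slice validation
is replaced by a geometric surrogate: accept a candidate iff its centroid
lies within 1.5 × the local lumen radius of the centerline (configurable);
this keeps wall calcium, including slightly off-wall centroids of large
plaques, and rejects vertebral/costal structures several centimetres away.
Scores use the classical Agatston rule — per-slice area × weight of the
slice peak HU (1: 130–199, 2: 200–299, 3: 300–399, 4: ≥ 400) — with no
slice-thickness rescaling: scores are reported on the native 2.5 mm slices,
as plain Agatston units. Segment assignment projects the lesion centroid to
the nearest centerline point and reads the segment at that arc length.

## Cohorts

`SubjectRecord`s carry sex, age, blood pressure, lipids, risk-factor flags,
a CAC score, and the five segment scores; standard TAC = s1+s5, extended
TAC = Σs1..s5. Groups: 1 — CAC=0 and extended TAC=0; 2 — CAC>0 or standard
TAC>0; 3 — CAC=0, standard TAC=0, extended TAC>0 (reclassification
candidates). The definitions are exhaustive and mutually exclusive.

The generator has two modes:

* **Stochastic** — independent per-segment Bernoulli positivity at the
  configured prevalences (defaults 4/12/42/55/31% for segments 1–5, 62% for
  CAC), an optional logistic age-dependence hook (default off, so marginal
  prevalences are exact targets), and log-normal positive scores
  (default μ=3.0, σ=1.6 on the log scale — median ≈ 20, heavy right tail,
  a realistic calcium-score shape). Covariates: age N(57, 9²), 77% male,
  risk-factor prevalences 49/82/54/9% (hypertension/hypercholesterolemia/
  smoking/diabetes), with blood pressure and lipids drawn consistently with
  their flags.
* **Exact-marginal** — a deterministic construction (by construction index,
  then shuffled with the seed) that reproduces a requested set of integer
  counts with equality: n=970 with 618 extended-positive, 296
  standard-positive (19 of them with no arch/ascending calcium), 598
  CAC-positive, 457 doubly positive, 211 calcium-free; per-segment positive
  counts (39, 116, 407, 533, 296); extended-positive counts per age tertile
  (123, 209, 286); and per-group sex/risk-factor counts. Requested counts
  are validated against the full set of consistency inequalities and
  violations are reported by name. Percentages derived from this cohort are
  integer-exact, which is what the table-parity tests check.

Percent reporting uses nearest-integer rounding, half away from zero. Age
tertiles are defined by stable sort on (age, id) and a three-way split with
sizes differing by at most one, so ties cannot unbalance the tertiles.

Group comparisons: one-way ANOVA plus Tukey's HSD for age and risk;
chi-square over the 2×3 table plus pairwise 2×2 chi-squares with a
Bonferroni factor of 3 for categorical factors; α = 0.05. Degenerate tables
(an all-positive or all-negative column) and groups with < 2 subjects are
skipped with warnings rather than imputed. Missing covariates are errors by
design — the analysis assumes a complete-case cohort.

**Framingham risk.** The 10-year risk uses the sex-specific continuous
Cox formulation of the Framingham general cardiovascular risk profile
(D'Agostino et al., Circulation 2008): log-transformed age, total
cholesterol, HDL and systolic pressure, indicator terms for smoking and
diabetes, `risk = 1 − S0^exp(LP − mean)`. This coefficient set was chosen
because it is fully continuous in the covariates the pipeline carries and
its published constants are embedded verbatim with their baseline survivals
(0.88936 men / 0.95012 women). Lipids are converted from mmol/l at
38.67 mg/dL per mmol/l. Tests pin determinism, strict age monotonicity, and
two reference values frozen from an independent hand implementation of the
same table.

## Problem sizes and tolerances

The validation suite runs the full 512×512×80 grid once (centerline
fidelity), 256×256×80 grids for the ≥ 100-lesion oracle-equality check, and
coarser 128×128×64 / 1 mm grids elsewhere; these sizes were chosen as the
smallest grids on which each property is meaningfully exercised at
acquisition-like resolution. Accuracy bands: centerline error median
< 0.5 and max < 1 in-plane voxel, diameter error (median) < 1 voxel, total
length within 2% — all on noise-free phantoms; with 20 HU background noise
the median error bound relaxes to one voxel. Score equality between the
pipeline and the per-voxel oracle is exact (no tolerance): both routes sum
identical exact products of integer counts, binary-exact pixel areas and
integer weights. ANOVA type-I error is checked over 1000 null simulations
against the [3%, 7%] band around the nominal 5%.

## Known limitations

* The lumen-membership and seed-plausibility windows are tuned for
  non-contrast blood-pool/fat contrast; low-contrast soft-tissue abutment
  (e.g. pulmonary artery walls) is not modelled and would need the HU
  tolerance lowered.
* Diameters in near-isotropic directions are sub-voxel accurate, but
  sections cut obliquely through 2.5 mm slices inherit axial partial-volume
  blur; worst-case diameter error is about one in-plane voxel.
* Cross-sections at the very ends of the tracked range (volume or vessel
  boundary) are clipped by the grid and their re-measured positions/diameters
  are less reliable; terminal points are kept but flagged by warnings when
  re-inscription fails.
* The per-cm lesion densities depend on segment lengths, which for real
  anatomies vary per subject; on phantoms they are validated as ratios only.
* The exact-marginal cohort reproduces marginal counts, not the full joint
  distribution of a real population; score magnitudes and covariate
  correlations beyond the constructed ones are synthetic.
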