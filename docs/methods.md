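# Methods

`ufib` implements an along-tract ("tractometry") analysis of short-ranged
superficial white-matter fibres — "U"-fibres — comparing a patient group
against controls. This note documents the models, the parameters that
matter, the synthetic data the package validates itself on, and the
numerical choices made where the design was genuinely open.

## The analysis model

### U-shape identification

A streamline is an ordered polyline in world millimetres (RAS). Writing
L for its arc length (sum of segment lengths) and d for the Euclidean
distance between its endpoints, a streamline is classified U-shaped when

    20 mm <= L <= 80 mm   and   d / L <= 1/3 .

The chord-to-arc ratio d/L captures trajectories that hook back on
themselves, as association fibres do when they pass under a sulcus to
connect adjacent gyri; a straight fibre has d/L = 1, a semicircle 2/pi ≈
0.637, and a 270° circular arc ≈ 0.300. Both the length band and the
ratio bounds are configurable (`UShapeCriteria`); boundaries are
inclusive, and a lower ratio bound (default 0) is exposed so that
"band" interpretations of the criterion can be reproduced. For a
circular arc of angle θ the ratio is 2·sin(θ/2)/θ in closed form, which
the tests exploit.

### Template clustering by label propagation

Subject U-shaped streamlines are assigned to tracts of a labelled
template that shares the analysis space. The similarity measure is the
mean-direct-flip (MDF) distance: both streamlines are resampled to 20
equidistant nodes (piecewise-linear interpolation on cumulative arc
length — no spline, deterministic) and the mean node-wise Euclidean
distance is minimised over direct and reversed orientation. Each
streamline takes the label of the template tract whose *prototype* — the
member with minimal summed flip-invariant distance to all other members
(the medoid) — is nearest; an optional `max_dist` rejects outliers.
Distance to the prototype rather than the minimum over all members keeps
the assignment O(|template|) per streamline and independent of template
tract size. The winning orientation is stored so that node 1…20 means
the same anatomical position on every member, every subject.

All tie-breaks in the package (template distance, parcel assignment,
surface labelling) resolve to the lowest integer label, making results
independent of iteration order.

### Anatomical assignment and tract selection

Each terminal end of a streamline is mapped to the nearest non-background
parcel voxel centre within a 4 mm radius (unassigned beyond it). A tract's
two *nodes* are the two most frequent parcel labels over all terminal
ends of its members (2N votes for N streamlines; a single dominant label
gives a self-pair). A tract enters group analysis only when

* both nodes carry the requested lobe tag (default `frontal`),
* at least 5 streamlines are present in a subject for that subject to
  count as "having" the tract, and
* the fraction of subjects having it is >= 70% in the control group and
  >= 70% in the patient group.

All three thresholds are inclusive and configurable. Node assignment is
performed once on the template (template space = analysis space here);
per-subject reassignment would make tract identity subject-dependent.

### DTI scalars and profiling

From sorted tensor eigenvalues λ1 >= λ2 >= λ3 >= 0 (mm²/s):

    MD = (λ1+λ2+λ3)/3,  AD = λ1,  RD = (λ2+λ3)/2,
    FA = sqrt(3/2) · ||λ − MD|| / ||λ||  ∈ [0, 1].

Negative eigenvalues (noisy fits) are clipped to zero. Scalar volumes
are sampled by trilinear interpolation in voxel space after the inverse
affine; nodes outside the grid become missing rather than clamped, which
avoids edge-value bias for superficial tracts near cortex. A subject's
tract profile is the node-wise mean over flip-aligned, 20-node-resampled
members, excluding missing samples node-wise. Group statistics always
operate on subject-level profiles — subjects, never pooled streamlines,
are the replicates.

### Statistics

Two levels, both residualized for age and sex (one pooled OLS fit with
intercept; sex coded M=0, F=1; residuals of both groups from the same
fit):

*Density level.* Per-tract streamline counts: Bartlett's variance test
is reported, group means are compared with Welch's two-sided t-test
(always Welch — no data-dependent switching between pooled and unequal-
variance forms), and Benjamini–Hochberg FDR corrects across tracts. The
per-subject total count over analysed tracts gets a separate Welch test.

*Along-tract level.* Every (tract, node) cell is tested with Welch's t
(sign convention: statistic = control − patient, so positive t means the
metric is lower in patients). Family-wise error over all (tract × node)
tests of one metric is controlled by permutation: group labels are
permuted on the residuals (covariates held fixed — simpler than
Freedman–Lane and valid under exchangeability of residuals, a documented
approximation), the family minimum p is recorded per permutation, and
the adjusted threshold is the empirical α-quantile of that null min-p
distribution. The threshold therefore always lies between Bonferroni
(α/m) and the uncorrected α, adapting to the strong spatial correlation
between neighbouring nodes. Families are per metric (metrics are
reported separately), configurable. Min-p rather than max-|t| is the
family summary; the two coincide only under a common null distribution,
which node-wise Welch tests approximately satisfy after residualization.
When the number of distinct label assignments C(n, n₁) does not exceed
the requested repetitions, the permutation group is enumerated exactly.

Contiguous significant nodes merge into *segments* (minimum run length 1
by default). Segment means per patient feed Pearson correlations with
clinical (PANSS-8 total/positive/negative, CGI-S, SOFAS, DUP, age of
onset) and cognitive (TMT-B time and errors, category fluency) scores,
pairwise-complete, with BH correction across the whole correlation
family. Metric/tract cells with no significant segment are simply absent
from the correlation table.

*Surface mapping.* Each analysed tract contributes its two terminal-end
centroids (means of first/last member points, orientation-aligned);
every surface vertex takes the label of the nearest centroid.

### Key defaults

| parameter | default | meaning |
|---|---|---|
| `min_length`, `max_length` | 20, 80 mm | U-shape length band |
| `max_endpoint_ratio` | 1/3 | chord/arc upper bound |
| `parcel_radius` | 4 mm | endpoint-to-parcel search radius |
| `min_streamlines` | 5 | per-subject tract presence floor |
| `presence` | 0.70 | per-group presence fraction |
| `n_perm` | 10 000 | permutation repetitions |
| `alpha` | 0.05 | family-wise level (`fdr_q` likewise 0.05) |
| nodes | 20 | along-tract sample count |

## The synthetic cohort generator

The generator (`ufib.synth`) produces everything the pipeline consumes —
template TCK + label table, parcellation NIfTI + lookup, per-subject TCK
and FA/RD/AD/MD NIfTI volumes, cohort TSV, surface vertices — plus a
truth manifest recording each streamline's generating bundle, the
affected bundle ids, the affected node window, and every derived seed.
All generation is a pure function of (config, master seed).

*Geometry.* Bundle cores are circular arcs of 270–300° with radii
8–14 mm, placed by rejection sampling so cores stay >= 10 mm apart. Arcs
give closed-form control of the selection criterion (chord/arc =
2·sin(θ/2)/θ <= 1/3 requires θ over ≈ 262°, and arc lengths stay inside
20–80 mm for these radii) — every core is U-shaped by construction, while
straight-line distractors (ratio ≈ 1) and short arcs (< 20 mm) are not.
Template members add a small rigid offset (SD 0.4 mm) and point noise
(SD 0.1 mm) to the core; subject streamlines copy random template
members with 0.3 mm point noise and one 0.5 mm rigid offset per subject.
Polyline points are spaced 3 mm apart: with jagged per-point noise,
denser sampling would systematically inflate measured arc length (each
segment gains ~noise²/segment-length), pushing bundles out of the length
band; at 3 mm spacing the inflation is ~3% and harmless.

*Fields.* 2 mm isotropic grids (48³ by default). Tissue is modelled as
axially symmetric tensors: axial diffusivity fixed (1.7×10⁻³ mm²/s in
bundle tubes of radius 3 mm, 1.0×10⁻³ in background), radial eigenvalue
solved in closed form so FA hits its target (0.45 tube, 0.20 background),
MD = (AD + 2·RD)/3 — the four maps are mutually consistent.
Between-subject variation is a global multiplicative FA factor (SD 3%,
with a −0.002/year age slope and +0.01 sex offset so residualization has
something real to remove), RD scaled inversely, and an independent AD
factor (SD 2%).

*Injected effect.* Patients multiply FA by 1 − δ·g(s) and divide RD by
the same factor inside affected bundles, where g is a Gaussian window in
arc fraction s (centre 0.5, SD 0.08 — FWHM covers nodes 9–12 of 20) and
δ defaults to 0.15 with 15% per-patient variability; AD is untouched.
This reproduces the qualitative FA-down/RD-up/AD-null microstructural
pattern the analysis is designed to detect, with the mid-tract locus
near the sulcal bend. Per-patient effect size can optionally be
correlated with the PANSS-8 total (`clinical_effect_r`) to create a
recoverable clinical association.

*Clinical scores.* Patients draw PANSS-like positively shifted scores
(total ≈ 20 ± 6 on the 8–48 range), CGI-S ≈ 4, SOFAS ≈ 55, log-normal
DUP, age-of-onset consistent with age and DUP; controls sit at floor
values (PANSS-8 = 8, CGI-S = 1) with DUP/onset missing, exercising the
pairwise-complete handling.

*What the generator does not emulate* — and hence what passing tests do
not show about real data: anatomically realistic gyral ribbons and
cortical folding, tensor estimation from DWI signal (fields are
piecewise-smooth tubes, not tensor fits), registration error between
template and subject, spatially varying noise, scanner effects, and
partial-volume structure beyond trilinear smoothing. The validation
demonstrates that the *procedure* is correct and calibrated, not that
any particular clinical effect exists.

## Numerical choices and degenerate inputs

* Consecutive duplicate points are dropped at load (zero-length segments
  break arc-length parameterization); streamlines reduced below two
  points are dropped with a logged count.
* TCK/TRK files store float32; round-trips are coordinate-preserving to
  ~1e-5 mm within ±100 mm of the origin.
* Residualization uses `lstsq`; a rank-deficient design raises an error
  naming a collinear column. Tests with fewer than two valid subjects in
  a group yield p = NaN and are treated as non-significant.
* Missing (subject, tract) profile entries (below the 5-streamline
  floor) stay NaN and are excluded pairwise; they are never zero-filled.
* Zero-variance samples make Bartlett's statistic undefined; the density
  table reports NaN for that cell and Welch still runs.
* The permutation null is sampled with replacement from the permutation
  group unless exhaustive enumeration is cheaper; a fixed seed makes the
  procedure bit-reproducible, and every pipeline rerun with the same
  config and seed reproduces all output tables byte-identically.

## Problem sizes used in validation

The package's own test suite validates the permutation machinery on 200
null datasets of 20 + 20 subjects (5 tracts × 20 nodes, 1000 repetitions
each) and effect recovery on 20 independently generated cohorts of
30 + 30 subjects at δ = 0.15 with 1000 repetitions — sizes chosen so the
full suite runs in minutes while leaving the Monte-Carlo error of the
calibration checks well inside their acceptance bands. The run-time
default stays at 10 000 repetitions.

## Known limitations

* Label permutation on residuals is approximate compared with
  Freedman–Lane when covariate effects are strong.
* The template is assumed already registered to the analysis space;
  no registration is performed.
* Weighted tractometry variants (e.g. Gaussian-along-core weighting),
  spline resampling, and curvature/torsion shape descriptors are out of
  scope.
* The endpoint-parcel vote treats every terminal end equally; tracts
  genuinely connecting more than two parcels are reduced to their two
  modal nodes.
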