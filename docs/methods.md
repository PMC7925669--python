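# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `dietmap`.

## Scope and inputs

The package starts where an image registration pipeline ends: it consumes
per-subject 3-D log-Jacobian determinant fields in a common consensus
space, a label atlas (integer segmentation plus a structure lookup) in the
same space, a subject design table, per-gene expression-energy volumes on
an expression-atlas grid, and gene-set collections in GMT format.
Registration, segmentation and raw image handling are out of scope; so are
live queries to expression or disease-gene databases — gene sets are
supplied as local GMT files.

Volumes travel as NIfTI-1 with an axis-aligned affine (0-based voxel
coordinates; world mapping from voxel size and origin). Missing expression
data uses the sentinel −1 and is carried as an explicit mask after read.
Transfer of binary masks between the MR and expression grids uses
nearest-neighbour resampling under a user-supplied affine (identity by
default); full nonlinear alignment between the two spaces is deliberately
not implemented, because the package's synthetic grids share one world
frame and real studies perform that alignment upstream.

## Morphometry models

At every brain-mask voxel the log-Jacobian is fitted by ordinary least
squares under two model families:

- **Factorial ANOVA** `logJ ~ diet * sex`, treatment-coded, 6 parameters
  for 3 diet groups × 2 sexes. Terms are tested with partial **Type-II**
  F statistics: each term's sum of squares is the RSS difference between
  nested models respecting marginality (diet given sex; sex given diet;
  interaction given both mains), divided by the full-model mean square
  with denominator df = n − 6. Type II was chosen because the design is
  near-balanced; the nested-RSS machinery makes a Type-III variant a
  small configuration change if ever needed.
- **Dose model** `logJ ~ fat_pct * sex` with dietary fat percentage
  continuous (10/45/60% kcal from fat), reporting slope and interaction
  t statistics, df = n − 4; designs without a sex column (dams) fit
  `logJ ~ fat_pct` with df = n − 2. Dam analyses use only the continuous
  model, offspring get both families.

Implementation is vectorised: one QR factorisation per design matrix,
applied to the subjects × voxels data matrix, so a 32³ study with 101
subjects fits in well under a second.

**Multiple comparisons.** Benjamini–Hochberg step-up q-values are computed
per statistical term, across brain-mask voxels only (background excluded),
and across structures for table statistics. The FDR family is per term
rather than pooled across terms, matching the separately thresholded
statistic maps the pipeline emits. Voxels with zero variance across
subjects are flagged degenerate, carry p = q = 1, and are excluded from
the FDR family so they cannot dilute it. BH uses the standard maximal-index
step-up; tied p-values share the adjusted value.

**Structure level.** Structure volumes are
V(s) = Σ_{v∈s} exp(logJ(v)) · voxel volume, which makes total brain volume
exactly the sum of structure volumes. Each structure gets the factorial
ANOVA plus Tukey HSD pairwise diet comparisons computed from the
studentized-range distribution using the factorial model's mean square and
residual df (raw diet-group means are compared; with the near-balanced
designs these coincide with least-squares means to within the noise
floor). Residual diagnostics per structure: a Kolmogorov–Smirnov test of
residuals standardized by the fitted sd against the standard normal (plain
KS, no Lilliefors correction — mildly conservative since the sd is
estimated), and the Breusch–Pagan LM test of squared residuals on the
model predictors. Both p-value families are BH-adjusted and the minimum q
per family is reported, mirroring how such checks are summarised.

## Region of interest and expression statistics

The ROI is defined from the diet F map either as voxels with q ≤ level
(default level 0.01 — the statistically defined object) or as the top
`level` fraction of mask voxels by statistic (the 0.65 fraction the
emulated study quotes as equivalent for its data). Ties at the top-fraction
cutoff are all included and reported. On synthetic data the two modes need
not agree, which is why the FDR mode is primary.

Per-gene preferential expression is the fold-change: mean expression
energy over non-missing ROI voxels divided by the mean over non-missing
brain voxels. Means rather than sums, so the statistic is invariant to
grid resolution. Genes with data on less than 20% of the brain are
excluded from every downstream universe. A spatially uniform gene has
fold-change exactly 1 by construction (the uniform case is detected and
pinned, so the identity survives floating-point summation order).

**Trajectory clustering.** Fold-change trajectories over the developmental
series are Z-scored per gene (mean 0, sd 1 across timepoints) and
clustered with squared-Euclidean k-means, k = 3 (the emulated analysis
reports three clusters; model selection for k is out of scope), ≥ 10
random restarts, best inertia kept. Genes with an incomplete trajectory,
with less than 5% fold-change deviation at every timepoint, or with zero
across-time variance are excluded (each with a reason flag). Cluster ids
are relabelled canonically — sorted by time of centroid peak, ties broken
by time of centroid trough — so a fixed seed yields identical labels
across runs and machines.

**Gene-set tests.** Two schemes:

1. *Mean fold-change permutation.* Observed statistic = mean fold-change
   of a set's members within the universe. The null randomises the
   association between sets and genes: each of n_perm (default 10,000)
   iterations relabels the fold-change vector over the universe once and
   rescores every set, preserving the between-set dependence structure.
   One-sided (greater) p with the add-one convention
   p = (1 + #{null ≥ obs}) / (1 + n_perm), so p is never 0 and the
   smallest attainable value is 1/(n_perm + 1). Sets with fewer than 15
   universe members are excluded before Bonferroni correction over the
   tested sets. The one-sided alternative matches the directional claim
   the test is built for (higher preferential expression in the ROI).
2. *Top-N over-representation.* The top 4000 genes by fold-change form
   the foreground; each set gets the one-sided hypergeometric tail of its
   overlap against the full universe as background, with BH-FDR across
   sets. This is a standard ranked-list over-representation test standing
   in for an external web tool's minimum-hypergeometric statistic — a
   deliberate methodological substitution, exact and dependency-free; the
   mHG statistic itself is out of scope.

A third, subject-level permutation mode reruns a caller-supplied pipeline
(voxelwise F → ROI → fold-change → set statistic) under shuffled diet
labels (diet and fat% move together; sex stays attached to its subject,
i.e. plain label shuffling without stratification), with per-permutation
failures retried on the next seed substream and counted.

## The synthetic-data generator

The generator exists so that every stage has a recovery test against known
truth. What it emulates, and its defaults:

- **Atlas**: contiguous cubic structures (≥ 8 voxels) packed into a
  background grid; default 32³ voxels at 0.04 mm (the emulated study's MR
  resolution), 12 structures with mouse-brain names.
- **Cohort**: the printed scan counts — offspring 17F/17M, 17F/17M,
  17F/16M across LF10/HF45/HF60 (101 scans) and 8 dams per group
  (24 scans, no sex column), with offspring assigned to same-diet dams.
  The dam id is generated but deliberately not used as a model term,
  matching the voxel models (diet, sex, interaction only); a dam-level
  random offset (default 0) exists for sensitivity experiments.
- **Determinant fields**: voxel value = planted group effect for the
  subject's diet×sex cell in that structure, plus a subject-level offset
  ~ N(0, 0.02), plus independent voxel noise ~ N(0, 0.05), all additive on
  the log scale (Gaussianity on logs is what the downstream ANOVA assumes
  and its KS diagnostic checks); outside-brain voxels are 0. The noise
  magnitudes are configuration, not claims about real data.
- **Default effect field**: a widespread high-fat enlargement, chosen to
  put the simulation in the same detection regime as the emulated study
  (whose ROI at 1% FDR spans 65% of brain voxels). Eight of twelve
  structures enlarge under high-fat diets, monotone in fat percentage
  (+2% at HF45); the basal forebrain and medial amygdala are anchored at
  the study's ~5% HF60 enlargement, the un-anchored structures at +7%, and
  the primary motor cortex shrinks (−3%/−4.5%), mirroring the reported
  negative dose correlation. A male-only high-fat offset of log(1.10) in
  the posterodorsal medial-amygdala subregion plants a diet-by-sex
  interaction confined to a subregion. Magnitudes were sized by an
  analytic noncentral-F power calculation at the self-consistent BH
  threshold (per-voxel power ≈ 0.9 at 1% FDR for the positive structures)
  so that the planted ROI is recoverable by design; the first-pass
  calculation that ignored group-spread dilution and the map-level
  correlation induced by the shared subject offset is documented as
  superseded.
- **Expression atlases**: per-gene positive expression with lognormal
  voxel noise on a grid defaulting to half the MR resolution (emulating
  the coarser expression-atlas grid and exercising mask resampling).
  Planted genes receive inside-ROI multipliers following three trajectory
  shapes over P4/P14/P28/P56 — low neonatal rising by the 3rd timepoint,
  high neonatal falling by the 3rd, high neonatal falling by the 2nd —
  with inflections pinned to the juvenile (P28) and pre-weaning (P14)
  timepoints. A stated fraction of unplanted genes (default 10%) gets
  random coverage below 20% to exercise the coverage filter, with exact
  counts by construction.
- **Gene sets**: one enriched set drawn from planted genes preferential in
  adulthood plus null sets drawn from the remainder; default 1 + 12 = 13
  sets of 20 (the emulated analysis tested 13 terms), with a warning for
  sets below the 15-member floor.

All four generators are bit-deterministic for a fixed seed.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: registration error and spatially correlated
residuals (noise is white within subject), realistic cortical geometry
(structures are blocks), intensity artefacts, non-Gaussian heavy-tailed
deformation noise, spatial autocorrelation of expression energy, homology
mapping of gene symbols, and any coupling between expression and anatomy
beyond the planted ROI preference. Recovery results certify the statistics
pipeline, not field performance on real images.

## Pipeline, seeding, provenance

`RunConfig` carries the analysis defaults (ROI FDR 0.01 / top fraction
0.65, coverage 0.2, k = 3, min fold-change 0.05, 10,000 permutations, top
4000 genes, 15-member floor) and a master seed. Each stochastic stage
derives its seed as a SHA-256 hash of (master seed, stage tag), so adding
a stage never perturbs another stage's randomness. Runs echo the effective
config, write per-stage logs with timings, and emit a manifest of output
content hashes; identical config + inputs reproduce all outputs
bit-identically. Stage failure halts the run and leaves a FAILED marker
beside the partial outputs. Exit codes: 0 success, 1 validation error,
2 runtime failure.

Sensitivity knobs mirroring the emulated study's robustness notes are
plain parameters: the top-fraction can be swept over 0.60–0.70 and the
top-N over 3000–5000 by rerunning with different config values.

## Test and acceptance problem sizes

The test suite and acceptance script run the generator at reduced scales
chosen to keep a laptop run in tens of seconds while preserving the
quantities of interest: 14³–16³ grids with 4–6 structures for calibration
and structure-recovery simulations (100 repetitions for structure ranking,
20 for null FDR calibration and for enriched-set detection at
n_perm = 999), the full 32³ / 101-subject default for ROI recovery, and
400–999 permutations where the permutation floor allows. The statistics
are size-invariant; only Monte-Carlo precision changes with scale.

## Known limitations

- No mixed-effects voxel models (litter effects are generated but not
  modelled), no longitudinal designs, no permutation-based cluster-extent
  inference.
- Tukey comparisons use raw group means with the factorial MSE; in
  strongly unbalanced designs least-squares means would differ.
- The KS normality check is conservative-biased (estimated sd, no
  Lilliefors correction).
- Nearest-neighbour mask transfer only; no nonlinear MR-to-expression
  alignment.
- The top-N over-representation test replaces, rather than reproduces, a
  minimum-hypergeometric ranked-list method.
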