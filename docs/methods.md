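# Methods

`lithmark` re-implements, as a tested pipeline over synthetic cohorts, the
discovery of a blood DNA-methylation signature separating excellent (ER)
from non-responders (NR) to lithium maintenance treatment in bipolar
disorder type 1, with partial responders (PR) used post hoc. This note
documents the statistical procedures, the design choices made where the
published description left the design open, the synthetic data model, and
what the tests do and do not establish.

## Pipeline

### CpG inclusion filter

A CpG enters the analysis only if it is covered by at least
`min_coverage` reads (default 5) in at least `min_fraction_per_group`
(default 0.80) of the samples of **each** response group, evaluated
separately on ER and NR. The comparison uses the exact fraction with
`>=` on both thresholds and no rounding of sample counts; PR samples are
excluded from the filter denominator in the primary analysis. Missing
methylation (zero coverage) is represented explicitly (NaN), never as 0,
because 0 is a valid methylation level. All internal coordinates are
1-based; conversion to 0-based half-open happens only when writing BED.

### DMR calling

The caller enforces the region criteria — at least 5 consecutive CpGs,
every adjacent gap strictly below 100 bp, coverage already guaranteed by
the upstream filter — with a documented, self-contained procedure rather
than a re-implementation of any particular external caller's internals:

1. **Pre-segmentation.** Maximal runs of CpGs whose adjacent gaps are all
   `< max_gap`; runs shorter than `min_cpg` are discarded.
2. **Recursive binary segmentation** of the per-CpG ER−NR mean-difference
   signal. A run with `>= 2*min_cpg` CpGs is split at the interior index
   maximizing |mean(left) − mean(right)|, provided the split increases the
   maximum absolute segment mean; ties break to the leftmost index for
   determinism. Terminal segments with `>= min_cpg` CpGs become candidates.
3. **Testing.** Each candidate is tested by a two-sided Mann–Whitney U on
   *per-sample region means* (mean over member CpGs with data). The unit
   of replication is the patient, not the CpG×sample cell, which respects
   within-sample correlation. Exact enumeration is used when both groups
   have ≤ 8 samples and there are no ties; otherwise the normal
   approximation with tie correction. A sample with no covered CpG in a
   region is dropped from that region's test with a warning.
4. **Multiplicity.** Benjamini–Hochberg across all candidates genome-wide
   (the FDR is controlled per region, matching how region-level FDRs are
   reported); regions with q < 0.05 are returned, sorted by coordinate,
   with `mean_diff = ER − NR` in percentage points (positive = ER
   hypermethylated).

Calibration: on null cohorts (no planted effects, 1,000 clusters) the
caller returns zero DMRs in ≥ 95% of replicate runs — the data-driven
split search inflates candidate extremity slightly, but the rank-based
test plus the BH step-up keeps the genome-wide false-call rate at the
nominal level in practice.

### Cell-type deconvolution

Each sample's ratios at marker CpGs are projected onto a reference
methylome matrix (default six blood types: CD4T, CD8T, B, NK, Mono,
Gran) by non-negative least squares, `min ||y − Pβ||², β ≥ 0`, with
missing markers dropped pairwise. β is *not* constrained to sum to one,
matching constrained-projection practice; a normalized view is reported
for interpretation. Marker matching requires an overlap of at least twice
the number of cell types. Group differences per cell type use Welch's
t-test. No public 450k reference is bundled; the reference is a
user-supplied or synthetic CSV.

### Confounder screen

Per-DMR mean methylation is standardized (odds ratios are per SD, making
the CI rule scale-free) and regressed on the ER/NR outcome by logistic
regression; DMRs with Wald p < 0.1 proceed. For each comedication
covariate — atypical antipsychotics, antidepressants, anticonvulsants,
number of psychotropic drugs (numeric), current lithium — a second model
adds that covariate **one at a time**; if the adjusted methylation OR
falls outside the 95% Wald CI of the crude OR, the DMR is excluded as
confounded. Covariates constant across the analysed samples are skipped
with a warning.

At n = 26, separation is common; separated or non-convergent fits fall
back to a Firth-type (Jeffreys-prior) penalized likelihood with a
logged flag. When the adjusted model required penalization, the crude CI
is re-derived under the same penalized likelihood before the comparison:
otherwise the rule fires on the estimator switch rather than on
confounding. Simulation shows the rule is conservative — with
independent medications it excludes ~2% of screened DMRs, and under
near-deterministic confounding its power plateaus around 80%, because
Firth-penalized Wald intervals at this sample size are intrinsically
wide. This ceiling is a property of the crude-vs-adjusted rule itself,
not of the implementation.

### Signature selection

For column-standardized X and y ∈ {−1, +1}, the first sparse PLS-DA
loading direction is w ∝ Xᵀy. Sparsity is Lasso-style soft-thresholding:
to keep k features, the threshold is the (k+1)-th largest |w|; survivors
shrink by it, the vector is renormalized to unit length, and scores are
t = Xw. The selected set therefore equals the top-k features by |Xᵀy|
(verified against the mixOmics reference implementation in the tests).

Model size grows one feature at a time along the |Xᵀy| ranking; at each
size the LOOCV-AUC is computed (AUC by the Mann–Whitney pair count, ties
½), and the final size is the smallest k attaining the trajectory
maximum. Two cross-validation modes exist:

* `fixed` (default): the selected set is named on all data; each
  leave-one-out fold refits only the loadings and the standardization.
  This evaluates pre-named combinations and carries selection optimism.
* `nested`: selection is re-run at the same k inside every fold; on null
  data this is unbiased, and the tests assert `nested ≤ fixed` on
  average.

Selection stability is the fraction of 1,000 group-stratified bootstrap
resamples (stratification preserves the 15/11 split, which unstratified
resampling can destroy) in which each feature is re-selected at the
final size. The reported operating point is the Youden-optimal threshold
on the LOOCV scores (a single sensitivity/specificity pair requires a
rule; Youden's J is the standard neutral choice). Everything is
deterministic under a fixed seed.

### Annotation and post-hoc

A DMR's location class is decided by its midpoint with precedence
Promoter-TSS > TTS > Exon > Intron > Intergenic. Windows default to
−1000..+100 bp of the TSS (strand-aware) and ±1000 bp of the TTS —
standard promoter-annotation defaults, configurable, since the class
names come without printed windows. The gene is the nearest qualifying
gene; intergenic DMRs carry none. The partial-responder post-hoc runs a
one-way ANOVA of each signature DMR across ER/PR/NR plus Tukey boxplot
summaries. Cohort description statistics use Mann–Whitney and Welch
t-tests for continuous variables, one-sided Fisher exact tests (in the
observed-enrichment direction) and Pearson chi-square without continuity
correction for binary ones, and a chi-square over the 1/2/≥3 table for
the psychotropic-drug count.

## Synthetic data model

The generator produces the study's design conditions: 15 ER / 11 NR /
14 PR; CpGs in clusters (5–15 CpGs, gaps 5–80 bp, cluster baselines
drawn from a bimodal Beta(0.4, 0.4)); per-sample expected methylation
formed as a Dirichlet cell-type mixture of reference profiles (blood-like
base composition, ~60% granulocytes); sequencing depth negative-binomial
around 30×; counts beta-binomial with overdispersion ρ = 0.05 (real
bisulfite data are overdispersed; FDR calibration against binomial noise
would be vacuously easy). Medications are drawn with group-dependent
log-odds reproducing the real cohort's direction: atypical antipsychotics
and anticonvulsants NR-enriched, current lithium strongly ER-enriched; a
`confounding` scalar scales all group deltas (0 = balanced).

Planted DMRs shift the ER−NR expectation by a configured effect (default
|effect| uniform on 3–16 pp, random sign), applied symmetrically
(ER +e/2, NR −e/2) with PR at the midpoint — reproducing the observed
PR-intermediate pattern as a testable property. Only clusters with
intermediate baseline methylation are eligible for planting, so the
shift is always representable without clipping: differential regions
live at partially methylated sites, not at fully (un)methylated ones.

The **feature-level generator** used for the screening and signature
experiments models region-mean methylation directly, with two
empirically grounded structural choices. First, per-region noise is
heterogeneous: each planted region's SD is backed out of its
(effect, single-region AUC) pair under a normal model,
σ = |effect| / (√2·Φ⁻¹(AUC)), giving 3–10 pp — the weak-effect region is
also the quietest. Second, a per-subject latent factor enters every
region with correlation ρ = 0.6, aligned with each planted region's
effect sign: co-selected regions covary within subjects (shared cell
composition and treatment biology), so combining regions improves
discrimination only gradually, which is exactly the pattern small-cohort
methylation classifiers show (a multi-region cross-validated AUC well
below the apparent single-region AUCs).

What the generator does **not** emulate: strand structure (sites are
destranded; CpG dyad merging is available but off by default, since no
merging procedure was described), SNP-confounded CpGs, read-level
artifacts, batch effects, and any real genome coordinates (the
annotation driver uses a synthetic gene set, labelled as such). Passing
tests therefore demonstrate internal statistical correctness and
calibration of the procedures, not performance on real SeqCap data.

## Numerical and operational choices

* Ties in the segmentation split search, in feature ranking and at the
  soft threshold break deterministically toward the lower index (with a
  warning at the threshold, where a tie has measure zero).
* Beta-binomial expectations are clipped to [1e-6, 1−1e-6] before
  drawing; a planted effect that would leave [0, 1] clips with a warning
  (the default planting scheme cannot trigger this).
* The pipeline's single seed fans out to per-stage seeds by CRC32 of
  `"{seed}:{stage}"`, so resuming a run never shifts random streams; all
  derived seeds are < 2³¹.
* Degenerate inputs: all-tied region values give p = 1; zero-variance
  features are dropped from the screen with a note; zero variance in
  both groups gives t = 0, p = 1 with a note; an empty post-filter
  matrix raises a dedicated error.
* Problem sizes in the test and acceptance suites (null calibration at
  1,000 clusters × 20 replicates, recovery at 200 clusters × 5 cohorts,
  500–1,000 screened features, 20 signature replicates at B = 1,000)
  were chosen to give stable Monte-Carlo estimates at interactive
  runtimes.

## Known limitations

* The crude-vs-adjusted OR rule's detection power saturates near 80%
  under even near-deterministic confounding at n = 26 (wide penalized
  Wald intervals); its false-exclusion rate is correspondingly low.
* In the stability-recovery experiment, the probability that **all**
  seven planted regions (including the weakest, d ≈ 1.1) land in the
  SSF top-10 simultaneously is ~0.6–0.75 per replicate: at n = 26 a
  genuinely informative region realizes a sample separation below the
  top null order statistics with non-trivial probability. This is a
  statement about small-cohort stability selection itself, and mirrors
  the modest published stability frequencies (13–51%).
* With strong planted count-level effects (≥ 12 pp at 30×), the LOOCV
  trajectory saturates at AUC 1.0 within a few features; gradual
  trajectories arise only under correlated, selection-inflated
  region noise, as modelled by the feature-level generator.
* The segmentation is a deliberate simplification implementing the
  printed region criteria; it does not reproduce any external caller's
  pre-scoring or circular segmentation, and region boundaries can differ
  from such tools on the same data.
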