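# lithmark

Discovery pipeline for a blood DNA-methylation signature of lithium
response in bipolar disorder type 1: from per-CpG bisulfite read counts
to a sparse, cross-validated multi-region classifier separating
excellent responders (ER, Alda total ≥ 7) from non-responders (NR,
Alda ≤ 3), with partial responders (PR) examined post hoc.

It is written for methylation researchers who want a self-contained,
testable version of this analysis style — targeted bisulfite sequencing
of a small, deeply phenotyped cohort — with every stage exposed as a
library function, a ground-truth synthetic cohort generator to validate
against, and end-to-end drivers.

## The analysis

Given methylated/total read counts *m₍ᵢⱼ₎ ≤ n₍ᵢⱼ₎* per CpG *i* and
sample *j*:

1. **Coverage filter** — keep CpGs with ≥ 5× coverage in ≥ 80% of the
   samples of each group; methylation ratio β₍ᵢⱼ₎ = m₍ᵢⱼ₎/n₍ᵢⱼ₎.
2. **DMR calling** — chain CpGs with gaps < 100 bp into runs of ≥ 5,
   recursively segment the per-CpG group mean-difference signal, test
   each candidate region by a two-sided Mann–Whitney U on per-sample
   region means, and control the FDR across all candidates by
   Benjamini–Hochberg (report q < 0.05; Δ = ER − NR in percentage
   points).
3. **Cell-type check** — estimate blood cell proportions per sample by
   non-negative least squares against a marker reference
   (min‖y − Pβ‖², β ≥ 0) and compare groups per cell type (Welch t).
4. **Confounder screen** — logistic regression of response on each
   DMR's standardized mean methylation (keep p < 0.1), then exclude any
   DMR whose medication-adjusted odds ratio falls outside the 95% CI of
   its crude OR (one covariate at a time: atypical antipsychotics,
   antidepressants, anticonvulsants, drug count, current lithium), with
   a Firth-penalized fallback under separation.
5. **Signature** — sparse PLS-DA first component (w ∝ Xᵀy,
   soft-thresholded to keepX features, unit norm); expand the panel one
   feature at a time and pick the smallest size maximizing the
   leave-one-out cross-validated AUC; assess stability as each
   feature's selection frequency over 1,000 group-stratified bootstrap
   resamples (SSF); report sensitivity/specificity at the
   Youden-optimal LOOCV threshold.
6. **Post-hoc** — genomic location classes (Promoter-TSS / TTS / Exon /
   Intron / Intergenic), one-way ANOVA of signature DMRs across
   ER/PR/NR, and cohort-description statistics (Mann–Whitney, Welch,
   one-sided Fisher, chi-square).

Because no patient-level data are public, the package ships a
first-class synthetic cohort generator (`lithmark.simulate`) that
reproduces the study's design: 15/11/14 cohort, clustered CpGs,
beta-binomial counts, cell-type mixtures, planted DMRs at the published
effect scale, and medications confounded with response. Every
downstream stage is tested against its planted ground truth; see
`docs/methods.md` for the model and its limits.

## Worked example

The numbered drivers under `analysis/` run the full discovery funnel on
a simulated cohort (seed 0), writing tables under `results/`:

```bash
python analysis/01_simulate_cohort.py      # cohort + reference + truth
python analysis/02_filter_and_ratios.py
python analysis/03_call_dmrs.py
python analysis/04_deconvolve_celltypes.py
python analysis/05_screen_confounders.py
python analysis/06_select_signature.py
python analysis/07_annotate_posthoc.py
python analysis/08_cohort_statistics.py
```

which prints, stage by stage:

```
cohort: 40 samples, 3704 CpGs (300 clusters + 600 markers), 20 planted DMRs -> results/data
coverage filter: 3704/3704 CpGs retained -> results/run/ratios.tsv
13 DMRs at FDR < 0.05 spanning 106 CpGs; 12/20 planted regions recovered (>= 50% overlap)
deconvolution RMSE vs truth: 0.0167; 1/6 cell types differ between groups at p < 0.05
funnel: 13 DMRs -> 13 at p < 0.1 -> 1 excluded as confounded -> 12 retained
signature: 1 DMRs ['DMR00006'], LOOCV-AUC 1.000, sensitivity 1.000, specificity 1.000
PR post-hoc: 1/1 signature DMRs with ANOVA p < 0.05; PR median intermediate for 1/1 DMRs
published margins: current Li one-sided Fisher p = 0.011, sex chi-square p = 0.95, anticonvulsants one-sided Fisher p = 0.17
```

Reading the output: the caller finds 13 significant regions — the
planted differences of 12–16 pp are recovered essentially always, while
those near the 3 pp end of the planted range are the ones it misses at
this depth. One region is dropped because adjusting for a medication
moves its odds ratio outside the crude CI. At these strong effect
sizes a single region already classifies the 26 samples perfectly under
LOOCV, so the stepwise search stops at one feature (its bootstrap
selection frequency is 0.85); the gradual multi-region trajectories
characteristic of weaker, correlated signals are exercised by the
feature-level experiments in the test suite. The final line recomputes
the three cohort statistics from the published contingency tables —
0.011, 0.95 and 0.17.

The same stages are scriptable via the `lithmark` CLI
(`simulate`, `filter`, `call-dmrs`, `deconvolve`, `screen`,
`select-signature`, `annotate`, `posthoc-pr`, `cohort-stats`, `run`) or
the `lithmark.pipeline.run_pipeline` orchestrator, which adds a
manifest, per-stage seeds and resumability.

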