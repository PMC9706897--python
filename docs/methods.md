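# Methods

## Differential methylation model

The pipeline treats methylation as a bounded per-CpG quantity: percent of
methylated reads for WGBS-style data, β in [0, 1] for array-style data.
Differential calling is deliberately simple, mirroring common practice for
small paired cohorts:

* **Paired t-test per site.** Two-sided, on tumor−normal differences
  within pairs. Sites whose paired differences have zero variance have an
  undefined t statistic; they are skipped (and counted in the log) rather
  than assigned p = 0. An unpaired Wilcoxon rank-sum mode exists for
  cohorts without pair structure.
* **Fold change** is the ratio of the larger group mean over the smaller,
  computed on the native scale with a pseudocount added to both means
  (1 percentage point for percent data, 0.01 for β) so fully unmethylated
  sites cannot divide by zero. Emission requires p < 0.05 AND FC ≥ 2.
  No multiple-testing correction is applied to the filter; a
  Benjamini–Hochberg FDR column is emitted for information.
* **Direction labels**: ESCC = hypermethylated in tumor, NC =
  hypermethylated in normal. Direction is a function of the group means,
  so no site can carry both labels.

## DMR chaining

Same-direction DMCs on one chromosome are chained greedily left to right:
the next DMC joins the open chain iff its gap to the previous member is
< 50 bp and the resulting span (last − first member position) stays
≤ 100 bp; otherwise the chain closes (emitted iff ≥ 3 members) and a new
chain starts at that DMC. There is no lookahead and no re-opening;
opposite-direction DMCs are invisible to a chain. Span is defined on
member cytosine positions; exported BED intervals are [first, last + 2) so
the final CpG dinucleotide is covered.

Consequence of the short span cap: a dense run can split. Six DMCs over
114 bp yield two regions at max_len = 100 and one at max_len = 300 — the
split-on-overflow behavior is intended, since the regions feed MSP
amplicon design where ~100 bp products are optimal. Note the greedy rule
means *larger* max_len can only merge chains, never create more of them;
windowing variants that re-seed chains differently can behave otherwise,
and no statistical p-value is attached to a region.

## Gene mapping and enrichment

A gene is a DMG for a direction iff ≥ 1 bp of a DMR of that direction
overlaps its gene-body interval (0-based half-open; strand ignored;
promoters/flanks are not added — users wanting flanks can pad the BED).
Genes hit by both directions are excluded from both lists, as
mixed-direction genes make poor single-direction markers. DMR genomic
location is classified by the region midpoint (inner-genic vs intergenic).

Family enrichment builds, per family, the 2×2 table {DMG, non-DMG
universe gene} × {in family, not in family}, where the universe is the
family table's declared background. The enrichment flag uses the
Yates-corrected chi-square p (< 0.05) together with an overrepresentation
requirement (in-family DMG proportion above background); the uncorrected
statistic is also reported, and a BH-FDR column is informational. Genes in
several families count in each independently.

## Risk score and ROC

Gene-level methylation is the unweighted mean over covered sites (missing
cells ignored; uncovered genes dropped and listed). The classifier is an
unpenalized maximum-likelihood logistic regression of tumor status on the
feature genes; under perfect separation — common at large planted effect
sizes — the fit falls back to an L2-penalized logistic regression
(penalty 1.0, recorded on the model). K-means subgrouping of marker genes
uses Euclidean distance with 10 restarts, labels renumbered by decreasing
cluster mean methylation so labellings are reproducible.

ROC thresholds sit at midpoints between consecutive distinct scores plus
±∞, with "positive" meaning score strictly greater than the threshold.
Trapezoid AUC over this curve equals the normalized Mann–Whitney
concordance with ties counted ½ (asserted to 1e-12 in tests); the 95% CI
uses DeLong's placement-based variance. The operating point maximizes the
Youden index, ties broken toward higher specificity. Stratified detection
rates use the strata × {positive, negative} chi-square; a single stratum
reports p as not applicable.

Rank tests (two-group comparisons) use the exact Mann–Whitney null when
both groups are ≤ 25 observations and tie-free; with ties, the normal
approximation with tie correction and no continuity correction, so that
identical group distributions give p = 1 exactly. More than two groups use
Kruskal–Wallis.

## Bisulfite/MSP model

Only the forward bisulfite strand is modelled: cytosines at methylated
offsets survive conversion, all other cytosines (including non-CpG
cytosines) read as T, and A/G/T are untouched. Calling from a converted
read is the inverse map restricted to CpG offsets (C → methylated, T →
unmethylated, anything else missing), so call∘convert recovers any
methylation mask exactly — a property the tests exercise in bulk.
Frequencies pool CpG-site × sample calls within a group (not per-sample
means), reported as percent rounded half-up to two decimals; group
comparisons use the Yates 2×2 chi-square, consistent with the enrichment
module.

## Synthetic methylome generator

The generator provides planted truth, not realism. Values follow a Beta
marginal at each site, parameterized by a mean and a shared concentration
(default 60, i.e. per-site SD ≈ 4.6 points at a 15% mean), sampled through
a Gaussian copula whose latent field is a stationary AR(1) along each
chromosome (default ρ = 0.7, chosen to reproduce the strong adjacent-CpG
correlation of real methylomes; the Beta transform attenuates the
realized Pearson r only mildly, ≈ 0.69 at ρ = 0.7). Defaults:

| parameter | default | meaning |
|---|---|---|
| `baseline_normal_mean` | 15% | background methylation of both groups |
| planted `delta` | caller-chosen, 30–40 pts | tumor−normal shift inside truth regions |
| `tumor_hypo_fraction` | 0 (0.02 in examples) | background sites given tumor hypomethylation |
| `hypo_delta` | 10 pts | size of the hypomethylation shift |
| `ar1_rho` | 0.7 | latent adjacent-site correlation |
| `concentration` | 60 | Beta precision (noise level) |
| `pair_effect_sd` | 2 pts | shared per-pair shift |
| `missing_rate` | 0 | NaN cells (array) / all-zero rows (WGBS) |

ESCC truth regions raise the tumor mean by delta; NC truth regions raise
the *normal* mean instead, so the signed difference is −delta without
clipping against 0 at low baselines. Because Beta quantile transforms of
uniform variates preserve the mean, the realized in-region tumor−normal
difference equals delta in expectation (checked within ±5 points at 9
pairs). The per-pair random effect shifts both members of a pair equally
and therefore cancels from paired differences.

Planted regions are chosen by `plant_dense_regions` as runs of consecutive
scaffold CpGs already satisfying the DMR gap/span rules, separated by
≥ 200 bp buffers — the benchmark measures whether the caller recovers
recoverable regions, not whether the rules themselves are achievable.

What the generator does **not** emulate: read-count/coverage noise and
beta-binomial overdispersion, CpG-island/shore structure, copy-number or
purity effects, batch effects, age-related drift, and realistic
chromosome-scale methylation domains. Passing the planted-truth tests
therefore shows the pipeline's logic is correct under its stated model,
not that the thresholds are well-calibrated for any particular real
cohort.

## Numerical and edge-case choices

* KNN imputation: plain Euclidean distance over mutually observed
  columns, donors must observe the target column, distance ties broken by
  row (coordinate) order, k = 10 by default and shrunk (with a log note)
  when fewer donors exist. A fully unobserved row is an error naming the
  row. Imputed values are donor means, hence always inside the donor
  range.
* Matrix rows are kept sorted by (chrom, pos); TSV round-trips are
  lossless to 10 significant digits.
* The WGBS "uncovered" convention is exact 0 in all samples; the array
  missingness filter removes rows missing in strictly more than 90% of
  samples (a row at exactly 90% is retained).
* Degenerate 2×2 tables (an empty margin) report statistic 0, p = 1
  instead of erroring.
* All simulation entry points take explicit integer seeds and are
  bit-reproducible for a fixed seed.

## Problem sizes

The shipped tests and the acceptance script run at desk scale: cohorts of
9–20 pairs over 4,000–10,000 CpGs, 1,000-instance DMR oracle sweeps, and
10,000 bisulfite round-trips — sizes where the exhaustive oracles
(per-site t formula, chain enumeration, quadratic interval scans,
concordance counts) remain practical while exercising every rule at
non-trivial density.

## Known limitations

* The DMR caller is rule-based; it attaches no significance measure and
  its greedy split points depend on scan order (leftmost-first).
* Fold change on near-zero means is pseudocount-sensitive.
* DeLong CIs are asymptotic and degenerate (zero-width) under perfect
  separation.
* The enrichment chi-square is approximate for very small families;
  Fisher's exact test is cross-checked in tests only where expected
  counts are large.
* Cross-validation of the risk score is not built in; evaluation is
  in-sample unless the user scores a held-out matrix.
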