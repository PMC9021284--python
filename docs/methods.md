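# Methods

## The comparison model

The unit of analysis is a patient-matched pair of single-sample germline
call sets: a frozen-tissue (FR) *reference* and a preserved-tissue (FFPE)
*query* from the same individual, called against the same reference genome.
Calls are keyed by genomic site `(contig, pos)` only; whether two calls "at
the same site" agree is decided on the concrete allele strings of the called
genotype. Matching by position rather than by position+alleles is an
assumption: two different records at one position are treated as competing
descriptions of the same locus, not as two loci.

No-call and homozygous-reference genotypes are excluded on input, as are
records failing FILTER (default: keep `PASS` or unset; configurable). Only
diploid genotypes are supported. Multi-allelic records are kept intact — the
called allele pair is resolved to allele strings, never split per-alt —
because the classification compares whole genotypes between samples, not
individual alternate alleles.

### Genotype quality

`GQ = second-smallest(PL) − smallest(PL)`, uncapped. Callers cap GQ at 99,
which collapses exactly the high-confidence right tail that separates
concordant from artifact calls; recomputing from PL removes the cap. When a
record carries GQ but no PL, the stored (possibly capped) value is used and
the record is flagged in the log; records with neither are dropped.

### Classification and precedence

At a shared site, precedence is: identical unordered allele pair →
`concordant`; differing zygosity → `zygosity_change` (even when the alleles
also differ — zygosity dominates because allelic dropout is the mechanism of
interest and it changes alleles as a side effect); same zygosity, different
alleles → `genotype_change`. Sites in one call set only are `unique`.
Phase is ignored throughout. A het genotype carrying two non-reference
alleles (1/2) is heterozygous like any other het and is compared as its
allele pair.

Transition labels are oriented query-relative-to-reference. An allele's
symbol is its substituted base for single-base substitutions, `INS`/`DEL`
for length-changing alleles, `MNV` for same-length multi-base replacements
and for genotypes with two distinct non-reference alleles.

REF strings at a shared site may legitimately differ in length (indel
records anchor differently); they are accepted when one is a prefix of the
other, which is exactly the condition for both to be substrings of one
reference genome at that position. Any other disagreement raises a
consistency error naming the site.

### Normalisation

Class counts are divided by the query sample's total SNP count, so
`concordant + unique_to_query + zygosity_change + genotype_change = 100%`.
The query side anchors the denominator because every class except
unique-to-reference is a statement about query calls; unique-to-reference
counts are reported separately, outside the 100% budget. Group-level values
are unweighted means of per-patient percentages.

### GQ curves and KS comparison

Pooled per-group GQ values are summarised as cumulative-percent curves
(percent of SNPs at or below each GQ). Scores above `max_gq = 300` are
excluded before curve construction — the comparison targets the bulk of the
distribution, not the extreme tail — but **not** from per-class GQ means,
which use the full range (their SDs exceed 300).

Two KS modes are exposed because "comparing the curves" is genuinely
ambiguous between two readings, and the choice is reported with every
result:

* `curve_values` (default): the two samples handed to the two-sided
  two-sample KS test are the cumulative-percent values of each curve on the
  shared integer grid 0..max_gq. This treats the curve itself as the object
  of comparison; its effective sample size is the grid size.
* `raw_scores`: the samples are the pooled GQ values themselves — the
  statistically conventional test, with p-values calibrated against the
  actual pooled n.

The KS p-value uses the exact small-sample null when feasible and the
asymptotic Kolmogorov distribution otherwise (scipy's `auto` policy).
No multiple-testing correction is applied across the KS matrix; its
p-values are reported raw.

### QC metric statistics

Metrics arrive as a tidy per-sample table (computing them from reads is out
of scope). The decision tree is fixed: Shapiro–Wilk per group and Levene
across groups are computed as an advisory screen (the designs are small and
frequently non-normal, so the inferential tests are nonparametric
regardless); two preservation groups → paired two-tailed Wilcoxon
signed-rank on patient-matched differences; three or more → Friedman on
complete patient blocks, and only if Friedman p < 0.05, all pairwise
signed-rank tests Holm-adjusted within that metric's family. Zero
differences are dropped and ties mid-ranked (standard conventions); the
exact signed-rank null is enumerated for n ≤ 25, the normal approximation
used above. Holm adjustment is step-down: sorted ascending,
`adj_i = max_{j≤i} min(1, (m−j+1)·p_j)`.

## The synthetic-data generator

The generator emulates the *statistical* structure of FFPE artifacts in
called genotypes, not their sequence biology. Per reference site exactly one
fate applies — dropped from the query, zygosity flip, genotype transition,
or kept concordant — then unique artifact calls are added at new sites.

Rate parameters (`p_unique_artifact`, `p_zygosity_change`,
`p_genotype_change`) are defined as fractions of the **query** call set, the
same denominator the analysis reports, and are converted internally to
per-shared-site probabilities (`q = p / (1 − p_unique_artifact)`); the
zygosity-flip probability is additionally conditioned on the reference
call's zygosity (`q_z·bias/h` for het sites, `q_z·(1−bias)/(1−h)` for hom,
with `h` the het fraction) so both the overall rate and the het→hom share
match their configured values in expectation. Configured rates are therefore
directly recoverable from classifier output, which is the basis of the
parameter-recovery tests.

Defaults are chosen to mirror the artifact structure reported for 12-h FFPE
DNA against frozen controls: unique fraction 0.609, zygosity change 0.022
with het→hom bias 0.9, genotype change 0.0003 dominated by INS/DEL
transitions (with T→A and A→G the leading substitutions), het fraction 0.65
and indel fraction 0.10 (typical of human germline call sets). GQ draws are
discretised gammas clipped to [0, 3000]: concordant `(shape 2.5, scale
120)` — mean 300, mode ≈ 180 — and artifact `(1.5, 8)` — mean 12; the
study-fixture group overrides reproduce the observed treated/untreated
contrasts (treated: unique ≈ 0.50, zygosity 0.038, artifact GQ mean ≈ 48).
Artifact GQ is uncapped so the 300-score exclusion rule is exercised.

PL vectors are constructed so the two smallest entries are exactly 0 and the
drawn GQ; round-tripping through VCF therefore reproduces every generative
GQ exactly. Sites live on four toy contigs with positions drawn without
replacement; all output is a pure function of `(config, patient_id,
sample_id)`, giving byte-identical VCFs across runs. In the study-shaped
fixture, one frozen reference per patient×tissue is shared by all of that
patient's FFPE groups, and 72-h groups exist only for the ovary arm.

What the generator does **not** model: read-level evidence, deamination
sequence context, coverage and mapping artifacts, tumor purity, linkage
between neighbouring sites, and population allele frequencies. Passing tests
therefore demonstrate that the *analysis* is correct and calibrated on data
with known artifact structure — not that real FFPE artifacts follow these
distributions.

Two generator edge cases are handled explicitly: a genotype-transition
target base is never the record's REF base (the result would be a reference
allele), and homozygous DEL→DEL transitions are excluded because both calls
would carry the identical anchor-base allele pair and be indistinguishable
from concordance at the string level.

## Numerical and reporting choices

* Sample SD uses the n−1 denominator; a single observation reports an
  absent SD, an empty class an n = 0 row.
* TSV floats are written with 6 decimals so repeated runs are
  byte-identical; the run manifest records config hash, seed and version.
* Curve grids are the distinct retained GQ values by default, or the dense
  integer grid 0..max_gq for cross-group alignment; curves end at exactly
  100.
* Degenerate inputs fail loudly: empty groups, zero denominators, all-zero
  difference vectors, incomplete patient blocks (named cell by cell), and
  infeasible simulator rate combinations are all errors, not warnings.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to make binomial
standard errors small relative to the configured rates: 1,000-site pairs
across 50 seeds for classifier/oracle agreement, 50,000-site pairs for rate
recovery (query n ≈ 87,000 puts 3 SE at ~0.17 percentage points for a 3%
class), pooled n = 10,000 per side for KS calibration (100 replicates), and
a 2-patient × 5,000-variant study fixture for end-to-end runs. The null
fixture for KS calibration uses a gamma `(2.5, 60)` GQ distribution lying
almost entirely inside the 0..300 analysis window, so the exclusion rule
does not shrink the nominal pooled size.

## Known limitations

* Position-only site matching cannot distinguish two genuinely different
  variants at one position from one re-represented variant; indel
  normalisation (left-alignment) is assumed to have been done by the caller.
* `curve_values` KS mode inherits its effective sample size from the grid,
  not from the data; treat its p-values as descriptive and prefer
  `raw_scores` when calibration matters.
* RNA call sets are handled as just another analyte label; no
  expression-dependent coverage modelling is attempted.
* The QC module assumes complete paired designs; unbalanced tables are
  rejected rather than analysed with mixed models.
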