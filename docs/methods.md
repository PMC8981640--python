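# Methods

## Problem setting

A lung-specific CUP patient contributes a pair of tumors: T1 intrathoracic
(lung) and T2 extrathoracic (stomach, colon/rectum, or cervix). The
package infers, per patient, (a) clonality — independent multiple
primaries vs one metastatic clone — and (b) the tissue of origin of a
metastatic clone. Inputs are *called* somatic alterations (panel-style
MAF-like tables or VCF) and *block-level* methylation beta values; variant
calling, bisulfite alignment and methylation calling are upstream of this
package.

## Shared-alteration matching

"Sharing" an alteration is the primitive the clonality rules rest on, and
panel reports do not make it precise, so the package fixes it as follows:
SNVs and small indels match on the exact genomic change (gene, chromosome,
1-based position, ref, alt); splice variants on the affected position
(gene, chromosome, position); rearrangements on the unordered gene pair
only, because reported breakpoints of the same fusion vary between samples;
copy-number events on (gene, direction). Duplicate records within one
profile are collapsed before matching (one biological event, one record),
so each alteration participates in at most one match and
|match(A,B)| = |match(B,A)| ≤ min(|A|,|B|) by construction. Allele
fractions are carried through I/O but play no role in the clonality call.

## The genomic decision cascade

Rules are evaluated strictly in order (zero-shared before the driver rule;
they cannot conflict, but the order pins behavior for future edits):

1. No shared alteration → multiple primaries (Class I). With a 520-gene
   panel the chance of two independent tumors sharing an identical variant
   is negligible, and conversely.
2. A shared actionable lung driver → metastatic, lung origin (Class I).
   The default whitelist is the standard actionable set — EGFR L858R,
   L861Q, G719A/C/S, S768I, T790M, any EGFR small indel (covering exon-19
   in-frame deletions and exon-20 insertions), and any rearrangement
   involving ALK or ROS1 — and is YAML-overridable; the source method
   names the gene classes but not an enumerated list.
3. Clonality criteria: (i) both tumors ≥ 5 alterations and ≥ 2 shared, or
   (ii) *at least one* tumor < 5 alterations and ≥ 1 shared. "Either
   tumor harbored < 5" is read inclusively (n1 < 5 or n2 < 5); the
   alternative reading ("exactly one") would change nothing for any
   reference patient. Failing both → relationship inconclusive.
4. Criteria met and interval ≥ 6 months (metachronous, ties at exactly 6
   count as metachronous) → metastatic from the organ of the
   earlier-detected tumor (Class II). Intervals are whole months; an
   interval ≥ 6 implies the detection months differ, so no tie-break is
   needed.
5. Criteria met, synchronous → metastatic, origin inconclusive
   (Class III).

Five distinct outcomes are surfaced (Class III and
relationship-inconclusive both route to methylation but are reported
separately). Microsatellite status is carried descriptively and never
influences the cascade.

## Methylation blocks and the MBS matrix

Neighboring CpGs are strongly co-methylated, so sites are aggregated
greedily left-to-right per chromosome: consecutive sites join a block
while the inter-site gap ≤ `max_gap` (default 500 bp); blocks with fewer
than `min_sites` (default 3) CpGs are dropped; the block value is the
arithmetic mean beta of its members. The aggregation rule is this
package's own concrete choice — the upstream assay literature defers
block construction to pipeline internals — and both knobs are exposed.
The samples × blocks matrix ("MBS") is the classifier input.

## Binary TOO classifiers and the Methyl Score

Per contrast organ, training samples are lung (label 0) vs organ
(label 1). The pipeline is:

1. **Differential-block selection**: rank blocks by |mean beta(label 0) −
   mean beta(label 1)|, ties broken by genomic order; keep the top 200
   (default). In the original setting selection came from an external
   reference panel; here it runs on the training panel itself, so when
   cross-validating, selection is re-done *inside every fold* on the
   training folds only — otherwise a null panel would show inflated CV
   AUC through selection leakage. The shipped model's blocks come from
   the full panel.
2. **SVM**: soft-margin linear SVM (the method describes a max-margin
   separator with a misclassification penalty and names no kernel);
   penalty grid {0.01, 0.1, 1, 10, 100}, chosen by stratified fivefold CV
   on out-of-fold AUC (ties → smaller C), final refit on all samples.
3. **Calibration**: Platt sigmoid P(non-lung | f) = 1/(1+exp(a·f+b)) fit
   by maximum likelihood with Platt's smoothed targets
   (t₁ = (n₁+1)/(n₁+2), t₀ = 1/(n₀+2)) on the out-of-fold decision values
   — the leak-free recipe that stays finite under perfect separation. The
   calibrated value is the Methyl Score; whether the original score was a
   probability or a normalized margin is unstated, so the package commits
   to the calibrated-probability reading, which matches its range and
   cutoff semantics.
4. **Cutoff**: Youden-index maximizer over calibrated out-of-fold scores.
   Candidate thresholds are midpoints between adjacent distinct sorted
   scores *plus 0.5 itself*; ties on J break toward the candidate closest
   to 0.5, then the smaller — so a signal-free ROC yields 0.5 rather than
   an arbitrary data midpoint, and a cleanly separated panel yields 0.5
   when 0.5 separates the calibrated classes. A constant score vector
   raises a degenerate-ROC error rather than inventing a cutoff.

Scoring a query maps it onto the model's blocks (missing blocks are a
refusal, not an imputation), applies the decision function and the
sigmoid, and calls lung-origin (score < cutoff), non-lung-origin
(score > cutoff), or indeterminate at exact equality — the source defines
only strict inequalities, and exact ties, while measure-zero, deserve an
explicit label. Patient-level: a lung lesion called lung-origin is a
primary (P), called non-lung a metastasis (M); polarity flips for the
extrathoracic lesion. (P,P) → multiple primaries, (P,M) → metastatic from
lung, (M,P) → metastatic from the organ, (M,M) is self-contradictory →
indeterminate (no such case occurs in the reference cohort). The organ of
the extrathoracic lesion selects which of the three models scores both
samples. A single-sample patient gets a lesion label but no relationship.

## Integration and concordance

Genomics first: Class I/II outcomes are final. Otherwise the methylation
diagnosis decides; when methylation says independent primaries but the
cascade had met the clonality criteria, methylation wins and the
discordance is recorded in the diagnosis notes (the reference cohort
contains such Class III cases, where the cascade's own origin call was
inconclusive, so no adjudicated conflict exists to learn a better rule
from). A single-sample methylation result cannot set the relationship;
the cascade's stands. Concordance counts patients whose origin both
tracks resolve independently (cascade Class I/II and a conclusive
two-sample methylation diagnosis); a concordant patient matches on both
relationship and origin.

## Survival

Kaplan–Meier product-limit estimation with the median defined as the
smallest time at which S(t) ≤ 0.5 (the product-limit convention; R's
`survfit` instead averages the two boundary times when the curve sits
exactly at 0.5, which is why an uncensored {2,4,6,8} instance yields 4
here and 5 there). Median 95% CI via the Greenwood log(−log) transform;
two-group log-rank chi-square with 1 df, simultaneous-death tie
convention, two-sided p, α = 0.05. Estimation and testing are delegated
to `lifelines`; unit tests pin the behavior to hand-checked and
R-`survdiff` oracles.

## Synthetic data: what it emulates, what it does not

`gen_cgp_case` plants an exact number of shared alterations (globally
unique coordinates; passenger genes drawn from a pool that excludes the
driver whitelist so no accidental driver hits) under four scenarios, and
returns the ground-truth inference derived *independently* of the cascade
code. `gen_methylation_cohort` emulates the training panel at its stated
composition (22/19/16/13) with 2000 blocks and, per organ, 200 disjoint
differential blocks whose organ mean sits `delta` away from the lung
mean, all values Gaussian (sd `noise_sd`) clipped to [0, 1]. The defaults
delta = 0.3, noise_sd = 0.05 put the classifier in the regime the
original models report (CV AUC ≈ 0.99); both are single-flag
configurable, and `sample_seed` lets query cohorts share a panel's
structure while drawing fresh samples.

Not emulated: realistic mutational signatures or per-gene alteration
frequencies; co-methylation structure beyond the block itself (blocks are
independent given the mean); assay artifacts (coverage-dependent beta
noise, batch effects); inter-patient heterogeneity of effect sizes.
Passing tests therefore show the *algorithms* are correct under their
stated assumptions, not that real tissue classification attains these
AUCs.

The 16-patient reference cohort is shipped as data (time lag,
extrathoracic site, genomic-evidence category, 29 per-lesion Methyl
Scores, expected labels). Because per-patient alteration *lists* are not
part of the record, `fixture_case_pairs` materializes each patient's
evidence category through the generator (seeded, deterministic) and the
cascade runs on real profile pairs; metachronous intervals are encoded as
8 months (only "≥ 6" is recorded), and the three driver patients carry
EGFR L858R, an EGFR exon-19 deletion, and an EML4–ALK fusion
respectively.

## Numerical and design choices

- Percent-style rates are reported to one decimal.
- Stratified CV folds are shuffled with an explicit integer seed;
  every random operation takes a seed and records it in its output.
- Chromosome ordering for "first driver in genomic order" is
  1–22, X, Y, MT.
- Degenerate inputs fail loudly: empty cohorts, single-label training
  sets, folds exceeding a class size, constant score vectors, missing
  model blocks, non-positive survival times.
- The cohort pipeline continues over per-patient stage failures,
  reporting patient id and stage, rather than aborting the run.

## Problem sizes in tests

The default test suite trains on reduced panels (300–400 blocks) where
the full-size regime is not itself under test, and uses the full default
panel (2000 blocks, 10 seeds × 3 contrasts) for the classifier
performance checks; the log-rank power property uses 500 simulations per
arm at n = 8 per group. These sizes are the package's own choice of a
desk-scale experiment that still pins the statistical behavior.

## Known limitations

- The cascade consumes alteration counts as given; it does not model
  panel size, sequencing depth, or the probability of chance sharing.
- Three fixed binary contrasts only; an unlisted extrathoracic organ has
  no model, and multi-class classification is out of scope.
- Calibration on ~40 out-of-fold values is coarse; the Methyl Score is
  best read as an ordering with a validated cutoff, not a literal
  posterior.
- Survival comparisons on 16-patient cohorts have low power; the package
  reports the test, not a causal claim.
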