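# Methods

## Setting and model

The package analyzes alternative-splicing dysregulation in a tumor cohort
profiled by bulk RNA-seq, quantified upstream by an rMATS-style tool as
per-sample junction-count tables. The central difficulty is the absence
of matched normal tissue: no per-sample control exists against which to
call a splice event aberrant. The design therefore treats the cohort
itself as the reference distribution for every event.

**PSI.** For an event with inclusion junction count `ijc`, skipping count
`sjc`, and effective form lengths `L_i`, `L_s`,

    PSI = (ijc / L_i) / (ijc / L_i + sjc / L_s),

undefined when `ijc + sjc = 0`. Events with fewer than 10 total junction
reads in a sample are discarded for that sample (read-support filter).
Coordinates are held 0-based half-open end to end (the rMATS
`exonStart_0base` convention); the only conversion to 1-based happens
when reading GTF transcript models, eliminating off-by-one drift.

**Differential call.** For event *e* and sample *i*, the z-score
`z_ei = (PSI_ei − mean_e) / sd_e` uses the cohort mean and *sample*
standard deviation (ddof = 1) over all samples measured for *e*, with the
focal sample included — a deliberate choice for the single-sample design;
a leave-one-out variant is available via a flag. A call is made strictly
beyond |2|: inclusion gain above, skipping below. Events with fewer than
3 measured samples or sd below `sd_floor = 0.01` are non-informative
(z explodes as sd → 0; quasi-constant exons should not generate calls).

**Splicing Burden Index.** `SBI_i = #called(i) / #measured(i)` per splice
type. The denominator is the per-sample measured-event count (a
cohort-universe denominator is a one-line switch). High/low strata are
assigned at the cohort quartiles of the SBI vector, boundary ties
included in the stratum (≥ Q3 is high, ≤ Q1 is low).

Under a null cohort (every sample from the same per-event distribution),
the expected SBI is the two-sided tail mass of the caller. Note the exact
finite-cohort value: for the included-moments z with n = 500 samples,
P(|z| > 2) = 0.0452 rather than the asymptotic 0.0455; the calibration
tests account for this through their Monte-Carlo error bands, whose
standard error combines the event-level and sample-level variance
components of the cross-classified call matrix.

## Recurrence, clustering, enrichment

An event is *recurrent* in a group when called in ≥ 2 of its samples
(parameter `min_n`); its direction is the consensus sign, or *mixed* on
disagreement — mixed events are retained as their own category
downstream. Shared-vs-specific structure is an exact set decomposition
(UpSet semantics); per-patient normalization divides group-unique counts
by group size.

Clustering operates on the top 5,000 most-variable skipped-exon events
(variance over measured samples, ties broken by event key so the
selection is deterministic and sample-order invariant), after event-mean
imputation of missing cells, with Ward linkage on Euclidean distances.
The linkage/metric/imputation are parameters recorded in output metadata
— nothing in the source analyses pins them — and when `k` is not given it
is chosen in 2..15 by maximal mean silhouette, with the full profile
reported. Cluster–label association is a two-sided Fisher exact test per
(cluster, label) with the sample odds ratio `ad/bc`; a Haldane 0.5
correction is applied and flagged when any cell is zero; BH adjustment
spans all tests and raw p-values are also emitted.

## Functional-site impact

Transcript models come from GTF (converted to 0-based half-open; CDS
outside exons or CDS length not divisible by 3 flags the model rather
than dropping it). A genomic interval maps to protein coordinates by
projecting its CDS-overlapping bases, strand-aware, to
`residue = floor(cds_offset / 3) + 1`; the implementation is interval
arithmetic over CDS blocks and is tested for exact agreement with a
per-base walk that assigns every CDS base its residue.

Every transcript of the event's gene whose CDS overlaps the cassette exon
is evaluated; the event-level verdict is the union of hits across
transcripts (no isoform-selection rule is assumed), and per-transcript
rows are also emitted so consumers can count either way. A feature and an
exon span overlap when they share at least one residue (closed
intervals). Impact follows the call direction: hits on an included exon
are functional-site gains, on a skipped exon losses, mixed for mixed
direction. Impact is assessed on the cassette exon's own residue span
only; frame-disrupting exons (length mod 3 ≠ 0) carry
`frame_preserving = False` but their downstream consequences (NMD,
truncation) are out of scope. UniProt feature types normalize to four
categories — domain, disulfide bond, modified residue, localization
signal — plus "other", via the mapping table in
`functional_impact.FEATURE_TYPE_MAP`.

## Pathway activity

The single-sample score is a deterministic rank-weighted running sum:
genes ranked by expression (average ranks on ties, which makes the score
invariant to strictly monotone transforms and well-defined on TPM
matrices with many zeros); walking the ranked list top-down, in-set genes
add `rank^alpha` (normalized to sum 1 over the set, `alpha = 0.25`),
out-of-set genes subtract `1/(N − |S|)`; the score is the sum of the
running sum (integral form). At `alpha = 0` this is a Kolmogorov–Smirnov
type statistic, cross-checked against a direct implementation. This is a
documented stand-in for kernel-ECDF GSVA: downstream checks are
directional and property-based, not score-identical. Group comparisons
are one-vs-rest Welch tests with Bonferroni adjustment; the primary
effect is the mean difference, with a secondary log2 ratio computed on
positively shifted scores (running-sum scores can be negative). The
protein-abundance correlation summarizes the abundance matrix as the
per-sample mean over pathway proteins (per-protein mode available).

## Survival

Kaplan–Meier, log-rank, and Cox proportional-hazards fitting delegate to
lifelines; the module owns treatment coding of factor covariates with
explicit reference levels (reference rows are emitted for forest plots),
interaction products, and quartile stratification of continuous scores
with Q1 reference — boundary ties fall to the lower stratum. Ties use the
Efron approximation. One consequence worth knowing: duplicating every
observation is only *approximately* invariant under Efron (duplication
manufactures ties), so the corresponding regression test allows 2%
relative slack. Continuous-PSI fits are the primary survival association
for splice events, with a median-split sensitivity mode, since no
principled cutpoint exists.

## Paired perturbation comparison

For replicate designs (e.g. 3 treated vs 3 control), ΔPSI is the
difference of arm means of count-derived PSI. The p-value is a
label-permutation test of the mean difference with *directional rank
semantics*: the fraction of relabelings whose signed difference is at
least as extreme in the observed direction. With an absolute-value
statistic every split would tie with its complement and the attainable
floor would double; the directional form keeps the granularity at
1/C(n, n_a) — for 3-vs-3, multiples of 1/20 with floor 0.05. All
C(n, n_a) ≤ 10,000 splits are enumerated exhaustively, otherwise fixed-
seed Monte-Carlo with the add-one rule. BH FDR across events; calls
require |ΔPSI| ≥ 0.1 and FDR < 0.05.

A structural consequence of exhaustive 3-vs-3 permutation: since p ≥
0.05, the BH-adjusted p is at least `0.05·m/k` and sparse planted signal
can never be *called* at FDR < 0.05 with three replicates — this is a
granularity fact about permutation tests, not a bug. Power tests
therefore use five replicates per arm (252 splits); at three replicates
the tests verify that planted events attain the minimal p. Gene-level
differential expression delegates to pydeseq2 (negative-binomial Wald)
behind a thin wrapper that owns the |log2FC| and adjusted-p thresholds;
dependency screens are consumed as a long-format z/FDR table filtered at
z < −1.5 (strict) and FDR < 0.05.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
with exact recorded truth:

- **Baseline PSI centers** per event per cluster ~ Beta(5, 5). Mid-range
  polymorphic events mirror what survives variable-event selection in
  real cohorts, and keep clipped-Gaussian draws effectively Gaussian so
  the z-caller calibration is meaningful. Real PSI distributions are
  U-shaped overall; the generator deliberately models the informative
  mid-range, not the near-constitutive mass.
- **Within-cluster noise** sd 0.05 (typical replicate-level PSI scatter at
  moderate depth); **aberrant shift** 3 sd; per-sample aberrant fraction
  `f_i` configurable per sample.
- **Junction counts** are back-computed deterministically from drawn PSI
  at depth 100 reads with SE form lengths (2, 1):
  `ijc = round(2·depth·PSI/(1+PSI))`, which reproduces the drawn PSI
  within 1/depth and passes the ≥ 10-read filter everywhere.
- **Histology labels** equal the true cluster with probability 0.9
  (configurable), giving known enrichment truth.
- **Survival** is exponential proportional hazards with log-HR
  coefficients on cluster and `f_i`; censoring is independent exponential
  with rate set to the target censoring fraction (approximate, adequate
  for recovery tests). **Expression** couples designated splicing-factor
  genes linearly to `f_i` over a noise floor.
- Toy **annotation** fixtures build random multi-exon transcripts on both
  strands with in-frame CDS and features at known residues; expected
  event impacts are recorded by the per-base residue walk, which serves
  as the independent oracle for the interval-arithmetic mapper.

What passing tests on these cohorts do *not* show: robustness to
U-shaped PSI marginals, overdispersed (beta-binomial) counts, batch
effects, missingness that is informative rather than random, or
annotation errors in real GTFs. The generator's role is to verify the
statistics and plumbing against known truth, not to imitate every
property of tumor RNA-seq.

## Numerical and design choices

- Event identity is (splice type, chrom, strand, exon span, upstream end,
  downstream start); conflicting gene annotations on identical
  coordinates keep the first-seen symbol with a logged warning.
- Events measured in < 80% of samples are dropped before variance
  ranking (`min_sample_fraction = 0.8`), so missingness cannot masquerade
  as variance; the floor is recorded in run metadata.
- Quartile boundaries use linear-interpolation percentiles; ties at a
  boundary always fall into the lower stratum (survival) or into the
  stratum (SBI high/low, where the convention is ≥/≤ by definition).
- Hierarchical clustering relabels clusters 1..k by first appearance so
  output is deterministic; partitions from the same tree are nested
  across k.
- The pipeline derives all stage outputs from declared files only, writes
  a JSON manifest with sha256 hashes, parameters and row counts, and is
  idempotent: identical config + seed reproduces identical hashes.
- Problem sizes in the test-suite simulations (e.g. 500×2,000 null
  cohort, 200-sample recovery designs, 100 Cox replicates) are chosen so
  the full suite runs in a few minutes while keeping Monte-Carlo bands
  tight enough to be informative.

## Known limitations

- The cohort z-score treats events independently; correlated splicing
  programs inflate the effective number of calls per sample but not the
  SBI's ranking behavior.
- The ssGSEA-style score is not numerically interchangeable with GSVA.
- The paired permutation test cannot reach small p-values at three
  replicates (see above); it is a desk-scale substitute for a
  likelihood-based paired splicing model, matching its output schema.
- No NMD or protein-structure modelling downstream of functional-site
  overlap; no batch correction; no time-varying covariates or competing
  risks in survival models.
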