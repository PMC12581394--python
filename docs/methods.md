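# Methods

## The concordance model

A follow-on companion diagnostic (FCD) is compared against two replicates
of an approved comparator (CCD1, CCD2) on the same samples, with no gold
standard. Each sample contributes a triple of qualitative calls
(positive/negative/invalid) plus its enrollment stratum. All agreement
statistics are functions of the triple's pattern counts: after invalid
filtering each row is one of eight (CCD1, CCD2, FCD) sign patterns, and
every PPA/NPA/OPA is a ratio of pattern-count sums.

**Invalid calls.** The primary analysis excludes any row containing an
invalid call. Best- and worst-case sensitivity analyses instead recode
each invalid call to the positive/negative value maximizing
(respectively minimizing) that row's pairwise agreement, with ties broken
toward negative; the filter summary records how many rows were dropped or
recoded.

**ζ differences and non-inferiority.** The four differences
ζ_PPA1 = PPA_C1C2 − PPA_C1F, ζ_PPA2 = PPA_C2C1 − PPA_C2F and the NPA
analogues compare replicate-to-replicate agreement with new-test
agreement. ε1 is the maximum upper 95% CI limit over the PPA-side ζs
(predictive claims), ε0 over the NPA-side ζs (selective claims); a side
passes iff ε < δ strictly. The ε↔ζ mapping is configurable
(`swap_mapping`) because claims that select on a negative result reverse
the roles. Note an exact identity useful for testing: if FCD coincides
with CCD1 call-for-call, then PPA_C2F = PPA_C2C1 and NPA_C2F = NPA_C2C1,
so the CCD2-referenced ζs are exactly 0; the CCD1-referenced ζs vanish
only under perfect replicate concordance.

**Bootstrap CIs.** Percentile bootstrap with 1,000 replicates by default,
resampling whole sample triples with replacement. Because every ζ depends
on the data only through the eight pattern counts, resampling is realized
as multinomial draws over those counts — distributionally identical to
row resampling and fully vectorized. CI limits are empirical
(α/2, 1−α/2) quantiles with linear interpolation. Replicates where a ζ is
undefined (an empty reference margin) are skipped and counted; more than
50% undefined replicates for any ζ aborts with an "unstable" error rather
than imputing. Runs are bit-reproducible given the seed, which is
recorded in the result object.

**Newcombe method 10.** For the unenriched (consecutively enrolled)
design the difference of paired proportions uses continuity-corrected
Wilson limits for each marginal, combined with the φ̂-corrected
covariance term of Newcombe (1998), φ̂ set to 0 when any marginal
vanishes and the (ad − bc) numerator continuity-corrected by n/2 when
positive.

**Single-proportion CIs.** Wilson score without continuity correction is
the default (its x = n lower limit is exactly n/(n+z²)); Clopper-Pearson
(exact, (α/2)^(1/n) at x = n) and continuity-corrected Wilson are
selectable. Published validation tables are not uniform in this choice —
perfect-agreement rows follow Wilson while some large-cohort rows follow
the exact interval — so both are first-class. All bounds are clipped to
[0, 1]. Percentages render at one decimal; computation is full precision.

**Prevalence adjustment.** Enriched cohorts over-represent pre-test
positives. The within-stratum joint distribution of (comparator call,
FCD call) is assumed transportable to the population; strata are
reweighted by the assumed population pre-test prevalence π via the law of
total probability and adjusted PPA = P(F+∧C+)/P(C+),
NPA = P(F−∧C−)/P(C−) are read off the reweighted joint. When π equals the
sample's stratum share the adjustment is the identity to machine
precision. The comparator arm defaults to CCD1.

## Analytical validation

**LoD.** Hit rate per dilution level = detected/replicates; the LoD is
the lowest level meeting the 95% threshold whose entire upper tail also
meets it (monotone-tail rule, tolerant of isolated sub-threshold dips
below the LoD but not above it). No probit/logistic fit is attempted —
the empirical rule mirrors how detection limits are claimed. When no
level qualifies the LoD is reported undefined ("> max tested level").

**LoB.** False-positive calls are pooled per variant class across
wild-type samples. Zero-event classes report the one-sided exact upper
bound 1 − α^(1/n); otherwise the two-sided Clopper-Pearson interval.

**DNA input study.** PPA/NPA per alteration class with the control input
as reference and exact CIs; the TMB metric is the absolute percent
difference of mean TMB between challenge and control, with a percentile
bootstrap (over paired samples) upper bound.

**Precision.** Balanced crossed random-main-effects ANOVA by method of
moments: for each declared factor, σ̂²_f = (MS_f − MS_resid)/(N/levels_f),
interactions pooled into the residual, negative estimates truncated to 0
before totaling (EP05-style). The residual is reported as within-run
variance; a declared run-day factor carries the between-run component.
%CV = 100·SD_total/mean, an error at mean 0. A factor observed at a
single level is flagged and contributes zero. The default simulated
design is 3 operator/instrument teams × 3 reagent lots × 4 run days × 1
replicate = 36 measurements, matching a 36-replicate precision study;
per-component estimates then carry only 2–3 df, so single-panel
estimates are noisy by design and recovery is assessed on averages over
repeated panels.

**Deming regression.** Closed-form errors-in-variables fit;
`variance_ratio` λ is the ratio of y-error to x-error variance (λ = 1 is
orthogonal regression; λ → ∞ recovers OLS of y on x). Degenerate inputs
(zero variance in both axes) are rejected; Pearson r is reported
alongside.

## Signature callers

All callers are pure threshold rules with inclusive "≥" boundaries
(MSI ≥ 39 loci, TMB ≥ 10 mut/Mb, LoH High ≥ 16%, GSS ≥ 46) except LST,
which counts loss segments strictly longer than 10 Mb. Choices worth
noting:

* **TMB denominator.** The sequenced footprint in Mb is a required
  parameter, defaulting to 30 Mb as a whole-exome approximation. The
  germline filter consumes pre-annotated evidence flags (dbSNP151,
  gnomAD AC>0, curated-benign) rather than querying databases live, so
  results do not drift with database versions.
* **Genomic LoH.** The percent of the fixed 552-segment map with LoH is
  rounded half-up to an integer percent before classification, making the
  High/Equivocal/Low bands exhaustive and mutually exclusive;
  QC failure (≤ 3,000 SNPs read or depth < 200×) dominates as
  Indeterminate. The optional per-segment derivation flags a segment LoH
  when its mean major-allele fraction ≥ 0.75 (configurable) and marks
  segments under 17 SNPs/Mb low-confidence; it is isolated so precomputed
  booleans can bypass it.
* **GSS.** The published rule states only that LoH and LST evidence
  contribute; the default combination here — LoH segments normalized to a
  0–100 scale (×100/552) plus 1 × LST count — is an assumption, flagged
  in every result, and replaceable by a caller-supplied formula. The HRD
  rule itself (BRCA1/2 pathogenic OR GSS ≥ 46) is exact regardless.
* **CNA classes.** Amplified requires copies ≥ max(caller threshold,
  copies LoD); copies meeting the threshold but below the LoD (the
  analytically reliable bound, default 8.3 copies) return `below_lod`
  rather than a confident call.

Coordinates: variant positions are 1-based; segment intervals half-open.

## Synthetic data: what it emulates and what it does not

The cohort generator draws latent biomarker truth at a set prevalence,
stratified by a noisy pre-test marker when enrichment is on (defaults:
half pre-test positives, matching positive-enriched designs with
date-matched negatives); arms call the truth through their
sensitivity/specificity, and the comparator replicates share an error
event with probability equal to the dependence parameter (a mixture
construction whose replicate-error correlation equals that parameter and
spans [0, 1]). Invalids are injected independently, so exclusion does not
bias the conditional agreements — which is why the closed-form
`theoretical_agreements` (total probability over strata and truth) is a
valid oracle for the valid-only estimates. Defaults (n = 400, arm
Se/Sp 0.97/0.99) reflect study-scale cohorts with high-90s agreements.

Not emulated: real assays fail in correlated, sample-quality-driven ways
(tumor content, degradation), errors across arms can be dependent through
the specimen, and invalidity is rarely independent of difficulty. Passing
simulation checks therefore demonstrates the estimators' correctness
under the stated model, not the field performance of any assay.

## Numerical and study-size choices

* Bootstrap default 1,000 replicates; all simulation studies run under a
  single seeded generator and are deterministic end to end.
* Coverage of the ζ bootstrap is assessed on n = 300 cohorts (500
  simulations) at moderate arm accuracies (CCD 0.90/0.92, FCD 0.87/0.90)
  so every component agreement stays off the [0, 1] boundary. This is
  deliberate: with agreements near 0.98 at n = 300 (a handful of
  discordant samples) the percentile bootstrap is known to undercover by
  several points — a real limitation of the interval for near-perfect
  assays at modest n, worth remembering when reading such CIs.
* The non-inferiority operating characteristic uses n = 2,000 cohorts
  (200 simulations) with the new test stochastically identical to the
  comparator and δ = 0.05; LoD recovery uses 500 logistic series at 20
  replicates/level; precision recovery uses 200 panels of the
  36-replicate design. These sizes keep each study to seconds on one CPU
  while leaving Monte-Carlo error well inside the assertion bands.

## Known limitations

* The percentile bootstrap's near-boundary undercoverage (above); a BCa
  or score-based interval is not provided.
* Method-of-moments variance components assume a balanced crossed design
  with additive effects; unbalanced or interaction-heavy designs are
  pooled into the residual rather than modeled (no REML).
* The GSS combination and the per-segment BAF rule are assumptions,
  clearly flagged, because the published definitions stop short of them.
* Prevalence adjustment assumes within-stratum transportability of the
  joint call distribution; violations (spectrum effects) are not
  detectable from the study data itself.
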