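# cdxval

Statistics for the clinical and analytical validation of companion
diagnostic (CDx) assays, written for biostatisticians and assay
scientists who need the agreement machinery of a follow-on CDx study and
the bench-side validation estimators in one tested Python library.

## What it computes

**Paired-comparator concordance and non-inferiority.** A follow-on CDx
(FCD) is validated without a gold standard by comparing one FCD replicate
to two replicates of the approved comparator (CCD1, CCD2) on the same
samples. From the eight component agreements (PPA/NPA for each ordered
arm pair) the four agreement differences are

    ζ_PPA1 = PPA_C1C2 − PPA_C1F    ζ_PPA2 = PPA_C2C1 − PPA_C2F
    ζ_NPA1 = NPA_C1C2 − NPA_C1F    ζ_NPA2 = NPA_C2C1 − NPA_C2F

where PPA_C1F is the proportion of CCD1-positive samples on which FCD is
also positive, and so on. Two-sided 95% CIs come from a percentile
bootstrap over sample triples (1,000 replicates by default) or, for
unenriched designs, from Newcombe's method-10 paired-difference interval.
With ε the maximum upper CI limit across a side's ζs and δ the
pre-specified margin, non-inferiority holds when ε < δ (strict).
Enrichment of the study cohort is undone by reweighting the
within-stratum joint call distribution to an assumed population
prevalence (Bayes / law of total probability). Single proportions get
Wilson (default), continuity-corrected Wilson, or Clopper-Pearson
intervals.

**Analytical validation.** Limit of detection as the lowest dilution
level with ≥ 95% replicate hit rate (monotone-tail rule); limit of blank
with exact binomial bounds; minimum-vs-optimal DNA-input concordance with
a bootstrap bound on the TMB percent difference; variance-component
precision (operator/instrument, reagent lot, between-run, within-run) by
method-of-moments ANOVA with %CV; variant-frequency-bucket call rates;
and Deming errors-in-variables regression for quantitative method
comparison.

**Genomic signature callers.** MSI-high at ≥ 39 frameshift-mutated loci
of 5,721; TMB as eligible somatic non-synonymous mutations per Mb
(high at ≥ 10 mut/Mb) with a germline-evidence filter; genomic LoH as the
percent of 552 fixed 2–6 Mb segments with loss of heterozygosity
(High ≥ 16%, Equivocal 11–15%, Low < 11%, Indeterminate on QC failure);
LST as loss segments strictly > 10 Mb; HRD positive on BRCA1/2 mutation
or genomic scar score ≥ 46; and copy-number amplification classes with an
analytically reliable copies bound.

**Synthetic data.** Every input can be simulated with known truth:
enriched concordance cohorts with latent biomarker status and per-arm
sensitivity/specificity (with tunable comparator-replicate dependence),
logistic dilution series, crossed random-effects precision panels, and
per-sample signature tables.

## A worked example

```python
from cdxval import (ConcordanceSimSpec, RunConfig,
                    run_concordance_study, simulate_concordance_cohort)

spec = ConcordanceSimSpec(n_samples=400, invalid_rate_fcd=0.02, seed=11)
table, truth = simulate_concordance_cohort(spec)
doc = run_concordance_study(table, RunConfig(delta1=0.05, delta0=0.05, seed=11))
ni = doc["noninferiority"]
print(ni["epsilon1"], ni["epsilon0"], ni["pass_overall"])
```

Running `python examples/concordance_study.py` (this example plus
reporting) prints:

```
Biomarker                        N  PPA (95% CI)            NPA (95% CI)
------------------------------------------------------------------------------------
simulated biomarker            387  96.9% (93.4, 98.6)      97.4% (94.1, 98.9)

zeta_ppa1: +0.0155  95% CI (-0.0101, +0.0421)
zeta_ppa2: +0.0051  95% CI (-0.0237, +0.0352)
zeta_npa1: -0.0052  95% CI (-0.0220, +0.0143)
zeta_npa2: +0.0000  95% CI (-0.0153, +0.0153)

epsilon1 = 0.0421 vs delta1 = 0.05  epsilon0 = 0.0153 vs delta0 = 0.05
non-inferiority: PASS
```

387 of 400 samples survive invalid-call exclusion; the FCD agrees with
each comparator replicate about as well as the replicates agree with each
other (every ζ near 0), and the largest upper CI limit on each side stays
below the 0.05 margin, so the simulated follow-on test is non-inferior.
`examples/analytical_validation.py` and `examples/signature_calling.py`
walk the other two capability groups the same way. A thin CLI mirrors the
library (`cdxval concordance|lod|lob|precision|input-study|deming|signatures|simulate`).

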