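"""A follow-on CDx concordance study, end to end on a simulated cohort.

Simulates an enriched cohort of 400 samples where the new test (FCD) and
the approved comparator (CCD, run in duplicate) share 97%/99%
sensitivity/specificity, then runs the full analysis: invalid-call
filtering, the eight component agreements, percentile-bootstrap CIs for
the four zeta differences, and the non-inferiority decision at
delta = 0.05.
"""

from cdxval import ConcordanceSimSpec, RunConfig, render_report, run_concordance_study, simulate_concordance_cohort

spec = ConcordanceSimSpec(n_samples=400, invalid_rate_fcd=0.02, seed=11)
table, truth = simulate_concordance_cohort(spec)
config = RunConfig(delta1=0.05, delta0=0.05, n_boot=1000, seed=11, prevalence=0.15)

doc = run_concordance_study(table, config)

print(render_report({"simulated biomarker": doc}, style="text_table"))
print()
for name in ("zeta_ppa1", "zeta_ppa2", "zeta_npa1", "zeta_npa2"):
    z = doc["zetas"][name]
    print(f"{name}: {z['point']:+.4f}  95% CI ({z['ci_low']:+.4f}, {z['ci_high']:+.4f})")
ni = doc["noninferiority"]
print(
    f"\nepsilon1 = {ni['epsilon1']:.4f} vs delta1 = {ni['delta1']}  "
    f"epsilon0 = {ni['epsilon0']:.4f} vs delta0 = {ni['delta0']}"
)
print("non-inferiority:", "PASS" if ni["pass_overall"] else "FAIL")
adj = doc["prevalence_adjusted"]
print(f"prevalence-adjusted (pi = 0.15): PPA {100 * adj['ppa']:.1f}%, NPA {100 * adj['npa']:.1f}%")

# A zeta near 0 means the new test agrees with a comparator replicate about
# as well as the two comparator replicates agree with each other; the study
# passes when every zeta's upper CI limit stays below the margin delta.
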