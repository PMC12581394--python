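"""Genomic signature calling on a simulated tumor sample.

Builds a sample with known signature truth (MSI-high, TMB-high, LoH-high),
round-trips the variants through a minimal VCF, and runs every caller.
"""

import tempfile
from pathlib import Path

from cdxval import SignatureSimSpec, call_signatures, simulate_signature_sample
from cdxval.io import read_variants_vcf, write_variants_vcf

spec = SignatureSimSpec(
    msi_frameshift_count=55,       # >= 39 of 5,721 loci -> MSI-high
    eligible_mutation_count=420,   # 420 / 30 Mb = 14 mut/Mb -> TMB-high
    germline_flagged_count=60,     # excluded from TMB by the germline filter
    synonymous_count=30,           # excluded: not a counted consequence class
    loh_segment_count=100,         # 100 / 552 = 18.1% -> LoH High
    lst_loss_lengths_mb=(14.0, 11.5, 9.0),  # two losses > 10 Mb -> LST = 2
    brca_status="wild_type",
    seed=17,
)
variants, msi_table, loh_table, cn_segments, truth = simulate_signature_sample(spec)

with tempfile.TemporaryDirectory() as tmp:
    vcf = Path(tmp) / "sample.vcf"
    write_variants_vcf(variants, vcf)
    variants = read_variants_vcf(vcf)   # VCF round trip

result = call_signatures(variants, msi_table, loh_table, cn_segments, brca_status="wild_type")

print(f"MSI status:   {result.msi_status}  (truth {truth['msi_status']})")
print(f"TMB:          {result.tmb_value:.1f} mut/Mb -> {result.tmb_class} "
      f"({result.tmb_eligible_count} eligible mutations / 30 Mb)")
print(f"genomic LoH:  {result.loh_percent:.1f}% of 552 segments -> {result.loh_class}")
print(f"LST count:    {result.lst_count} loss segments > 10 Mb")
print(f"GSS:          {result.gss:.1f} (assumed combination: {result.gss_formula_assumed})")
print(f"HRD call:     {result.hrd_call} (BRCA {result.brca_status}, GSS cutoff 46)")

# Every call is a deterministic threshold rule, so the simulated truth is
# recovered exactly; the GSS line is flagged because its exact combination
# of LoH and LST evidence is an assumption of this package.
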