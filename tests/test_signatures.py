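"""Signature callers: thresholds, filters, and end-to-end truth recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdxval.signatures import (
    CnSegment,
    LohSegment,
    LohSegmentTable,
    MsiLocusTable,
    VariantRecord,
    call_genomic_loh,
    call_hrd,
    call_msi,
    call_signatures,
    classify_cna,
    compute_gss,
    compute_tmb,
    count_lst,
    segment_loh_from_baf,
)
from cdxval.simulate import SignatureSimSpec, simulate_signature_sample


def msi_table(n_frameshift, universe=5721):
    return MsiLocusTable(
        locus_ids=tuple(f"L{i}" for i in range(universe)),
        frameshift_mutated=tuple(i < n_frameshift for i in range(universe)),
        universe_size=universe,
    )


@pytest.mark.parametrize("count,expected", [(39, "MSI_high"), (38, "MSS"), (0, "MSS"), (5721, "MSI_high")])
def test_msi_threshold(count, expected):
    assert call_msi(msi_table(count)) == expected


def test_msi_incomplete_universe_indeterminate():
    partial = MsiLocusTable(locus_ids=("a", "b"), frameshift_mutated=(True, True))
    assert call_msi(partial) == "indeterminate"
    assert call_msi(partial, threshold_loci=2, allow_incomplete=True) == "MSI_high"


def test_msi_monotone_in_frameshift_count():
    order = {"MSS": 0, "MSI_high": 1}
    calls = [order[call_msi(msi_table(k))] for k in range(30, 50)]
    assert calls == sorted(calls)


# ---------------------------------------------------------------------------
# TMB


def variant(consequence, flags=(), vf=0.2):
    return VariantRecord(
        chrom="chr1", pos=100, ref="A", alt="T", vf=vf, depth=500,
        consequence=consequence, germline_evidence=frozenset(flags),
    )


def test_tmb_boundary_inclusive():
    variants = [variant("missense")] * 300
    value, cls, n = compute_tmb(variants, panel_mb=30.0)
    assert (value, cls, n) == (10.0, "high", 300)


def test_tmb_zero():
    assert compute_tmb([], panel_mb=30.0) == (0.0, "not_high", 0)


def test_tmb_eligibility_filter_hand_enumeration():
    """12-variant fixture; eligibility enumerated by hand: the 4 somatic
    missense and 2 somatic nonsense count; germline-flagged, synonymous and
    flagged-frameshift variants do not -> 6 eligible."""
    fixture = (
        [variant("missense")] * 4
        + [variant("nonsense")] * 2
        + [variant("missense", ["gnomad_ac_gt0"])] * 3
        + [variant("synonymous")] * 2
        + [variant("frameshift", ["dbsnp151"])]
    )
    oracle = sum(
        1
        for v in fixture
        if v.consequence in {"missense", "nonsense", "inframe_indel", "frameshift"}
        and not v.germline_evidence
    )
    assert oracle == 6
    value, _, n = compute_tmb(fixture, panel_mb=30.0)
    assert n == 6
    assert value == pytest.approx(6 / 30)


@settings(derandomize=True, max_examples=30)
@given(
    n_somatic=st.integers(0, 40),
    flagged=st.lists(st.sampled_from(["dbsnp151", "gnomad_ac_gt0", "curated_benign"]), max_size=5),
)
def test_tmb_germline_flagged_variants_never_count(n_somatic, flagged):
    base = [variant("nonsense")] * n_somatic
    v0, _, _ = compute_tmb(base, panel_mb=30.0)
    padded = base + [variant("missense", [f]) for f in flagged]
    v1, _, _ = compute_tmb(padded, panel_mb=30.0)
    assert v1 == v0
    v2, _, _ = compute_tmb(padded + [variant("frameshift")], panel_mb=30.0)
    assert v2 == pytest.approx(v0 + 1 / 30.0)


def test_tmb_invalid_footprint():
    with pytest.raises(ValueError, match="panel_mb"):
        compute_tmb([], panel_mb=0)


# ---------------------------------------------------------------------------
# genomic LoH


def loh_table(n_loh, snps_read=250_000, depth=500.0):
    segs = tuple(
        LohSegment(
            segment_id=i + 1, chrom="chr1", start=i * 4_000_000 + 1,
            end=(i + 1) * 4_000_000, het_snp_count=70, mean_depth=depth,
            loh=i < n_loh,
        )
        for i in range(552)
    )
    return LohSegmentTable(segments=segs, snps_read=snps_read, sample_depth=depth)


def test_loh_high_at_89_segments():
    pct, cls = call_genomic_loh(loh_table(89))
    assert pct == pytest.approx(100 * 89 / 552)
    assert cls == "High"


def test_loh_indeterminate_on_low_snp_count():
    pct, cls = call_genomic_loh(loh_table(89, snps_read=2900))
    assert (pct, cls) == (None, "Indeterminate")


def test_loh_indeterminate_on_low_depth():
    assert call_genomic_loh(loh_table(89, depth=150.0))[1] == "Indeterminate"


def test_loh_zero_is_low():
    assert call_genomic_loh(loh_table(0)) == (0.0, "Low")


def test_loh_classes_exhaustive_and_ordered():
    """Over all possible segment counts the class bands partition 0..552 in
    order Low -> Equivocal -> High with no gaps."""
    classes = [call_genomic_loh(loh_table(k))[1] for k in range(553)]
    order = {"Low": 0, "Equivocal": 1, "High": 2}
    ranks = [order[c] for c in classes]
    assert ranks == sorted(ranks)
    assert set(classes) == {"Low", "Equivocal", "High"}


def test_segment_loh_from_baf_rules():
    flags, low_conf = segment_loh_from_baf({1: np.full(60, 0.5), 2: np.full(60, 0.95)})
    assert flags == {1: False, 2: True}
    # boundary: mean major fraction 0.749 < 0.75 threshold
    flags, _ = segment_loh_from_baf({1: np.array([0.749] * 10)})
    assert flags == {1: False}
    flags, _ = segment_loh_from_baf({1: np.array([0.75] * 10)})
    assert flags == {1: True}
    with pytest.raises(ValueError, match="no heterozygous SNPs"):
        segment_loh_from_baf({1: np.array([])})


def test_segment_loh_density_flagging():
    flags, low_conf = segment_loh_from_baf(
        {1: np.full(10, 0.9)}, segment_lengths_mb={1: 4.0}
    )  # 2.5 SNPs/Mb < 17
    assert low_conf == [1]


# ---------------------------------------------------------------------------
# LST / GSS / HRD / CNA


def loss(chrom, start_mb, length_mb):
    return CnSegment(chrom, int(start_mb * 1e6), int((start_mb + length_mb) * 1e6), "loss")


def test_lst_counting():
    assert count_lst([loss("chr1", 10, 12)]) == 1
    assert count_lst([loss("chr1", 10, 10.0)]) == 0  # strictly > 10 Mb
    segs = [loss("chr1", 0, 8), loss("chr2", 0, 11), loss("chr3", 0, 25)]
    segs += [CnSegment("chr4", 0, 20_000_000, "gain"), CnSegment("chr5", 0, 30_000_000, "neutral")]
    assert count_lst(segs) == 2
    assert count_lst(list(reversed(segs))) == 2  # order-invariant


def test_lst_overlap_rejected():
    with pytest.raises(ValueError, match="overlapping"):
        count_lst([loss("chr1", 0, 20), loss("chr1", 15, 20)])


def test_gss_zero_and_monotonicity():
    assert compute_gss(0, 0)[0] == 0.0
    g1, assumed = compute_gss(150, 20)
    g2, _ = compute_gss(150, 21)
    g3, _ = compute_gss(151, 20)
    assert assumed is True
    assert g2 > g1 and g3 > g1
    with pytest.raises(ValueError, match="non-negative"):
        compute_gss(10, 5, w_loh=-1)


@pytest.mark.parametrize(
    "gss,brca,expected",
    [(20.0, "pathogenic", "positive"), (46.0, "wild_type", "positive"), (45.0, "wild_type", "negative")],
)
def test_hrd_disjunctive_rule(gss, brca, expected):
    assert call_hrd(gss, brca) == expected


def test_hrd_indeterminate_without_evidence():
    with pytest.raises(ValueError, match="indeterminate"):
        call_hrd(None, "unknown")


@pytest.mark.parametrize(
    "copies,expected",
    [(8.3, "amplified"), (2.0, "not_amplified"), (6.0, "not_amplified"), (20.0, "amplified")],
)
def test_cna_classification(copies, expected):
    assert classify_cna(copies, amp_threshold=8.3, lod_copies=8.3) == expected


def test_cna_below_lod_band():
    assert classify_cna(7.0, amp_threshold=6.0, lod_copies=8.3) == "below_lod"
    with pytest.raises(ValueError):
        classify_cna(-1.0)


# ---------------------------------------------------------------------------
# end-to-end on a simulated genome


def test_simulated_triple_high_profile_recovered_exactly():
    spec = SignatureSimSpec(
        msi_frameshift_count=60,
        eligible_mutation_count=450,
        germline_flagged_count=40,
        synonymous_count=25,
        panel_mb=30.0,
        loh_segment_count=120,
        lst_loss_lengths_mb=(12.0, 11.0, 9.0, 30.0),
        brca_status="wild_type",
        seed=21,
    )
    variants, msi, loh, cn, truth = simulate_signature_sample(spec)
    res = call_signatures(variants, msi, loh, cn, brca_status="wild_type")
    assert res.msi_status == truth["msi_status"] == "MSI_high"
    assert res.tmb_value == pytest.approx(truth["tmb_value"]) == 15.0
    assert res.tmb_class == "high"
    assert res.loh_class == truth["loh_class"] == "High"
    assert res.lst_count == truth["lst_count"] == 3
    assert res.gss == pytest.approx(truth["gss"])
    assert res.hrd_call == truth["hrd_call"]


def test_simulated_quiet_profile():
    spec = SignatureSimSpec(
        msi_frameshift_count=3,
        eligible_mutation_count=90,
        loh_segment_count=20,
        lst_loss_lengths_mb=(8.0,),
        brca_status="wild_type",
        seed=4,
    )
    variants, msi, loh, cn, truth = simulate_signature_sample(spec)
    res = call_signatures(variants, msi, loh, cn, brca_status="wild_type")
    assert res.msi_status == "MSS"
    assert res.tmb_class == "not_high"
    assert res.loh_class == "Low"
    assert res.lst_count == 0
    assert res.hrd_call == "negative"
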