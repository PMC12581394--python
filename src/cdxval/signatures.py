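"""Genomic signature callers: MSI, TMB, genomic LoH, LST, GSS and HRD.

These are deterministic threshold rules applied to upstream-pipeline
outputs (variant tables, microsatellite locus tables, LoH segment maps,
copy-number segments):

* MSI-high: >= 39 frameshift-mutated loci out of a 5,721-locus universe.
* TMB: eligible somatic non-synonymous mutations (missense, nonsense,
  in-frame indel, frameshift; no germline-database evidence) per Mb of
  panel footprint; high at >= 10 mut/Mb.
* Genomic LoH: percent of 552 fixed 2-6 Mb segments showing loss of
  heterozygosity; High >= 16%, Equivocal 11-15%, Low < 11%,
  Indeterminate on QC failure (<= 3,000 SNPs read or depth < 200x).
* LST: count of chromosomal loss segments strictly longer than 10 Mb.
* HRD: positive iff BRCA1/2 pathogenic or genomic scar score >= 46.

The GSS combination of LoH and LST evidence is not published; the default
here (LoH percent + LST count) is flagged as an assumed formula and is
pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "VariantRecord",
    "MsiLocusTable",
    "LohSegmentTable",
    "LohSegment",
    "CnSegment",
    "SignatureResult",
    "ELIGIBLE_CONSEQUENCES",
    "GERMLINE_FLAGS",
    "call_msi",
    "compute_tmb",
    "call_genomic_loh",
    "segment_loh_from_baf",
    "count_lst",
    "compute_gss",
    "call_hrd",
    "classify_cna",
    "call_signatures",
]

CONSEQUENCES = (
    "missense",
    "nonsense",
    "inframe_indel",
    "frameshift",
    "synonymous",
    "splice",
    "other",
)
ELIGIBLE_CONSEQUENCES = frozenset({"missense", "nonsense", "inframe_indel", "frameshift"})
GERMLINE_FLAGS = ("dbsnp151", "gnomad_ac_gt0", "curated_benign")

MSI_LOCUS_UNIVERSE = 5721
LOH_SEGMENT_UNIVERSE = 552


@dataclass(frozen=True)
class VariantRecord:
    """One small variant with the annotations the TMB filter consumes."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vf: float
    depth: int
    consequence: str
    germline_evidence: frozenset[str] = frozenset()
    gene: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be 1-based (>= 1)")
        if not 0.0 <= self.vf <= 1.0:
            raise ValueError("variant frequency must be in [0, 1]")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        unknown = set(self.germline_evidence) - set(GERMLINE_FLAGS)
        if unknown:
            raise ValueError(f"unknown germline flags: {sorted(unknown)}")
        object.__setattr__(self, "germline_evidence", frozenset(self.germline_evidence))


@dataclass(frozen=True)
class MsiLocusTable:
    """Frameshift status per microsatellite locus over a fixed universe."""

    locus_ids: tuple[str, ...]
    frameshift_mutated: tuple[bool, ...]
    universe_size: int = MSI_LOCUS_UNIVERSE

    def __post_init__(self) -> None:
        if len(self.locus_ids) != len(set(self.locus_ids)):
            raise ValueError("locus ids must be unique")
        if len(self.locus_ids) != len(self.frameshift_mutated):
            raise ValueError("locus_ids and frameshift_mutated length mismatch")

    @property
    def complete(self) -> bool:
        return len(self.locus_ids) == self.universe_size

    @property
    def frameshift_count(self) -> int:
        return int(sum(self.frameshift_mutated))


@dataclass(frozen=True)
class LohSegment:
    segment_id: int
    chrom: str
    start: int  # half-open genomic interval
    end: int
    het_snp_count: int
    mean_depth: float
    loh: bool | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def length_mb(self) -> float:
        return (self.end - self.start) / 1e6


@dataclass(frozen=True)
class LohSegmentTable:
    segments: tuple[LohSegment, ...]
    snps_read: int = 0
    sample_depth: float = 0.0
    universe_size: int = LOH_SEGMENT_UNIVERSE

    def __post_init__(self) -> None:
        ids = [s.segment_id for s in self.segments]
        if len(ids) != len(set(ids)):
            raise ValueError("segment ids must be unique")

    @property
    def loh_count(self) -> int:
        if any(s.loh is None for s in self.segments):
            raise ValueError("unresolved LoH booleans; derive with segment_loh_from_baf first")
        return sum(bool(s.loh) for s in self.segments)


@dataclass(frozen=True)
class CnSegment:
    chrom: str
    start: int
    end: int
    copy_state: str  # loss | neutral | gain

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if self.copy_state not in ("loss", "neutral", "gain"):
            raise ValueError(f"unknown copy state {self.copy_state!r}")

    @property
    def length_mb(self) -> float:
        return (self.end - self.start) / 1e6


@dataclass(frozen=True)
class SignatureResult:
    msi_status: str
    tmb_value: float
    tmb_class: str
    tmb_eligible_count: int
    loh_percent: float | None
    loh_class: str
    lst_count: int
    gss: float
    gss_formula_assumed: bool
    hrd_call: str
    brca_status: str
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return self.__dict__.copy()


# ---------------------------------------------------------------------------
# callers


def call_msi(
    table: MsiLocusTable, threshold_loci: int = 39, allow_incomplete: bool = False
) -> str:
    """MSI-high iff the frameshift-mutated locus count meets the threshold."""
    if not table.complete and not allow_incomplete:
        return "indeterminate"
    return "MSI_high" if table.frameshift_count >= threshold_loci else "MSS"


def compute_tmb(
    variants: list[VariantRecord], panel_mb: float = 30.0, cutoff: float = 10.0
) -> tuple[float, str, int]:
    """Tumor mutational burden in mutations per megabase.

    Eligible mutations are the non-synonymous classes (missense, nonsense,
    in-frame indel, frameshift) with no prior germline evidence (dbSNP151,
    gnomAD AC>0, curated-benign). Class is high at >= ``cutoff`` mut/Mb
    (boundary inclusive). The panel footprint in Mb is a required
    denominator; 30 Mb approximates a whole-exome footprint.
    """
    if panel_mb <= 0:
        raise ValueError("panel_mb must be positive")
    eligible = sum(
        1
        for v in variants
        if v.consequence in ELIGIBLE_CONSEQUENCES and not v.germline_evidence
    )
    tmb = eligible / panel_mb
    return tmb, ("high" if tmb >= cutoff else "not_high"), eligible


def segment_loh_from_baf(
    het_snp_bafs: dict[int, np.ndarray],
    major_fraction_threshold: float = 0.75,
    min_snps_per_mb: float = 17.0,
    segment_lengths_mb: dict[int, float] | None = None,
) -> tuple[dict[int, bool], list[int]]:
    """Flag each segment LoH from its heterozygous-SNP allele fractions.

    A segment is LoH when the mean major-allele fraction
    (``max(baf, 1-baf)`` per SNP) is >= the threshold. Segments under the
    SNP-density target are returned in a low-confidence list; segments
    with zero SNPs are unevaluable and raise. This per-segment rule is an
    assumption of this package, isolated here so precomputed booleans can
    bypass it.
    """
    flags: dict[int, bool] = {}
    low_confidence: list[int] = []
    for seg_id, bafs in het_snp_bafs.items():
        bafs = np.asarray(bafs, dtype=float)
        if bafs.size == 0:
            raise ValueError(f"segment {seg_id} has no heterozygous SNPs; unevaluable")
        major = np.maximum(bafs, 1.0 - bafs)
        flags[seg_id] = bool(major.mean() >= major_fraction_threshold)
        if segment_lengths_mb is not None:
            density = bafs.size / segment_lengths_mb[seg_id]
            if density < min_snps_per_mb:
                low_confidence.append(seg_id)
    return flags, low_confidence


def call_genomic_loh(
    table: LohSegmentTable, min_snps: int = 3000, min_depth: float = 200.0
) -> tuple[float | None, str]:
    """Genomic LoH percent over the fixed segment map and its class.

    The percent is classified after rounding to the nearest integer
    percent: High >= 16, Equivocal 11-15, Low < 11; QC failure
    (snps_read <= min_snps or depth < min_depth) is Indeterminate.
    """
    if table.snps_read <= min_snps or table.sample_depth < min_depth:
        return None, "Indeterminate"
    pct = 100.0 * table.loh_count / table.universe_size
    rounded = int(np.floor(pct + 0.5))  # half-up
    if rounded >= 16:
        cls = "High"
    elif rounded >= 11:
        cls = "Equivocal"
    else:
        cls = "Low"
    return pct, cls


def count_lst(segments: list[CnSegment]) -> int:
    """Large-scale state transitions: loss segments strictly > 10 Mb."""
    by_chrom: dict[str, list[CnSegment]] = {}
    for s in segments:
        if s.copy_state == "loss":
            by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, losses in by_chrom.items():
        losses = sorted(losses, key=lambda s: s.start)
        for a, b in zip(losses, losses[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping loss segments on {chrom}")
    return sum(
        1 for s in segments if s.copy_state == "loss" and s.length_mb > 10.0
    )


def default_gss(loh_segment_count: int, lst_count: int) -> float:
    """Assumed GSS combination: LoH percent-of-map plus LST count."""
    return 100.0 * loh_segment_count / LOH_SEGMENT_UNIVERSE + float(lst_count)


def compute_gss(
    loh_segment_count: int,
    lst_count: int,
    w_loh: float = 100.0 / LOH_SEGMENT_UNIVERSE,
    w_lst: float = 1.0,
    formula: Callable[[int, int], float] | None = None,
) -> tuple[float, bool]:
    """Genomic scar score from LoH and LST evidence.

    Returns ``(gss, formula_assumed)``. The default linear combination
    (normalized LoH segment count + LST count) is an assumption — the
    published rule specifies only that both contribute — so the flag is
    True unless a caller-supplied formula is used, in which case its
    provenance is the caller's.
    """
    if loh_segment_count < 0 or lst_count < 0:
        raise ValueError("inputs must be non-negative")
    if formula is not None:
        return float(formula(loh_segment_count, lst_count)), True
    if w_loh < 0 or w_lst < 0:
        raise ValueError("weights must be non-negative")
    return w_loh * loh_segment_count + w_lst * lst_count, True


def call_hrd(gss: float | None, brca_status: str, gss_cutoff: float = 46.0) -> str:
    """HRD positive iff BRCA1/2 pathogenic OR GSS >= cutoff (inclusive)."""
    if brca_status not in ("pathogenic", "wild_type", "unknown"):
        raise ValueError(f"unknown brca_status {brca_status!r}")
    if brca_status == "pathogenic":
        return "positive"
    if gss is None:
        if brca_status == "unknown":
            raise ValueError("indeterminate: GSS missing and BRCA status unknown")
        raise ValueError("indeterminate: GSS missing for BRCA wild-type sample")
    return "positive" if gss >= gss_cutoff else "negative"


def classify_cna(
    copies: float, amp_threshold: float = 8.3, lod_copies: float = 8.3
) -> str:
    """Classify an estimated gene copy number.

    Amplified when copies reach both the caller threshold and the
    analytically reliable bound (the copies LoD); copies meeting the
    threshold but under the LoD are below_lod (unreliable); anything else
    is not_amplified.
    """
    if copies < 0:
        raise ValueError("copies must be non-negative")
    if copies >= max(amp_threshold, lod_copies):
        return "amplified"
    if copies >= amp_threshold:
        return "below_lod"
    return "not_amplified"


def call_signatures(
    variants: list[VariantRecord],
    msi_table: MsiLocusTable,
    loh_table: LohSegmentTable,
    cn_segments: list[CnSegment],
    brca_status: str = "unknown",
    panel_mb: float = 30.0,
    msi_threshold: int = 39,
    tmb_cutoff: float = 10.0,
    gss_cutoff: float = 46.0,
) -> SignatureResult:
    """Run every signature caller on one sample's tables."""
    msi = call_msi(msi_table, threshold_loci=msi_threshold)
    tmb_value, tmb_class, eligible = compute_tmb(variants, panel_mb, tmb_cutoff)
    loh_percent, loh_class = call_genomic_loh(loh_table)
    lst = count_lst(cn_segments)
    gss, assumed = compute_gss(loh_table.loh_count, lst)
    if brca_status == "unknown" and gss is None:
        hrd = "indeterminate"
    else:
        hrd = call_hrd(gss, brca_status, gss_cutoff)
    return SignatureResult(
        msi_status=msi,
        tmb_value=tmb_value,
        tmb_class=tmb_class,
        tmb_eligible_count=eligible,
        loh_percent=loh_percent,
        loh_class=loh_class,
        lst_count=lst,
        gss=gss,
        gss_formula_assumed=assumed,
        hrd_call=hrd,
        brca_status=brca_status,
        thresholds={
            "msi_threshold_loci": msi_threshold,
            "tmb_cutoff": tmb_cutoff,
            "gss_cutoff": gss_cutoff,
            "panel_mb": panel_mb,
        },
    )
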