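"""File formats, run configuration and report rendering.

Tabular inputs are tab- or comma-separated text with required headers;
variants travel as a minimal VCFv4.2 subset (INFO keys VF, DP, CSQCLASS,
GERMDB, GENE) read back through pysam. JSON outputs embed the seed and a
hash of the configuration so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import pysam

from .analytical import BlankPanel, DilutionSeries, PrecisionPanel
from .calls import PairedCallTable, filter_invalid
from .concordance import (
    PrevalenceSpec,
    all_agreements,
    bootstrap_zeta_ci,
    noninferiority_decision,
    prevalence_adjust,
)
from .signatures import CnSegment, LohSegment, LohSegmentTable, VariantRecord

__all__ = [
    "RunConfig",
    "read_calls",
    "read_variants_csv",
    "read_variants_vcf",
    "write_variants_vcf",
    "read_loh_segments",
    "read_cn_segments",
    "read_series",
    "read_precision_panel",
    "read_blank_panel",
    "render_report",
    "config_hash",
    "run_concordance_study",
]

_CALL_ALIASES = {
    "pos": "positive",
    "positive": "positive",
    "neg": "negative",
    "negative": "negative",
    "invalid": "invalid",
    "inv": "invalid",
}
_STRATUM_ALIASES = {
    "pretest_positive": "pretest_positive",
    "pretest_negative": "pretest_negative",
    "unenriched": "unenriched",
}


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and knobs for a concordance run, JSON-loadable."""

    delta1: float = 0.05
    delta0: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    level: float = 0.95
    prevalence: float | None = None
    invalid_policy: str = "exclude"
    ci_method: str = "wilson"
    swap_epsilon_mapping: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.delta1 <= 1 or not 0 < self.delta0 <= 1:
            raise ValueError("non-inferiority margins must be in (0, 1]")
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        if not 0 < self.level < 1:
            raise ValueError("confidence level must be in (0, 1)")
        if self.prevalence is not None and not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.invalid_policy not in ("exclude", "best_case", "worst_case"):
            raise ValueError(f"unknown invalid policy {self.invalid_policy!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# tabular readers


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, dtype=str)


def read_calls(path: str | Path) -> PairedCallTable:
    """Read a paired-call TSV/CSV (sample_id, ccd1, ccd2, fcd, stratum).

    Call values POS/NEG/INVALID (case-insensitive, full words accepted);
    malformed rows are reported with their line number.
    """
    df = _read_table(path)
    required = ["sample_id", "ccd1", "ccd2", "fcd", "stratum"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: schema mismatch, missing columns {missing}")
    for col in ("ccd1", "ccd2", "fcd"):
        vals = df[col].str.strip().str.lower()
        bad = ~vals.isin(_CALL_ALIASES)
        if bad.any():
            i = int(bad.idxmax())
            raise ValueError(
                f"{path}: line {i + 2}: unknown call value {df.at[i, col]!r} in column {col}"
            )
        df[col] = vals.map(_CALL_ALIASES)
    vals = df["stratum"].str.strip().str.lower()
    bad = ~vals.isin(_STRATUM_ALIASES)
    if bad.any():
        i = int(bad.idxmax())
        raise ValueError(f"{path}: line {i + 2}: unknown stratum {df.at[i, 'stratum']!r}")
    df["stratum"] = vals.map(_STRATUM_ALIASES)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    return PairedCallTable(df)


def read_series(path: str | Path) -> list[DilutionSeries]:
    """Dilution-series CSV/TSV: analyte_id, level, detected, replicates."""
    df = _read_table(path)
    out = []
    for analyte, sub in df.groupby("analyte_id", sort=True):
        sub = sub.astype({"level": float, "detected": int, "replicates": int})
        sub = sub.sort_values("level")
        out.append(
            DilutionSeries(
                analyte_id=str(analyte),
                levels=tuple(sub["level"]),
                detected=tuple(sub["detected"]),
                replicates=tuple(sub["replicates"]),
            )
        )
    return out


def read_precision_panel(path: str | Path, factors: tuple[str, ...] | None = None) -> PrecisionPanel:
    df = _read_table(path)
    df["value"] = df["value"].astype(float)
    if factors is None:
        return PrecisionPanel(df)
    return PrecisionPanel(df, factors=factors)


def read_blank_panel(path: str | Path) -> BlankPanel:
    df = _read_table(path)
    df = df.astype({"false_positive_calls": int, "opportunities": int})
    return BlankPanel(df)


def read_loh_segments(
    path: str | Path, snps_read: int, sample_depth: float
) -> LohSegmentTable:
    """BED-like TSV: segment_id, chrom, start, end, het_snp_count, mean_depth, loh."""
    df = _read_table(path)
    segs = tuple(
        LohSegment(
            segment_id=int(r.segment_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            het_snp_count=int(r.het_snp_count),
            mean_depth=float(r.mean_depth),
            loh={"true": True, "false": False}[str(r.loh).strip().lower()],
        )
        for r in df.itertuples()
    )
    return LohSegmentTable(segments=segs, snps_read=snps_read, sample_depth=sample_depth)


def read_cn_segments(path: str | Path) -> list[CnSegment]:
    """BED-like TSV: chrom, start, end, state."""
    df = _read_table(path)
    return [
        CnSegment(chrom=str(r.chrom), start=int(r.start), end=int(r.end), copy_state=str(r.state))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# variants: CSV and minimal VCF


def read_variants_csv(path: str | Path) -> list[VariantRecord]:
    """CSV/TSV with chrom, pos, ref, alt, vf, depth, consequence, germline_flags."""
    df = _read_table(path)
    out = []
    for i, r in enumerate(df.itertuples()):
        flags = getattr(r, "germline_flags", "") or ""
        flagset = frozenset(f for f in str(flags).split(";") if f and f != "nan")
        try:
            out.append(
                VariantRecord(
                    chrom=str(r.chrom),
                    pos=int(r.pos),
                    ref=str(r.ref),
                    alt=str(r.alt),
                    vf=float(r.vf),
                    depth=int(r.depth),
                    consequence=str(r.consequence),
                    germline_evidence=flagset,
                    gene=str(getattr(r, "gene", "")),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return out


def write_variants_vcf(variants: list[VariantRecord], path: str | Path) -> None:
    """Write a minimal, uncompressed VCFv4.2 with per-record INFO annotations."""
    chroms = sorted({v.chrom for v in variants})
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=VF,Number=1,Type=Float,Description="Variant frequency">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=CSQCLASS,Number=1,Type=String,Description="Consequence class">',
        '##INFO=<ID=GERMDB,Number=.,Type=String,Description="Germline evidence flags">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    ]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        info = [f"VF={v.vf:.6g}", f"DP={v.depth}", f"CSQCLASS={v.consequence}"]
        if v.germline_evidence:
            info.append("GERMDB=" + ",".join(sorted(v.germline_evidence)))
        if v.gene:
            info.append(f"GENE={v.gene}")
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t" + ";".join(info)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_variants_vcf(path: str | Path) -> list[VariantRecord]:
    """Read the minimal VCF subset back into VariantRecords (via pysam)."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            flags = rec.info.get("GERMDB", ())
            if isinstance(flags, str):
                flags = (flags,)
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    vf=float(rec.info["VF"]),
                    depth=int(rec.info["DP"]),
                    consequence=str(rec.info["CSQCLASS"]),
                    germline_evidence=frozenset(flags),
                    gene=str(rec.info.get("GENE", "")),
                )
            )
    return out


# ---------------------------------------------------------------------------
# high-level concordance run + report


def run_concordance_study(table: PairedCallTable, config: RunConfig) -> dict:
    """Full concordance analysis: filter, agreements, zetas, decision.

    Returns a JSON-serializable document with the filter summary, the
    eight component agreements, bootstrap zeta CIs, the non-inferiority
    decision and (when a prevalence is configured) the enrichment-adjusted
    PPA/NPA.
    """
    filtered = filter_invalid(table, config.invalid_policy)
    agreements = all_agreements(filtered, ci_method=config.ci_method, level=config.level)
    zetas = bootstrap_zeta_ci(
        filtered, n_boot=config.n_boot, level=config.level, seed=config.seed
    )
    decision = noninferiority_decision(
        zetas, config.delta1, config.delta0, swap_mapping=config.swap_epsilon_mapping
    )
    doc = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "filter_summary": filtered.filter_summary.__dict__,
        "agreements": {k: v.to_dict() for k, v in agreements.items()},
        "zetas": zetas.to_dict(),
        "noninferiority": decision.to_dict(),
    }
    if config.prevalence is not None:
        adj = prevalence_adjust(filtered, PrevalenceSpec(config.prevalence))
        doc["prevalence_adjusted"] = adj.to_dict()
    return doc


def render_report(results: dict, style: str = "json") -> str:
    """Render an analysis document as canonical JSON or a summary table.

    The text table mirrors the validation-summary layout: biomarker, N,
    PPA (95% CI), NPA (95% CI), one-decimal percentages. ``results`` maps
    a biomarker name to its analysis document for the table style; for
    JSON any serializable document is accepted and key order is stable.
    """
    if style == "json":
        return json.dumps(results, sort_keys=True, indent=2)
    if style != "text_table":
        raise ValueError(f"unknown report style {style!r}")

    def fmt(a: dict) -> str:
        return (
            f"{100 * a['numerator'] / a['denominator']:.1f}% "
            f"({100 * a['ci_low']:.1f}, {100 * a['ci_high']:.1f})"
        )

    header = f"{'Biomarker':<28}{'N':>6}  {'PPA (95% CI)':<24}{'NPA (95% CI)':<24}"
    lines = [header, "-" * len(header)]
    for name, doc in results.items():
        ags = doc.get("agreements", {})
        ppa = ags.get("PPA_C1F")
        npa = ags.get("NPA_C1F")
        n = doc.get("filter_summary", {}).get("n_output", "")
        lines.append(
            f"{name:<28}{n:>6}  "
            f"{fmt(ppa) if ppa else 'N/A':<24}{fmt(npa) if npa else 'N/A':<24}"
        )
    return "\n".join(lines)
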