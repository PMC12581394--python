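"""Synthetic study generators with known ground truth.

Every input the statistics and callers consume can be simulated here:
enriched paired-call cohorts with latent biomarker truth, logistic
detection-vs-concentration dilution series, crossed random-effects
precision panels, and per-sample signature tables. Truth is always
returned alongside the data so the estimators can be checked against it,
and closed-form population agreement values are available for the
concordance design.

Default conditions mirror the validation study design: cohorts of a few
hundred samples enriched to roughly half pre-test positives (positive
samples enrolled consecutively, matched by an equal number of negatives),
arm accuracies in the high-90s consistent with the reported >97%
agreements, a 36-replicate precision design (3 operator/instrument teams
x 3 reagent lots x 4 run days), and 20 replicates per dilution level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analytical import DilutionSeries, PrecisionPanel
from .calls import PairedCallTable
from .signatures import (
    CnSegment,
    LOH_SEGMENT_UNIVERSE,
    LohSegment,
    LohSegmentTable,
    MSI_LOCUS_UNIVERSE,
    MsiLocusTable,
    VariantRecord,
    call_genomic_loh,
    call_hrd,
    compute_gss,
)

__all__ = [
    "ConcordanceSimSpec",
    "SignatureSimSpec",
    "simulate_concordance_cohort",
    "theoretical_agreements",
    "simulate_dilution_series",
    "simulate_precision_panel",
    "simulate_signature_sample",
]


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")


# ---------------------------------------------------------------------------
# concordance cohorts


@dataclass(frozen=True)
class ConcordanceSimSpec:
    """Generative model of the paired-comparator concordance design.

    Latent biomarker truth is drawn at ``prevalence`` (within enrollment
    strata when ``enrichment`` is set), each arm calls it with its
    sensitivity/specificity, and the two comparator replicates share an
    error event with probability ``ccd_dependence`` (a mixture model:
    correlation between replicate errors equals the dependence parameter,
    attainable over [0, 1]). Invalid calls are injected independently per
    arm. ``enrichment=None`` gives the unenriched, consecutively-enrolled
    design.
    """

    n_samples: int = 400
    prevalence: float = 0.5
    ccd_sensitivity: float = 0.97
    ccd_specificity: float = 0.99
    fcd_sensitivity: float = 0.97
    fcd_specificity: float = 0.99
    ccd_dependence: float = 0.0
    invalid_rate_ccd: float = 0.0
    invalid_rate_fcd: float = 0.0
    enrichment: float | None = 0.5
    pretest_sensitivity: float = 0.95
    pretest_specificity: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name in (
            "prevalence",
            "ccd_sensitivity",
            "ccd_specificity",
            "fcd_sensitivity",
            "fcd_specificity",
            "invalid_rate_ccd",
            "invalid_rate_fcd",
            "pretest_sensitivity",
            "pretest_specificity",
        ):
            _check_prob(name, getattr(self, name))
        if not 0.0 <= self.ccd_dependence <= 1.0:
            raise ValueError(
                "ccd_dependence outside the attainable range [0, 1] of the "
                "shared-error mixture model"
            )
        if self.enrichment is not None:
            _check_prob("enrichment", self.enrichment)

    def stratum_truth_probs(self) -> dict[str, tuple[float, float]]:
        """{stratum: (weight, P(truth positive | stratum))}."""
        pi = self.prevalence
        if self.enrichment is None:
            return {"unenriched": (1.0, pi)}
        se, sp = self.pretest_sensitivity, self.pretest_specificity
        p_pre_pos = pi * se + (1 - pi) * (1 - sp)
        p_pre_neg = 1 - p_pre_pos
        if p_pre_pos == 0 or p_pre_neg == 0:
            raise ValueError("degenerate pre-test marker: one stratum has probability 0")
        t_pos = pi * se / p_pre_pos
        t_neg = pi * (1 - se) / p_pre_neg
        return {
            "pretest_positive": (self.enrichment, t_pos),
            "pretest_negative": (1 - self.enrichment, t_neg),
        }


def simulate_concordance_cohort(
    spec: ConcordanceSimSpec, rng: np.random.Generator | None = None
) -> tuple[PairedCallTable, pd.DataFrame]:
    """Draw a cohort; returns the call table and the latent truth record."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    strata = spec.stratum_truth_probs()
    rows = []
    names, weights = zip(*((s, w) for s, (w, _) in strata.items()))
    counts = np.round(np.asarray(weights) * spec.n_samples).astype(int)
    # rounding drift goes to the first stratum
    counts[0] += spec.n_samples - counts.sum()
    i = 0
    for stratum, n_s in zip(names, counts):
        t_prob = strata[stratum][1]
        truth = rng.random(n_s) < t_prob
        p_ccd = np.where(truth, spec.ccd_sensitivity, 1 - spec.ccd_specificity)
        p_fcd = np.where(truth, spec.fcd_sensitivity, 1 - spec.fcd_specificity)
        shared = rng.random(n_s) < spec.ccd_dependence
        u_shared = rng.random(n_s)
        u1, u2, uf = rng.random((3, n_s))
        c1 = np.where(shared, u_shared < p_ccd, u1 < p_ccd)
        c2 = np.where(shared, u_shared < p_ccd, u2 < p_ccd)
        f = uf < p_fcd
        inv1, inv2 = rng.random((2, n_s)) < spec.invalid_rate_ccd
        invf = rng.random(n_s) < spec.invalid_rate_fcd
        for k in range(n_s):
            rows.append(
                {
                    "sample_id": f"S{i:06d}",
                    "ccd1": "invalid" if inv1[k] else ("positive" if c1[k] else "negative"),
                    "ccd2": "invalid" if inv2[k] else ("positive" if c2[k] else "negative"),
                    "fcd": "invalid" if invf[k] else ("positive" if f[k] else "negative"),
                    "stratum": stratum,
                    "truth": bool(truth[k]),
                }
            )
            i += 1
    df = pd.DataFrame(rows)
    truth_df = df[["sample_id", "stratum", "truth"]].copy()
    table = PairedCallTable(df.drop(columns="truth"))
    return table, truth_df


def theoretical_agreements(spec: ConcordanceSimSpec) -> dict[str, float]:
    """Exact population agreements and zetas under the generative model.

    Computed by total probability over the stratum mixture and the latent
    truth, using the shared-error mixture for the comparator replicate
    pair and conditional independence for FCD. Invalid injection is
    independent of the calls, so the valid-only conditional agreements are
    unchanged by exclusion.
    """

    def arm_p(truth: bool, arm: str) -> float:
        if arm == "fcd":
            return spec.fcd_sensitivity if truth else 1 - spec.fcd_specificity
        return spec.ccd_sensitivity if truth else 1 - spec.ccd_specificity

    dep = spec.ccd_dependence
    strata = spec.stratum_truth_probs()

    def mix(fn) -> float:
        total = 0.0
        for w, t in strata.values():
            total += w * (t * fn(True) + (1 - t) * fn(False))
        return total

    def joint_cc(pos: bool) -> float:
        # P(C1 = C2 = pos-or-neg side | mixture)
        def f(truth: bool) -> float:
            p = arm_p(truth, "ccd1")
            p = p if pos else 1 - p
            return dep * p + (1 - dep) * p * p

        return mix(f)

    def joint_cf(arm: str, pos: bool) -> float:
        def f(truth: bool) -> float:
            pc = arm_p(truth, arm)
            pf = arm_p(truth, "fcd")
            return (pc if pos else 1 - pc) * (pf if pos else 1 - pf)

        return mix(f)

    def marginal(arm: str, pos: bool) -> float:
        def f(truth: bool) -> float:
            p = arm_p(truth, arm)
            return p if pos else 1 - p

        return mix(f)

    out: dict[str, float] = {}
    for pol, pos in (("PPA", True), ("NPA", False)):
        cc = joint_cc(pos)
        m_c = marginal("ccd1", pos)  # both CCD arms share the marginal
        out[f"{pol}_C1C2"] = cc / m_c
        out[f"{pol}_C2C1"] = cc / m_c
        out[f"{pol}_C1F"] = joint_cf("ccd1", pos) / m_c
        out[f"{pol}_C2F"] = joint_cf("ccd2", pos) / m_c
    out["zeta_ppa1"] = out["PPA_C1C2"] - out["PPA_C1F"]
    out["zeta_ppa2"] = out["PPA_C2C1"] - out["PPA_C2F"]
    out["zeta_npa1"] = out["NPA_C1C2"] - out["NPA_C1F"]
    out["zeta_npa2"] = out["NPA_C2C1"] - out["NPA_C2F"]
    return out


# ---------------------------------------------------------------------------
# dilution series


def simulate_dilution_series(
    true_lod_level: float,
    slope: float,
    levels: list[float],
    replicates: int = 20,
    analyte_id: str = "analyte",
    seed: int | np.random.Generator = 0,
) -> DilutionSeries:
    """Bernoulli detection along a logistic curve.

    The curve is parameterized so its 95%-detection quantile sits exactly
    at ``true_lod_level``: p(level) = logistic(slope * (level - m)) with
    m = true_lod_level - logit(0.95)/slope. ``slope=inf`` gives the step
    function (detect iff level >= true LoD).
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be sorted strictly ascending")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lv = np.asarray(levels, dtype=float)
    if np.isinf(slope):
        p = (lv >= true_lod_level).astype(float)
    else:
        m = true_lod_level - np.log(0.95 / 0.05) / slope
        p = 1.0 / (1.0 + np.exp(-slope * (lv - m)))
    detected = rng.binomial(replicates, p)
    return DilutionSeries(
        analyte_id=analyte_id,
        levels=tuple(float(x) for x in lv),
        detected=tuple(int(d) for d in detected),
        replicates=tuple([replicates] * len(lv)),
    )


# ---------------------------------------------------------------------------
# precision panels


def simulate_precision_panel(
    mean: float,
    sigma_operator: float = 0.0,
    sigma_lot: float = 0.0,
    sigma_run: float = 0.0,
    sigma_resid: float = 1.0,
    n_operators: int = 3,
    n_lots: int = 3,
    n_days: int = 4,
    n_replicates: int = 1,
    panel_member: str = "member",
    seed: int | np.random.Generator = 0,
) -> PrecisionPanel:
    """Crossed random-effects draws for one panel member.

    Additive effects per operator/instrument team, reagent lot and run
    day, plus an independent residual per replicate. The default
    3 x 3 x 4 x 1 design yields the 36 replicates of the precision study.
    """
    for name, s in (
        ("sigma_operator", sigma_operator),
        ("sigma_lot", sigma_lot),
        ("sigma_run", sigma_run),
        ("sigma_resid", sigma_resid),
    ):
        if s < 0:
            raise ValueError(f"{name} must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    op_eff = rng.normal(0, sigma_operator, n_operators)
    lot_eff = rng.normal(0, sigma_lot, n_lots)
    day_eff = rng.normal(0, sigma_run, n_days)
    rows = []
    for o in range(n_operators):
        for l in range(n_lots):
            for d in range(n_days):
                resid = rng.normal(0, sigma_resid, n_replicates)
                for r in range(n_replicates):
                    rows.append(
                        {
                            "panel_member": panel_member,
                            "value": mean + op_eff[o] + lot_eff[l] + day_eff[d] + resid[r],
                            "operator_instrument": f"op{o + 1}",
                            "reagent_lot": f"lot{l + 1}",
                            "run_day": f"day{d + 1}",
                            "replicate": r + 1,
                        }
                    )
    return PrecisionPanel(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# signature samples


@dataclass(frozen=True)
class SignatureSimSpec:
    """Counts that pin down one sample's signature truth."""

    msi_frameshift_count: int = 0
    eligible_mutation_count: int = 0
    germline_flagged_count: int = 0
    synonymous_count: int = 0
    panel_mb: float = 30.0
    loh_segment_count: int = 0
    lst_loss_lengths_mb: tuple[float, ...] = ()
    cn_gain_count: int = 0
    brca_status: str = "wild_type"
    snps_read: int = 250_000
    sample_depth: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.msi_frameshift_count <= MSI_LOCUS_UNIVERSE:
            raise ValueError(
                f"msi_frameshift_count must be within the {MSI_LOCUS_UNIVERSE}-locus universe"
            )
        if not 0 <= self.loh_segment_count <= LOH_SEGMENT_UNIVERSE:
            raise ValueError(
                f"loh_segment_count must be within the {LOH_SEGMENT_UNIVERSE}-segment map"
            )
        for name in ("eligible_mutation_count", "germline_flagged_count", "synonymous_count", "cn_gain_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.panel_mb <= 0:
            raise ValueError("panel_mb must be positive")
        if any(length <= 0 for length in self.lst_loss_lengths_mb):
            raise ValueError("loss segment lengths must be positive")
        if self.brca_status not in ("pathogenic", "wild_type", "unknown"):
            raise ValueError(f"unknown brca_status {self.brca_status!r}")


_ELIGIBLE_CYCLE = ("missense", "nonsense", "inframe_indel", "frameshift")
_GERMLINE_CYCLE = ("dbsnp151", "gnomad_ac_gt0", "curated_benign")
_BASES = ("A", "C", "G", "T")


def simulate_signature_sample(
    spec: SignatureSimSpec,
) -> tuple[list[VariantRecord], MsiLocusTable, LohSegmentTable, list[CnSegment], dict]:
    """Emit per-sample tables whose deterministic signature calls match the
    spec's intended truth; the truth dict is returned last."""
    rng = np.random.default_rng(spec.seed)

    # variants
    variants: list[VariantRecord] = []

    def _variant(consequence: str, flags: frozenset[str]) -> VariantRecord:
        ref = _BASES[rng.integers(4)]
        alt = _BASES[(list(_BASES).index(ref) + 1 + rng.integers(3)) % 4]
        return VariantRecord(
            chrom=f"chr{int(rng.integers(1, 23))}",
            pos=int(rng.integers(1, 200_000_000)),
            ref=ref,
            alt=alt,
            vf=float(rng.uniform(0.05, 0.5)),
            depth=int(rng.integers(200, 1500)),
            consequence=consequence,
            germline_evidence=flags,
            gene=f"GENE{int(rng.integers(1, 500))}",
        )

    for k in range(spec.eligible_mutation_count):
        variants.append(_variant(_ELIGIBLE_CYCLE[k % 4], frozenset()))
    for k in range(spec.germline_flagged_count):
        variants.append(_variant(_ELIGIBLE_CYCLE[k % 4], frozenset({_GERMLINE_CYCLE[k % 3]})))
    for _ in range(spec.synonymous_count):
        variants.append(_variant("synonymous", frozenset()))

    # MSI loci
    mutated = np.zeros(MSI_LOCUS_UNIVERSE, dtype=bool)
    mutated[rng.choice(MSI_LOCUS_UNIVERSE, spec.msi_frameshift_count, replace=False)] = True
    msi_table = MsiLocusTable(
        locus_ids=tuple(f"MSI{k:04d}" for k in range(MSI_LOCUS_UNIVERSE)),
        frameshift_mutated=tuple(bool(b) for b in mutated),
    )

    # LoH segment map: 552 segments of 2-6 Mb tiled across chromosomes
    loh_flags = np.zeros(LOH_SEGMENT_UNIVERSE, dtype=bool)
    loh_flags[rng.choice(LOH_SEGMENT_UNIVERSE, spec.loh_segment_count, replace=False)] = True
    segments = []
    pos = 1_000_000
    for k in range(LOH_SEGMENT_UNIVERSE):
        length = int(rng.uniform(2e6, 6e6))
        chrom = f"chr{k % 22 + 1}"
        segments.append(
            LohSegment(
                segment_id=k + 1,
                chrom=chrom,
                start=pos,
                end=pos + length,
                het_snp_count=int(17 * length / 1e6 + rng.integers(0, 20)),
                mean_depth=float(rng.uniform(250, 600)),
                loh=bool(loh_flags[k]),
            )
        )
        pos += length + 100_000
    loh_table = LohSegmentTable(
        segments=tuple(segments),
        snps_read=spec.snps_read,
        sample_depth=spec.sample_depth,
    )

    # copy-number segments: each loss on its own coordinate block, plus gains
    cn_segments: list[CnSegment] = []
    pos = 5_000_000
    for k, length in enumerate(spec.lst_loss_lengths_mb):
        cn_segments.append(
            CnSegment(chrom=f"chr{k % 22 + 1}", start=pos, end=pos + int(length * 1e6), copy_state="loss")
        )
        pos += int(length * 1e6) + 20_000_000
    for k in range(spec.cn_gain_count):
        cn_segments.append(
            CnSegment(chrom=f"chr{k % 22 + 1}", start=pos, end=pos + 5_000_000, copy_state="gain")
        )
        pos += 25_000_000

    lst_true = sum(1 for length in spec.lst_loss_lengths_mb if length > 10.0)
    tmb_true = spec.eligible_mutation_count / spec.panel_mb
    loh_percent, loh_class = call_genomic_loh(loh_table)
    gss, _ = compute_gss(spec.loh_segment_count, lst_true)
    truth = {
        "msi_status": "MSI_high" if spec.msi_frameshift_count >= 39 else "MSS",
        "tmb_value": tmb_true,
        "tmb_class": "high" if tmb_true >= 10.0 else "not_high",
        "tmb_eligible_count": spec.eligible_mutation_count,
        "loh_percent": loh_percent,
        "loh_class": loh_class,
        "lst_count": lst_true,
        "gss": gss,
        "hrd_call": call_hrd(gss, spec.brca_status)
        if not (spec.brca_status == "unknown" and gss is None)
        else "indeterminate",
        "brca_status": spec.brca_status,
    }
    return variants, msi_table, loh_table, cn_segments, truth
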