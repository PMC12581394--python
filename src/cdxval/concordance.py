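"""Agreement statistics and the non-inferiority decision for follow-on CDx studies.

With no reference standard, a follow-on companion diagnostic (FCD) is
validated against two replicates of the approved comparator (CCD1, CCD2).
Eight pairwise agreements are formed (PPA and NPA for each ordered arm
pair), and four differences compare replicate-to-replicate agreement with
FCD-to-replicate agreement::

    zeta_PPA1 = PPA_C1C2 - PPA_C1F      zeta_PPA2 = PPA_C2C1 - PPA_C2F
    zeta_NPA1 = NPA_C1C2 - NPA_C1F      zeta_NPA2 = NPA_C2C1 - NPA_C2F

A positive zeta means the comparator agrees with itself better than the
new test agrees with the comparator. Non-inferiority holds on a side when
the maximum upper 95% CI limit (epsilon) across that side's zetas is
strictly below the pre-specified margin delta. CIs come from a percentile
bootstrap over sample triples (1000 replicates by default), or from
Newcombe's paired-difference interval for the unenriched design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calls import ARMS, NEGATIVE, POSITIVE, STRATA, PairedCallTable
from .intervals import newcombe10_ci, proportion_ci

__all__ = [
    "AgreementEstimate",
    "ZetaInterval",
    "ZetaSet",
    "NonInferiorityResult",
    "PrevalenceSpec",
    "AdjustedAgreement",
    "pairwise_agreement",
    "zeta_differences",
    "bootstrap_zeta_ci",
    "newcombe10_paired_diff_ci",
    "prevalence_adjust",
    "noninferiority_decision",
]

ZETA_NAMES = ("zeta_ppa1", "zeta_ppa2", "zeta_npa1", "zeta_npa2")


# ---------------------------------------------------------------------------
# result types


@dataclass(frozen=True)
class AgreementEstimate:
    """A single PPA/NPA/OPA with its binomial CI."""

    kind: str  # PPA | NPA | OPA
    reference_arm: str
    test_arm: str
    numerator: int
    denominator: int
    estimate: float
    ci_low: float
    ci_high: float
    ci_method: str

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("numerator must be in [0, denominator]")
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")

    @property
    def percent(self) -> float:
        return 100.0 * self.estimate

    def render(self) -> str:
        """One-decimal percentage with CI, Table-style: '92.1% (89.2, 94.4) 409/444'."""
        return (
            f"{self.percent:.1f}% ({100 * self.ci_low:.1f}, {100 * self.ci_high:.1f}) "
            f"{self.numerator}/{self.denominator}"
        )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "reference_arm": self.reference_arm,
            "test_arm": self.test_arm,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_method": self.ci_method,
        }


@dataclass(frozen=True)
class ZetaInterval:
    point: float
    ci_low: float | None = None
    ci_high: float | None = None
    method: str | None = None

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None and self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")

    def to_dict(self) -> dict:
        return {
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "method": self.method,
        }


@dataclass(frozen=True)
class ZetaSet:
    """The four agreement differences, optionally with CIs."""

    zeta_ppa1: ZetaInterval
    zeta_ppa2: ZetaInterval
    zeta_npa1: ZetaInterval
    zeta_npa2: ZetaInterval
    n_boot: int | None = None
    n_undefined_replicates: int | None = None
    seed: int | None = None

    def __getitem__(self, name: str) -> ZetaInterval:
        if name not in ZETA_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def to_dict(self) -> dict:
        d = {name: self[name].to_dict() for name in ZETA_NAMES}
        d["n_boot"] = self.n_boot
        d["n_undefined_replicates"] = self.n_undefined_replicates
        d["seed"] = self.seed
        return d


@dataclass(frozen=True)
class NonInferiorityResult:
    epsilon1: float
    epsilon0: float
    delta1: float
    delta0: float
    pass_predictive: bool
    pass_selective: bool
    pass_overall: bool

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass(frozen=True)
class PrevalenceSpec:
    """Population pre-test marker prevalence used for enrichment adjustment."""

    population_positive_prevalence: float
    sample_positive_prevalence: float | None = None

    def __post_init__(self) -> None:
        p = self.population_positive_prevalence
        if not 0.0 < p < 1.0:
            raise ValueError("population prevalence must be strictly inside (0, 1)")


@dataclass(frozen=True)
class AdjustedAgreement:
    ppa: float
    npa: float
    comparator_arm: str
    population_prevalence: float
    sample_prevalence: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


# ---------------------------------------------------------------------------
# count-space machinery
#
# After invalid filtering each row is one of 8 patterns indexed by bits
# (ccd1+, ccd2+, fcd+); all agreements are ratios of pattern-count sums,
# which lets the bootstrap run as vectorized multinomial resampling.

_BIT = {"ccd1": 4, "ccd2": 2, "fcd": 1}


def pattern_counts(table: PairedCallTable) -> np.ndarray:
    """Length-8 count vector of (ccd1, ccd2, fcd) call patterns."""
    if table.has_invalid:
        raise ValueError("table contains invalid calls; apply filter_invalid first")
    df = table.frame
    idx = np.zeros(len(df), dtype=np.int64)
    for arm, bit in _BIT.items():
        idx += bit * (df[arm] == POSITIVE).to_numpy(dtype=np.int64)
    return np.bincount(idx, minlength=8).astype(np.int64)


def _arm_mask(arm: str, positive: bool) -> np.ndarray:
    k = np.arange(8)
    m = (k & _BIT[arm]) > 0
    return m if positive else ~m


def agreement_from_counts(
    counts: np.ndarray, reference_arm: str, test_arm: str, polarity: str
) -> tuple[np.ndarray, np.ndarray]:
    """(numerator, denominator) for an agreement over pattern counts.

    ``counts`` may be a batch with shape (..., 8); sums are taken over the
    last axis, so the bootstrap evaluates all replicates in one call.
    """
    counts = np.asarray(counts)
    if polarity == "OPA":
        num = counts[..., _arm_mask(reference_arm, True) & _arm_mask(test_arm, True)].sum(axis=-1)
        num = num + counts[..., _arm_mask(reference_arm, False) & _arm_mask(test_arm, False)].sum(axis=-1)
        den = counts.sum(axis=-1)
        return num, den
    positive = polarity == "PPA"
    if not positive and polarity != "NPA":
        raise ValueError(f"unknown polarity {polarity!r}")
    ref = _arm_mask(reference_arm, positive)
    tst = _arm_mask(test_arm, positive)
    num = counts[..., ref & tst].sum(axis=-1)
    den = counts[..., ref].sum(axis=-1)
    return num, den


def _zetas_from_counts(counts: np.ndarray) -> np.ndarray:
    """Batched zetas; shape (..., 4), NaN where a component is undefined."""
    comps = {
        "zeta_ppa1": (("ccd1", "ccd2", "PPA"), ("ccd1", "fcd", "PPA")),
        "zeta_ppa2": (("ccd2", "ccd1", "PPA"), ("ccd2", "fcd", "PPA")),
        "zeta_npa1": (("ccd1", "ccd2", "NPA"), ("ccd1", "fcd", "NPA")),
        "zeta_npa2": (("ccd2", "ccd1", "NPA"), ("ccd2", "fcd", "NPA")),
    }
    out = []
    with np.errstate(invalid="ignore", divide="ignore"):
        for (r1, t1, p1), (r2, t2, p2) in comps.values():
            n1, d1 = agreement_from_counts(counts, r1, t1, p1)
            n2, d2 = agreement_from_counts(counts, r2, t2, p2)
            z = n1 / d1 - n2 / d2
            out.append(np.where((d1 > 0) & (d2 > 0), z, np.nan))
    return np.stack(out, axis=-1)


# ---------------------------------------------------------------------------
# public operations


def pairwise_agreement(
    table: PairedCallTable,
    reference_arm: str,
    test_arm: str,
    polarity: str = "PPA",
    ci_method: str = "wilson",
    level: float = 0.95,
) -> AgreementEstimate:
    """PPA/NPA/OPA of ``test_arm`` against ``reference_arm``.

    PPA_C1F, say, is the proportion of CCD1-positive samples on which the
    FCD call is also positive. The CI is a single-proportion interval on
    the agreement fraction.
    """
    if reference_arm not in ARMS or test_arm not in ARMS:
        raise ValueError(f"arms must be among {ARMS}")
    counts = pattern_counts(table)
    num, den = agreement_from_counts(counts, reference_arm, test_arm, polarity)
    num, den = int(num), int(den)
    if den == 0:
        side = "positive" if polarity == "PPA" else "negative"
        raise ValueError(f"no reference-{side} samples in arm {reference_arm}")
    low, high = proportion_ci(num, den, method=ci_method, level=level)
    return AgreementEstimate(
        kind=polarity,
        reference_arm=reference_arm,
        test_arm=test_arm,
        numerator=num,
        denominator=den,
        estimate=num / den,
        ci_low=low,
        ci_high=high,
        ci_method=ci_method,
    )


def all_agreements(table: PairedCallTable, ci_method: str = "wilson", level: float = 0.95) -> dict:
    """The eight component agreements (PPA/NPA x four ordered arm pairs)."""
    pairs = [("ccd1", "ccd2"), ("ccd1", "fcd"), ("ccd2", "ccd1"), ("ccd2", "fcd")]
    out = {}
    for polarity in ("PPA", "NPA"):
        for ref, tst in pairs:
            key = f"{polarity}_{_short(ref)}{_short(tst)}"
            out[key] = pairwise_agreement(table, ref, tst, polarity, ci_method, level)
    return out


def _short(arm: str) -> str:
    return {"ccd1": "C1", "ccd2": "C2", "fcd": "F"}[arm]


def zeta_differences(table: PairedCallTable) -> ZetaSet:
    """Point estimates of the four agreement differences."""
    counts = pattern_counts(table)
    z = _zetas_from_counts(counts)
    for name, val in zip(ZETA_NAMES, z):
        if np.isnan(val):
            raise ValueError(f"undefined zeta: component agreement of {name} has empty denominator")
    return ZetaSet(*(ZetaInterval(point=float(v)) for v in z))


def bootstrap_zeta_ci(
    table: PairedCallTable,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> ZetaSet:
    """Percentile-bootstrap CIs for the four zetas.

    Whole sample triples are resampled with replacement ``n_boot`` times
    (realized as multinomial draws over the eight call-pattern counts,
    which is the same distribution). Each zeta's CI is the empirical
    (alpha/2, 1-alpha/2) percentile interval, linear interpolation.
    Replicates where a zeta is undefined are skipped and counted; more
    than 50% undefined for any zeta aborts.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    points = zeta_differences(table)
    counts = pattern_counts(table)
    n = int(counts.sum())
    if isinstance(seed, np.random.Generator):
        rng, seed_rec = seed, None
    else:
        rng, seed_rec = np.random.default_rng(seed), int(seed)
    boot_counts = rng.multinomial(n, counts / n, size=n_boot)
    z = _zetas_from_counts(boot_counts)  # (n_boot, 4)
    undefined = np.isnan(z)
    n_undef = int(undefined.any(axis=1).sum())
    alpha = 1 - level
    intervals = []
    for j, name in enumerate(ZETA_NAMES):
        col = z[:, j]
        valid = col[~np.isnan(col)]
        if len(valid) < n_boot / 2:
            raise ValueError(f"bootstrap unstable for this margin: >50% undefined {name}")
        lo = float(np.quantile(valid, alpha / 2))
        hi = float(np.quantile(valid, 1 - alpha / 2))
        intervals.append(
            ZetaInterval(point=points[name].point, ci_low=lo, ci_high=hi, method="percentile_bootstrap")
        )
    return ZetaSet(*intervals, n_boot=n_boot, n_undefined_replicates=n_undef, seed=seed_rec)


def newcombe10_paired_diff_ci(
    table: PairedCallTable,
    arm_a: str,
    arm_b: str,
    polarity: str = "PPA",
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Paired difference P(arm_a calls the polarity) - P(arm_b calls it).

    Continuity-corrected Wilson limits combined per Newcombe (1998)
    method 10 — the interval used for the unenriched (KRAS/NRAS-style)
    analysis where sampling is consecutive rather than enriched.
    """
    if arm_a not in ARMS or arm_b not in ARMS:
        raise ValueError(f"arms must be among {ARMS}")
    if table.has_invalid:
        raise ValueError("table contains invalid calls; apply filter_invalid first")
    target = POSITIVE if polarity == "PPA" else NEGATIVE
    df = table.frame
    a_pos = (df[arm_a] == target).to_numpy()
    b_pos = (df[arm_b] == target).to_numpy()
    a = int((a_pos & b_pos).sum())
    b = int((a_pos & ~b_pos).sum())
    c = int((~a_pos & b_pos).sum())
    d = int((~a_pos & ~b_pos).sum())
    return newcombe10_ci(a, b, c, d, level=level)


def prevalence_adjust(
    table: PairedCallTable,
    spec: PrevalenceSpec,
    comparator_arm: str = "ccd1",
) -> AdjustedAgreement:
    """Enrichment-adjusted PPA/NPA via the law of total probability.

    The within-stratum joint distribution of (comparator call, FCD call)
    is assumed transportable; strata are reweighted from their sample
    shares to the assumed population pre-test prevalence. Adjusted
    PPA = P(F+ and C+)/P(C+), NPA = P(F- and C-)/P(C-) under the
    reweighted joint.
    """
    if table.has_invalid:
        raise ValueError("table contains invalid calls; apply filter_invalid first")
    pi = spec.population_positive_prevalence
    df = table.frame
    strata_needed = ("pretest_positive", "pretest_negative")
    joints = {}
    for s in strata_needed:
        sub = df[df["stratum"] == s]
        if len(sub) == 0:
            raise ValueError(f"stratum unobserved: {s}")
        cpos = sub[comparator_arm] == POSITIVE
        fpos = sub["fcd"] == POSITIVE
        n = len(sub)
        joints[s] = np.array(
            [
                [(cpos & fpos).sum(), (cpos & ~fpos).sum()],
                [(~cpos & fpos).sum(), (~cpos & ~fpos).sum()],
            ]
        ) / n
    w = {"pretest_positive": pi, "pretest_negative": 1 - pi}
    joint = sum(w[s] * joints[s] for s in strata_needed)
    p_cpos = joint[0].sum()
    p_cneg = joint[1].sum()
    if p_cpos == 0 or p_cneg == 0:
        raise ValueError("degenerate comparator margin after reweighting")
    n_strat = (df["stratum"] == "pretest_positive").sum()
    sample_prev = n_strat / (n_strat + (df["stratum"] == "pretest_negative").sum())
    return AdjustedAgreement(
        ppa=float(joint[0, 0] / p_cpos),
        npa=float(joint[1, 1] / p_cneg),
        comparator_arm=comparator_arm,
        population_prevalence=pi,
        sample_prevalence=float(sample_prev),
    )


def noninferiority_decision(
    zetas: ZetaSet,
    delta1: float,
    delta0: float,
    swap_mapping: bool = False,
) -> NonInferiorityResult:
    """Compare the observed margins epsilon to the targets delta.

    epsilon1 (predictive side) is the max upper CI limit over the PPA-side
    zetas, epsilon0 (selective side) over the NPA-side zetas; passing
    requires strict inequality epsilon < delta. ``swap_mapping`` flips the
    sides for indications that select on a negative result (e.g. an
    MSS-not-MSI-high claim).
    """
    for name in ZETA_NAMES:
        zi = zetas[name]
        if zi.ci_low is None or zi.ci_high is None:
            raise ValueError(f"incomplete input: {name} has no CI")
    ppa_upper = max(zetas["zeta_ppa1"].ci_high, zetas["zeta_ppa2"].ci_high)
    npa_upper = max(zetas["zeta_npa1"].ci_high, zetas["zeta_npa2"].ci_high)
    eps1, eps0 = (npa_upper, ppa_upper) if swap_mapping else (ppa_upper, npa_upper)
    pass_pred = eps1 < delta1
    pass_sel = eps0 < delta0
    return NonInferiorityResult(
        epsilon1=float(eps1),
        epsilon0=float(eps0),
        delta1=float(delta1),
        delta0=float(delta0),
        pass_predictive=bool(pass_pred),
        pass_selective=bool(pass_sel),
        pass_overall=bool(pass_pred and pass_sel),
    )
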