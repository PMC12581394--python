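"""Analytical-validation statistics: LoD, LoB, input study, precision, Deming.

Covers the bench-side half of an assay validation: limit of detection
from dilution-series hit rates, limit of blank from wild-type panels,
minimum-vs-optimal DNA input concordance, variance-component precision
with %CV, variant-frequency-bucket call rates, and Deming
errors-in-variables regression for quantitative method comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import clopper_pearson_ci, proportion_ci

__all__ = [
    "DilutionSeries",
    "LodResult",
    "BlankPanel",
    "LobClassResult",
    "PrecisionPanel",
    "VarianceDecomposition",
    "InputStudyResult",
    "estimate_lod",
    "estimate_lob",
    "input_concordance",
    "variance_components",
    "vf_bucket_precision",
    "deming_regression",
]


# ---------------------------------------------------------------------------
# limit of detection


@dataclass(frozen=True)
class DilutionSeries:
    """Replicate detection outcomes along a dilution axis (VF %, copies,
    or % tumor content), levels strictly increasing."""

    analyte_id: str
    levels: tuple[float, ...]
    detected: tuple[int, ...]
    replicates: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.levels) == len(self.detected) == len(self.replicates)):
            raise ValueError("levels, detected and replicates must have equal length")
        if len(self.levels) == 0:
            raise ValueError("empty dilution series")
        if any(r < 1 for r in self.replicates):
            raise ValueError("each level needs at least one replicate")
        if any(not 0 <= d <= r for d, r in zip(self.detected, self.replicates)):
            raise ValueError("detected must be within [0, replicates]")
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError("level values must be strictly increasing")

    @property
    def hit_rates(self) -> np.ndarray:
        return np.asarray(self.detected) / np.asarray(self.replicates)


@dataclass(frozen=True)
class LodResult:
    analyte_id: str
    lod_level: float | None  # None => "> max tested level"
    hit_rate_threshold: float
    per_level_hit_rates: dict[float, float]

    def to_dict(self) -> dict:
        return {
            "analyte_id": self.analyte_id,
            "lod_level": self.lod_level,
            "hit_rate_threshold": self.hit_rate_threshold,
            "per_level_hit_rates": {str(k): v for k, v in self.per_level_hit_rates.items()},
        }


def estimate_lod(series: DilutionSeries, hit_rate_threshold: float = 0.95) -> LodResult:
    """Lowest level with hit rate >= threshold and a qualifying tail.

    The LoD is the lowest concentration at which at least the threshold
    fraction of replicates detect the analyte, requiring every higher
    tested level to qualify as well (monotone-tail rule, which tolerates
    isolated sub-threshold dips below the LoD). ``lod_level=None`` means
    no level qualifies, reported downstream as "> max tested level".
    """
    rates = series.hit_rates
    ok = rates >= hit_rate_threshold
    lod = None
    # scan from the top: the LoD is the start of the maximal qualifying suffix
    for lvl, good in zip(series.levels[::-1], ok[::-1]):
        if not good:
            break
        lod = lvl
    return LodResult(
        analyte_id=series.analyte_id,
        lod_level=lod,
        hit_rate_threshold=hit_rate_threshold,
        per_level_hit_rates=dict(zip(series.levels, map(float, rates))),
    )


# ---------------------------------------------------------------------------
# limit of blank


@dataclass(frozen=True)
class BlankPanel:
    """False-positive opportunities on analyte-free (wild-type) samples."""

    frame: pd.DataFrame  # sample_id, variant_class, false_positive_calls, opportunities

    def __post_init__(self) -> None:
        req = ["sample_id", "variant_class", "false_positive_calls", "opportunities"]
        missing = [c for c in req if c not in self.frame.columns]
        if missing:
            raise ValueError(f"blank panel missing columns: {missing}")
        if len(self.frame) == 0:
            raise ValueError("empty blank panel")
        if (self.frame["false_positive_calls"] > self.frame["opportunities"]).any():
            raise ValueError("false_positive_calls exceeds opportunities")


@dataclass(frozen=True)
class LobClassResult:
    variant_class: str
    calls: int
    opportunities: int
    rate: float
    ci_low: float
    ci_high: float
    ci_method: str

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def estimate_lob(panel: BlankPanel, level: float = 0.95) -> dict[str, LobClassResult]:
    """Pooled false-positive rate per variant class with exact binomial CI.

    Zero-call classes report rate 0 with the one-sided exact upper bound
    ``1 - alpha**(1/n)`` (the usual rule-of-three-style limit of blank).
    """
    out = {}
    for cls, sub in panel.frame.groupby("variant_class", sort=True):
        calls = int(sub["false_positive_calls"].sum())
        opp = int(sub["opportunities"].sum())
        if opp == 0:
            raise ValueError(f"zero opportunities for class {cls}")
        if calls == 0:
            low, high = 0.0, 1 - (1 - level) ** (1 / opp)
            method = "exact_one_sided_upper"
        else:
            low, high = clopper_pearson_ci(calls, opp, level)
            method = "clopper_pearson"
        out[str(cls)] = LobClassResult(str(cls), calls, opp, calls / opp, low, high, method)
    return out


# ---------------------------------------------------------------------------
# DNA input study


@dataclass(frozen=True)
class InputStudyResult:
    """Challenge-vs-control input concordance plus the TMB difference bound."""

    agreements: dict  # per-class {"PPA": AgreementEstimate-like dict, "NPA": ...}
    tmb_abs_pct_diff: float | None
    tmb_abs_pct_diff_ci_upper: float | None

    def to_dict(self) -> dict:
        return {
            "agreements": self.agreements,
            "tmb_abs_pct_diff": self.tmb_abs_pct_diff,
            "tmb_abs_pct_diff_ci_upper": self.tmb_abs_pct_diff_ci_upper,
        }


def input_concordance(
    control_calls: pd.DataFrame,
    challenge_calls: pd.DataFrame,
    tmb_control: np.ndarray | None = None,
    tmb_challenge: np.ndarray | None = None,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> InputStudyResult:
    """Concordance of a challenge DNA input against the control input.

    ``control_calls``/``challenge_calls`` carry columns
    ``sample_id, alteration_class, positive`` (bool), paired on
    (sample_id, alteration_class); PPA/NPA per class use the control arm
    as reference with Clopper-Pearson CIs. The TMB metric is the absolute
    percent difference of mean TMB (challenge vs control), with a
    percentile-bootstrap upper bound over paired samples.
    """
    key = ["sample_id", "alteration_class"]
    merged = control_calls.merge(
        challenge_calls, on=key, how="outer", suffixes=("_ctrl", "_chal"), indicator=True
    )
    if (merged["_merge"] != "both").any():
        raise ValueError("unpaired samples between control and challenge call sets")
    agreements: dict = {}
    for cls, sub in merged.groupby("alteration_class", sort=True):
        ctrl = sub["positive_ctrl"].to_numpy(dtype=bool)
        chal = sub["positive_chal"].to_numpy(dtype=bool)
        cls_out = {}
        for kind, mask in (("PPA", ctrl), ("NPA", ~ctrl)):
            den = int(mask.sum())
            if den == 0:
                cls_out[kind] = None
                continue
            num = int((chal[mask] == ctrl[mask]).sum())
            low, high = proportion_ci(num, den, method="clopper_pearson", level=level)
            cls_out[kind] = {
                "numerator": num,
                "denominator": den,
                "estimate": num / den,
                "ci_low": low,
                "ci_high": high,
                "ci_method": "clopper_pearson",
            }
        agreements[str(cls)] = cls_out

    tmb_diff = tmb_upper = None
    if tmb_control is not None and tmb_challenge is not None:
        x = np.asarray(tmb_control, dtype=float)
        y = np.asarray(tmb_challenge, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("TMB vectors must be 1-D and paired")
        if x.mean() == 0:
            raise ValueError("control mean TMB is zero; percent difference undefined")
        tmb_diff = 100.0 * abs(y.mean() - x.mean()) / x.mean()
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(x), size=(n_boot, len(x)))
        bx, by = x[idx].mean(axis=1), y[idx].mean(axis=1)
        boot = 100.0 * np.abs(by - bx) / bx
        tmb_upper = float(np.quantile(boot, 1 - (1 - level) / 2))
    return InputStudyResult(agreements, tmb_diff, tmb_upper)


# ---------------------------------------------------------------------------
# precision: variance components and %CV


@dataclass(frozen=True)
class PrecisionPanel:
    """Long-format replicate measurements indexed by precision factors."""

    frame: pd.DataFrame  # panel_member, value, + factor columns
    factors: tuple[str, ...] = ("operator_instrument", "reagent_lot", "run_day")

    def __post_init__(self) -> None:
        req = ["panel_member", "value", *self.factors]
        missing = [c for c in req if c not in self.frame.columns]
        if missing:
            raise ValueError(f"precision panel missing columns: {missing}")
        if len(self.frame) == 0:
            raise ValueError("empty precision panel")


@dataclass(frozen=True)
class VarianceDecomposition:
    components: dict[str, float]  # per-factor + "within_run"
    total_variance: float
    total_sd: float
    mean: float
    cv_percent: float
    flags: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "components": dict(self.components),
            "total_variance": self.total_variance,
            "total_sd": self.total_sd,
            "mean": self.mean,
            "cv_percent": self.cv_percent,
            "flags": list(self.flags),
        }


def variance_components(
    panel: PrecisionPanel, panel_member: str | None = None
) -> VarianceDecomposition:
    """Method-of-moments ANOVA decomposition of within-lab variability.

    For a balanced crossed random-effects design (additive main effects
    per declared factor, interactions pooled into the residual), each
    component is ``(MS_factor - MS_residual) / (N / n_levels)``, truncated
    at zero before totaling. The residual is reported as within-run
    variance; a run-day factor, when declared, carries the between-run
    component. %CV = 100 * total SD / mean (error when the mean is 0).
    """
    df = panel.frame
    if panel_member is not None:
        df = df[df["panel_member"] == panel_member]
        if len(df) == 0:
            raise ValueError(f"no rows for panel member {panel_member!r}")
    y = df["value"].to_numpy(dtype=float)
    n = len(y)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    flags: list[str] = []

    ss = {}
    df_factor = {}
    for f in panel.factors:
        groups = df.groupby(f)["value"]
        means = groups.mean()
        sizes = groups.size()
        if len(means) < 2:
            flags.append(f"factor {f} has a single level; contributes zero variance")
            ss[f], df_factor[f] = 0.0, 0
            continue
        ss[f] = float((sizes * (means - grand) ** 2).sum())
        df_factor[f] = len(means) - 1
    ss_resid = ss_total - sum(ss.values())
    df_resid = (n - 1) - sum(df_factor.values())
    if df_resid <= 0:
        raise ValueError("need at least 2 replicates at the innermost level")
    ms_resid = max(ss_resid, 0.0) / df_resid

    components: dict[str, float] = {}
    for f in panel.factors:
        if df_factor[f] == 0:
            components[f] = 0.0
            continue
        ms_f = ss[f] / df_factor[f]
        n_per_level = n / (df_factor[f] + 1)
        components[f] = max((ms_f - ms_resid) / n_per_level, 0.0)
    components["within_run"] = ms_resid

    total_var = float(sum(components.values()))
    total_sd = math.sqrt(total_var)
    if grand == 0:
        raise ValueError("%CV undefined: mean value is 0")
    return VarianceDecomposition(
        components=components,
        total_variance=total_var,
        total_sd=total_sd,
        mean=float(grand),
        cv_percent=100.0 * total_sd / abs(grand),
        flags=tuple(flags),
    )


def vf_bucket_precision(
    tracked_calls: pd.DataFrame,
    buckets: tuple[float, ...] = (0.05, 0.08, 0.10, 0.15),
) -> dict[float, float | None]:
    """Positive call rate per variant-frequency bucket.

    ``tracked_calls`` has one row per (tracked variant, replicate) with
    columns ``target_vf`` (fraction) and ``detected`` (bool); bucket
    ``>= v`` pools every replicate of every variant whose target VF is at
    least ``v``. Empty buckets report None (undefined), never 0.
    """
    req = ["target_vf", "detected"]
    missing = [c for c in req if c not in tracked_calls.columns]
    if missing:
        raise ValueError(f"tracked call table missing columns: {missing}")
    out: dict[float, float | None] = {}
    vf = tracked_calls["target_vf"].to_numpy(dtype=float)
    det = tracked_calls["detected"].to_numpy(dtype=bool)
    for b in buckets:
        mask = vf >= b
        out[b] = float(det[mask].mean()) if mask.any() else None
    return out


# ---------------------------------------------------------------------------
# Deming regression


def deming_regression(
    x: np.ndarray, y: np.ndarray, variance_ratio: float = 1.0
) -> dict[str, float]:
    """Errors-in-variables straight-line fit for method comparison.

    ``variance_ratio`` is the ratio of the y-error variance to the
    x-error variance (1 = orthogonal regression; -> infinity recovers OLS
    of y on x). Returns slope, intercept and Pearson r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need at least 3 finite paired measurements")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if variance_ratio <= 0:
        raise ValueError("variance_ratio must be positive")
    sxx = float(((x - x.mean()) ** 2).sum())
    syy = float(((y - y.mean()) ** 2).sum())
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    if sxx == 0 and syy == 0:
        raise ValueError("degenerate fit: zero variance in both variables")
    lam = variance_ratio
    if sxy == 0:
        # axis-aligned degenerate: vertical or horizontal line
        slope = 0.0 if syy <= lam * sxx else math.inf
    else:
        slope = (syy - lam * sxx + math.sqrt((syy - lam * sxx) ** 2 + 4 * lam * sxy**2)) / (2 * sxy)
    intercept = float(y.mean() - slope * x.mean())
    r = sxy / math.sqrt(sxx * syy) if sxx > 0 and syy > 0 else float("nan")
    return {"slope": float(slope), "intercept": intercept, "pearson_r": float(r)}
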