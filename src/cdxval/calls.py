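"""Paired qualitative call tables for follow-on CDx concordance studies.

The study design compares one replicate of the follow-on companion
diagnostic (FCD) to two replicates of the comparator companion diagnostic
(CCD1, CCD2) on the same samples. Each row of a :class:`PairedCallTable`
holds the three qualitative calls plus the enrollment stratum the sample
was recruited under (biomarker-enriched cohorts are recruited on a noisy
pre-test marker; the KRAS/NRAS-style design enrolls unenriched).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import pandas as pd

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "INVALID",
    "ARMS",
    "STRATA",
    "PairedCallTable",
    "FilterSummary",
    "filter_invalid",
]

POSITIVE = "positive"
NEGATIVE = "negative"
INVALID = "invalid"
CALL_VALUES = (POSITIVE, NEGATIVE, INVALID)

ARMS = ("ccd1", "ccd2", "fcd")
STRATA = ("pretest_positive", "pretest_negative", "unenriched")

_PAIRS = (("ccd1", "ccd2"), ("ccd1", "fcd"), ("ccd2", "fcd"))


@dataclass(frozen=True)
class FilterSummary:
    """Bookkeeping attached by :func:`filter_invalid`."""

    policy: str
    n_input: int
    n_output: int
    n_dropped: int
    n_recoded_calls: int


@dataclass
class PairedCallTable:
    """Per-sample triples of qualitative calls (CCD1, CCD2, FCD).

    Wraps a DataFrame with columns ``sample_id, ccd1, ccd2, fcd, stratum``
    and optionally ``tumor_type``. Sample ids must be unique and every call
    must be one of ``positive/negative/invalid``.
    """

    frame: pd.DataFrame
    filter_summary: FilterSummary | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        df = self.frame
        required = ["sample_id", "ccd1", "ccd2", "fcd", "stratum"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"call table missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("call table must contain at least one row")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_id values: {dups[:5]}")
        for arm in ARMS:
            bad = ~df[arm].isin(CALL_VALUES)
            if bad.any():
                val = df.loc[bad, arm].iloc[0]
                raise ValueError(f"unknown call value {val!r} in arm {arm}")
        bad = ~df["stratum"].isin(STRATA)
        if bad.any():
            val = df.loc[bad, "stratum"].iloc[0]
            raise ValueError(f"unknown stratum {val!r}; expected one of {STRATA}")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def has_invalid(self) -> bool:
        return bool(self.frame[list(ARMS)].isin([INVALID]).any().any())

    @classmethod
    def from_records(cls, records: list[dict]) -> "PairedCallTable":
        df = pd.DataFrame.from_records(records)
        if "stratum" not in df.columns:
            df["stratum"] = "unenriched"
        return cls(df)


def _row_agreement(calls: dict[str, str]) -> int:
    """Number of agreeing arm pairs among the three pairwise comparisons."""
    return sum(calls[x] == calls[y] for x, y in _PAIRS)


def filter_invalid(table: PairedCallTable, policy: str = "exclude") -> PairedCallTable:
    """Resolve invalid calls ahead of the concordance analysis.

    policy:
      * ``exclude`` — drop any row with an invalid call (the primary
        analysis of the validation design);
      * ``best_case`` — recode each invalid call to the positive/negative
        assignment maximizing that row's pairwise agreement;
      * ``worst_case`` — recode to the assignment minimizing it.

    Best-/worst-case are the sensitivity analyses. Recoding ties are
    broken toward ``negative``. The returned table carries a
    :class:`FilterSummary`.
    """
    if policy not in ("exclude", "best_case", "worst_case"):
        raise ValueError(f"unknown invalid policy {policy!r}")
    df = table.frame.copy()
    invalid_mask = df[list(ARMS)].isin([INVALID])
    n_input = len(df)

    if policy == "exclude":
        keep = ~invalid_mask.any(axis=1)
        out = df.loc[keep]
        if len(out) == 0:
            raise ValueError("no analyzable samples: every row contains an invalid call")
        summary = FilterSummary("exclude", n_input, len(out), n_input - len(out), 0)
        return PairedCallTable(out, filter_summary=summary)

    n_recoded = int(invalid_mask.to_numpy().sum())
    best = policy == "best_case"
    for i in df.index[invalid_mask.any(axis=1)]:
        arms_invalid = [a for a in ARMS if df.at[i, a] == INVALID]
        base = {a: df.at[i, a] for a in ARMS}
        # enumerate recodings; NEGATIVE first so ties resolve to negative
        choices = []
        for combo in product((NEGATIVE, POSITIVE), repeat=len(arms_invalid)):
            trial = dict(base, **dict(zip(arms_invalid, combo)))
            choices.append((_row_agreement(trial), combo))
        combo = max(choices, key=lambda t: t[0])[1] if best else min(choices, key=lambda t: t[0])[1]
        for a, v in zip(arms_invalid, combo):
            df.at[i, a] = v
    summary = FilterSummary(policy, n_input, len(df), 0, n_recoded)
    return PairedCallTable(df, filter_summary=summary)
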