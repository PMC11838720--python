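"""Reading paired-result extracts and applying pairing exclusion rules.

Laboratory extracts arrive as CSV with one row per current/previous pair.
Values are read as raw strings first, because censored results such as
``"<0.04"`` must survive parsing to be counted by the exclusion stage.

Exclusion rules (applied in this order, first match wins, per record):

1. ``non_numeric`` — a result that cannot be parsed as a number (and has no
   inequality sign), or an unparseable timestamp;
2. ``inequality_sign`` — a result censored at an assay limit (``<`` / ``>``);
3. ``interval_too_short`` — less than 24 h between the paired tests (too
   close to reflect an independent physiological state);
4. ``interval_too_long`` — more than 3 years (1095 days) between tests;
5. ``under_age`` — patient younger than 19 years (adults only);
6. ``nonpositive_value`` — a parsed value <= 0, which would make a percent
   change undefined;
7. ``group_too_small`` — after the record-level filters, any
   (analyte x group) stratum with fewer than 1000 surviving pairs is
   dropped whole, as small strata give unstable percentile limits.

The stratum-size rule necessarily runs after the record-level rules (it is
defined on surviving pairs), so it is last regardless of the log ordering.
Counts reconcile: retained + sum of exclusions = input records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import PAIR_COLUMNS

__all__ = [
    "ResultPair",
    "ExclusionLog",
    "read_pairs",
    "write_pairs",
    "apply_exclusions",
    "EXCLUSION_REASONS",
]

EXCLUSION_REASONS = (
    "non_numeric",
    "inequality_sign",
    "interval_too_short",
    "interval_too_long",
    "under_age",
    "group_too_small",
    "nonpositive_value",
)


@dataclass(frozen=True)
class ResultPair:
    """One current/previous paired observation with patient metadata."""

    patient_id: str
    analyte: str
    group: str
    sex: str
    age: int
    institution: str
    prev_value: float
    prev_time: pd.Timestamp
    curr_value: float
    curr_time: pd.Timestamp

    @property
    def delta_interval(self) -> float:
        """Days between the previous and current test."""
        return (self.curr_time - self.prev_time) / pd.Timedelta(days=1)


@dataclass
class ExclusionLog:
    """Per-reason exclusion counts for one filtering pass."""

    total: int = 0
    retained: int = 0
    counts: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in EXCLUSION_REASONS}
    )
    dropped_strata: list[tuple[str, str]] = field(default_factory=list)

    def reconciles(self) -> bool:
        return self.retained + sum(self.counts.values()) == self.total

    def to_json(self) -> str:
        return json.dumps(
            {
                "total": self.total,
                "retained": self.retained,
                "excluded": self.counts,
                "dropped_strata": [list(s) for s in self.dropped_strata],
            },
            indent=2,
        )


def read_pairs(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a raw pairs CSV, keeping every value as a string.

    ``schema`` maps canonical column names (``PAIR_COLUMNS``) to the file's
    column names, for extracts with different headers.  Row order is
    preserved; censored values like ``"<0.04"`` are kept verbatim for the
    exclusion stage.

    Raises ``ValueError`` naming the first missing required column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        rename = {src: canon for canon, src in schema.items()}
        missing = [src for src in schema.values() if src not in df.columns]
        if missing:
            raise ValueError(f"missing column in {path}: {missing[0]!r}")
        df = df.rename(columns=rename)
    for col in PAIR_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column in {path}: {col!r}")
    return df[PAIR_COLUMNS].reset_index(drop=True)


def write_pairs(pairs: pd.DataFrame, path) -> None:
    """Write a pairs table to CSV with ISO-8601 timestamps."""
    out = pairs.copy()
    for col in ("prev_time", "curr_time"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def _has_inequality(raw: pd.Series) -> pd.Series:
    return raw.str.contains("<|>", regex=True, na=False)


def apply_exclusions(
    records: pd.DataFrame,
    min_interval_days: float = 1.0,
    max_interval_days: float = 1095.0,
    min_age: int = 19,
    min_group_n: int = 1000,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the pairing exclusion rules to a raw (string-typed) table.

    Returns the retained pairs with numeric ``prev_value``/``curr_value``,
    datetime timestamps and a ``delta_interval`` column in days, plus an
    ``ExclusionLog`` whose counts reconcile with the input size.  Never
    raises on record content; everything is counted.
    """
    df = records.copy().reset_index(drop=True)
    n = len(df)
    log = ExclusionLog(total=n)
    if n == 0:
        return df.iloc[0:0], log

    prev_raw = df["prev_value"].astype(str).str.strip()
    curr_raw = df["curr_value"].astype(str).str.strip()
    prev_num = pd.to_numeric(prev_raw, errors="coerce")
    curr_num = pd.to_numeric(curr_raw, errors="coerce")
    prev_t = pd.to_datetime(df["prev_time"], errors="coerce", format="mixed")
    curr_t = pd.to_datetime(df["curr_time"], errors="coerce", format="mixed")
    age = pd.to_numeric(df["age"], errors="coerce")
    interval = (curr_t - prev_t) / pd.Timedelta(days=1)

    inequality = _has_inequality(prev_raw) | _has_inequality(curr_raw)
    non_numeric = (
        (prev_num.isna() | curr_num.isna()) & ~inequality
    ) | prev_t.isna() | curr_t.isna() | age.isna()

    reason = pd.Series("", index=df.index)
    checks = [
        ("non_numeric", non_numeric),
        ("inequality_sign", inequality),
        ("interval_too_short", interval < min_interval_days),
        ("interval_too_long", interval > max_interval_days),
        ("under_age", age < min_age),
        ("nonpositive_value", (prev_num <= 0) | (curr_num <= 0)),
    ]
    for name, mask in checks:
        hit = mask.fillna(False) & (reason == "")
        reason[hit] = name
        log.counts[name] = int(hit.sum())

    keep = reason == ""
    clean = df.loc[keep].copy()
    clean["prev_value"] = prev_num[keep]
    clean["curr_value"] = curr_num[keep]
    clean["prev_time"] = prev_t[keep]
    clean["curr_time"] = curr_t[keep]
    clean["age"] = age[keep].astype(int)
    clean["delta_interval"] = interval[keep]

    # stratum-size rule on survivors
    sizes = clean.groupby(["analyte", "group"], sort=False).size()
    small = sizes[sizes < min_group_n]
    if len(small) > 0:
        drop_keys = set(small.index)
        in_small = clean.apply(
            lambda r: (r["analyte"], r["group"]) in drop_keys, axis=1
        ) if len(clean) else pd.Series(dtype=bool)
        log.counts["group_too_small"] = int(in_small.sum())
        log.dropped_strata = sorted(drop_keys)
        clean = clean.loc[~in_small]

    log.retained = len(clean)
    assert log.reconciles()
    return clean.reset_index(drop=True), log
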