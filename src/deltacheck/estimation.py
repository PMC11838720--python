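"""Delta check limit (DCL) estimation.

The limit for each analyte, clinical group and metric is the upper 95th
percentile of the metric's distribution in a development set: by
construction about 5% of comparable results will exceed it.  The data are
split 6:4 into development and validation sets at random within each
(analyte x group) stratum; a combined limit for both groups is the
unweighted arithmetic mean of the two group limits, so that the larger
group does not dominate.  Two-sided (2.5th/97.5th) percentiles of the
signed deltas, stratified by sex, support sex-specific limits for analytes
such as testosterone and prolactin.

Percentiles use linear interpolation between order statistics
(Hyndman-Fan type 7, the default of most statistical environments); at the
stratum sizes required here (>= 1000) the choice of convention moves a
limit by less than one inter-order-statistic gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deltas import METRIC_COLUMNS

__all__ = [
    "SplitAssignment",
    "DclEstimate",
    "split_dev_val",
    "estimate_percentile",
    "estimate_dcls",
    "combine_dcls",
    "sex_stratified_percentiles",
]


@dataclass(frozen=True)
class SplitAssignment:
    """Development/validation row indices per (analyte, group) stratum."""

    dev_ids: dict[tuple[str, str], np.ndarray]
    val_ids: dict[tuple[str, str], np.ndarray]
    ratio: float
    seed: int

    def dev_index(self) -> np.ndarray:
        if not self.dev_ids:
            return np.array([], dtype=int)
        return np.concatenate(list(self.dev_ids.values()))

    def val_index(self) -> np.ndarray:
        if not self.val_ids:
            return np.array([], dtype=int)
        return np.concatenate(list(self.val_ids.values()))


@dataclass(frozen=True)
class DclEstimate:
    """One delta check limit.

    ``limit`` is in analyte units for absDD and percent for absDPC;
    ``group`` is IE, O or combined; ``n_dev`` the development-set size it
    was estimated from.
    """

    analyte: str
    group: str
    metric: str
    percentile: float
    limit: float
    n_dev: int

    def __post_init__(self) -> None:
        if self.limit < 0:
            raise ValueError("limit must be >= 0")
        if self.metric not in METRIC_COLUMNS:
            raise ValueError(f"unknown metric {self.metric!r}")


def split_dev_val(
    records: pd.DataFrame, ratio: float = 0.6, seed: int = 0
) -> SplitAssignment:
    """Randomly split each (analyte x group) stratum into dev and val sets.

    The development set takes the first round(ratio * n) rows (round half
    up) of a seeded per-stratum permutation; deterministic for a fixed seed.
    Empty strata cannot occur (groupby only yields non-empty groups).
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    dev_ids: dict[tuple[str, str], np.ndarray] = {}
    val_ids: dict[tuple[str, str], np.ndarray] = {}
    for key, idx in records.groupby(["analyte", "group"], sort=True).groups.items():
        idx = np.asarray(idx)
        perm = rng.permutation(len(idx))
        n_dev = int(math.floor(ratio * len(idx) + 0.5))  # round half up
        dev_ids[key] = np.sort(idx[perm[:n_dev]])
        val_ids[key] = np.sort(idx[perm[n_dev:]])
    return SplitAssignment(dev_ids=dev_ids, val_ids=val_ids, ratio=ratio, seed=seed)


def estimate_percentile(values, p: float, method: str = "linear") -> float:
    """Sample percentile by linear interpolation (Hyndman-Fan type 7).

    Requires at least two finite values and 0 < p < 100; monotone in ``p``
    and always between the sample minimum and maximum.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values for a percentile estimate")
    if not np.isfinite(arr).all():
        raise ValueError("values must be finite")
    if not 0.0 < p < 100.0:
        raise ValueError("p must lie in (0, 100)")
    return float(np.quantile(arr, p / 100.0, method=method))


def estimate_dcls(
    dev: pd.DataFrame,
    percentile: float = 95.0,
    metrics: tuple[str, ...] = ("absDD", "absDPC"),
    min_n: int = 2,
) -> list[DclEstimate]:
    """Estimate one DCL per (analyte x group x metric) from a development set.

    Strata with fewer than ``min_n`` records are skipped (the upstream
    stratum-size exclusion normally guarantees far larger sizes).
    """
    out: list[DclEstimate] = []
    for (analyte, group), sub in dev.groupby(["analyte", "group"], sort=True):
        if len(sub) < min_n:
            continue
        for metric in metrics:
            col = METRIC_COLUMNS[metric]
            out.append(
                DclEstimate(
                    analyte=analyte,
                    group=group,
                    metric=metric,
                    percentile=percentile,
                    limit=estimate_percentile(sub[col].to_numpy(), percentile),
                    n_dev=len(sub),
                )
            )
    return out


def combine_dcls(dcl_ie: DclEstimate, dcl_o: DclEstimate) -> DclEstimate:
    """Combined-group DCL: the unweighted mean of the IE and O limits."""
    if dcl_ie.analyte != dcl_o.analyte or dcl_ie.metric != dcl_o.metric:
        raise ValueError("can only combine limits for the same analyte and metric")
    if dcl_ie.percentile != dcl_o.percentile:
        raise ValueError("percentile levels differ")
    if {dcl_ie.group, dcl_o.group} != {"IE", "O"}:
        raise ValueError("expected one IE and one O limit")
    return DclEstimate(
        analyte=dcl_ie.analyte,
        group="combined",
        metric=dcl_ie.metric,
        percentile=dcl_ie.percentile,
        limit=(dcl_ie.limit + dcl_o.limit) / 2.0,
        n_dev=dcl_ie.n_dev + dcl_o.n_dev,
    )


def sex_stratified_percentiles(
    records: pd.DataFrame,
    lower: float = 2.5,
    upper: float = 97.5,
    min_n: int = 2,
) -> pd.DataFrame:
    """Two-sided percentiles of the signed deltas per analyte and sex.

    Returns a tidy table (analyte, sex, metric in {DD, DPC}, p_lower,
    p_upper); cells with fewer than ``min_n`` records are omitted.
    """
    rows = []
    for (analyte, sex), sub in records.groupby(["analyte", "sex"], sort=True):
        if len(sub) < min_n:
            continue
        for metric, col in (("DD", "dd"), ("DPC", "dpc")):
            vals = sub[col].to_numpy()
            rows.append({
                "analyte": analyte,
                "sex": sex,
                "metric": metric,
                "n": len(sub),
                "p_lower": estimate_percentile(vals, lower),
                "p_upper": estimate_percentile(vals, upper),
            })
    return pd.DataFrame(
        rows, columns=["analyte", "sex", "metric", "n", "p_lower", "p_upper"]
    )
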