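"""Validation of delta check limits on held-out data.

Because a DCL is the development-set 95th percentile, about 5% of an
exchangeable validation set should exceed it.  Three applications are
checked:

* own-group — each group's limit applied to its own validation set
  (coverage check: proportion outside should be ~5%);
* cross-group — IE's limit applied to O's validation set and vice versa
  (interchangeability check: large deviations from 5% mean the groups need
  separate limits);
* combined — the averaged limit applied to both groups, with a Pearson
  chi-squared test comparing the outside/inside proportions between the
  groups.

Group differences at the 95th percentile itself are tested by quantile
regression of the metric on a group indicator: minimizing the pinball
(check) loss sum rho_tau(y - b0 - b1*[group == IE]) over (b0, b1).  With a
single binary covariate the problem separates, so b0 is the tau-quantile of
group O and b0 + b1 that of group IE under the pinball definition (an order
statistic, not the interpolated percentile — the two differ by at most one
inter-order-statistic gap).  Significance of b1 comes from a seeded
case-resampling bootstrap within each group (percentile method).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .deltas import METRIC_COLUMNS
from .estimation import DclEstimate

__all__ = [
    "ValidationReport",
    "GroupComparison",
    "QuantileRegressionResult",
    "proportion_outside",
    "cross_validate",
    "chisq_compare",
    "pinball_loss",
    "pinball_quantile",
    "quantreg_group_test",
]


@dataclass(frozen=True)
class ValidationReport:
    """Proportion of a validation set outside one DCL."""

    analyte: str
    metric: str
    dcl_source: str     # IE, O or combined
    applied_to: str     # IE or O
    limit: float
    n_val: int
    n_outside: int
    expected: float = 5.0

    @property
    def proportion_outside(self) -> float:
        """Percent of validation results above the limit."""
        return 100.0 * self.n_outside / self.n_val


@dataclass(frozen=True)
class GroupComparison:
    """Chi-squared comparison of outside/inside counts between IE and O."""

    analyte: str
    metric: str
    table: np.ndarray   # 2x2: rows (IE, O), cols (outside, inside)
    statistic: float
    p_value: float
    correction: bool
    degenerate: bool = False


@dataclass(frozen=True)
class QuantileRegressionResult:
    """Pinball-loss fit of a tau-quantile with a binary group covariate."""

    analyte: str
    metric: str
    tau: float
    intercept: float    # tau-quantile of group O
    coef_group: float   # IE-minus-O difference at the tau-quantile
    p_value: float
    n_boot: int
    seed: int


def proportion_outside(
    val: pd.DataFrame,
    dcl: DclEstimate,
    applied_to: str | None = None,
    strict: bool = True,
) -> ValidationReport:
    """Count validation results beyond a limit.

    ``strict`` counts values strictly greater than the limit (a result
    exactly at the limit was seen in the development distribution and is
    not flagged); set False for >=.
    """
    if len(val) == 0:
        raise ValueError("empty validation set")
    if val["analyte"].nunique() != 1 or val["analyte"].iloc[0] != dcl.analyte:
        raise ValueError("validation records do not match the DCL's analyte")
    values = val[METRIC_COLUMNS[dcl.metric]].to_numpy()
    outside = values > dcl.limit if strict else values >= dcl.limit
    if applied_to is None:
        groups = val["group"].unique()
        applied_to = groups[0] if len(groups) == 1 else "mixed"
    return ValidationReport(
        analyte=dcl.analyte,
        metric=dcl.metric,
        dcl_source=dcl.group,
        applied_to=applied_to,
        limit=dcl.limit,
        n_val=len(val),
        n_outside=int(outside.sum()),
    )


def cross_validate(
    dcls: dict[str, DclEstimate],
    val_ie: pd.DataFrame | None,
    val_o: pd.DataFrame | None,
    strict: bool = True,
) -> list[ValidationReport]:
    """Own- and cross-group validation for one analyte and metric.

    ``dcls`` maps group name (IE/O) to its limit.  With both groups present
    this yields four reports (IE->IE, IE->O, O->IE, O->O); with one group
    missing, the reduced set.
    """
    sets = {"IE": val_ie, "O": val_o}
    reports = []
    for source, dcl in sorted(dcls.items()):
        for target, val in sorted(sets.items()):
            if val is None or len(val) == 0:
                continue
            reports.append(
                proportion_outside(val, dcl, applied_to=target, strict=strict)
            )
    return reports


def chisq_compare(
    report_ie: ValidationReport,
    report_o: ValidationReport,
    correction: bool = False,
) -> GroupComparison:
    """Pearson chi-squared on the 2x2 outside/inside table for IE vs O.

    Both reports must apply the same combined limit.  ``correction``
    enables the Yates continuity correction (off by default).  A zero
    margin (e.g. no result outside the limit in either group) makes the
    test undefined; the comparison is then flagged degenerate with p = nan.
    """
    if (report_ie.analyte, report_ie.metric) != (report_o.analyte, report_o.metric):
        raise ValueError("reports compare different analytes or metrics")
    if report_ie.limit != report_o.limit:
        raise ValueError("reports apply different limits")
    table = np.array([
        [report_ie.n_outside, report_ie.n_val - report_ie.n_outside],
        [report_o.n_outside, report_o.n_val - report_o.n_outside],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return GroupComparison(
            analyte=report_ie.analyte, metric=report_ie.metric, table=table,
            statistic=float("nan"), p_value=float("nan"),
            correction=correction, degenerate=True,
        )
    res = stats.chi2_contingency(table, correction=correction)
    return GroupComparison(
        analyte=report_ie.analyte,
        metric=report_ie.metric,
        table=table,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        correction=correction,
    )


def pinball_loss(y: np.ndarray, q: float, tau: float) -> float:
    """Check loss sum_i rho_tau(y_i - q)."""
    r = np.asarray(y, dtype=float) - q
    return float(np.sum(np.where(r >= 0, tau * r, (tau - 1.0) * r)))


def pinball_quantile(y: np.ndarray, tau: float) -> float:
    """Sample tau-quantile minimizing the pinball loss.

    The minimizer is the ceil(n*tau)-th order statistic; when n*tau is an
    integer every point of the interval between the (n*tau)-th and the next
    order statistic is optimal and the lower endpoint is returned.
    """
    y = np.sort(np.asarray(y, dtype=float))
    n = y.size
    if n == 0:
        raise ValueError("empty sample")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    k = max(1, math.ceil(n * tau))
    return float(y[k - 1])


def quantreg_group_test(
    dev_ie: pd.DataFrame | np.ndarray,
    dev_o: pd.DataFrame | np.ndarray,
    metric: str = "absDD",
    tau: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
    analyte: str = "",
) -> QuantileRegressionResult:
    """Test for an IE-vs-O difference at the tau-quantile of a delta metric.

    Accepts delta tables (the metric column is extracted) or raw value
    arrays.  The point fit is the exact pinball-loss minimizer; the
    two-sided p-value is the percentile-bootstrap probability that the
    group coefficient crosses zero, from ``n_boot`` within-group case
    resamples (deterministic under ``seed``).
    """
    def _values(x):
        if isinstance(x, pd.DataFrame):
            return x[METRIC_COLUMNS[metric]].to_numpy(dtype=float)
        return np.asarray(x, dtype=float)

    y_ie = _values(dev_ie)
    y_o = _values(dev_o)
    if y_ie.size == 0 or y_o.size == 0:
        raise ValueError("both groups must be non-empty")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")

    b0 = pinball_quantile(y_o, tau)
    b1 = pinball_quantile(y_ie, tau) - b0

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        ie_s = y_ie[rng.integers(0, y_ie.size, y_ie.size)]
        o_s = y_o[rng.integers(0, y_o.size, y_o.size)]
        boot[b] = pinball_quantile(ie_s, tau) - pinball_quantile(o_s, tau)
    # two-sided percentile bootstrap: how often the resampled coefficient
    # lands on either side of zero
    p_low = np.mean(boot <= 0.0)
    p_high = np.mean(boot >= 0.0)
    p = min(1.0, 2.0 * min(p_low, p_high))
    return QuantileRegressionResult(
        analyte=analyte,
        metric=metric,
        tau=tau,
        intercept=b0,
        coef_group=b1,
        p_value=float(p),
        n_boot=n_boot,
        seed=seed,
    )
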