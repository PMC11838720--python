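"""Asymmetric reference change values (RCV) from biological variation.

A change between two serial results is only meaningful once it exceeds the
combined "noise" of within-subject biological variation (CV_I) and analytical
imprecision (CV_A).  Under a lognormal model for serial results the RCV is
asymmetric: the threshold for a significant increase is larger in magnitude
than the threshold for a significant decrease, and the two are reciprocal,

    (1 + increase/100) * (1 + decrease/100) = 1.

With CVs expressed in percent, the per-result log-scale variance is

    sigma^2 = ln(1 + CV_I^2/10^4) + ln(1 + CV_A^2/10^4)

and for a two-sided standard-normal quantile ``z`` (1.96 for 95%, 2.57 for
99% probability),

    increase = 100 * (exp(+z * sqrt(2) * sigma) - 1)
    decrease = 100 * (exp(-z * sqrt(2) * sigma) - 1).

The sqrt(2) reflects that a delta involves two independently measured
results.  An alternative formulation pools the CVs before the log transform,
``sigma^2 = ln(1 + (CV_I^2 + CV_A^2)/10^4)``; both are available via
``mode`` and agree closely for CVs below ~50%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "BioVariationInput",
    "RcvResult",
    "asymmetric_rcv",
    "rcv_table",
    "compare_rcv_dcl",
    "Z_95",
    "Z_99",
]

#: conventional two-sided z-scores as printed in the biological-variation
#: literature (rounded to 2 d.p.)
Z_95 = 1.96
Z_99 = 2.57


@dataclass(frozen=True)
class BioVariationInput:
    """Biological-variation inputs for one analyte.

    CVs are in percent.  Confidence-interval limits, when available, bracket
    the point estimates; ``cv_i`` may be ``None`` for analytes without a
    published within-subject estimate (the RCV is then undefined).
    """

    analyte: str
    cv_i: float | None
    cv_a: float
    cv_i_ci: tuple[float, float] | None = None
    cv_a_ci: tuple[float, float] | None = None
    z: float = Z_95

    def __post_init__(self) -> None:
        if self.cv_i is not None and self.cv_i < 0:
            raise ValueError(f"{self.analyte}: cv_i must be >= 0")
        if self.cv_a < 0:
            raise ValueError(f"{self.analyte}: cv_a must be >= 0")
        if self.z <= 0:
            raise ValueError(f"{self.analyte}: z must be > 0")
        for name, ci, point in (
            ("cv_i_ci", self.cv_i_ci, self.cv_i),
            ("cv_a_ci", self.cv_a_ci, self.cv_a),
        ):
            if ci is not None:
                lo, hi = ci
                if point is None or not (lo <= hi):
                    raise ValueError(f"{self.analyte}: malformed {name}")


@dataclass(frozen=True)
class RcvResult:
    """Asymmetric RCV for one analyte at one z level, in percent change.

    ``decrease`` is negative, ``increase`` positive; ``decrease_ci`` /
    ``increase_ci`` are present when CV confidence limits were supplied
    (computed by plugging lower-with-lower and upper-with-upper CV limits
    into the same closed form).
    """

    analyte: str
    z: float
    decrease: float
    increase: float
    decrease_ci: tuple[float, float] | None = None
    increase_ci: tuple[float, float] | None = None


def _log_sigma(cv_i: float, cv_a: float, mode: str) -> float:
    if mode == "sum":
        s2 = math.log1p(cv_i**2 / 1e4) + math.log1p(cv_a**2 / 1e4)
    elif mode == "total":
        s2 = math.log1p((cv_i**2 + cv_a**2) / 1e4)
    else:
        raise ValueError(f"unknown sigma mode {mode!r}")
    return math.sqrt(s2)


def _rcv_pair(cv_i: float, cv_a: float, z: float, mode: str) -> tuple[float, float]:
    half = z * math.sqrt(2.0) * _log_sigma(cv_i, cv_a, mode)
    return 100.0 * math.expm1(-half), 100.0 * math.expm1(half)


def asymmetric_rcv(inp: BioVariationInput, mode: str = "sum") -> RcvResult:
    """Compute the asymmetric RCV for one analyte.

    Parameters
    ----------
    inp
        CV_I and CV_A in percent, z level, and optional CV confidence limits.
    mode
        ``"sum"`` (default) combines CV_I and CV_A as a sum of log-variances,
        matching the EFLM biological-variation calculator; ``"total"`` pools
        the squared CVs before the log transform.

    Raises
    ------
    ValueError
        If ``cv_i`` is missing (no within-subject estimate exists).
    """
    if inp.cv_i is None:
        raise ValueError(f"{inp.analyte}: RCV undefined without a CV_I estimate")
    dec, inc = _rcv_pair(inp.cv_i, inp.cv_a, inp.z, mode)
    dec_ci = inc_ci = None
    if inp.cv_i_ci is not None and inp.cv_a_ci is not None:
        lo = _rcv_pair(inp.cv_i_ci[0], inp.cv_a_ci[0], inp.z, mode)
        hi = _rcv_pair(inp.cv_i_ci[1], inp.cv_a_ci[1], inp.z, mode)
        dec_ci = (lo[0], hi[0])
        inc_ci = (lo[1], hi[1])
    return RcvResult(
        analyte=inp.analyte,
        z=inp.z,
        decrease=dec,
        increase=inc,
        decrease_ci=dec_ci,
        increase_ci=inc_ci,
    )


def rcv_table(
    inputs: list[BioVariationInput],
    z_levels: tuple[float, ...] = (Z_95, Z_99),
    mode: str = "sum",
) -> tuple[list[RcvResult], list[str]]:
    """RCVs at every z level for every analyte with a CV_I estimate.

    Returns the results plus the names of analytes skipped for lack of a
    within-subject CV.
    """
    results: list[RcvResult] = []
    skipped: list[str] = []
    for inp in inputs:
        if inp.cv_i is None:
            skipped.append(inp.analyte)
            continue
        for z in z_levels:
            results.append(
                asymmetric_rcv(
                    BioVariationInput(
                        analyte=inp.analyte,
                        cv_i=inp.cv_i,
                        cv_a=inp.cv_a,
                        cv_i_ci=inp.cv_i_ci,
                        cv_a_ci=inp.cv_a_ci,
                        z=z,
                    ),
                    mode=mode,
                )
            )
    return results, skipped


@dataclass(frozen=True)
class RcvDclComparison:
    """Ordering of an RCV increase threshold against a percent-change DCL."""

    analyte: str
    z: float
    rcv_increase: float
    dcl_limit: float
    rcv_increase_below_dcl: bool
    rcv_increase_above_dcl: bool
    tie: bool = field(default=False)


def compare_rcv_dcl(rcv: RcvResult, combined_dpc_dcl) -> RcvDclComparison:
    """Compare an RCV increase with a combined absDPC delta check limit.

    The DCL must be an absDPC limit for the combined group of the same
    analyte; both quantities are percent changes, so the comparison is
    direct.
    """
    if combined_dpc_dcl.metric != "absDPC":
        raise ValueError("DCL metric must be absDPC for comparison with an RCV")
    if combined_dpc_dcl.group != "combined":
        raise ValueError("DCL must be a combined-group limit")
    if combined_dpc_dcl.analyte != rcv.analyte:
        raise ValueError(
            f"analyte mismatch: {rcv.analyte} vs {combined_dpc_dcl.analyte}"
        )
    limit = combined_dpc_dcl.limit
    return RcvDclComparison(
        analyte=rcv.analyte,
        z=rcv.z,
        rcv_increase=rcv.increase,
        dcl_limit=limit,
        rcv_increase_below_dcl=rcv.increase < limit,
        rcv_increase_above_dcl=rcv.increase > limit,
        tie=rcv.increase == limit,
    )
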