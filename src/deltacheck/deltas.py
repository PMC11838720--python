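"""Delta statistics for current/previous result pairs.

Two deltas are used for result verification, each in signed and absolute
form:

* delta difference   DD  = current - previous          (analyte units)
* delta percent change DPC = DD / previous * 100       (%)

absDD = |DD| and absDPC = |DPC| are the flagging statistics; the signed
versions are kept for two-sided percentile tables (e.g. sex-stratified
2.5th/97.5th percentiles).  The percent change divides by the previous
result, so pairs with a non-positive previous value must be filtered out
upstream.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["compute_deltas", "METRIC_COLUMNS"]

#: flagging-metric name -> column holding it
METRIC_COLUMNS = {"absDD": "abs_dd", "absDPC": "abs_dpc"}


def compute_deltas(pairs: pd.DataFrame) -> pd.DataFrame:
    """Append dd, abs_dd, dpc and abs_dpc columns to a pairs table.

    ``abs_dd`` is in the analyte's units, ``abs_dpc`` in percent.  Raises
    ``ValueError`` if any ``prev_value`` is not strictly positive (a
    contract violation: the exclusion stage removes those pairs).
    """
    if (pairs["prev_value"] <= 0).any():
        raise ValueError("prev_value must be > 0; filter pairs upstream")
    out = pairs.copy()
    out["dd"] = out["curr_value"] - out["prev_value"]
    out["abs_dd"] = out["dd"].abs()
    out["dpc"] = out["dd"] / out["prev_value"] * 100.0
    out["abs_dpc"] = out["dpc"].abs()
    return out
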