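"""Synthetic paired-result cohorts for delta check development.

Real current/previous hormone pairs are hospital data and rarely shareable,
so this module generates cohorts with the statistical structure that delta
check analysis assumes:

* strictly positive, right-skewed results — each synthetic patient carries a
  lognormal homeostatic set-point whose median and interquartile range match
  the configured group statistics;
* within-patient serial correlation — the current and previous results share
  the set-point and differ only by independent multiplicative lognormal
  within-subject (CV_I) and analytical (CV_A) noise;
* clinical strata — inpatient/emergency ("IE") vs outpatient ("O") groups
  with their own location/spread, sex with an optional multiplicative
  location ratio, age, and institution labels;
* sampling-interval structure — days between the paired results follow a
  discretized lognormal with a configurable median, truncated to the
  1-day-to-3-year window that pairing rules impose.

CVs are percent; a CV of c maps to a log-scale variance of ln(1 + c^2/1e4),
so the noise factor exp(N(0, sigma^2)) has exactly that coefficient of
variation and unit median.  Values are clipped (not rejected) at the
analytical measurement interval, mirroring instrument reporting limits.

One pair is drawn per synthetic patient; downstream stages treat every pair
as an independent observation in any case.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AnalyteSpec",
    "CohortConfig",
    "generate_cohort",
    "inject_gross_errors",
    "cv_to_log_sigma",
    "setpoint_log_sigma",
    "PAIR_COLUMNS",
]

#: canonical column order of a pairs table
PAIR_COLUMNS = [
    "patient_id", "analyte", "group", "sex", "age", "institution",
    "prev_value", "prev_time", "curr_value", "curr_time",
]

_Z75 = 0.6744897501960817  # 75th standard-normal percentile
_STUDY_START = pd.Timestamp("2020-01-01")
_STUDY_END = pd.Timestamp("2022-08-31")


def cv_to_log_sigma(cv_percent: float) -> float:
    """Log-scale SD of a lognormal factor with the given percent CV."""
    return math.sqrt(math.log1p(cv_percent**2 / 1e4))


def setpoint_log_sigma(median: float, iqr: float) -> float:
    """Log-scale SD of a lognormal set-point matching a median and IQR width.

    For LN(mu, s) the quartiles are exp(mu -/+ z75*s), so the IQR width is
    2*median*sinh(z75*s); inverting gives a closed form.
    """
    if median <= 0:
        raise ValueError("median must be > 0")
    if iqr < 0:
        raise ValueError("iqr must be >= 0")
    return math.asinh(iqr / (2.0 * median)) / _Z75


@dataclass(frozen=True)
class AnalyteSpec:
    """Generator parameters for one analyte.

    ``median_*``/``iqr_*`` describe the target result distribution per
    clinical group (IE = inpatient/emergency, O = outpatient); when
    ``sex_effect != 1`` they apply to females and male set-points are
    multiplied by ``sex_effect``.  ``cv_i``/``cv_a`` are the within-subject
    and analytical CVs in percent; ``ami_low``/``ami_high`` bound reportable
    values (the analytical measurement interval).
    """

    name: str
    unit: str
    ami_low: float
    ami_high: float
    median_ie: float
    iqr_ie: float
    median_o: float
    iqr_o: float
    cv_i: float
    cv_a: float
    sex_effect: float = 1.0

    def __post_init__(self) -> None:
        vals = [self.ami_low, self.ami_high, self.median_ie, self.iqr_ie,
                self.median_o, self.iqr_o, self.cv_i, self.cv_a, self.sex_effect]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"{self.name}: non-finite spec value")
        if not 0 < self.ami_low < self.ami_high:
            raise ValueError(f"{self.name}: need 0 < ami_low < ami_high")
        if self.cv_i < 0 or self.cv_a < 0:
            raise ValueError(f"{self.name}: CVs must be >= 0")
        if self.iqr_ie < 0 or self.iqr_o < 0:
            raise ValueError(f"{self.name}: IQR widths must be >= 0")
        if self.sex_effect <= 0:
            raise ValueError(f"{self.name}: sex_effect must be > 0")
        for m in (self.median_ie, self.median_o):
            if not self.ami_low <= m <= self.ami_high:
                raise ValueError(f"{self.name}: median {m} outside AMI")

    def median(self, group: str) -> float:
        return self.median_ie if group == "IE" else self.median_o

    def iqr(self, group: str) -> float:
        return self.iqr_ie if group == "IE" else self.iqr_o


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generator parameters.

    Delta intervals (days between previous and current test) are drawn from
    a discretized lognormal with group-specific median and IQR width,
    truncated to [1, 1095] days.
    """

    analytes: tuple[AnalyteSpec, ...]
    n_pairs_ie: int
    n_pairs_o: int
    female_fraction_ie: float = 0.6
    female_fraction_o: float = 0.65
    delta_interval_median_ie: float = 30.0
    delta_interval_median_o: float = 150.0
    delta_interval_iqr_ie: float = 120.0
    delta_interval_iqr_o: float = 130.0
    n_institutions: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs_ie < 0 or self.n_pairs_o < 0:
            raise ValueError("pair counts must be >= 0")
        for f in (self.female_fraction_ie, self.female_fraction_o):
            if not 0.0 <= f <= 1.0:
                raise ValueError("female fractions must lie in [0, 1]")
        if self.n_institutions < 1:
            raise ValueError("need at least one institution")
        if self.delta_interval_median_ie <= 0 or self.delta_interval_median_o <= 0:
            raise ValueError("delta-interval medians must be > 0")

    def to_json(self) -> str:
        d = asdict(self)
        d["analytes"] = [asdict(a) for a in self.analytes]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        d = json.loads(text)
        d["analytes"] = tuple(AnalyteSpec(**a) for a in d["analytes"])
        return cls(**d)


def _draw_intervals(rng: np.random.Generator, n: int, median: float,
                    iqr: float) -> np.ndarray:
    s = setpoint_log_sigma(median, iqr)
    days = np.rint(np.exp(rng.normal(math.log(median), s, size=n)))
    return np.clip(days, 1, 1095).astype(int)


def _generate_stratum(rng: np.random.Generator, spec: AnalyteSpec, group: str,
                      n: int, female_fraction: float, interval_median: float,
                      interval_iqr: float, n_institutions: int) -> pd.DataFrame:
    sex = np.where(rng.random(n) < female_fraction, "F", "M")
    mu = math.log(spec.median(group)) + np.where(
        sex == "M", math.log(spec.sex_effect), 0.0
    )
    s_between = setpoint_log_sigma(spec.median(group), spec.iqr(group))
    setpoint = np.exp(rng.normal(mu, s_between))
    s_noise = math.hypot(cv_to_log_sigma(spec.cv_i), cv_to_log_sigma(spec.cv_a))
    prev = setpoint * np.exp(rng.normal(0.0, s_noise, size=n))
    curr = setpoint * np.exp(rng.normal(0.0, s_noise, size=n))
    prev = np.clip(prev, spec.ami_low, spec.ami_high)
    curr = np.clip(curr, spec.ami_low, spec.ami_high)

    intervals = _draw_intervals(rng, n, interval_median, interval_iqr)
    span_days = (_STUDY_END - _STUDY_START).days
    curr_time = _STUDY_START + pd.to_timedelta(
        rng.integers(0, span_days + 1, size=n), unit="D"
    )
    prev_time = curr_time - pd.to_timedelta(intervals, unit="D")

    institutions = np.array(
        [chr(ord("A") + i) for i in range(n_institutions)]
    )[rng.integers(0, n_institutions, size=n)]

    return pd.DataFrame({
        "patient_id": [f"{spec.name}-{group}-{i:06d}" for i in range(n)],
        "analyte": spec.name,
        "group": group,
        "sex": sex,
        "age": rng.integers(19, 91, size=n),
        "institution": institutions,
        "prev_value": prev,
        "prev_time": prev_time,
        "curr_value": curr,
        "curr_time": curr_time,
    })


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a paired-result cohort as a tidy table (one row per pair).

    Deterministic for a fixed config (including seed).  Returns
    ``n_pairs_ie + n_pairs_o`` rows per analyte with columns
    ``PAIR_COLUMNS``; values lie in each analyte's measurement interval and
    delta intervals in [1, 1095] days.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    for spec in config.analytes:
        for group, n, ff, im, iq in (
            ("IE", config.n_pairs_ie, config.female_fraction_ie,
             config.delta_interval_median_ie, config.delta_interval_iqr_ie),
            ("O", config.n_pairs_o, config.female_fraction_o,
             config.delta_interval_median_o, config.delta_interval_iqr_o),
        ):
            if n == 0:
                continue
            frames.append(
                _generate_stratum(rng, spec, group, n, ff, im, iq,
                                  config.n_institutions)
            )
    if not frames:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(frames, ignore_index=True)[PAIR_COLUMNS]


def inject_gross_errors(
    pairs: pd.DataFrame, rate: float, magnitude: float, seed: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Corrupt a random subset of current values by a fold-change.

    A Bernoulli(``rate``) subset of rows has ``curr_value`` multiplied or
    divided (fair coin) by ``magnitude``, emulating gross errors such as
    sample mix-ups or dilution mistakes.  Returns the modified copy and a
    boolean flag array marking altered rows; unflagged rows are untouched.
    This is a demonstration utility for error-flagging studies, not part of
    limit estimation itself.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if magnitude <= 0:
        raise ValueError("magnitude must be > 0")
    rng = np.random.default_rng(seed)
    flags = rng.random(len(pairs)) < rate
    out = pairs.copy()
    factor = np.where(rng.random(len(pairs)) < 0.5, magnitude, 1.0 / magnitude)
    out.loc[flags, "curr_value"] = out.loc[flags, "curr_value"] * factor[flags]
    return out, flags
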