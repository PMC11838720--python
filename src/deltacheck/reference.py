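"""Reference parameter sets for frequently requested hormone tests.

Two tables are shipped:

``BIOLOGICAL_VARIATION``
    Within-subject biological variation (CV_I, percent, with confidence
    limits from the EFLM biological-variation database) and analytical
    imprecision (CV_A, percent, averaged over hospital QC materials) for
    six hormones.  ACTH has no published CV_I, so its entry carries
    ``cv_i=None`` and no RCV can be computed for it.

``DEFAULT_ANALYTES``
    Generator presets for seven hormones: analytical measurement interval
    (AMI), group-wise result medians and interquartile ranges for the
    inpatient/emergency (IE) and outpatient (O) strata, and the CVs above.
    For insulin, testosterone and thyroglobulin only outpatient statistics
    are available (inpatient volumes for these tests are low), so the O
    values stand in for both groups.  ACTH is given a nominal CV_I of 25%
    for simulation purposes only; that number is a placeholder, not a
    biological-variation estimate.
"""

from __future__ import annotations

from .rcv import BioVariationInput
from .synthetic import AnalyteSpec

__all__ = ["BIOLOGICAL_VARIATION", "DEFAULT_ANALYTES"]

BIOLOGICAL_VARIATION: dict[str, BioVariationInput] = {
    "ACTH": BioVariationInput(
        analyte="ACTH", cv_i=None, cv_a=2.50, cv_a_ci=(2.30, 2.70)
    ),
    "cortisol": BioVariationInput(
        analyte="cortisol",
        cv_i=16.1, cv_i_ci=(15.5, 26.6),
        cv_a=2.12, cv_a_ci=(2.02, 2.22),
    ),
    "PTH": BioVariationInput(
        analyte="PTH",
        cv_i=14.7, cv_i_ci=(11.3, 25.9),
        cv_a=2.19, cv_a_ci=(2.07, 2.31),
    ),
    "prolactin": BioVariationInput(
        analyte="prolactin",
        cv_i=45.0, cv_i_ci=(39.2, 58.0),
        cv_a=1.95, cv_a_ci=(1.85, 2.04),
    ),
    "insulin": BioVariationInput(
        analyte="insulin",
        cv_i=25.4, cv_i_ci=(21.1, 37.1),
        cv_a=2.54, cv_a_ci=(2.41, 2.67),
    ),
    "testosterone": BioVariationInput(
        analyte="testosterone",
        cv_i=14.5, cv_i_ci=(10.9, 16.3),
        cv_a=2.41, cv_a_ci=(2.32, 2.50),
    ),
    "thyroglobulin": BioVariationInput(
        analyte="thyroglobulin",
        cv_i=10.9, cv_i_ci=(10.3, 16.2),
        cv_a=2.93, cv_a_ci=(2.76, 3.09),
    ),
}

# median/iqr are (location, width) of the observed result distributions per
# clinical group; iqr width = Q3 - Q1.
DEFAULT_ANALYTES: dict[str, AnalyteSpec] = {
    "ACTH": AnalyteSpec(
        name="ACTH", unit="pmol/L", ami_low=0.330, ami_high=440.0,
        median_ie=4.8, iqr_ie=6.7, median_o=4.6, iqr_o=5.0,
        cv_i=25.0, cv_a=2.50,  # nominal CV_I; no published estimate
    ),
    "cortisol": AnalyteSpec(
        name="cortisol", unit="nmol/L", ami_low=1.5, ami_high=1750.0,
        median_ie=325.7, iqr_ie=315.4, median_o=187.7, iqr_o=240.1,
        cv_i=16.1, cv_a=2.12,
    ),
    "PTH": AnalyteSpec(
        name="PTH", unit="pmol/L", ami_low=0.127, ami_high=530.0,
        median_ie=3.2, iqr_ie=4.4, median_o=6.1, iqr_o=20.4,
        cv_i=14.7, cv_a=2.19,
    ),
    "prolactin": AnalyteSpec(
        name="prolactin", unit="ug/L", ami_low=0.094, ami_high=470.0,
        median_ie=38.8, iqr_ie=69.0, median_o=17.1, iqr_o=23.7,
        cv_i=45.0, cv_a=1.95,
    ),
    "insulin": AnalyteSpec(
        name="insulin", unit="pmol/L", ami_low=2.78, ami_high=6945.0,
        median_ie=57.0, iqr_ie=57.0, median_o=57.0, iqr_o=57.0,
        cv_i=25.4, cv_a=2.54,
    ),
    "testosterone": AnalyteSpec(
        name="testosterone", unit="nmol/L", ami_low=0.087, ami_high=52.0,
        median_ie=0.1, iqr_ie=0.5, median_o=0.1, iqr_o=0.5,
        cv_i=14.5, cv_a=2.41, sex_effect=20.0,
    ),
    "thyroglobulin": AnalyteSpec(
        name="thyroglobulin", unit="ug/L", ami_low=0.04, ami_high=500.0,
        median_ie=2.6, iqr_ie=6.8, median_o=2.6, iqr_o=6.8,
        cv_i=10.9, cv_a=2.93,
    ),
}
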