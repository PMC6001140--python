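"""Printed summary counts from the original ISCOPE cohort study (n = 2211).

These are inputs, not results: the original individual-level data are not
public, but the published univariate table prints the 2x2 cell counts for
every categorical predictor against relevant functional decline, and the
composite-outcome component counts.  Recomputing odds ratios, confidence
intervals and the decline prevalence from these counts exercises the
inference module against values that are exactly reproducible.

Cell convention follows :class:`declina.inference.TwoByTwo`:
a = exposed with decline, b = unexposed (reference level) with decline,
c = exposed without decline, d = unexposed without decline.
"""

from __future__ import annotations

from .inference import TwoByTwo

# Composite outcome components among the 2211 analysed participants.
N_ANALYSED = 2211
N_DIED = 148
N_NURSING_HOME = 45
N_GARS_P90 = 201

# Categorical predictor 2x2 tables vs relevant functional decline
# (exposure level shown; reference level in the comment).
UNIVARIATE_TABLES: dict[str, TwoByTwo] = {
    # female vs male
    "female": TwoByTwo(a=246, b=148, c=1258, d=559),
    # >= 4 daily medications vs < 4
    "polypharmacy": TwoByTwo(a=287, b=107, c=1214, d=603),
    # > 1 chronic disease vs <= 1
    "multimorbidity": TwoByTwo(a=363, b=31, c=1648, d=169),
    # home for older persons vs independent
    "home_for_older_persons": TwoByTwo(a=65, b=329, c=161, d=1656),
    # GP opinion vs not_vulnerable
    "gp_possibly_vulnerable": TwoByTwo(a=99, b=92, c=518, d=802),
    "gp_vulnerable": TwoByTwo(a=203, b=92, c=497, d=802),
    # ISCOPE score vs score 0
    "iscope_1": TwoByTwo(a=11, b=19, c=172, d=179),
    "iscope_2": TwoByTwo(a=106, b=19, c=508, d=179),
    "iscope_3": TwoByTwo(a=156, b=19, c=687, d=179),
    "iscope_4": TwoByTwo(a=102, b=19, c=271, d=179),
}

# Odds ratios and 95% CIs as printed, for cross-checking recomputation.
PUBLISHED_ORS: dict[str, tuple[float, float, float]] = {
    "female": (0.74, 0.59, 0.93),
    "polypharmacy": (1.33, 1.05, 1.70),
    "multimorbidity": (1.20, 0.81, 1.79),
    "home_for_older_persons": (2.03, 1.49, 2.77),
    "gp_possibly_vulnerable": (1.67, 1.23, 2.26),
    "gp_vulnerable": (3.56, 2.72, 4.67),
    "iscope_1": (0.60, 0.28, 1.30),
    "iscope_2": (1.97, 1.17, 3.30),
    "iscope_3": (2.14, 1.29, 3.54),
    "iscope_4": (3.55, 2.10, 5.99),
}

# Baseline-characteristics comparison, analysed vs not included:
# sex counts (male, female) per group, printed chi-square p = 0.362.
SEX_INCLUDED = (707, 1504)
SEX_EXCLUDED = (150, 352)
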