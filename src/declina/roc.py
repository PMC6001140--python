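"""ROC curves, AUC, and the DeLong paired test for nested-model comparison.

The AUC is computed as the normalized Mann-Whitney statistic — the fraction
of case-control pairs the score orders correctly, ties counting one half —
which equals the trapezoidal area under the empirical ROC curve.  Paired
comparison of two models evaluated on the same participants uses DeLong's
nonparametric test: the variance of the AUC difference follows from the
empirical covariance of per-case and per-control placement values.  A seeded
paired-bootstrap alternative is provided as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata


class RocError(ValueError):
    pass


@dataclass
class RocResult:
    thresholds: np.ndarray          # descending score cut-offs
    sensitivity: np.ndarray         # true-positive rate at each cut-off
    one_minus_specificity: np.ndarray
    auc: float
    case_placements: np.ndarray     # per-case fraction of controls scored below
    control_placements: np.ndarray  # per-control fraction of cases scored above


@dataclass
class AucComparison:
    auc_a: float
    auc_b: float
    delta: float          # auc_b - auc_a
    variance: float
    z: float
    p_value: float
    note: str = ""


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midrank placement values; their means both equal the AUC."""
    cases = scores[labels]
    controls = scores[~labels]
    m, n = cases.size, controls.size
    ranks_all = rankdata(np.concatenate([cases, controls]))
    ranks_cases = rankdata(cases)
    ranks_controls = rankdata(controls)
    # V10[i]: fraction of controls below case i (ties half)
    v10 = (ranks_all[:m] - ranks_cases) / n
    # V01[j]: fraction of cases above control j (ties half)
    v01 = 1.0 - (ranks_all[m:] - ranks_controls) / m
    return v10, v01


def auc(scores, labels) -> RocResult:
    """Empirical ROC and AUC. Requires at least one case and one control."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise RocError("scores and labels length mismatch")
    n_cases = int(labels.sum())
    n_controls = int((~labels).sum())
    if n_cases == 0 or n_controls == 0:
        raise RocError("AUC undefined: need at least one case and one control")

    v10, v01 = _placements(scores, labels)
    area = float(v10.mean())

    # empirical curve over unique descending thresholds
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores) != 0), scores.size - 1]
    tp = np.cumsum(sorted_labels)[distinct]
    fp = np.cumsum(~sorted_labels)[distinct]
    sens = np.r_[0.0, tp / n_cases]
    fpr = np.r_[0.0, fp / n_controls]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        one_minus_specificity=fpr,
        auc=area,
        case_placements=v10,
        control_placements=v01,
    )


def compare_paired(scores_a, scores_b, labels) -> AucComparison:
    """DeLong's paired test of AUC difference between two score vectors on
    the same participants; two-sided normal p-value.

    Identical score vectors give delta 0 and p 1.  Zero estimated variance
    with a nonzero delta is reported with a floor p-value and a note.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise RocError("paired comparison requires equal-length inputs")
    ra = auc(scores_a, labels)
    rb = auc(scores_b, labels)
    delta = rb.auc - ra.auc

    m = ra.case_placements.size
    n = ra.control_placements.size
    d10 = rb.case_placements - ra.case_placements
    d01 = rb.control_placements - ra.control_placements
    # sample variances of the placement differences (ddof=1; 0 if only one)
    s10 = float(np.var(d10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(d01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n

    note = ""
    if np.array_equal(scores_a, scores_b):
        return AucComparison(ra.auc, rb.auc, 0.0, var, 0.0, 1.0)
    if var <= 0.0:
        if delta == 0.0:
            return AucComparison(ra.auc, rb.auc, 0.0, 0.0, 0.0, 1.0)
        note = "zero estimated variance with nonzero AUC difference; p floored"
        return AucComparison(ra.auc, rb.auc, delta,
                             0.0, math.copysign(math.inf, delta),
                             5e-324, note)
    z = delta / math.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return AucComparison(ra.auc, rb.auc, delta, var, z, p, note)


def compare_bootstrap(
    scores_a, scores_b, labels, n_boot: int = 2000, seed: int = 0
) -> AucComparison:
    """Paired-bootstrap cross-check: resample participants with replacement,
    recompute both AUCs, and take the percentile-z p-value of the difference."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    ra = auc(scores_a, labels)
    rb = auc(scores_b, labels)
    delta = rb.auc - ra.auc
    rng = np.random.default_rng(seed)
    n = labels.size
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(n, size=n)
        lab = labels[idx]
        if lab.all() or not lab.any():
            deltas[b] = np.nan
            continue
        deltas[b] = auc(scores_b[idx], lab).auc - auc(scores_a[idx], lab).auc
    deltas = deltas[~np.isnan(deltas)]
    var = float(np.var(deltas, ddof=1)) if deltas.size > 1 else 0.0
    if var <= 0.0:
        return AucComparison(ra.auc, rb.auc, delta, 0.0, 0.0, 1.0,
                             "degenerate bootstrap distribution")
    z = delta / math.sqrt(var)
    return AucComparison(ra.auc, rb.auc, delta, var, z, 2.0 * norm.sf(abs(z)))
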