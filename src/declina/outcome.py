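"""Relevant functional decline: ceiling-corrected stratified-percentile label.

A raw 12-month change in GARS means different things at different baselines:
someone starting at 30 can rise by 42 points, someone at 65 by at most 7
(ceiling effect).  The proportional increase

    (GARS_12 - GARS_0) / (72 - GARS_0)

rescales the change by the room left on the scale.  Participants are then
binned into six baseline-GARS strata (18-26, 27-35, 36-44, 45-53, 54-62,
63-72) and flagged when their proportional increase exceeds the 90th
percentile of their stratum, so roughly the worst-declining tenth of each
stratum is labelled.  Death and nursing-home admission during follow-up count
as relevant decline unconditionally; lost-to-follow-up participants are
excluded from both labelling and percentile computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

STRATUM_EDGES = ((18, 26), (27, 35), (36, 44), (45, 53), (54, 62), (63, 72))
N_STRATA = len(STRATUM_EDGES)


class OutcomeError(ValueError):
    pass


@dataclass(frozen=True)
class OutcomeLabel:
    declined: bool
    reason: str  # died | nursing_home | gars_p90 | none
    proportional_increase: float | None = None
    stratum: int | None = None


@dataclass
class StratumCutoffs:
    """Per-stratum accounting: evaluable participant count, the p90 cut-off
    of the proportional increase (None for empty strata), flagged count."""

    n: list[int]
    p90: list[float | None]
    flagged: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": range(1, N_STRATA + 1),
                "gars_t0_low": [lo for lo, _ in STRATUM_EDGES],
                "gars_t0_high": [hi for _, hi in STRATUM_EDGES],
                "n": self.n,
                "p90": self.p90,
                "flagged": self.flagged,
            }
        )


def proportional_increase(g0: int, g12: int) -> float:
    """Ceiling-corrected change; always <= 1.

    The degenerate both-at-ceiling case (g0 = g12 = 72) returns 0 (no
    change); improvement *from* the ceiling (g0 = 72, g12 < 72) has no
    defined potential increase and returns NaN — callers treat such
    participants as ceiling cases, excluded from percentile computation.
    """
    for name, v in (("baseline", g0), ("12-month", g12)):
        if not 18 <= v <= 72:
            raise OutcomeError(f"{name} GARS total {v} outside 18..72")
    if g0 == 72:
        return 0.0 if g12 == 72 else math.nan
    return (g12 - g0) / (72 - g0)


def assign_stratum(g0: int) -> int:
    """Closed-interval baseline-GARS bin, 1..6."""
    for k, (lo, hi) in enumerate(STRATUM_EDGES, start=1):
        if lo <= g0 <= hi:
            return k
    raise OutcomeError(f"baseline GARS total {g0} outside 18..72")


def stratum_p90(values, method: str = "nearest-rank") -> float:
    """90th percentile of a non-empty collection.

    nearest-rank: the ceil(0.9 n)-th order statistic, the smallest value v
    such that at least 90% of observations are <= v.  "linear" uses the
    usual interpolated sample quantile.
    """
    arr = np.asarray(sorted(values), dtype=float)
    if arr.size == 0:
        raise OutcomeError("p90 of an empty stratum")
    if method == "nearest-rank":
        rank = math.ceil(0.9 * arr.size)
        return float(arr[rank - 1])
    if method == "linear":
        return float(np.quantile(arr, 0.9))
    raise OutcomeError(f"unknown quantile method {method!r}")


def flag_by_stratum_p90(
    strata,
    values,
    method: str = "nearest-rank",
    inequality: str = "strict",
) -> tuple[np.ndarray, StratumCutoffs]:
    """Core percentile rule on pre-computed (stratum, proportional-increase)
    pairs: within each stratum, flag values beyond the stratum's p90.

    ``inequality="strict"`` flags values strictly greater than the cut-off
    (the default rule); ``"weak"`` flags >=.  NaN values are never flagged
    and never contribute to the cut-off.
    """
    if inequality not in ("strict", "weak"):
        raise OutcomeError(f"unknown inequality {inequality!r}")
    strata = np.asarray(strata, dtype=int)
    values = np.asarray(values, dtype=float)
    if strata.shape != values.shape:
        raise OutcomeError("strata and values length mismatch")
    flags = np.zeros(values.shape, dtype=bool)
    ns, p90s, counts = [], [], []
    for k in range(1, N_STRATA + 1):
        mask = (strata == k) & ~np.isnan(values)
        nk = int(mask.sum())
        ns.append(nk)
        if nk == 0:
            p90s.append(None)
            counts.append(0)
            continue
        cut = stratum_p90(values[mask], method=method)
        p90s.append(cut)
        if inequality == "strict":
            fl = mask & (values > cut)
        else:
            fl = mask & (values >= cut)
        flags |= fl
        counts.append(int(fl.sum()))
    return flags, StratumCutoffs(n=ns, p90=p90s, flagged=counts)


def classify_cohort(
    scored: pd.DataFrame,
    method: str = "nearest-rank",
    inequality: str = "strict",
    exclude_ceiling: bool = False,
) -> tuple[pd.DataFrame, StratumCutoffs]:
    """Label a scored cohort (see :func:`declina.scoring.score_cohort`).

    Returns the evaluable rows (lost-to-follow-up dropped; both-at-ceiling
    participants additionally dropped when ``exclude_ceiling``) with
    ``declined``, ``reason``, ``prop_increase`` and ``stratum`` columns,
    plus the per-stratum cut-off report.  Percentiles are computed over
    followed-up participants only; deaths and nursing-home admissions are
    labelled declined unconditionally and contribute no proportional
    increase.
    """
    df = scored[scored["event"] != "lost"].copy()
    if df.empty:
        raise OutcomeError("no evaluable participants")
    df["stratum"] = df["gars_t0"].map(assign_stratum)

    followed = df["event"] == "followed_up"
    prop = np.full(len(df), np.nan)
    g0 = df["gars_t0"].to_numpy()
    g12 = df["gars_t12"].to_numpy(dtype=float)
    idx = np.flatnonzero(followed.to_numpy())
    for i in idx:
        prop[i] = proportional_increase(int(g0[i]), int(g12[i]))
    df["prop_increase"] = prop

    if exclude_ceiling:
        ceiling = followed.to_numpy() & (g0 == 72)
        df = df[~ceiling].copy()
        followed = df["event"] == "followed_up"
        prop = df["prop_increase"].to_numpy()

    strata = df["stratum"].to_numpy()
    vals = np.where(followed.to_numpy(), df["prop_increase"].to_numpy(), np.nan)
    flags, cutoffs = flag_by_stratum_p90(strata, vals, method=method,
                                         inequality=inequality)

    reason = np.where(
        df["event"] == "died", "died",
        np.where(df["event"] == "nursing_home", "nursing_home",
                 np.where(flags, "gars_p90", "none")),
    )
    df["reason"] = reason
    df["declined"] = df["reason"] != "none"
    return df, cutoffs
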