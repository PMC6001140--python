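"""End-to-end analysis: inclusion, scoring, outcome, tables, model ladder.

The prediction-model ladder comprises eight nested logistic models:

    1  age + sex
    2  model 1 + polypharmacy + multimorbidity + living situation
    3  model 1 + ISCOPE score
    4  model 1 + GP opinion
    5  model 1 + ISCOPE score + GP opinion
    6  model 2 + ISCOPE score
    7  model 2 + GP opinion
    8  model 2 + ISCOPE score + GP opinion

compared pairwise (2 vs 1, 3 vs 1, 4 vs 1, 5 vs 4, 6 vs 2, 7 vs 2, 8 vs 7)
by in-sample AUC with DeLong's paired test, plus the AUC of the GP opinion
alone.  Baseline GARS is never a predictor in the ladder.  Two sensitivity
analyses re-run the ladder within each baseline-GARS stratum and after
excluding participants at the GARS ceiling at both time points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, mannwhitneyu

from . import outcome as outcome_mod
from .config import DEFAULT_DOMAIN_ITEM_MAP
from .inference import (
    FittedModel,
    InferenceError,
    build_design,
    fit_model,
    nagelkerke_r2,
    predicted_risk,
)
from .records import ParticipantRecord
from .roc import auc, compare_paired
from .scoring import score_cohort

log = logging.getLogger("declina")

MODEL_TERMS: dict[int, list[str]] = {
    1: ["age", "sex"],
    2: ["age", "sex", "polypharmacy", "multimorbidity", "living"],
    3: ["age", "sex", "iscope_score"],
    4: ["age", "sex", "gp_opinion"],
    5: ["age", "sex", "iscope_score", "gp_opinion"],
    6: ["age", "sex", "polypharmacy", "multimorbidity", "living", "iscope_score"],
    7: ["age", "sex", "polypharmacy", "multimorbidity", "living", "gp_opinion"],
    8: ["age", "sex", "polypharmacy", "multimorbidity", "living", "iscope_score",
        "gp_opinion"],
}

# model -> comparator in the ladder
MODEL_COMPARATORS: dict[int, int | None] = {
    1: None, 2: 1, 3: 1, 4: 1, 5: 4, 6: 2, 7: 2, 8: 7,
}

UNIVARIATE_EXPOSURES = [
    ("female", "sex", "female"),
    ("polypharmacy", "polypharmacy", True),
    ("multimorbidity", "multimorbidity", True),
    ("home_for_older_persons", "living", "home_for_older_persons"),
    ("gp_possibly_vulnerable", "gp_opinion", "possibly_vulnerable"),
    ("gp_vulnerable", "gp_opinion", "vulnerable"),
    ("iscope_1", "iscope_score", 1),
    ("iscope_2", "iscope_score", 2),
    ("iscope_3", "iscope_score", 3),
    ("iscope_4", "iscope_score", 4),
]

UNIVARIATE_REFERENCES = {
    "sex": "male",
    "polypharmacy": False,
    "multimorbidity": False,
    "living": "independent",
    "gp_opinion": "not_vulnerable",
    "iscope_score": 0,
}


@dataclass
class InclusionAccounting:
    total: int
    followed_up: int
    died: int
    nursing_home: int
    excluded: dict[str, int]

    @property
    def included(self) -> int:
        return self.followed_up + self.died + self.nursing_home


@dataclass
class AnalysisReport:
    inclusion: InclusionAccounting
    baseline_table: pd.DataFrame
    cutoffs: pd.DataFrame
    univariate: pd.DataFrame
    ladder: pd.DataFrame
    gp_only_auc: float
    stratified: pd.DataFrame
    ceiling_sensitivity: pd.DataFrame
    labelled: pd.DataFrame = field(repr=False, default=None)
    models: dict[int, FittedModel] = field(repr=False, default_factory=dict)


def apply_inclusion(records: list[ParticipantRecord]):
    """Complete-case filter: keep followed-up participants with full data,
    plus deaths and nursing-home admissions with full baseline data.
    Excluded records carry a reason code."""
    included: list[ParticipantRecord] = []
    excluded: list[tuple[ParticipantRecord, str]] = []
    for r in records:
        if r.event == "lost":
            excluded.append((r, "lost"))
        elif r.event == "followed_up" and r.gars_items_t12 is None:
            excluded.append((r, "missing-followup"))
        else:
            included.append(r)
    return included, excluded


def baseline_table(scored_a: pd.DataFrame, scored_b: pd.DataFrame) -> pd.DataFrame:
    """Group comparison of baseline characteristics: median (IQR) with a
    two-sided Mann-Whitney p for continuous variables; counts (%) with a
    Pearson chi-square p (no continuity correction) over the variable's
    full category set for categoricals."""
    rows = []
    for var in ("age", "gars_t0"):
        a = scored_a[var].dropna().to_numpy(dtype=float)
        b = scored_b[var].dropna().to_numpy(dtype=float)
        p = np.nan
        if a.size and b.size:
            p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({
            "variable": var, "level": "median (IQR)",
            "group_a": _median_iqr(a), "group_b": _median_iqr(b),
            "p_value": p,
        })
    for var in ("sex", "polypharmacy", "multimorbidity", "living", "gp_opinion",
                "iscope_score"):
        levels = sorted(set(scored_a[var].dropna()) | set(scored_b[var].dropna()),
                        key=str)
        counts_a = [int((scored_a[var] == lev).sum()) for lev in levels]
        counts_b = [int((scored_b[var] == lev).sum()) for lev in levels]
        keep = [i for i in range(len(levels)) if counts_a[i] + counts_b[i] > 0]
        if len(keep) < len(levels):
            log.info("baseline_table: dropping empty categories of %s", var)
        table = np.array([[counts_a[i] for i in keep], [counts_b[i] for i in keep]])
        p = np.nan
        if table.shape[1] >= 2 and table.sum(axis=1).min() > 0:
            p = float(chi2_contingency(table, correction=False)[1])
        for i in keep:
            rows.append({
                "variable": var, "level": str(levels[i]),
                "group_a": f"{counts_a[i]} ({100 * counts_a[i] / max(1, sum(counts_a)):.1f}%)",
                "group_b": f"{counts_b[i]} ({100 * counts_b[i] / max(1, sum(counts_b)):.1f}%)",
                "p_value": p,
            })
    return pd.DataFrame(rows)


def _median_iqr(x: np.ndarray) -> str:
    if x.size == 0:
        return "-"
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    return f"{q2:.1f} ({q1:.1f}; {q3:.1f})"


def univariate_table(labelled: pd.DataFrame) -> pd.DataFrame:
    """Per-exposure 2x2 odds ratios with Woolf 95% CIs against decline,
    plus the per-year age OR from a univariate logistic fit."""
    from .inference import TwoByTwo, odds_ratio

    y = labelled["declined"].to_numpy(dtype=bool)
    rows = []
    m_age = fit_model(labelled.assign(declined01=y.astype(int)), "declined01", ["age"])
    b, se = m_age.coef("age"), m_age.se("age")
    rows.append({
        "exposure": "age_per_year",
        "a": np.nan, "b": np.nan, "c": np.nan, "d": np.nan,
        "odds_ratio": float(np.exp(b)),
        "ci_low": float(np.exp(b - 1.959963984540054 * se)),
        "ci_high": float(np.exp(b + 1.959963984540054 * se)),
    })
    for name, col, level in UNIVARIATE_EXPOSURES:
        ref = UNIVARIATE_REFERENCES[col]
        exposed = labelled[col] == level
        refgrp = labelled[col] == ref
        t = TwoByTwo(
            a=int((exposed & y).sum()), b=int((refgrp & y).sum()),
            c=int((exposed & ~y).sum()), d=int((refgrp & ~y).sum()),
        )
        try:
            or_, lo, hi = odds_ratio(t)
        except Exception:
            or_, lo, hi = np.nan, np.nan, np.nan
        rows.append({"exposure": name, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                     "odds_ratio": or_, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def fit_ladder(labelled: pd.DataFrame) -> tuple[dict[int, FittedModel], dict[int, np.ndarray]]:
    df = labelled.assign(declined01=labelled["declined"].astype(int))
    models: dict[int, FittedModel] = {}
    risks: dict[int, np.ndarray] = {}
    for k, terms in MODEL_TERMS.items():
        m = fit_model(df, "declined01", terms)
        if not m.converged:
            raise RuntimeError(f"model {k} failed to converge: {m.diagnostic}")
        X, _ = build_design(df, terms)
        models[k] = m
        risks[k] = predicted_risk(m, X)
    return models, risks


def ladder_table(labelled: pd.DataFrame) -> tuple[pd.DataFrame, dict[int, FittedModel], float]:
    """Model-ladder table: in-sample AUC per model, comparator per the fixed
    ladder structure, DeLong delta/p, Nagelkerke R²; plus the AUC of the GP
    opinion entered alone."""
    y = labelled["declined"].to_numpy(dtype=bool)
    models, risks = fit_ladder(labelled)
    rows = []
    for k in sorted(MODEL_TERMS):
        res = auc(risks[k], y)
        comp = MODEL_COMPARATORS[k]
        delta = p = np.nan
        if comp is not None:
            cmp_res = compare_paired(risks[comp], risks[k], y)
            delta, p = cmp_res.delta, cmp_res.p_value
        rows.append({
            "model": k,
            "terms": "+".join(MODEL_TERMS[k]),
            "auc": res.auc,
            "compared_to": comp if comp is not None else "",
            "delta_auc": delta,
            "p_value": p,
            "nagelkerke_r2": nagelkerke_r2(models[k]),
        })
    df_gp = labelled.assign(declined01=labelled["declined"].astype(int))
    m_gp = fit_model(df_gp, "declined01", ["gp_opinion"])
    X_gp, _ = build_design(df_gp, ["gp_opinion"])
    gp_auc = auc(predicted_risk(m_gp, X_gp), y).auc
    return pd.DataFrame(rows), models, gp_auc


def sensitivity_stratified(labelled: pd.DataFrame, min_size: int = 40) -> pd.DataFrame:
    """Re-run the ladder within each baseline-GARS stratum.  Strata below
    ``min_size`` evaluable participants, or without both outcome classes,
    are reported as not evaluable."""
    rows = []
    for k in range(1, outcome_mod.N_STRATA + 1):
        sub = labelled[labelled["stratum"] == k]
        n = len(sub)
        n_decl = int(sub["declined"].sum())
        base = {"stratum": k, "n": n, "n_declined": n_decl}
        if n < min_size or n_decl == 0 or n_decl == n:
            for m in sorted(MODEL_TERMS):
                rows.append({**base, "model": m, "auc": np.nan,
                             "evaluable": False})
            continue
        try:
            _, risks = fit_ladder(sub)
        except (RuntimeError, InferenceError):
            for m in sorted(MODEL_TERMS):
                rows.append({**base, "model": m, "auc": np.nan,
                             "evaluable": False})
            continue
        y = sub["declined"].to_numpy(dtype=bool)
        for m in sorted(MODEL_TERMS):
            rows.append({**base, "model": m, "auc": auc(risks[m], y).auc,
                         "evaluable": True})
    return pd.DataFrame(rows)


def run_full_analysis(
    records: list[ParticipantRecord],
    domain_item_map=DEFAULT_DOMAIN_ITEM_MAP,
    quantile_method: str = "nearest-rank",
    inequality: str = "strict",
    min_stratum_size: int = 40,
) -> AnalysisReport:
    """Run the whole analysis on a cohort and assemble the report."""
    log.info("inclusion filter on %d records", len(records))
    included, excluded = apply_inclusion(records)
    if not included:
        raise RuntimeError("inclusion: no evaluable participants")
    scored = score_cohort(included, domain_item_map)
    scored_excl = score_cohort([r for r, _ in excluded], domain_item_map)

    reasons: dict[str, int] = {}
    for _, why in excluded:
        reasons[why] = reasons.get(why, 0) + 1
    inclusion = InclusionAccounting(
        total=len(records),
        followed_up=int((scored["event"] == "followed_up").sum()),
        died=int((scored["event"] == "died").sum()),
        nursing_home=int((scored["event"] == "nursing_home").sum()),
        excluded=reasons,
    )

    btable = (
        baseline_table(scored, scored_excl)
        if len(scored_excl) else pd.DataFrame()
    )

    log.info("outcome labelling (%s, %s)", quantile_method, inequality)
    labelled, cutoffs = outcome_mod.classify_cohort(
        scored, method=quantile_method, inequality=inequality
    )
    uni = univariate_table(labelled)
    log.info("fitting model ladder")
    ladder, models, gp_auc = ladder_table(labelled)
    strat = sensitivity_stratified(labelled, min_size=min_stratum_size)

    # ceiling sensitivity: drop participants at 72 at both time points
    labelled_nc, _ = outcome_mod.classify_cohort(
        scored, method=quantile_method, inequality=inequality, exclude_ceiling=True
    )
    ladder_nc, _, _ = ladder_table(labelled_nc)
    ceiling = ladder.merge(
        ladder_nc[["model", "auc"]], on="model", suffixes=("", "_no_ceiling")
    )[["model", "auc", "auc_no_ceiling"]]

    return AnalysisReport(
        inclusion=inclusion,
        baseline_table=btable,
        cutoffs=cutoffs.to_frame(),
        univariate=uni,
        ladder=ladder,
        gp_only_auc=gp_auc,
        stratified=strat,
        ceiling_sensitivity=ceiling,
        labelled=labelled,
        models=models,
    )


def write_report(report: AnalysisReport, outdir) -> None:
    """Serialize the report: one CSV per table plus a text summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.baseline_table.to_csv(outdir / "baseline_table.csv", index=False)
    report.cutoffs.to_csv(outdir / "stratum_cutoffs.csv", index=False)
    report.univariate.to_csv(outdir / "univariate_odds_ratios.csv", index=False)
    report.ladder.to_csv(outdir / "model_ladder.csv", index=False)
    report.stratified.to_csv(outdir / "stratified_sensitivity.csv", index=False)
    report.ceiling_sensitivity.to_csv(outdir / "ceiling_sensitivity.csv", index=False)
    for k, m in report.models.items():
        m.to_json(outdir / f"model_{k}.json")
    inc = report.inclusion
    n_decl = int(report.labelled["declined"].sum())
    lines = [
        "Functional-decline prediction analysis",
        "=" * 40,
        f"records in cohort file : {inc.total}",
        f"included               : {inc.included} "
        f"(followed up {inc.followed_up}, died {inc.died}, "
        f"nursing home {inc.nursing_home})",
        f"excluded               : {sum(inc.excluded.values())} {inc.excluded}",
        f"relevant decline       : {n_decl} "
        f"({100 * n_decl / inc.included:.1f}%)",
        f"GP opinion alone AUC   : {report.gp_only_auc:.3f}",
        "",
        "Model ladder (in-sample AUC, DeLong comparison):",
    ]
    for _, r in report.ladder.iterrows():
        comp = f" vs model {r['compared_to']}" if r["compared_to"] != "" else ""
        ptxt = f", p = {r['p_value']:.3f}" if np.isfinite(r["p_value"]) else ""
        lines.append(
            f"  model {int(r['model'])}: AUC {r['auc']:.3f}"
            f" (R2 {r['nagelkerke_r2']:.3f}){comp}{ptxt}"
        )
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
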