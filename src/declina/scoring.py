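"""GARS totals, screening-questionnaire domain score, derived covariates.

GARS (Groningen Activities Restriction Scale): 18 items, the first 11 basic
and the last 7 instrumental activities of daily living, each scored 1 ("fully
independently") to 4 ("only with someone's help"); total 18-72.

ISCOPE score: number of health domains (somatic, functional, psychological,
social) in which a participant reports >= 2 of the 23 screening items as a
problem; range 0-4.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import DEFAULT_DOMAIN_ITEM_MAP, ConfigError, validate_domain_map
from .records import N_GARS_ITEMS, N_ISCOPE_ITEMS, ParticipantRecord

DOMAIN_PROBLEM_THRESHOLD = 2  # items flagged as a problem for a domain to count


class ScoringError(ValueError):
    """Invalid questionnaire input; message identifies the offending item."""


@dataclass(frozen=True)
class GarsScore:
    total: int
    badl_subtotal: int
    iadl_subtotal: int


@dataclass(frozen=True)
class IscopeDomains:
    problems_per_domain: tuple[int, int, int, int]
    domain_flags: tuple[bool, bool, bool, bool]
    score: int


def gars_total(items, badl_count: int = 11) -> GarsScore:
    """Sum 18 GARS items; subtotals split the first ``badl_count`` (BADL)
    from the rest (IADL)."""
    items = list(items)
    if len(items) != N_GARS_ITEMS:
        raise ScoringError(f"expected {N_GARS_ITEMS} GARS items, got {len(items)}")
    for i, v in enumerate(items, start=1):
        if int(v) != v or not (1 <= int(v) <= 4):
            raise ScoringError(f"GARS item {i} = {v!r} outside 1..4")
    badl = sum(int(v) for v in items[:badl_count])
    iadl = sum(int(v) for v in items[badl_count:])
    return GarsScore(total=badl + iadl, badl_subtotal=badl, iadl_subtotal=iadl)


def iscope_score(items, domain_item_map=DEFAULT_DOMAIN_ITEM_MAP) -> IscopeDomains:
    """Count problem items per domain; a domain counts toward the score when
    it holds >= 2 problems.  Missing responses (None) count as no problem."""
    items = list(items)
    if len(items) != N_ISCOPE_ITEMS:
        raise ScoringError(f"expected {N_ISCOPE_ITEMS} items, got {len(items)}")
    validate_domain_map(domain_item_map)
    counts = tuple(
        sum(1 for idx in domain if items[idx - 1]) for domain in domain_item_map
    )
    flags = tuple(c >= DOMAIN_PROBLEM_THRESHOLD for c in counts)
    return IscopeDomains(problems_per_domain=counts, domain_flags=flags,
                         score=sum(flags))


def derive_covariates(record: ParticipantRecord) -> dict:
    """Pre-selected predictors: polypharmacy is > 3 daily medications
    (i.e. >= 4), multimorbidity > 1 (i.e. >= 2) of the 17 listed chronic
    conditions."""
    return {
        "age": record.age,
        "sex": record.sex,
        "polypharmacy": record.medication_count >= 4,
        "multimorbidity": sum(record.disease_flags) >= 2,
        "living": record.living_situation,
    }


def score_cohort(records, domain_item_map=DEFAULT_DOMAIN_ITEM_MAP) -> pd.DataFrame:
    """One row per participant with identifiers, derived covariates, the
    ISCOPE score, GARS totals at both time points, and the event code."""
    rows = []
    for r in records:
        cov = derive_covariates(r)
        g0 = gars_total(r.gars_items_t0)
        row = {
            "id": r.id,
            "age": cov["age"],
            "sex": cov["sex"],
            "polypharmacy": cov["polypharmacy"],
            "multimorbidity": cov["multimorbidity"],
            "living": cov["living"],
            "gp_opinion": r.gp_opinion,
            "iscope_score": iscope_score(r.iscope_items, domain_item_map).score,
            "gars_t0": g0.total,
            "gars_t12": (
                gars_total(r.gars_items_t12).total
                if r.gars_items_t12 is not None else pd.NA
            ),
            "event": r.event,
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    df["gars_t12"] = df["gars_t12"].astype("Int64")
    return df
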