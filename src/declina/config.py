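"""Cohort-generator configuration.

The generator's joint structure is a single standard-normal latent frailty
per participant, with one loading per observable channel.  Defaults are
calibrated so the synthetic marginals resemble a community-dwelling
general-practice population aged 75+ visited at home: median age ~82
(IQR ~79-87), 68% female, ~68% polypharmacy, ~91% multimorbidity, ~10% in a
home for older persons, GP vulnerability rating roughly 40/28/32%,
median baseline GARS ~31, ~6.7% deaths and ~2% nursing-home admissions over
12 months, and ~18.5% lost to follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


class ConfigError(ValueError):
    """A configuration field violates its invariant; message names the field."""


DEFAULT_DOMAIN_ITEM_MAP: tuple[tuple[int, ...], ...] = (
    tuple(range(1, 7)),    # somatic
    tuple(range(7, 13)),   # functional
    tuple(range(13, 19)),  # psychological
    tuple(range(19, 24)),  # social
)


@dataclass
class FrailtyEffects:
    """Per-channel loadings of the standard-normal latent frailty.

    Log-odds slopes per SD of frailty for the binary/ordinal channels
    (questionnaire problems, GP opinion cut-point model, death,
    nursing-home admission) and linear slopes for the Poisson medication
    log-rate, the baseline-GARS item latent, and the raw 12-month GARS
    increment (points per SD).
    """

    iscope_items: float = 0.6
    medication: float = 0.25
    disease: float = 0.5
    living: float = 0.5
    gp_opinion: float = 1.2
    gars_baseline: float = 0.9
    decline: float = 2.0
    death: float = 0.9
    nursing_home: float = 0.8


@dataclass
class CohortConfig:
    """Everything :func:`declina.cohort.generate_cohort` needs.

    ``age_location``/``age_scale`` parameterise a normal age distribution
    lower-truncated at 75 years.  ``decline_mean``/``decline_sd`` set the raw
    (pre-shrinkage) 12-month GARS increment in points.  ``apply_visit_sampling``
    emulates the screening design in which 15% of those with score 0/1, 60%
    with score 2 and 100% with score 3/4 received a home visit.
    """

    n_participants: int = 2711
    seed: int = 0
    age_location: float = 80.9
    age_scale: float = 6.0
    female_fraction: float = 0.68
    frailty_effects: FrailtyEffects = field(default_factory=FrailtyEffects)
    dropout_fraction: float = 0.185
    death_fraction: float = 0.065
    nursing_home_fraction: float = 0.020
    medication_log_rate: float = 1.55
    disease_log_odds: float = -1.15
    living_log_odds: float = -2.35
    iscope_item_log_odds: float = -0.5
    iscope_domain_noise_sd: float = 0.8
    # cut-points in SD units of the (frailty + noise) latent
    gp_cutpoints: tuple[float, float] = (-0.243, 0.476)
    gars_item_cutpoints: tuple[float, float, float] = (-0.1, 0.7, 1.3)
    gars_item_noise_sd: float = 1.0
    decline_mean: float = 3.0
    decline_sd: float = 8.0
    domain_item_map: tuple[tuple[int, ...], ...] = DEFAULT_DOMAIN_ITEM_MAP
    apply_visit_sampling: bool = False

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants: must be >= 1")
        for name in ("female_fraction", "dropout_fraction", "death_fraction",
                     "nursing_home_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: probability {v} outside [0, 1]")
        if self.age_scale <= 0:
            raise ConfigError("age_scale: must be positive")
        if self.decline_sd <= 0:
            raise ConfigError("decline_sd: must be positive")
        if not self.gp_cutpoints[0] < self.gp_cutpoints[1]:
            raise ConfigError("gp_cutpoints: must be strictly increasing")
        if list(self.gars_item_cutpoints) != sorted(self.gars_item_cutpoints):
            raise ConfigError("gars_item_cutpoints: must be non-decreasing")
        validate_domain_map(self.domain_item_map)


def validate_domain_map(domain_item_map) -> None:
    """A valid map partitions items 1..23 into exactly four domains."""
    if len(domain_item_map) != 4:
        raise ConfigError("domain_item_map: expected 4 domains")
    seen: list[int] = []
    for d in domain_item_map:
        seen.extend(int(i) for i in d)
    if sorted(seen) != list(range(1, 24)):
        raise ConfigError("domain_item_map: not a partition of items 1..23")


def config_to_yaml(config: CohortConfig, path) -> None:
    d = asdict(config)
    d["domain_item_map"] = [list(t) for t in config.domain_item_map]
    d["gp_cutpoints"] = list(config.gp_cutpoints)
    d["gars_item_cutpoints"] = list(config.gars_item_cutpoints)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path) -> CohortConfig:
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh) or {}
    if "frailty_effects" in d:
        d["frailty_effects"] = FrailtyEffects(**d["frailty_effects"])
    if "domain_item_map" in d:
        d["domain_item_map"] = tuple(tuple(x) for x in d["domain_item_map"])
    for k in ("gp_cutpoints", "gars_item_cutpoints"):
        if k in d:
            d[k] = tuple(d[k])
    cfg = CohortConfig(**d)
    cfg.validate()
    return cfg
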