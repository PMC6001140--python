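"""Seeded synthetic cohorts with a latent-frailty joint structure.

One standard-normal frailty value per participant drives, through
per-channel loadings, the screening-questionnaire problem flags, the GP's
vulnerability rating (ordered-threshold model with two cut-points), the
baseline GARS items (ordinal threshold model), the 12-month GARS increment
(shrunk toward the 72-point ceiling), and the probabilities of death and
nursing-home admission.  This produces the positive co-movement of
predictors and outcome that the downstream analysis assumes, with one knob
per association so recovery tests are simple.

Randomness: every channel draws from its own child stream of a single
``numpy.random.SeedSequence``, spawned in a fixed order.  Changing only the
loading coefficients therefore never perturbs the underlying draws of other
channels, and the generated cohort is byte-identical for identical
config + seed.
"""

from __future__ import annotations

import numpy as np

from .config import CohortConfig, ConfigError
from .records import (
    N_DISEASE_FLAGS,
    N_GARS_ITEMS,
    N_ISCOPE_ITEMS,
    ParticipantRecord,
)

# Fixed spawn order of per-channel RNG streams; append only.
_CHANNELS = (
    "frailty", "age", "sex", "medication", "disease", "living",
    "gp_opinion", "iscope", "gars_t0", "decline", "gars_t12_alloc",
    "death", "nursing_home", "dropout", "visit_sampling",
)


def _channel_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_CHANNELS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_CHANNELS, children)}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: CohortConfig) -> list[ParticipantRecord]:
    """Generate a synthetic cohort; deterministic given ``config`` + seed."""
    config.validate()
    n = config.n_participants
    fe = config.frailty_effects
    rngs = _channel_rngs(config.seed)

    z = rngs["frailty"].standard_normal(n)

    # Age: normal, lower-truncated at 75 by inverse-CDF sampling.
    from scipy.stats import truncnorm
    a = (75.0 - config.age_location) / config.age_scale
    age = truncnorm.ppf(
        rngs["age"].uniform(size=n), a, np.inf,
        loc=config.age_location, scale=config.age_scale,
    )

    female = rngs["sex"].uniform(size=n) < config.female_fraction

    lam = np.exp(config.medication_log_rate + fe.medication * z)
    med_count = rngs["medication"].poisson(lam)

    p_dis = _sigmoid(config.disease_log_odds + fe.disease * z)
    diseases = rngs["disease"].uniform(size=(n, N_DISEASE_FLAGS)) < p_dis[:, None]

    p_home = _sigmoid(config.living_log_odds + fe.living * z)
    home = rngs["living"].uniform(size=n) < p_home

    # GP opinion: ordered thresholds on a noisy frailty signal.
    gp_latent = fe.gp_opinion * z + rngs["gp_opinion"].standard_normal(n)
    c1, c2 = config.gp_cutpoints
    sd = np.hypot(fe.gp_opinion, 1.0)
    gp_idx = (gp_latent > c1 * sd).astype(int) + (gp_latent > c2 * sd).astype(int)

    # Questionnaire items: frailty loading plus a shared per-domain effect,
    # so problems cluster within domains as they do on real questionnaires.
    iscope_rng = rngs["iscope"]
    domain_re = config.iscope_domain_noise_sd * iscope_rng.standard_normal((n, 4))
    item_domain = np.empty(N_ISCOPE_ITEMS, dtype=int)
    for d, items in enumerate(config.domain_item_map):
        for it in items:
            item_domain[it - 1] = d
    p_item = _sigmoid(
        config.iscope_item_log_odds
        + fe.iscope_items * z[:, None]
        + domain_re[:, item_domain]
    )
    iscope = iscope_rng.uniform(size=(n, N_ISCOPE_ITEMS)) < p_item

    # Baseline GARS items: ordinal thresholds on frailty + item noise.
    lat = (
        fe.gars_baseline * z[:, None]
        + config.gars_item_noise_sd * rngs["gars_t0"].standard_normal((n, N_GARS_ITEMS))
    )
    gsd = np.hypot(fe.gars_baseline, config.gars_item_noise_sd)
    cut = np.asarray(config.gars_item_cutpoints) * gsd
    g0_items = 1 + (lat[..., None] > cut).sum(axis=2)
    g0_total = g0_items.sum(axis=1)

    # 12-month increment: raw normal draw, proportionally shrunk toward the
    # scale bounds so total stays in [18, 72] and participants near the
    # ceiling can only register small raw increases.
    raw = config.decline_mean + fe.decline * z + config.decline_sd * rngs[
        "decline"
    ].standard_normal(n)
    frac = np.clip(raw / 54.0, -1.0, 1.0)
    potential = 72 - g0_total
    floor_room = g0_total - 18
    inc = np.where(
        frac >= 0,
        np.rint(frac * potential),
        np.rint(frac * floor_room),
    ).astype(int)

    p_death = _sigmoid(
        _logit(config.death_fraction) + fe.death * z - fe.death**2 / 2.0
    )
    p_nh = _sigmoid(
        _logit(config.nursing_home_fraction) + fe.nursing_home * z - fe.nursing_home**2 / 2.0
    )
    died = rngs["death"].uniform(size=n) < p_death
    nh = (~died) & (rngs["nursing_home"].uniform(size=n) < p_nh)
    lost = (~died) & (~nh) & (rngs["dropout"].uniform(size=n) < config.dropout_fraction)

    alloc_rng = rngs["gars_t12_alloc"]
    records: list[ParticipantRecord] = []
    for i in range(n):
        if died[i]:
            event, t12 = "died", None
        elif nh[i]:
            event, t12 = "nursing_home", None
        elif lost[i]:
            event, t12 = "lost", None
        else:
            event = "followed_up"
            t12 = _allocate_items(g0_items[i], int(inc[i]), alloc_rng)
        rec = ParticipantRecord(
            id=f"p{i:06d}",
            age=round(float(age[i]), 1),
            sex="female" if female[i] else "male",
            medication_count=int(med_count[i]),
            disease_flags=[bool(v) for v in diseases[i]],
            living_situation="home_for_older_persons" if home[i] else "independent",
            gp_opinion=("not_vulnerable", "possibly_vulnerable", "vulnerable")[gp_idx[i]],
            iscope_items=[bool(v) for v in iscope[i]],
            gars_items_t0=[int(v) for v in g0_items[i]],
            gars_items_t12=t12,
            event=event,
        )
        records.append(rec)

    if config.apply_visit_sampling:
        records = _visit_sample(records, config, rngs["visit_sampling"])
    return records


def _logit(p: float) -> float:
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    return float(np.log(p / (1.0 - p)))


def _allocate_items(g0_items: np.ndarray, inc: int, rng: np.random.Generator) -> list[int]:
    """Distribute a total increment over 18 ordinal items, respecting 1..4."""
    items = [int(v) for v in g0_items]
    step = 1 if inc >= 0 else -1
    bound = 4 if inc >= 0 else 1
    for _ in range(abs(inc)):
        movable = [j for j, v in enumerate(items) if v != bound]
        if not movable:
            break
        items[movable[rng.integers(len(movable))]] += step
    return items


def _visit_sample(records, config: CohortConfig, rng: np.random.Generator):
    """Emulate the home-visit selection: 15% of score 0/1, 60% of score 2,
    100% of score 3/4 retained."""
    from .scoring import iscope_score

    keep_prob = {0: 0.15, 1: 0.15, 2: 0.60, 3: 1.0, 4: 1.0}
    u = rng.uniform(size=len(records))
    out = []
    for i, r in enumerate(records):
        s = iscope_score(r.iscope_items, config.domain_item_map).score
        if u[i] < keep_prob[s]:
            out.append(r)
    return out


def simulate_logistic_decline(
    config: CohortConfig,
    intercept: float,
    polypharmacy_log_odds: float,
) -> "tuple[list[ParticipantRecord], np.ndarray]":
    """Covariates from the standard generator plus a binary decline drawn
    directly from a logistic law in polypharmacy.

    The percentile-based outcome flags a fixed fraction within each stratum,
    so no fixed covariate→outcome log-odds exists on that path; calibration
    experiments that need a *known* generating coefficient (parameter
    recovery for the inference stage) use this helper instead.

    Returns the records and the 0/1 outcome vector.
    """
    config.validate()
    records = generate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(
        len(_CHANNELS) + 1)[-1])
    poly = np.array([r.medication_count >= 4 for r in records], dtype=float)
    eta = intercept + polypharmacy_log_odds * poly
    y = (rng.uniform(size=len(records)) < _sigmoid(eta)).astype(int)
    return records, y
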