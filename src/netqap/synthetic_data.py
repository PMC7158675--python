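"""Synthetic school-cohort generator for dyadic network-regression studies.

The generator emulates the study design the analysis modules expect: a
small secondary-school cohort (default 49 pupils across 4 classes) with
questionnaire attributes, two correlated directed friendship networks
(nominations active during school hours and after school, out-degree
capped at 8), and a binary post-intervention vaccination response whose
dyadic similarity is planted along after-school ties.

Attribute marginals are sampled *exactly* — each categorical column is a
shuffled fixed multiset — so a default cohort reproduces the configured
counts verbatim rather than merely in expectation. Friendship ties follow
a logistic tie model with class/gender homophily, reciprocity and
transitivity terms, sampled by a fixed number of full-network sweeps;
after-school ties are drawn conditional on school ties through a
cross-context overlap term. Outcomes come from a two-stage process: a
latent hesitancy stage in which a small exact number of "index" pupils
(default one) is placed uniformly at random — independently of the
network — followed by one contagion sweep along the after-school network
that lowers a pupil's outcome log-odds by ``outcome_tie_effect`` for each
after-school contact who is an index case. The intercept is calibrated so
the mean outcome probability equals ``outcome_base_rate``; with the tie
effect at zero the outcomes are i.i.d. and carry no network signal, which
keeps downstream permutation tests calibrated under the null.

All randomness flows from ``SimulationConfig.seed`` through documented
per-stage substreams (stage 0 cohort, 1 networks, 2 outcomes), so each
stage is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .net_model import Network, NodeTable, ValidationError

__all__ = [
    "SimulationConfig",
    "generate_cohort",
    "generate_friendship_networks",
    "generate_outcomes",
    "simulate_study",
]

#: log-odds pull of a pupil's own latent hesitancy on the final outcome;
#: fixed so the contagion sweep modifies, rather than replaces, the seeds
_LATENT_ANCHOR_LOG_ODDS = 4.0


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the descriptive marginals of the motivating cohort:
    49 pupils in classes of 18/12/9/10, 27 male / 22 female, 4 pupils of
    minority ethnicity, parent ages ~ Normal(43.53, 4.59) truncated
    positive, 7-point relevance scores and a 5-level medical-visit
    category drawn from the published count tables, nominations capped at
    8, and an ~80% positive outcome rate.
    """

    n_pupils: int = 49
    class_sizes: tuple[int, ...] = (18, 12, 9, 10)
    gender_split: tuple[int, int] = (27, 22)  # (male, female)
    ethnicity_minority_count: int = 4
    out_degree_cap: int = 8
    homophily_log_odds: dict = field(
        default_factory=lambda: {"class": 2.0, "gender": 0.8}
    )
    reciprocity_log_odds: float = 1.5
    transitivity_log_odds: float = 0.8
    cross_context_overlap: float = 2.5
    base_tie_log_odds: dict = field(
        default_factory=lambda: {"school": -3.0, "after_school": -3.5}
    )
    n_sweeps: int = 3
    outcome_base_rate: float = 0.80
    outcome_tie_effect: float = 3.5
    hesitancy_seed_count: int = 1
    parent_age_mean: float = 43.53
    parent_age_sd: float = 4.59
    likert_distributions: dict = field(
        default_factory=lambda: {
            # counts over scale levels, low to high (published marginals)
            "pupil_relevance": (0, 0, 2, 4, 10, 6, 27),
            "parent_relevance": (0, 0, 1, 3, 7, 2, 36),
            "medical_visits": (0, 5, 10, 28, 6),
        }
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if sum(self.class_sizes) != self.n_pupils:
            raise ValidationError(
                f"class_sizes sum to {sum(self.class_sizes)}, expected {self.n_pupils}"
            )
        if sum(self.gender_split) != self.n_pupils:
            raise ValidationError("gender_split must sum to n_pupils")
        if not 0 <= self.ethnicity_minority_count <= self.n_pupils:
            raise ValidationError("ethnicity_minority_count out of range")
        if self.out_degree_cap < 1:
            raise ValidationError("out_degree_cap must be >= 1")
        if not 0 < self.outcome_base_rate < 1:
            raise ValidationError("outcome_base_rate must lie in (0, 1)")
        if not 0 <= self.hesitancy_seed_count < self.n_pupils:
            raise ValidationError("hesitancy_seed_count out of range")
        for name, counts in self.likert_distributions.items():
            if sum(counts) != self.n_pupils:
                raise ValidationError(
                    f"likert_distributions[{name!r}] counts must sum to n_pupils"
                )
        if len(self.likert_distributions["pupil_relevance"]) != 7:
            raise ValidationError("pupil_relevance needs 7 scale levels")
        if len(self.likert_distributions["parent_relevance"]) != 7:
            raise ValidationError("parent_relevance needs 7 scale levels")
        if len(self.likert_distributions["medical_visits"]) != 5:
            raise ValidationError("medical_visits needs 5 category levels")


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    seed = 0 if config.seed is None else int(config.seed)
    return np.random.default_rng([seed, stage])


def _shuffled_multiset(
    counts, levels, rng: np.random.Generator
) -> np.ndarray:
    values = np.repeat(levels, counts)
    return rng.permutation(values)


# ---------------------------------------------------------------------------
# stage 0: cohort attributes
# ---------------------------------------------------------------------------


def generate_cohort(config: SimulationConfig) -> NodeTable:
    """Cohort attribute table with exact categorical marginals.

    ``positive_response`` is left missing; :func:`generate_outcomes` fills
    it once the after-school network exists.
    """
    rng = _stage_rng(config, 0)
    n = config.n_pupils
    width = len(str(n))
    node_ids = [f"P{i + 1:0{width}d}" for i in range(n)]
    class_label = np.repeat(
        [f"C{k + 1}" for k in range(len(config.class_sizes))], config.class_sizes
    )
    gender = _shuffled_multiset(config.gender_split, np.array(["M", "F"]), rng)
    ethnicity = _shuffled_multiset(
        (n - config.ethnicity_minority_count, config.ethnicity_minority_count),
        np.array(["Italian", "Other"]),
        rng,
    )
    likert = config.likert_distributions
    pupil_rel = _shuffled_multiset(likert["pupil_relevance"], np.arange(1, 8), rng)
    parent_rel = _shuffled_multiset(likert["parent_relevance"], np.arange(1, 8), rng)
    visits = _shuffled_multiset(likert["medical_visits"], np.arange(1, 6), rng)
    ages = rng.normal(config.parent_age_mean, config.parent_age_sd, size=n)
    while (ages <= 0).any():  # truncate positive; essentially never triggers
        bad = ages <= 0
        ages[bad] = rng.normal(config.parent_age_mean, config.parent_age_sd, bad.sum())

    return NodeTable(
        pd.DataFrame(
            {
                "node_id": node_ids,
                "class_label": class_label,
                "gender": gender,
                "ethnicity": ethnicity,
                "pupil_relevance": pupil_rel,
                "parent_relevance": parent_rel,
                "parent_age": np.round(ages, 2),
                "medical_visits": visits,
                "positive_response": np.full(n, np.nan),
            }
        )
    )


# ---------------------------------------------------------------------------
# stage 1: friendship networks
# ---------------------------------------------------------------------------


def _cap_out_degree(
    draw: np.ndarray, probs: np.ndarray, cap: int, rng: np.random.Generator
) -> np.ndarray:
    """Keep at most ``cap`` nominations per sender, preferring high-probability
    ties (random tie-break)."""
    n = draw.shape[0]
    adj = np.zeros((n, n), dtype=np.int8)
    tiebreak = rng.random((n, n)) * 1e-9
    for i in range(n):
        picked = np.nonzero(draw[i])[0]
        if picked.size > cap:
            keys = probs[i, picked] + tiebreak[i, picked]
            picked = picked[np.argsort(-keys)[:cap]]
        adj[i, picked] = 1
    return adj


def _sample_network(
    config: SimulationConfig,
    same_class: np.ndarray,
    same_gender: np.ndarray,
    context: str,
    rng: np.random.Generator,
    conditioning: np.ndarray | None = None,
) -> np.ndarray:
    n = same_class.shape[0]
    base = (
        config.base_tie_log_odds[context]
        + config.homophily_log_odds["class"] * same_class
        + config.homophily_log_odds["gender"] * same_gender
    )
    if conditioning is not None:
        base = base + config.cross_context_overlap * conditioning
    adj = np.zeros((n, n), dtype=np.int8)
    for _ in range(config.n_sweeps):
        two_path = adj.astype(np.int64) @ adj.astype(np.int64)
        np.fill_diagonal(two_path, 0)
        utility = (
            base
            + config.reciprocity_log_odds * adj.T
            + config.transitivity_log_odds * (two_path >= 1)
        )
        probs = expit(utility)
        np.fill_diagonal(probs, 0.0)
        draw = rng.random((n, n)) < probs
        np.fill_diagonal(draw, False)
        adj = _cap_out_degree(draw, probs, config.out_degree_cap, rng)
    return adj


def generate_friendship_networks(
    cohort: NodeTable, config: SimulationConfig
) -> tuple[Network, Network]:
    """Sample the (school, after_school) directed nomination networks.

    Tie probabilities follow a logistic model on class match, gender
    match, reciprocation of the current tie and presence of a closing
    two-path, iterated for ``n_sweeps`` full-network redraws (the first
    sweep sees an empty network, so it is homophily-only). After-school
    ties receive an extra ``cross_context_overlap`` log-odds bonus where a
    school tie exists, producing the positive cross-context correlation
    typical of such cohorts. Every out-degree is capped by
    top-probability truncation.
    """
    rng = _stage_rng(config, 1)
    cls = cohort.attribute("class_label")
    gen = cohort.attribute("gender")
    same_class = (cls[:, None] == cls[None, :]).astype(float)
    same_gender = (gen[:, None] == gen[None, :]).astype(float)
    np.fill_diagonal(same_class, 0.0)
    np.fill_diagonal(same_gender, 0.0)

    school_adj = _sample_network(config, same_class, same_gender, "school", rng)
    after_adj = _sample_network(
        config, same_class, same_gender, "after_school", rng, conditioning=school_adj
    )
    nodes = cohort.node_ids
    return (
        Network(nodes=nodes, adjacency=school_adj, context="school"),
        Network(nodes=nodes, adjacency=after_adj, context="after_school"),
    )


# ---------------------------------------------------------------------------
# stage 2: outcomes
# ---------------------------------------------------------------------------


def generate_outcomes(
    cohort: NodeTable, after_school: Network, config: SimulationConfig
) -> NodeTable:
    """Fill the binary positive-response column.

    Two-stage hesitancy-contagion process:

    1. ``hesitancy_seed_count`` latent index cases are placed uniformly at
       random — independently of the network, so that with the tie effect
       at zero the outcomes are i.i.d. and downstream permutation tests
       stay calibrated.
    2. One contagion sweep lowers each pupil's outcome log-odds by
       ``outcome_tie_effect`` for every after-school contact (tie in
       either direction) who is an index case; index cases themselves are
       anchored to hesitancy by a fixed own-state log-odds pull.

    The intercept is calibrated by bisection so the mean outcome
    probability equals ``outcome_base_rate``. The planted structure is a
    pocket of refusals around each index case, i.e. dyadic outcome
    similarity concentrated along after-school ties.
    """
    if after_school.nodes != cohort.node_ids:
        raise ValidationError("after-school network node order differs from cohort")
    rng = _stage_rng(config, 2)
    n = cohort.n
    hesitant = np.zeros(n)
    if config.hesitancy_seed_count:
        seeds = rng.choice(n, size=config.hesitancy_seed_count, replace=False)
        hesitant[seeds] = 1.0

    contacts = ((after_school.adjacency + after_school.adjacency.T) > 0).astype(float)
    exposure = contacts @ hesitant  # number of index-case contacts

    anchor = -_LATENT_ANCHOR_LOG_ODDS * (2.0 * hesitant - 1.0)
    shift = -config.outcome_tie_effect * exposure

    target = config.outcome_base_rate
    lo, hi = logit(target) - 60.0, logit(target) + 60.0
    for _ in range(100):  # bisection on the intercept for the mean outcome rate
        mid = 0.5 * (lo + hi)
        if expit(mid + anchor + shift).mean() < target:
            lo = mid
        else:
            hi = mid
    probs = expit(0.5 * (lo + hi) + anchor + shift)
    y = (rng.random(n) < probs).astype(int)
    return cohort.with_outcome(y)


def simulate_study(
    config: SimulationConfig | None = None,
) -> tuple[NodeTable, dict[str, Network]]:
    """Full study draw: cohort with outcomes plus both friendship networks."""
    config = config or SimulationConfig()
    cohort = generate_cohort(config)
    school, after = generate_friendship_networks(cohort, config)
    cohort = generate_outcomes(cohort, after, config)
    return cohort, {"school": school, "after_school": after}
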