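"""Per-step innovation dynamics and the full simulation loop.

At every monthly step each agent may innovate **at most one** new
behaviour.  The two behaviour categories are processed in random order
per agent; for each category an acquisition is attempted with a
probability drawn around ``1 - state`` for that category (the less an
agent's functional needs are met, the more it innovates).  Which
behaviour is attempted depends on the parameter ``S``: with
probability ``S`` the choice is frequency-weighted — proportional to
one plus the number of agents in the population currently expressing
each behaviour of the category (non-copying social mediation: common
behaviours catalyse their own reinnovation, while rare or unexpressed
ones keep the baseline chance any individual has of innovating them
alone) — otherwise it is uniform over the category.  The chosen
behaviour is then actually acquired only with probability ``p_g``
(social) or ``p_g * p_e`` (food) at the agent's site.  No specifics of
behavioural form pass between agents: social influence only reweights
what an agent was latently able to innovate alone.

Populations at different sites never interact; each site runs on its
own random substream, so trajectories are reproducible and
site-independent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .census import (
    DEFAULT_AGE_CLASSES,
    AgeClasses,
    CensusTable,
    PatternTable,
    assign_patterns,
    build_census,
    count_cultural,
)
from .demography import Population, demographic_step, init_population
from .world import (
    BehaviourSpace,
    ConfigurationError,
    PropensityTable,
    SiteMap,
    assign_propensities,
    build_behaviour_space,
)

__all__ = [
    "SimulationParams",
    "SimulationResult",
    "social_state",
    "food_state",
    "social_states",
    "food_states",
    "innovation_probability",
    "select_behaviour",
    "innovation_step",
    "run_simulation",
]

#: Steps of pre-drawn randomness per chunk of the inner loop.
_CHUNK = 256


@dataclass(frozen=True)
class SimulationParams:
    """Run parameters.

    S
        Probability that an acquisition is socially mediated/triggered
        (frequency-weighted) rather than uniformly random.
    alpha_g, alpha_e
        Per-behaviour probabilities that genetic propensity /
        ecological availability differ across sites via a geographic
        gradient, rather than being site-constant.
    t_max
        Number of monthly steps; 6000 (500 years) reaches a stationary
        behavioural distribution.
    sigma
        Spread of the normal draw around ``1 - state`` for the
        per-category innovation probability.
    seed
        Master seed for all randomness in the run.
    """

    S: float = 1.0
    alpha_g: float = 0.2
    alpha_e: float = 0.8
    t_max: int = 6000
    sigma: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("S", "alpha_g", "alpha_e"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.t_max < 0:
            raise ConfigurationError(f"t_max must be >= 0, got {self.t_max}")
        if self.sigma < 0:
            raise ConfigurationError(f"sigma must be >= 0, got {self.sigma}")


@dataclass
class SimulationResult:
    """Everything a finished run produced: the final populations, the
    propensity table they were gated by, and the method-of-exclusion
    census/pattern tables derived from the final state."""

    params: SimulationParams
    sites: SiteMap
    space: BehaviourSpace
    propensities: PropensityTable
    populations: list[Population]
    census: CensusTable
    patterns: PatternTable
    #: steps at which the optional trace was recorded
    trace_steps: np.ndarray | None = None
    #: site_index -> (n_recorded_steps, n_behaviours) expresser counts
    trace: Mapping[int, np.ndarray] | None = None
    #: step -> (census, patterns) snapshots at requested checkpoints
    checkpoint_censuses: dict[int, tuple[CensusTable, PatternTable]] = field(
        default_factory=dict
    )

    @property
    def n_cultural(self) -> int:
        """Number of pattern-D ("cultural") behaviours in the census."""
        return count_cultural(self.patterns)


# ---------------------------------------------------------------------------
# States


def social_states(repertoires: np.ndarray, space: BehaviourSpace) -> np.ndarray:
    """Social state of each agent: the fraction of social sub-categories
    in which the agent expresses at least one behaviour."""
    rep_s = np.asarray(repertoires, dtype=bool)[:, : space.n_social]
    fulfilled = (rep_s.astype(np.uint8) @ space._social_membership) > 0
    return fulfilled.sum(axis=1) / space.n_social_subcategories


def food_states(repertoires: np.ndarray, space: BehaviourSpace) -> np.ndarray:
    """Food state of each agent: fulfilled food sub-categories penalised
    by the imbalance between nutrient-Y and nutrient-Z sub-categories,
    normalised by the number of food sub-categories.

    With ``F`` fulfilled sub-categories of which ``F_Y`` provide Y and
    ``F_Z`` provide Z, the state is ``(F - |F_Y - F_Z|) / C`` clipped to
    [0, 1] — equivalently ``2 * min(F_Y, F_Z) / C``: a balanced diet is
    what counts.
    """
    rep_f = np.asarray(repertoires, dtype=bool)[:, space.n_social :]
    fulfilled = (rep_f.astype(np.uint8) @ space._food_membership) > 0
    y_mask = space.food_subcat_nutrient == "Y"
    f_total = fulfilled.sum(axis=1)
    f_y = fulfilled[:, y_mask].sum(axis=1)
    f_z = f_total - f_y
    state = (f_total - np.abs(f_y - f_z)) / space.n_food_subcategories
    return np.clip(state, 0.0, 1.0)


def _agent_row(agent, space: BehaviourSpace) -> np.ndarray:
    row = np.zeros((1, space.n_behaviours), dtype=bool)
    ids = np.fromiter(agent.repertoire, dtype=np.int64, count=len(agent.repertoire))
    if ids.size:
        row[0, ids - 1] = True
    return row


def social_state(agent, space: BehaviourSpace) -> float:
    """Social state of a single :class:`~moexsim.demography.Agent`."""
    return float(social_states(_agent_row(agent, space), space)[0])


def food_state(agent, space: BehaviourSpace) -> float:
    """Food state of a single :class:`~moexsim.demography.Agent`."""
    return float(food_states(_agent_row(agent, space), space)[0])


# ---------------------------------------------------------------------------
# Innovation primitives


def innovation_probability(
    state: float, sigma: float, rng: np.random.Generator
) -> float:
    """One innovation probability: Normal(1 - state, sigma) clipped to
    [0, 1].  With ``sigma == 0`` this is exactly ``1 - state``."""
    if not 0.0 <= state <= 1.0:
        raise ConfigurationError(f"state must be in [0, 1], got {state}")
    return float(np.clip(rng.normal(1.0 - state, sigma), 0.0, 1.0))


def _choose_behaviours(
    counts: np.ndarray,
    weighted: np.ndarray,
    u_sel: np.ndarray,
    k: int,
) -> np.ndarray:
    """Vectorised category-local behaviour choice for many agents.

    ``weighted`` marks agents whose draw is frequency-weighted: each
    behaviour's weight is its expresser count plus one, so common
    behaviours are preferentially reinnovated while every behaviour of
    the category — including currently unexpressed ones — keeps a
    baseline chance of individual innovation (social exposure
    catalyses, it does not veto).  The rest draw uniformly over the
    ``k`` behaviours.
    """
    uniform_choice = (u_sel * k).astype(np.int64)
    cdf = np.cumsum(counts + 1)
    weighted_choice = np.searchsorted(cdf, u_sel * cdf[-1], side="right")
    return np.where(weighted, weighted_choice, uniform_choice)


def select_behaviour(
    category: Literal["social", "food"],
    counts: np.ndarray | Sequence[int],
    S: float,
    rng: np.random.Generator,
    space: BehaviourSpace | None = None,
) -> int:
    """Pick one behaviour of a category for an innovation attempt.

    With probability ``S`` the pick is frequency-weighted: proportional
    to ``counts + 1``, where ``counts`` holds the number of current
    expressers of each behaviour of the category.  The unit baseline
    keeps unexpressed behaviours individually innovable (when all
    counts are zero the weighted draw is simply uniform).  With
    probability ``1 - S`` the pick is uniform.  Returns a 1-based
    global behaviour id (``space`` supplies the food id offset; by
    default the categories are assumed equally sized).
    """
    if category not in ("social", "food"):
        raise ConfigurationError(f"unknown behaviour category: {category!r}")
    counts = np.asarray(counts, dtype=np.int64)
    if counts.ndim != 1 or (counts < 0).any():
        raise ConfigurationError("counts must be a 1-D non-negative array")
    weighted = np.array([rng.random() < S])
    local = int(_choose_behaviours(counts, weighted, rng.random(1), len(counts))[0])
    if category == "food":
        offset = space.n_social if space is not None else len(counts)
        return local + offset + 1
    return local + 1


# ---------------------------------------------------------------------------
# The fused per-step kernel


def _innovate(
    rep: np.ndarray,
    gates_social: np.ndarray,
    gates_food: np.ndarray,
    space: BehaviourSpace,
    S: float,
    sigma: float,
    u: np.ndarray,
    z: np.ndarray,
    idx: np.ndarray,
) -> None:
    """One innovation step over a whole population, in place.

    ``u`` is a (9, n) block of uniforms and ``z`` a (2, n) block of
    standard normals; the fixed row layout keeps the number of random
    draws per step independent of what happens, so runs are
    reproducible and sites consuming their own substreams never
    interact.  Rows of ``u``: category order, social/food attempt,
    social/food weighted-branch, social/food selection, social/food
    gate.
    """
    n_social = space.n_social
    counts = rep.sum(axis=0)

    # all sub-category fulfilments in one pass (see social_states /
    # food_states for the reference formulations)
    n_ss = space.n_social_subcategories
    fulfilled = (rep.astype(np.uint8) @ space._membership) > 0
    s_state = fulfilled[:, :n_ss].sum(axis=1) / n_ss
    food_f = fulfilled[:, n_ss:]
    f_total = food_f.sum(axis=1)
    f_y = food_f[:, space._food_y_mask].sum(axis=1)
    f_state = (f_total - np.abs(2 * f_y - f_total)) / space.n_food_subcategories

    p_social = np.clip(1.0 - s_state + sigma * z[0], 0.0, 1.0)
    p_food = np.clip(1.0 - f_state + sigma * z[1], 0.0, 1.0)

    attempt_s = u[1] < p_social
    attempt_f = u[2] < p_food

    chosen_s = _choose_behaviours(counts[:n_social], u[3] < S, u[5], n_social)
    chosen_f = _choose_behaviours(counts[n_social:], u[4] < S, u[6], space.n_food)

    ok_s = attempt_s & (u[7] < gates_social[chosen_s])
    ok_f = attempt_f & (u[8] < gates_food[chosen_f])
    new_s = ok_s & ~rep[idx, chosen_s]
    new_f = ok_f & ~rep[idx, n_social + chosen_f]

    # one innovation per agent per step: the category processed first
    # (random per agent) blocks the second on success
    social_first = u[0] < 0.5
    add_s = new_s & (social_first | ~new_f)
    add_f = new_f & (~social_first | ~new_s)

    rep[idx[add_s], chosen_s[add_s]] = True
    rep[idx[add_f], n_social + chosen_f[add_f]] = True


def innovation_step(
    pop: Population,
    table: PropensityTable,
    space: BehaviourSpace,
    params: SimulationParams,
    rng: np.random.Generator,
) -> Population:
    """Run one innovation step for every agent of a population, in
    place.  Frequency counts are snapshotted once at the start, so all
    agents see the same within-step frequencies."""
    n = len(pop)
    i = pop.site_index
    gates_social = table.p_g[: space.n_social, i]
    gates_food = table.p_g[space.n_social :, i] * table.p_e[space.n_social :, i]
    _innovate(
        pop.repertoires,
        gates_social,
        gates_food,
        space,
        params.S,
        params.sigma,
        rng.random((9, n)),
        rng.standard_normal((2, n)),
        np.arange(n),
    )
    return pop


# ---------------------------------------------------------------------------
# Full run


def run_simulation(
    params: SimulationParams,
    sites: SiteMap | None = None,
    space: BehaviourSpace | None = None,
    *,
    age_classes: AgeClasses = DEFAULT_AGE_CLASSES,
    checkpoints: Sequence[int] = (),
    trace_every: int | None = None,
) -> SimulationResult:
    """Run the full model: build propensities once, then iterate
    ``t_max`` steps of demography followed by innovation at every site,
    and census the final populations.

    Sites evolve completely independently (there is no inter-site
    transmission of any kind); each consumes its own random substream
    spawned from ``params.seed``, so a run is bit-reproducible and any
    site's trajectory is unaffected by the others.

    ``checkpoints`` requests additional census/pattern snapshots at the
    given step numbers; ``trace_every`` records per-site expresser
    counts every so many steps.
    """
    if sites is None:
        sites = SiteMap.default()
    if space is None:
        space = build_behaviour_space()

    ss = np.random.SeedSequence(params.seed)
    world_seed, *site_seeds = ss.spawn(1 + len(sites))
    table = assign_propensities(
        space, sites, params.alpha_g, params.alpha_e, np.random.default_rng(world_seed)
    )

    checkpoint_set = {int(t) for t in checkpoints}
    snapshots: dict[int, list[Population]] = {t: [] for t in sorted(checkpoint_set)}
    trace_steps = (
        np.arange(trace_every, params.t_max + 1, trace_every)
        if trace_every
        else None
    )
    trace: dict[int, np.ndarray] | None = {} if trace_every else None

    populations: list[Population] = []
    for i, site in enumerate(sites.sites):
        rng = np.random.default_rng(site_seeds[i])
        pop = init_population(site.n, rng, space.n_behaviours, site_index=i)
        n = len(pop)
        idx = np.arange(n)
        gates_social = table.p_g[: space.n_social, i].copy()
        gates_food = (
            table.p_g[space.n_social :, i] * table.p_e[space.n_social :, i]
        ).copy()
        if trace is not None:
            trace[i] = np.zeros((len(trace_steps), space.n_behaviours), dtype=np.int32)

        t = 0
        while t < params.t_max:
            block = min(_CHUNK, params.t_max - t)
            U = rng.random((block, 10, n))
            Z = rng.standard_normal((block, 2, n))
            for j in range(block):
                t += 1
                u = U[j]
                demographic_step(pop, rng, death_draws=u[0])
                _innovate(
                    pop.repertoires,
                    gates_social,
                    gates_food,
                    space,
                    params.S,
                    params.sigma,
                    u[1:],
                    Z[j],
                    idx,
                )
                if trace is not None and t % trace_every == 0:
                    trace[i][t // trace_every - 1] = pop.repertoires.sum(axis=0)
                if t in checkpoint_set:
                    snapshots[t].append(pop.copy())
        populations.append(pop)

    census = build_census(populations, table, sites, age_classes)
    patterns = assign_patterns(census)
    checkpoint_censuses = {}
    for t, pops in snapshots.items():
        c = build_census(pops, table, sites, age_classes)
        checkpoint_censuses[t] = (c, assign_patterns(c))

    return SimulationResult(
        params=params,
        sites=sites,
        space=space,
        propensities=table,
        populations=populations,
        census=census,
        patterns=patterns,
        trace_steps=trace_steps,
        trace=trace,
        checkpoint_censuses=checkpoint_censuses,
    )
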