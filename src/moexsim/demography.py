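"""Age-dependent birth/death process with fixed population sizes.

One simulation step is one month of life.  Individuals face no
mortality until month 300 (25 years); from then on they die with a
constant hazard of 1% per month, and death is certain past month 720
(60 years).  Every death is immediately replaced, in the same slot, by
a newborn with an empty behavioural repertoire — population size is an
invariant of the process.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .world import ConfigurationError

__all__ = [
    "MORTALITY_ONSET_MONTHS",
    "MONTHLY_HAZARD",
    "MAX_AGE_MONTHS",
    "MAX_INITIAL_AGE_MONTHS",
    "Agent",
    "Population",
    "init_population",
    "demographic_step",
]

#: Age (months) from which the monthly mortality hazard applies, inclusive.
MORTALITY_ONSET_MONTHS = 300
#: Monthly probability of death once past the onset age.
MONTHLY_HAZARD = 0.01
#: Hard longevity cap (months): exceeding it means certain death.
MAX_AGE_MONTHS = 720
#: Initial ages are drawn uniformly from [0, this) months.
MAX_INITIAL_AGE_MONTHS = 300


@dataclass(frozen=True)
class Agent:
    """Read-only snapshot of one individual: age in months and the set
    of behaviour ids (1-based) it currently expresses."""

    age: int
    repertoire: frozenset[int]


@dataclass
class Population:
    """One site's population, stored columnar for vectorised updates.

    ``ages`` is an ``(n,)`` integer array of ages in months;
    ``repertoires`` an ``(n, n_behaviours)`` boolean matrix where entry
    ``[i, b]`` means agent ``i`` expresses behaviour ``b + 1``.  An
    agent's repertoire only grows while it is alive; it resets only
    when the slot is recycled to a newborn.
    """

    site_index: int
    ages: np.ndarray
    repertoires: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=np.int64)
        self.repertoires = np.asarray(self.repertoires, dtype=bool)
        if self.ages.ndim != 1 or self.repertoires.ndim != 2:
            raise ConfigurationError("ages must be (n,), repertoires (n, n_behaviours)")
        if len(self.ages) != len(self.repertoires):
            raise ConfigurationError("ages and repertoires disagree on population size")

    def __len__(self) -> int:
        return len(self.ages)

    @property
    def n_behaviours(self) -> int:
        return self.repertoires.shape[1]

    @property
    def agents(self) -> list[Agent]:
        """Per-agent snapshots (1-based behaviour ids)."""
        return [
            Agent(int(a), frozenset((np.flatnonzero(r) + 1).tolist()))
            for a, r in zip(self.ages, self.repertoires)
        ]

    def expression_counts(self) -> np.ndarray:
        """(n_behaviours,) number of agents expressing each behaviour."""
        return self.repertoires.sum(axis=0)

    def copy(self) -> "Population":
        return Population(self.site_index, self.ages.copy(), self.repertoires.copy())


def init_population(
    n: int,
    rng: np.random.Generator,
    n_behaviours: int = 64,
    site_index: int = 0,
) -> Population:
    """Create a population of ``n`` agents with ages drawn uniformly
    over integer months [0, 300) and empty repertoires.

    Starting everyone — including initialised adults — with an empty
    repertoire is harmless because runs are long enough for the
    behavioural distribution to equilibrate before censusing.
    """
    if n < 1:
        raise ConfigurationError(f"population size must be >= 1, got {n}")
    ages = rng.integers(0, MAX_INITIAL_AGE_MONTHS, size=n)
    repertoires = np.zeros((n, n_behaviours), dtype=bool)
    return Population(site_index, ages, repertoires)


def demographic_step(
    pop: Population,
    rng: np.random.Generator,
    death_draws: np.ndarray | None = None,
) -> Population:
    """Advance one month of ageing and mortality, in place.

    Every age increments by one month; agents at or past the mortality
    onset (post-increment) die with probability :data:`MONTHLY_HAZARD`,
    and any agent exceeding :data:`MAX_AGE_MONTHS` dies with certainty.
    Dead agents are replaced in their slot by age-0 newborns with empty
    repertoires, so the population size never changes.

    ``death_draws`` lets the simulation loop supply pre-drawn uniforms
    (one per agent); by default they are drawn from ``rng``.
    """
    pop.ages += 1
    if death_draws is None:
        death_draws = rng.random(len(pop))
    dead = (pop.ages >= MORTALITY_ONSET_MONTHS) & (death_draws < MONTHLY_HAZARD)
    dead |= pop.ages > MAX_AGE_MONTHS
    if dead.any():
        pop.ages[dead] = 0
        pop.repertoires[dead] = False
    return pop
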