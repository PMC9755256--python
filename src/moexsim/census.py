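"""Method-of-exclusion census: per-site behaviour classification,
distributional patterns A-D, cultural-trait counting and local
restriction.

Each behaviour at each site is classified by observed frequency:

* ``customary`` — expressed by strictly more than 50% of at least one
  (non-empty) age class;
* ``habitual`` — expressed by at least two individuals site-wide;
* ``present`` — expressed by exactly one individual;
* ``ecological_explanation`` — expressed by nobody *and* locally
  unavailable (ecological availability exactly 0);
* ``absent`` — expressed by nobody, with no ecological excuse.

The per-behaviour cross-site profile then yields one of four patterns:
A (expressed everywhere), B (nowhere reaching habitual), C (every
absence ecologically explained), and D — habitual or customary
somewhere yet absent elsewhere without ecological explanation, the
operational definition of a "cultural" behaviour under the
distributional approach.  An observational "unknown" category does not
arise: the simulation output is fully observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import numpy as np
import pandas as pd

from .demography import MAX_AGE_MONTHS, Population
from .world import ConfigurationError, PropensityTable, SiteMap

__all__ = [
    "Level",
    "LEVEL_SYMBOLS",
    "AgeClasses",
    "DEFAULT_AGE_CLASSES",
    "CensusTable",
    "PatternTable",
    "classify_behaviour",
    "build_census",
    "assign_patterns",
    "count_cultural",
    "locally_restricted",
    "per_population_cultural_counts",
]


class Level(IntEnum):
    """Per-site classification levels, ordered by observed frequency
    (the two unexpressed levels sort below ``PRESENT``)."""

    ABSENT = 0
    ECOLOGICAL_EXPLANATION = 1
    PRESENT = 2
    HABITUAL = 3
    CUSTOMARY = 4


LEVEL_SYMBOLS = {
    Level.CUSTOMARY: "C",
    Level.HABITUAL: "H",
    Level.PRESENT: "P",
    Level.ABSENT: "-",
    Level.ECOLOGICAL_EXPLANATION: "E",
}


@dataclass(frozen=True)
class AgeClasses:
    """Partition of [0, 720] months into age classes by interior
    cut-points.  The default (192, 480) gives three classes —
    juveniles to 16 years, prime adults to 40, and elders — used by the
    customary-majority rule.
    """

    boundaries: tuple[int, ...] = (192, 480)

    def __post_init__(self) -> None:
        b = self.boundaries
        if list(b) != sorted(set(b)) or not b:
            raise ConfigurationError("age-class boundaries must be strictly increasing")
        if b[0] <= 0 or b[-1] > MAX_AGE_MONTHS:
            raise ConfigurationError(
                f"age-class boundaries must lie in (0, {MAX_AGE_MONTHS}]"
            )

    @property
    def n_classes(self) -> int:
        return len(self.boundaries) + 1

    def class_of(self, ages: np.ndarray) -> np.ndarray:
        """Index of the age class containing each age."""
        return np.searchsorted(np.asarray(self.boundaries), ages, side="right")


DEFAULT_AGE_CLASSES = AgeClasses()


@dataclass(frozen=True)
class CensusTable:
    """Behaviour-by-site classification grid.

    ``levels`` is an ``(n_behaviours, n_sites)`` integer array of
    :class:`Level` codes; ``site_names`` labels the columns.
    """

    levels: np.ndarray
    site_names: tuple[str, ...]

    @property
    def n_behaviours(self) -> int:
        return self.levels.shape[0]

    @property
    def n_sites(self) -> int:
        return self.levels.shape[1]

    def expressed(self) -> np.ndarray:
        """Boolean grid: behaviour expressed (present or better) at site."""
        return self.levels >= Level.PRESENT

    def to_frame(self) -> pd.DataFrame:
        """Symbol grid (C/H/P/-/E), behaviours as rows, sites as columns."""
        symbols = np.array([LEVEL_SYMBOLS[Level(v)] for v in range(5)])
        return pd.DataFrame(
            symbols[self.levels],
            index=pd.RangeIndex(1, self.n_behaviours + 1, name="behaviour_id"),
            columns=list(self.site_names),
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass(frozen=True)
class PatternTable:
    """Per-behaviour distributional pattern labels (A/B/C/D)."""

    pattern: np.ndarray  # (n_behaviours,) of "A".."D"

    def counts(self) -> dict[str, int]:
        return {p: int((self.pattern == p).sum()) for p in "ABCD"}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "behaviour_id": np.arange(1, len(self.pattern) + 1),
                "pattern": self.pattern,
            }
        )

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            self.to_frame().to_csv(fh, index=False)
            c = self.counts()
            fh.write(f"# A={c['A']} B={c['B']} C={c['C']} D={c['D']}\n")


# ---------------------------------------------------------------------------
# Classification


def _census_site(
    pop: Population,
    p_e_col: np.ndarray,
    age_classes: AgeClasses,
) -> np.ndarray:
    """Vectorised classification of all behaviours at one site."""
    n_beh = pop.n_behaviours
    counts = pop.expression_counts()

    class_idx = age_classes.class_of(pop.ages)
    customary = np.zeros(n_beh, dtype=bool)
    for c in range(age_classes.n_classes):
        members = class_idx == c
        size = int(members.sum())
        if size == 0:
            continue  # empty classes carry no vacuous majorities
        class_counts = pop.repertoires[members].sum(axis=0)
        customary |= class_counts * 2 > size  # strictly over 50%

    levels = np.full(n_beh, Level.ABSENT, dtype=np.int8)
    levels[(counts == 0) & (p_e_col == 0)] = Level.ECOLOGICAL_EXPLANATION
    levels[counts == 1] = Level.PRESENT
    levels[counts >= 2] = Level.HABITUAL
    levels[customary & (counts >= 1)] = Level.CUSTOMARY
    return levels


def classify_behaviour(
    pop: Population,
    behaviour_id: int,
    age_classes: AgeClasses = DEFAULT_AGE_CLASSES,
    p_e_at_site: float = 1.0,
) -> Level:
    """Classify a single behaviour (1-based id) in one population."""
    col = np.full(pop.n_behaviours, 1.0)
    col[behaviour_id - 1] = p_e_at_site
    return Level(_census_site(pop, col, age_classes)[behaviour_id - 1])


def build_census(
    populations: Sequence[Population],
    table: PropensityTable,
    sites: SiteMap,
    age_classes: AgeClasses = DEFAULT_AGE_CLASSES,
) -> CensusTable:
    """Classify every behaviour at every site from final populations."""
    levels = np.column_stack(
        [
            _census_site(pop, table.p_e[:, i], age_classes)
            for i, pop in enumerate(populations)
        ]
    )
    return CensusTable(levels=levels, site_names=tuple(sites.names))


# ---------------------------------------------------------------------------
# Patterns


def _patterns_from_levels(levels: np.ndarray) -> np.ndarray:
    """Pattern labels for an (n_behaviours, n_sites) level grid.

    Precedence A -> B -> C -> D is exhaustive: a behaviour failing A has
    an unexpressed site; failing B has a habitual-or-better site;
    failing C has a plain absence — which together is exactly D.
    """
    expressed = levels >= Level.PRESENT
    habitual_plus = levels >= Level.HABITUAL
    plain_absent = levels == Level.ABSENT

    pattern = np.full(levels.shape[0], "D")
    is_a = expressed.all(axis=1)
    is_b = ~is_a & ~habitual_plus.any(axis=1)
    is_c = ~is_a & ~is_b & ~plain_absent.any(axis=1)
    pattern[is_a] = "A"
    pattern[is_b] = "B"
    pattern[is_c] = "C"
    return pattern


def assign_patterns(census: CensusTable) -> PatternTable:
    """Assign each behaviour its distributional pattern (A/B/C/D)."""
    return PatternTable(pattern=_patterns_from_levels(census.levels))


def count_cultural(patterns: PatternTable) -> int:
    """Number of behaviours classified as cultural (pattern D)."""
    return int((patterns.pattern == "D").sum())


def locally_restricted(census: CensusTable) -> list[int]:
    """Ids of behaviours expressed at exactly one site."""
    n_expressed = census.expressed().sum(axis=1)
    return (np.flatnonzero(n_expressed == 1) + 1).tolist()


def per_population_cultural_counts(
    census: CensusTable, patterns: PatternTable
) -> np.ndarray:
    """Per site: how many pattern-D behaviours are expressed there
    (present, habitual or customary)."""
    cultural = patterns.pattern == "D"
    return (census.expressed() & cultural[:, None]).sum(axis=0)
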