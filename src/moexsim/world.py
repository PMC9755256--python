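"""Static world construction: sites, the latent behaviour space, and
per-site genetic/ecological propensities.

The world consists of a small number of spatially separated populations
and a fixed repertoire of latent behaviours that any individual can in
principle innovate on its own.  Behaviours fall into two categories —
*social* and *food-related* — each organised into functional
sub-categories.  Every behaviour additionally carries, per site, a
genetic propensity ``p_g`` and (food only) an ecological availability
``p_e``; these gate whether an attempted innovation actually succeeds
at that site.

Cross-site variation in the propensities is controlled by two
probabilities, ``alpha_g`` and ``alpha_e``: with probability alpha the
propensity of a behaviour differs between sites following a geographic
distance gradient; otherwise it is a single uniform draw shared by all
sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "Site",
    "SiteMap",
    "FoodSubcategory",
    "BehaviourSpace",
    "PropensityTable",
    "DEFAULT_FOOD_STRUCTURE",
    "SOCIAL_SUBCATEGORY_NAMES",
    "build_behaviour_space",
    "gradient_probabilities",
    "assign_propensities",
]


class ConfigurationError(ValueError):
    """Raised when world-building inputs violate structural constraints."""


# ---------------------------------------------------------------------------
# Sites


@dataclass(frozen=True)
class Site:
    """A population site: a name, planar coordinates and a fixed size."""

    name: str
    x: float
    y: float
    n: int


# Six sites at the relative positions of the classic long-term ape
# field sites: two small western populations far from an eastern
# cluster of four (two southern lakeside sites, two north-eastern
# ones).  Coordinates are arbitrary planar units — shifted degrees —
# and only relative distances matter, but the geometry is load-bearing:
# which site is farthest from a random gradient point, and hence gets
# propensity exactly 0, depends on it.
_DEFAULT_SITES = (
    Site("site_1", 0.00, 13.75, 20),
    Site("site_2", 1.15, 11.95, 42),
    Site("site_3", 38.13, 1.43, 49),
    Site("site_4", 38.25, 0.00, 76),
    Site("site_5", 38.89, 6.59, 50),
    Site("site_6", 40.00, 7.82, 95),
)

# Continental extent of the map the default sites sit on (same
# shifted-degree units).  Random gradient anchor points are drawn
# uniformly from this region: the continent reaches much farther east
# and south of the site cloud than west or north of it, and that
# asymmetry decides how often each site is "farthest" from an anchor
# point and therefore locally barred from a gradient-assigned
# behaviour.  An arbitrary polygon can be supplied instead of the
# rectangle for finer map shapes.
_DEFAULT_GRADIENT_REGION = ((-9.0, -28.7), (60.0, 43.4))


def _point_in_polygon(x: float, y: float, poly: np.ndarray) -> bool:
    """Even-odd ray-casting test."""
    inside = False
    x0, y0 = poly[-1]
    for x1, y1 in poly:
        if (y1 > y) != (y0 > y) and x < (x0 - x1) * (y - y1) / (y0 - y1) + x1:
            inside = not inside
        x0, y0 = x1, y1
    return inside

DEFAULT_POPULATION_SIZES = (20, 42, 49, 76, 50, 95)


@dataclass(frozen=True)
class SiteMap:
    """An ordered collection of sites, plus the map region random
    gradient points are drawn from.

    The default map has exactly six sites with population sizes
    (20, 42, 49, 76, 50, 95) and a continental-extent gradient region.
    Custom maps may have any number of sites >= 2, but no two sites may
    share coordinates; without an explicit ``gradient_region`` their
    bounding box is used.
    """

    sites: tuple[Site, ...]
    #: either two (lower, upper) rectangle corners, or >= 3 polygon
    #: vertices; ``None`` falls back to the sites' bounding box
    gradient_region: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if len(self.sites) < 2:
            raise ConfigurationError("a SiteMap needs at least 2 sites")
        coords = {(s.x, s.y) for s in self.sites}
        if len(coords) != len(self.sites):
            raise ConfigurationError("two sites share identical coordinates")
        if any(s.n < 1 for s in self.sites):
            raise ConfigurationError("every site needs a population size >= 1")
        if self.gradient_region is not None:
            pts = np.asarray(self.gradient_region, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
                raise ConfigurationError(
                    "gradient_region needs two rectangle corners or >= 3 vertices"
                )
            if len(pts) == 2 and not (pts[0] < pts[1]).all():
                raise ConfigurationError("gradient_region corners must be ordered")

    @classmethod
    def default(cls) -> "SiteMap":
        return cls(_DEFAULT_SITES, gradient_region=_DEFAULT_GRADIENT_REGION)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sites]

    @property
    def coords(self) -> np.ndarray:
        """(n_sites, 2) array of planar coordinates."""
        return np.array([(s.x, s.y) for s in self.sites], dtype=float)

    @property
    def sizes(self) -> np.ndarray:
        """(n_sites,) array of population sizes."""
        return np.array([s.n for s in self.sites], dtype=np.int64)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corners of the sites' axis-aligned bounding box."""
        c = self.coords
        return c.min(axis=0), c.max(axis=0)

    def sample_gradient_point(self, rng: np.random.Generator) -> np.ndarray:
        """One anchor point for a propensity gradient, drawn uniformly
        from the map region: the ``gradient_region`` rectangle or
        polygon if set (polygons via rejection sampling), else the
        sites' bounding box."""
        if self.gradient_region is None:
            lo, hi = self.bounding_box()
            return rng.uniform(lo, hi)
        pts = np.asarray(self.gradient_region, dtype=float)
        if len(pts) == 2:
            return rng.uniform(pts[0], pts[1])
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        while True:
            p = rng.uniform(lo, hi)
            if _point_in_polygon(p[0], p[1], pts):
                return p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": self.names, "x": self.coords[:, 0], "y": self.coords[:, 1], "n": self.sizes}
        )


# ---------------------------------------------------------------------------
# Behaviour space


@dataclass(frozen=True)
class FoodSubcategory:
    size: int
    nutrient: str  # "Y" or "Z"


#: Default partition of the 32 food behaviours into 10 sub-categories of
#: varying size, nutrients alternating so that 5 provide Y and 5 provide Z.
DEFAULT_FOOD_STRUCTURE: tuple[FoodSubcategory, ...] = tuple(
    FoodSubcategory(size, nutrient)
    for size, nutrient in zip(
        (8, 5, 4, 4, 3, 2, 2, 2, 1, 1), ("Y", "Z") * 5
    )
)

SOCIAL_SUBCATEGORY_NAMES = ("play", "display", "groom", "courtship")


class BehaviourSpace:
    """The latent behaviour repertoire: which behaviours exist, their
    category, sub-category and (for food) nutrient.

    Behaviour ids are 1-based and contiguous: social behaviours first,
    then food behaviours.  The default space has 64 behaviours — 32
    social in 4 sub-categories of 8, and 32 food-related in the
    sub-categories given by :data:`DEFAULT_FOOD_STRUCTURE`.

    Internally the class pre-computes the membership matrices used by
    the vectorised state computations in :mod:`moexsim.dynamics`.
    """

    def __init__(
        self,
        social_subcategory_sizes: Sequence[int],
        food_subcategories: Sequence[FoodSubcategory],
        social_subcategory_names: Sequence[str] | None = None,
    ) -> None:
        self.social_subcategory_sizes = tuple(int(s) for s in social_subcategory_sizes)
        self.food_subcategories = tuple(food_subcategories)
        if social_subcategory_names is None:
            social_subcategory_names = [
                f"social_{i + 1}" for i in range(len(self.social_subcategory_sizes))
            ]
        self.social_subcategory_names = tuple(social_subcategory_names)

        self.n_social = sum(self.social_subcategory_sizes)
        self.n_food = sum(f.size for f in self.food_subcategories)
        self.n_behaviours = self.n_social + self.n_food
        self.n_social_subcategories = len(self.social_subcategory_sizes)
        self.n_food_subcategories = len(self.food_subcategories)

        # per-behaviour sub-category index, within each category block
        self.social_subcat_of = np.repeat(
            np.arange(self.n_social_subcategories),
            self.social_subcategory_sizes,
        )
        self.food_subcat_of = np.repeat(
            np.arange(self.n_food_subcategories),
            [f.size for f in self.food_subcategories],
        )
        self.food_subcat_nutrient = np.array(
            [f.nutrient for f in self.food_subcategories]
        )

        # one-hot membership matrices (uint8 so that rep @ M stays integer)
        self._social_membership = np.zeros(
            (self.n_social, self.n_social_subcategories), dtype=np.uint8
        )
        self._social_membership[np.arange(self.n_social), self.social_subcat_of] = 1
        self._food_membership = np.zeros(
            (self.n_food, self.n_food_subcategories), dtype=np.uint8
        )
        self._food_membership[np.arange(self.n_food), self.food_subcat_of] = 1
        # block-diagonal join of the two membership matrices, so the hot
        # loop can resolve all sub-category fulfilments in one matmul
        self._membership = np.zeros(
            (self.n_behaviours, self.n_social_subcategories + self.n_food_subcategories),
            dtype=np.uint8,
        )
        self._membership[: self.n_social, : self.n_social_subcategories] = (
            self._social_membership
        )
        self._membership[self.n_social :, self.n_social_subcategories :] = (
            self._food_membership
        )
        self._food_y_mask = self.food_subcat_nutrient == "Y"

    # -- id conventions -----------------------------------------------------

    @property
    def social_ids(self) -> np.ndarray:
        """1-based ids of social behaviours (1..n_social)."""
        return np.arange(1, self.n_social + 1)

    @property
    def food_ids(self) -> np.ndarray:
        """1-based ids of food behaviours (n_social+1..n_behaviours)."""
        return np.arange(self.n_social + 1, self.n_behaviours + 1)

    def is_food(self, behaviour_id: int) -> bool:
        return behaviour_id > self.n_social

    @property
    def food_mask(self) -> np.ndarray:
        """(n_behaviours,) boolean mask, True for food behaviours."""
        mask = np.zeros(self.n_behaviours, dtype=bool)
        mask[self.n_social :] = True
        return mask

    def to_frame(self) -> pd.DataFrame:
        """Long-format listing: id, category, subcategory, nutrient."""
        subcat = [
            self.social_subcategory_names[i] for i in self.social_subcat_of
        ] + [f"food_{i + 1}" for i in self.food_subcat_of]
        nutrient = ["none"] * self.n_social + [
            self.food_subcat_nutrient[i] for i in self.food_subcat_of
        ]
        return pd.DataFrame(
            {
                "behaviour_id": np.arange(1, self.n_behaviours + 1),
                "category": ["social"] * self.n_social + ["food"] * self.n_food,
                "subcategory": subcat,
                "nutrient": nutrient,
            }
        )


def _coerce_food_structure(
    food_structure: Iterable[FoodSubcategory | dict | tuple],
) -> tuple[FoodSubcategory, ...]:
    out = []
    for item in food_structure:
        if isinstance(item, FoodSubcategory):
            out.append(item)
        elif isinstance(item, dict):
            out.append(FoodSubcategory(int(item["size"]), str(item["nutrient"])))
        else:
            size, nutrient = item
            out.append(FoodSubcategory(int(size), str(nutrient)))
    return tuple(out)


def build_behaviour_space(
    food_structure: Iterable[FoodSubcategory | dict | tuple] | None = None,
) -> BehaviourSpace:
    """Build the default 64-behaviour space.

    Parameters
    ----------
    food_structure
        Optional partition of the 32 food behaviours into sub-categories,
        as a sequence of ``FoodSubcategory``, ``{"size": .., "nutrient": ..}``
        mappings, or ``(size, nutrient)`` pairs.  Sizes must sum to 32,
        each must be >= 1, and both nutrients Y and Z must occur.
        Defaults to :data:`DEFAULT_FOOD_STRUCTURE`.

    Returns
    -------
    BehaviourSpace
        32 social behaviours (ids 1-32, four sub-categories of eight)
        followed by 32 food behaviours (ids 33-64).
    """
    if food_structure is None:
        food = DEFAULT_FOOD_STRUCTURE
    else:
        food = _coerce_food_structure(food_structure)

    if any(f.size < 1 for f in food):
        raise ConfigurationError("every food sub-category needs size >= 1")
    total = sum(f.size for f in food)
    if total != 32:
        raise ConfigurationError(
            f"food sub-category sizes must sum to 32, got {total}"
        )
    nutrients = {f.nutrient for f in food}
    if not nutrients <= {"Y", "Z"}:
        raise ConfigurationError(f"unknown nutrient label(s): {nutrients - {'Y', 'Z'}}")
    if nutrients != {"Y", "Z"}:
        raise ConfigurationError("need at least one Y and one Z food sub-category")

    return BehaviourSpace(
        social_subcategory_sizes=(8, 8, 8, 8),
        food_subcategories=food,
        social_subcategory_names=SOCIAL_SUBCATEGORY_NAMES,
    )


# ---------------------------------------------------------------------------
# Propensities


def gradient_probabilities(point: Sequence[float], sites: SiteMap) -> np.ndarray:
    """Distance-gradient probabilities of a random geographic point.

    Euclidean distances from ``point`` to each site are min-max rescaled
    to [0, 1] and inverted: the nearest site gets probability exactly 1,
    the farthest exactly 0, and ties give identical values.  A behaviour
    assigned such a gradient can therefore never be expressed at the
    farthest site.
    """
    point = np.asarray(point, dtype=float)
    if point.shape != (2,) or not np.all(np.isfinite(point)):
        raise ConfigurationError("point must be a finite (x, y) pair")
    d = np.linalg.norm(sites.coords - point, axis=1)
    dmin, dmax = d.min(), d.max()
    if dmax == dmin:
        # all sites equidistant (measure-zero for >= 3 non-collinear
        # sites): no geographic signal, treat every site as nearest
        return np.ones(len(sites))
    return 1.0 - (d - dmin) / (dmax - dmin)


@dataclass(frozen=True)
class PropensityTable:
    """Per-behaviour, per-site gates: genetic propensity ``p_g`` and
    ecological availability ``p_e`` (both (n_behaviours, n_sites),
    entries in [0, 1]; ``p_e`` is fixed to 1 for social behaviours)."""

    p_g: np.ndarray
    p_e: np.ndarray

    def to_frame(self, sites: SiteMap) -> pd.DataFrame:
        """Long format: behaviour_id, site, p_g, p_e."""
        n_beh, n_sites = self.p_g.shape
        return pd.DataFrame(
            {
                "behaviour_id": np.repeat(np.arange(1, n_beh + 1), n_sites),
                "site": np.tile(np.array(sites.names), n_beh),
                "p_g": self.p_g.ravel(),
                "p_e": self.p_e.ravel(),
            }
        )

    def to_csv(self, path, sites: SiteMap) -> None:
        self.to_frame(sites).to_csv(path, index=False)


def assign_propensities(
    space: BehaviourSpace,
    sites: SiteMap,
    alpha_g: float,
    alpha_e: float,
    rng: np.random.Generator,
) -> PropensityTable:
    """Draw the genetic/ecological gate table for one simulation run.

    Independently for each behaviour, with probability ``alpha_g`` the
    ``p_g`` row follows a geographic gradient anchored at a point drawn
    uniformly from the map region the sites live on (see
    :meth:`SiteMap.sample_gradient_point`); otherwise it is a single
    uniform(0, 1) draw shared by all sites.  ``p_e`` rows are assigned
    the same way with ``alpha_e``, but only for food behaviours:
    social rows are fixed at 1 (ecology never limits social
    behaviours).
    """
    for name, alpha in (("alpha_g", alpha_g), ("alpha_e", alpha_e)):
        if not 0.0 <= alpha <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1], got {alpha}")

    n_sites = len(sites)

    def draw_row(alpha: float) -> np.ndarray:
        if rng.random() < alpha:
            point = sites.sample_gradient_point(rng)
            return gradient_probabilities(point, sites)
        return np.full(n_sites, rng.random())

    p_g = np.empty((space.n_behaviours, n_sites))
    p_e = np.ones((space.n_behaviours, n_sites))
    for b in range(space.n_behaviours):
        p_g[b] = draw_row(alpha_g)
    for b in range(space.n_social, space.n_behaviours):
        p_e[b] = draw_row(alpha_e)
    return PropensityTable(p_g=p_g, p_e=p_e)
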