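"""Experiment harness: parameter sweeps, the population-size vs.
cultural-count correlation, and the social-mediation (S) effect.

Every run in an experiment gets a reproducible integer seed derived
from the experiment's base seed and the run's grid position, and that
seed is recorded in the output row — any row can be reconstructed by
rerunning :func:`~moexsim.dynamics.run_simulation` with it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .census import locally_restricted, per_population_cultural_counts
from .dynamics import SimulationParams, run_simulation
from .world import (
    BehaviourSpace,
    ConfigurationError,
    FoodSubcategory,
    Site,
    SiteMap,
)

__all__ = [
    "UndefinedCorrelationError",
    "CorrelationStats",
    "CorrelationResult",
    "SEffectResult",
    "DEFAULT_ALPHA_E_GRID",
    "DEFAULT_ALPHA_G_GRID",
    "derive_seed",
    "sweep_grid",
    "rank_correlation",
    "correlation_experiment",
    "s_effect_experiment",
    "mini_world",
]

#: Default sweep grid: moderate-to-high ecological variability crossed
#: with zero-to-moderate genetic differences (6 x 5 combinations; with
#: 20 replicates each, 600 runs).
DEFAULT_ALPHA_E_GRID = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
DEFAULT_ALPHA_G_GRID = (0.0, 0.125, 0.25, 0.375, 0.5)


class UndefinedCorrelationError(ValueError):
    """Raised when a rank correlation is undefined (a variable is
    constant)."""


def derive_seed(base_seed: int, *key: int) -> int:
    """Reproducible integer seed (< 2**31) for one run of an
    experiment, derived from the base seed and the run's position."""
    ss = np.random.SeedSequence([int(base_seed), *map(int, key)])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def _one_run(
    params: SimulationParams,
    sites: SiteMap | None,
    space: BehaviourSpace | None,
) -> dict:
    res = run_simulation(params, sites, space)
    return {
        "n_cultural": res.n_cultural,
        "n_locally_restricted": len(locally_restricted(res.census)),
        "per_population": per_population_cultural_counts(res.census, res.patterns),
    }


# ---------------------------------------------------------------------------
# Parameter sweep


def sweep_grid(
    alpha_e_values: Sequence[float] = DEFAULT_ALPHA_E_GRID,
    alpha_g_values: Sequence[float] = DEFAULT_ALPHA_G_GRID,
    S: float = 1.0,
    replicates: int = 20,
    base_seed: int = 0,
    t_max: int = 6000,
    sites: SiteMap | None = None,
    space: BehaviourSpace | None = None,
) -> pd.DataFrame:
    """Run the full (alpha_e x alpha_g x replicate) grid.

    Returns one row per run with columns ``alpha_e``, ``alpha_g``,
    ``S``, ``seed``, ``replicate``, ``n_cultural`` and
    ``n_locally_restricted``.
    """
    alpha_e_values = tuple(alpha_e_values)
    alpha_g_values = tuple(alpha_g_values)
    if not alpha_e_values or not alpha_g_values or replicates < 1:
        raise ConfigurationError("sweep grid and replicates must be non-empty")

    rows = []
    for ci, (ae, ag) in enumerate(
        (ae, ag) for ae in alpha_e_values for ag in alpha_g_values
    ):
        for r in range(replicates):
            seed = derive_seed(base_seed, ci, r)
            params = SimulationParams(
                S=S, alpha_g=ag, alpha_e=ae, t_max=t_max, seed=seed
            )
            out = _one_run(params, sites, space)
            rows.append(
                {
                    "alpha_e": ae,
                    "alpha_g": ag,
                    "S": S,
                    "seed": seed,
                    "replicate": r,
                    "n_cultural": out["n_cultural"],
                    "n_locally_restricted": out["n_locally_restricted"],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rank correlation


@dataclass(frozen=True)
class CorrelationStats:
    rho: float
    p_value: float
    n: int
    method: str


def rank_correlation(
    pairs: Iterable[tuple[float, float]] | np.ndarray,
    method: str = "spearman",
    permutations: int = 0,
    seed: int | None = None,
) -> CorrelationStats:
    """Correlation between the two columns of ``pairs``.

    ``spearman`` (default) uses average ranks for ties with the
    asymptotic t-approximation p-value; ``pearson`` is offered for
    sensitivity.  ``permutations > 0`` replaces the asymptotic p-value
    with a permutation p-value over that many shuffles.
    """
    arr = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ConfigurationError("need an (n >= 3, 2) array of pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: a variable has zero variance"
        )
    stat = {"spearman": sps.spearmanr, "pearson": sps.pearsonr}[method]
    res = stat(x, y)
    rho, p = float(res.statistic), float(res.pvalue)
    if permutations:
        rng = np.random.default_rng(seed)
        obs = abs(rho)
        hits = 0
        y_perm = y.copy()
        for _ in range(permutations):
            rng.shuffle(y_perm)
            hits += abs(float(stat(x, y_perm).statistic)) >= obs
        p = (hits + 1) / (permutations + 1)
    return CorrelationStats(rho=rho, p_value=p, n=len(x), method=method)


# ---------------------------------------------------------------------------
# Population size vs. cultural repertoire


@dataclass(frozen=True)
class CorrelationResult:
    """Pooled (population size, expressed cultural behaviours) pairs —
    one per site per run — and their rank correlation."""

    pairs: pd.DataFrame
    rho: float
    p_value: float
    n: int
    method: str


def correlation_experiment(
    runs: int = 100,
    params: SimulationParams = SimulationParams(),
    base_seed: int = 0,
    sites: SiteMap | None = None,
    space: BehaviourSpace | None = None,
    method: str = "spearman",
) -> CorrelationResult:
    """For each run, record how many pattern-D behaviours each site
    expresses; pool all (size, count) pairs and rank-correlate."""
    if runs < 2:
        raise ConfigurationError("need at least 2 runs")
    site_map = sites if sites is not None else SiteMap.default()
    sizes = site_map.sizes
    rows = []
    for r in range(runs):
        seed = derive_seed(base_seed, r)
        run_params = SimulationParams(
            S=params.S,
            alpha_g=params.alpha_g,
            alpha_e=params.alpha_e,
            t_max=params.t_max,
            sigma=params.sigma,
            seed=seed,
        )
        out = _one_run(run_params, site_map, space)
        for i, name in enumerate(site_map.names):
            rows.append(
                {
                    "run": r,
                    "seed": seed,
                    "site": name,
                    "population_size": int(sizes[i]),
                    "n_cultural_expressed": int(out["per_population"][i]),
                    "n_cultural_run": out["n_cultural"],
                }
            )
    pairs = pd.DataFrame(rows)
    stats_ = rank_correlation(
        pairs[["population_size", "n_cultural_expressed"]].to_numpy(), method=method
    )
    return CorrelationResult(
        pairs=pairs,
        rho=stats_.rho,
        p_value=stats_.p_value,
        n=stats_.n,
        method=stats_.method,
    )


# ---------------------------------------------------------------------------
# Effect of S


@dataclass(frozen=True)
class SEffectResult:
    """Per-run cultural counts across values of S, plus per-S means."""

    runs: pd.DataFrame
    summary: pd.DataFrame


def s_effect_experiment(
    S_values: Sequence[float],
    params: SimulationParams = SimulationParams(),
    replicates: int = 20,
    base_seed: int = 0,
    sites: SiteMap | None = None,
    space: BehaviourSpace | None = None,
) -> SEffectResult:
    """Sweep S at fixed (alpha_e, alpha_g) and summarise the mean
    number of cultural behaviours per S value."""
    S_values = tuple(S_values)
    if not S_values or replicates < 1:
        raise ConfigurationError("need at least one S value and one replicate")
    rows = []
    for si, S in enumerate(S_values):
        for r in range(replicates):
            seed = derive_seed(base_seed, si, r)
            run_params = SimulationParams(
                S=S,
                alpha_g=params.alpha_g,
                alpha_e=params.alpha_e,
                t_max=params.t_max,
                sigma=params.sigma,
                seed=seed,
            )
            out = _one_run(run_params, sites, space)
            rows.append(
                {
                    "S": S,
                    "alpha_e": params.alpha_e,
                    "alpha_g": params.alpha_g,
                    "seed": seed,
                    "replicate": r,
                    "n_cultural": out["n_cultural"],
                }
            )
    runs = pd.DataFrame(rows)
    summary = (
        runs.groupby("S", as_index=False)["n_cultural"]
        .agg(["mean", "std", "count"])
        .rename(columns={"mean": "mean_n_cultural"})
    )
    return SEffectResult(runs=runs, summary=summary)


# ---------------------------------------------------------------------------
# Fixtures


def mini_world() -> tuple[SiteMap, BehaviourSpace]:
    """A deterministic miniature world for fast tests: two sites of ten
    agents and an 8-behaviour space (2 social sub-categories of 2, plus
    one Y and one Z food sub-category of 2)."""
    sites = SiteMap((Site("west", 0.0, 0.0, 10), Site("east", 4.0, 1.0, 10)))
    space = BehaviourSpace(
        social_subcategory_sizes=(2, 2),
        food_subcategories=(FoodSubcategory(2, "Y"), FoodSubcategory(2, "Z")),
        social_subcategory_names=("play", "groom"),
    )
    return sites, space


def plot_sweep_heatmap(df: pd.DataFrame, threshold: int = 38, path=None):
    """Mean cultural count per (alpha_g, alpha_e) cell, with cells above
    ``threshold`` highlighted.  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = df.pivot_table(
        index="alpha_g", columns="alpha_e", values="n_cultural", aggfunc="mean"
    )
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(grid.to_numpy(), cmap="coolwarm", origin="lower")
    ax.set_xticks(range(grid.shape[1]), [f"{v:g}" for v in grid.columns])
    ax.set_yticks(range(grid.shape[0]), [f"{v:g}" for v in grid.index])
    ax.set_xlabel("alpha_e")
    ax.set_ylabel("alpha_g")
    for (i, j), v in np.ndenumerate(grid.to_numpy()):
        ax.text(j, i, f"{v:.0f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label=f"mean cultural count (threshold {threshold})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
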