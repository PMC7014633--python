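"""Weighted p-median facility siting over the road network.

Choose the best k facility sites from a candidate pool, minimizing the
sum over demand points of ``w_i * d(i, nearest selected site)`` where d
is network driving distance.  Four weighting scenarios are supported:
uniform (distance only), population, dengue case counts, and HCI.

The reference instance (10 candidates, k = 2, 45 subsets) is tiny, so
exhaustive enumeration is the default solver; a seeded Teitz-Bart
vertex-substitution heuristic is provided for larger candidate pools.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .census_attributes import Neighborhood
from .route_costing import NeighborhoodCost

__all__ = [
    "WEIGHTING_MODES",
    "AllocationConfig",
    "AllocationResult",
    "ComparisonMetrics",
    "scenario_weights",
    "pmedian_objective",
    "solve_enumerate",
    "solve_teitz_bart",
    "solve",
    "compare_scenarios",
    "EnumerationLimitExceeded",
]

WEIGHTING_MODES = ("distance_only", "population", "dengue_cases", "hci")


class EnumerationLimitExceeded(RuntimeError):
    """Too many candidate subsets to enumerate; use the heuristic solver."""


@dataclass(frozen=True)
class AllocationConfig:
    k: int = 2
    weighting_mode: str = "distance_only"
    enumeration_limit: int = 10_000
    heuristic_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.weighting_mode not in WEIGHTING_MODES:
            raise ValueError(f"weighting_mode must be one of {WEIGHTING_MODES}")


@dataclass(frozen=True)
class AllocationResult:
    selected: tuple[Hashable, ...]  # facility ids, sorted
    objective: float  # sum_i w_i * d(i, nearest selected)
    assignments: dict[Hashable, Hashable]  # demand id -> facility id
    solver: str  # "exact" | "heuristic"


@dataclass(frozen=True)
class ComparisonMetrics:
    mean_cost_reduction_pct: float
    cheapest_class_population_change_pct: float


def scenario_weights(
    neighborhoods: Sequence[Neighborhood], mode: str
) -> dict[Hashable, float]:
    """Per-neighborhood demand weights for one of the four scenarios."""
    if mode == "distance_only":
        return {n.id: 1.0 for n in neighborhoods}
    if mode == "population":
        return {n.id: float(n.population) for n in neighborhoods}
    if mode == "dengue_cases":
        return {n.id: float(n.dengue_cases) for n in neighborhoods}
    if mode == "hci":
        return {n.id: float(n.hci) for n in neighborhoods}
    raise ValueError(f"unknown weighting mode {mode!r}")


def _aligned(
    dm: pd.DataFrame, weights: Mapping[Hashable, float]
) -> tuple[np.ndarray, np.ndarray, list, list]:
    demand = list(dm.columns)
    w = np.array([weights[d] for d in demand], dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    return dm.to_numpy(dtype=float), w, list(dm.index), demand


def pmedian_objective(
    dm: pd.DataFrame,
    selected: Sequence[Hashable],
    weights: Mapping[Hashable, float],
) -> float:
    """Weighted sum of distances from each demand point (columns of
    ``dm``) to its nearest selected facility (rows of ``dm``)."""
    selected = list(selected)
    if not selected:
        raise ValueError("empty facility selection")
    sub = dm.loc[selected].to_numpy(dtype=float)
    w = np.array([weights[d] for d in dm.columns], dtype=float)
    return float(sub.min(axis=0) @ w)


def _assignments(
    dm: pd.DataFrame, selected: Sequence[Hashable]
) -> dict[Hashable, Hashable]:
    """Nearest selected facility per demand point; distance ties broken
    by smallest facility id (string order)."""
    ordered = sorted(selected, key=str)
    sub = dm.loc[ordered].to_numpy(dtype=float)
    winners = sub.argmin(axis=0)  # argmin takes the first (= smallest id) on ties
    return {d: ordered[winners[j]] for j, d in enumerate(dm.columns)}


def _result(dm, selected, weights, solver) -> AllocationResult:
    sel = tuple(sorted(selected, key=str))
    return AllocationResult(
        selected=sel,
        objective=pmedian_objective(dm, sel, weights),
        assignments=_assignments(dm, sel),
        solver=solver,
    )


def solve_enumerate(
    dm: pd.DataFrame,
    candidates: Sequence[Hashable],
    k: int,
    weights: Mapping[Hashable, float],
    enumeration_limit: int = 10_000,
) -> AllocationResult:
    """Global optimum by exhaustive evaluation of every k-subset.

    Objective ties are broken by the lexicographically smallest id set.
    Raises :class:`EnumerationLimitExceeded` when C(n, k) exceeds
    ``enumeration_limit``.
    """
    candidates = sorted(set(candidates), key=str)
    if not 1 <= k <= len(candidates):
        raise ValueError(f"k={k} outside [1, {len(candidates)}]")
    n_subsets = math.comb(len(candidates), k)
    if n_subsets > enumeration_limit:
        raise EnumerationLimitExceeded(
            f"{n_subsets} subsets exceed limit {enumeration_limit}; "
            "use solve_teitz_bart"
        )
    matrix, w, _, _ = _aligned(dm.loc[candidates], weights)
    best_obj, best_sel = math.inf, None
    for combo in itertools.combinations(range(len(candidates)), k):
        obj = float(matrix[list(combo)].min(axis=0) @ w)
        if obj < best_obj - 1e-12 or (
            abs(obj - best_obj) <= 1e-12
            and best_sel is not None
            and combo < best_sel
        ):
            best_obj, best_sel = obj, combo
    selected = [candidates[i] for i in best_sel]
    return _result(dm, selected, weights, "exact")


def solve_teitz_bart(
    dm: pd.DataFrame,
    candidates: Sequence[Hashable],
    k: int,
    weights: Mapping[Hashable, float],
    restarts: int = 5,
    seed: int = 0,
) -> AllocationResult:
    """Teitz-Bart vertex substitution: from a random k-subset, repeatedly
    apply the best improving single swap until a local optimum; keep the
    best local optimum over ``restarts`` seeded starts."""
    candidates = sorted(set(candidates), key=str)
    if not 1 <= k <= len(candidates):
        raise ValueError(f"k={k} outside [1, {len(candidates)}]")
    matrix, w, _, _ = _aligned(dm.loc[candidates], weights)
    n = len(candidates)
    rng = np.random.default_rng(seed)

    def objective(idx: frozenset[int]) -> float:
        return float(matrix[list(idx)].min(axis=0) @ w)

    best_obj, best_sel = math.inf, None
    for _ in range(max(1, restarts)):
        current = frozenset(rng.choice(n, size=k, replace=False).tolist())
        cur_obj = objective(current)
        improved = True
        while improved:
            improved = False
            swap_best = (cur_obj, current)
            for out in sorted(current):
                for inc in range(n):
                    if inc in current:
                        continue
                    trial = (current - {out}) | {inc}
                    obj = objective(frozenset(trial))
                    if obj < swap_best[0] - 1e-12:
                        swap_best = (obj, frozenset(trial))
            if swap_best[0] < cur_obj - 1e-12:
                cur_obj, current = swap_best
                improved = True
        key = tuple(sorted(current))
        if cur_obj < best_obj - 1e-12 or (
            abs(cur_obj - best_obj) <= 1e-12
            and best_sel is not None
            and key < tuple(sorted(best_sel))
        ):
            best_obj, best_sel = cur_obj, current
    selected = [candidates[i] for i in sorted(best_sel)]
    return _result(dm, selected, weights, "heuristic")


def solve(
    dm: pd.DataFrame,
    candidates: Sequence[Hashable],
    config: AllocationConfig,
    weights: Mapping[Hashable, float],
) -> AllocationResult:
    """Enumerate when the instance is small enough, else fall back to
    the Teitz-Bart heuristic."""
    try:
        return solve_enumerate(
            dm, candidates, config.k, weights, config.enumeration_limit
        )
    except EnumerationLimitExceeded:
        return solve_teitz_bart(
            dm,
            candidates,
            config.k,
            weights,
            restarts=config.heuristic_restarts,
            seed=config.seed,
        )


def compare_scenarios(
    baseline_costs: Sequence[NeighborhoodCost],
    alternative_costs: Sequence[NeighborhoodCost],
    neighborhoods: Sequence[Neighborhood],
    class_edges: Sequence[float],
) -> ComparisonMetrics:
    """Compare an alternative facility scenario against the baseline.

    ``mean_cost_reduction_pct``: percent reduction in the mean total
    access cost.  ``cheapest_class_population_change_pct``: percent
    change in population whose cost falls in the cheapest class, with
    class edges fixed from the baseline so both scenarios are measured
    against the same break.  Both scenarios must cover the same
    neighborhood set.  Undefined metrics (zero baseline) are NaN.
    """
    base_ids = {c.neighborhood_id for c in baseline_costs}
    alt_ids = {c.neighborhood_id for c in alternative_costs}
    if base_ids != alt_ids:
        raise ValueError("scenarios cover different neighborhood sets")
    if not class_edges:
        raise ValueError("class_edges required (baseline-derived)")

    pop = {n.id: n.population for n in neighborhoods}
    cheapest_edge = float(class_edges[0])

    mean_base = float(np.mean([c.total_cost_usd for c in baseline_costs]))
    mean_alt = float(np.mean([c.total_cost_usd for c in alternative_costs]))
    reduction = (
        (mean_base - mean_alt) / mean_base * 100.0 if mean_base > 0 else math.nan
    )

    def cheapest_pop(costs: Sequence[NeighborhoodCost]) -> float:
        return float(
            sum(pop[c.neighborhood_id] for c in costs if c.total_cost_usd <= cheapest_edge)
        )

    pop_base = cheapest_pop(baseline_costs)
    pop_alt = cheapest_pop(alternative_costs)
    change = (pop_alt - pop_base) / pop_base * 100.0 if pop_base > 0 else math.nan

    return ComparisonMetrics(
        mean_cost_reduction_pct=reduction,
        cheapest_class_population_change_pct=change,
    )
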