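"""Farm-level decision optimizers: crop-to-plot allocation at planting and
labor-to-plot allocation at harvest.

Planting is a constrained binary program over the assignment matrix x_ij
(crop i on plot j), at most one crop per plot, maximizing expected profit

    Psi(x) = sum_ij (V_i * Y_ij * h_i * L_ij - C_L * L_ij - a_ij) * x_ij

under the full-harvest labor assumption L_ij = S_j / h_i (the planner cannot
anticipate the labor draw, which happens after allocation). Because the
objective is separable across plots, free-mode planting reduces to a per-plot
argmax; strategy-constrained planting adds a coverage constraint (every
strategy crop on at least one plot, every plot planted) and is solved by exact
enumeration with a lexicographic (crop index, plot index) tie-break, or
optionally by a mixed-integer solver.

Harvesting fixes x and allocates a labor budget across planted cells,
maximizing sum (V_i * Y_ij * h_i - C_L) * L_ij subject to the budget and the
per-cell capacity S_j * r_i. This is a continuous knapsack: a greedy fill by
descending marginal profit per laborer is exactly optimal, and cells whose
marginal profit is non-positive receive no labor (partial harvests are
allowed; unprofitable ones are not taken).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .model import (
    CropParams,
    EconomyParams,
    FarmingUnit,
    InvariantError,
    MarketState,
    PlotSpec,
    harvest_capacity,
)


class InfeasibleStrategyError(InvariantError):
    """The unit's strategy cannot be realized on its plots."""


@dataclass(frozen=True)
class PlantingPlan:
    """A crop-to-plot assignment: ``crop_by_plot[j]`` is the crop name planted
    on the unit's j-th plot, or ``None`` for fallow. Equivalent to a binary
    matrix x_ij with column sums <= 1."""

    crop_by_plot: tuple[str | None, ...]

    @property
    def planted(self) -> bool:
        return any(c is not None for c in self.crop_by_plot)

    def planted_cells(self, plots: list[PlotSpec]) -> list[tuple[str, PlotSpec]]:
        return [
            (crop, plot)
            for crop, plot in zip(self.crop_by_plot, plots)
            if crop is not None
        ]


@dataclass(frozen=True)
class HarvestPlan:
    """A labor allocation over planted (crop, plot) cells.

    ``labor`` maps (crop name, plot_id) to laborers assigned (L_ij >= 0, at
    most the cell's harvest capacity). ``harvested_mass`` is the resulting kg
    per crop; ``realized_cost`` is the labor bill C_L * sum(L).
    """

    labor: dict[tuple[str, str], float]
    harvested_mass: dict[str, float]
    realized_cost: float

    @property
    def total_labor(self) -> float:
        return sum(self.labor.values())


@dataclass(frozen=True)
class ProfitBreakdown:
    """Seasonal profit components: profit = revenue - labor - production."""

    revenue: float
    labor_cost: float
    production_cost: float

    @property
    def profit(self) -> float:
        return self.revenue - self.labor_cost - self.production_cost


def _cell_values(
    plots: list[PlotSpec],
    crops: list[CropParams],
    prices: MarketState,
    economy: EconomyParams,
) -> np.ndarray:
    """Full-harvest net value of planting crop i on plot j, USD.

    With L_ij at capacity S_j * r_i, revenue is V_i * Y_ij * S_j, labor cost
    is C_L * r_i * S_j, and production cost is a_ij = c_i * S_j.
    """
    values = np.empty((len(crops), len(plots)))
    for i, crop in enumerate(crops):
        v = prices.price_by_crop[crop.name]
        for j, plot in enumerate(plots):
            values[i, j] = plot.size_acres * (
                v * plot.crop_yield(crop.name)
                - economy.labor_cost_per_laborer * crop.labor_requirement_per_acre
                - crop.production_cost_per_acre
            )
    return values


def expected_profit(
    plan: PlantingPlan,
    labor: HarvestPlan | None,
    prices: MarketState,
    unit: FarmingUnit,
    crops: list[CropParams],
    economy: EconomyParams,
) -> ProfitBreakdown:
    """Evaluate the profit of a planting plan under a labor allocation.

    ``labor=None`` means the full-harvest assumption (every planted cell is
    staffed to capacity), which is what the planting optimizer maximizes.
    Production cost is incurred for every planted plot regardless of how much
    of it is harvested.

    Raises
    ------
    InvariantError
        If ``labor`` assigns positive labor to a cell the plan did not plant.
    """
    crop_by_name = {c.name: c for c in crops}
    planted = {
        (crop, plot.plot_id): plot for crop, plot in plan.planted_cells(unit.plots)
    }
    if labor is not None:
        for (crop_name, plot_id), lab in labor.labor.items():
            if lab > 0 and (crop_name, plot_id) not in planted:
                raise InvariantError(
                    f"labor assigned to unplanted cell ({crop_name!r}, {plot_id!r})"
                )

    revenue = 0.0
    total_labor = 0.0
    production = 0.0
    for (crop_name, plot_id), plot in planted.items():
        crop = crop_by_name[crop_name]
        if labor is None:
            lab = harvest_capacity(plot, crop)
        else:
            lab = labor.labor.get((crop_name, plot_id), 0.0)
        revenue += (
            prices.price_by_crop[crop_name]
            * plot.crop_yield(crop_name)
            * crop.harvest_efficiency
            * lab
        )
        total_labor += lab
        production += crop.production_cost_per_acre * plot.size_acres
    labor_cost = economy.labor_cost_per_laborer * total_labor
    return ProfitBreakdown(
        revenue=revenue, labor_cost=labor_cost, production_cost=production
    )


def plan_planting(
    unit: FarmingUnit,
    crops: list[CropParams],
    expected_prices: MarketState,
    economy: EconomyParams,
    mode: str = "strategy_constrained",
    backend: str = "enumerate",
) -> PlantingPlan:
    """Choose the profit-maximizing crop-to-plot assignment.

    Modes
    -----
    ``"free"``
        Any crop (or fallow) on any plot, at most one crop per plot. The
        objective is separable, so each plot independently takes the best
        option; a plot is left fallow only when every crop's net value is
        strictly negative.
    ``"strategy_constrained"``
        Only the unit's strategy crops may be planted, every plot is planted
        in its entirety, and each strategy crop occupies at least one plot.

    Ties between equal-objective optima are resolved lexicographically: the
    lower-indexed crop goes on the lower-indexed plot (``backend="enumerate"``,
    the default). ``backend="milp"`` solves the same program with scipy's
    mixed-integer solver; it guarantees the optimal objective but not the
    tie-break.
    """
    if mode not in ("free", "strategy_constrained"):
        raise ValueError(f"unknown mode {mode!r}")
    for crop in crops:
        if crop.name not in expected_prices.price_by_crop:
            raise InvariantError(f"no expected price for crop {crop.name!r}")

    if mode == "strategy_constrained":
        strategy_crops = [c for c in crops if c.name in unit.strategy.crops]
        if len(strategy_crops) != len(unit.strategy.crops):
            missing = set(unit.strategy.crops) - {c.name for c in crops}
            raise InvariantError(f"strategy names unknown crops: {sorted(missing)}")
        if len(strategy_crops) > len(unit.plots):
            raise InfeasibleStrategyError(
                f"unit {unit.unit_id!r}: {len(strategy_crops)} strategy crops "
                f"but only {len(unit.plots)} plots"
            )
        candidates = strategy_crops
    else:
        candidates = list(crops)

    values = _cell_values(unit.plots, candidates, expected_prices, economy)

    if backend == "milp":
        return _plan_planting_milp(unit, candidates, values, mode)
    if backend != "enumerate":
        raise ValueError(f"unknown backend {backend!r}")

    n_plots = len(unit.plots)
    if mode == "free":
        # separable: per-plot argmax over crops (index order) then fallow
        assignment: list[str | None] = []
        for j in range(n_plots):
            best_val = -np.inf
            best: str | None = None
            for i, crop in enumerate(candidates):
                if values[i, j] > best_val:
                    best_val = values[i, j]
                    best = crop.name
            if best_val < 0.0:
                best = None  # fallow beats a strictly negative net
            assignment.append(best)  # at an exact zero tie the crop is kept
        return PlantingPlan(crop_by_plot=tuple(assignment))

    # strategy_constrained: enumerate crop choices per plot, coverage required.
    # itertools.product varies the last plot fastest, so the first strict
    # maximum encountered is the lexicographically smallest optimum
    # (lower-indexed crop on lower-indexed plot).
    m = len(candidates)
    best_obj = -np.inf
    best_choice: tuple[int, ...] | None = None
    for choice in itertools.product(range(m), repeat=n_plots):
        if len(set(choice)) != m:
            continue
        obj = sum(values[i, j] for j, i in enumerate(choice))
        if obj > best_obj:
            best_obj = obj
            best_choice = choice
    assert best_choice is not None  # feasibility guaranteed above
    return PlantingPlan(
        crop_by_plot=tuple(candidates[i].name for i in best_choice)
    )


def _plan_planting_milp(
    unit: FarmingUnit,
    candidates: list[CropParams],
    values: np.ndarray,
    mode: str,
) -> PlantingPlan:
    from scipy.optimize import LinearConstraint, milp

    m, n = values.shape
    c = -values.ravel()  # maximize
    constraints = []
    # one crop per plot: sum_i x_ij <= 1 (== 1 in strategy mode)
    col = np.zeros((n, m * n))
    for j in range(n):
        col[j, j::n] = 1.0
    lo = 1.0 if mode == "strategy_constrained" else 0.0
    constraints.append(LinearConstraint(col, lo, 1.0))
    if mode == "strategy_constrained":
        row = np.zeros((m, m * n))
        for i in range(m):
            row[i, i * n : (i + 1) * n] = 1.0
        constraints.append(LinearConstraint(row, 1.0, n))
    res = milp(
        c,
        integrality=np.ones(m * n),
        bounds=(0, 1),
        constraints=constraints,
    )
    if not res.success:  # pragma: no cover - constraints are always feasible
        raise RuntimeError(f"planting MILP failed: {res.message}")
    x = res.x.reshape(m, n)
    assignment: list[str | None] = []
    for j in range(n):
        picked = np.flatnonzero(x[:, j] > 0.5)
        assignment.append(candidates[picked[0]].name if picked.size else None)
    return PlantingPlan(crop_by_plot=tuple(assignment))


def plan_harvest(
    unit: FarmingUnit,
    decision_prices: MarketState,
    labor_budget: float,
    crops: list[CropParams],
    economy: EconomyParams,
) -> HarvestPlan:
    """Allocate a labor budget across the unit's planted cells.

    Fills cells in order of descending marginal profit per laborer
    V_i * Y_ij * h_i - C_L, each up to its harvest capacity, until the budget
    runs out; cells with non-positive marginal profit get no labor. Ties are
    broken by (crop index, plot index). This greedy fill is the exact optimum
    of the underlying linear program.
    """
    if labor_budget < 0:
        raise InvariantError(f"labor_budget must be >= 0, got {labor_budget}")
    if unit.planting_plan is None:
        raise InvariantError(f"unit {unit.unit_id!r} has no planting plan")
    plan: PlantingPlan = unit.planting_plan
    crop_by_name = {c.name: c for c in crops}
    crop_index = {c.name: i for i, c in enumerate(crops)}

    cells = []
    for j, (crop_name, plot) in enumerate(zip(plan.crop_by_plot, unit.plots)):
        if crop_name is None:
            continue
        crop = crop_by_name[crop_name]
        margin = (
            decision_prices.price_by_crop[crop_name]
            * plot.crop_yield(crop_name)
            * crop.harvest_efficiency
            - economy.labor_cost_per_laborer
        )
        cells.append((margin, crop_index[crop_name], j, crop, plot))
    cells.sort(key=lambda c: (-c[0], c[1], c[2]))

    labor: dict[tuple[str, str], float] = {}
    harvested: dict[str, float] = {}
    remaining = labor_budget
    for margin, _, _, crop, plot in cells:
        if margin <= 0 or remaining <= 0:
            lab = 0.0
        else:
            lab = min(remaining, harvest_capacity(plot, crop))
            remaining -= lab
        labor[(crop.name, plot.plot_id)] = lab
        if lab > 0:
            harvested[crop.name] = (
                harvested.get(crop.name, 0.0)
                + crop.harvest_efficiency * plot.crop_yield(crop.name) * lab
            )
    total = sum(labor.values())
    return HarvestPlan(
        labor=labor,
        harvested_mass=harvested,
        realized_cost=economy.labor_cost_per_laborer * total,
    )
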