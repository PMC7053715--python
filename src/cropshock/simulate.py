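"""The deterministic season loop.

One season runs, in order: (1) every unit allocates crops to plots using the
current market prices as expected prices; (2) every unit allocates its equal
share of the season's labor to harvest, decisions priced at the same expected
prices; (3) harvests are aggregated per crop over the region; (4) end-of-season
prices are recomputed from the aggregate harvest on the constant-elasticity
demand curve; (5) each unit's realized revenue is booked at the *new* prices
and its funds are updated with the season's profit.

Decisions therefore use lagged (previous-season) prices, while profit is
realized at the price the region's own harvest produces — the channel through
which units interact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .decisions import (
    HarvestPlan,
    PlantingPlan,
    ProfitBreakdown,
    plan_harvest,
    plan_planting,
)
from .model import (
    InvariantError,
    RegionState,
    ShockSchedule,
    update_market_price,
)


@dataclass(frozen=True)
class UnitOutcome:
    unit_id: str
    strategy_label: str
    plan: PlantingPlan
    harvest: HarvestPlan
    profit: ProfitBreakdown
    funds_after: float
    exited: bool = False


@dataclass(frozen=True)
class SeasonOutcome:
    """Everything that happened in one season."""

    season: int
    labor_available: float
    unit_outcomes: list[UnitOutcome]
    regional_harvest_by_crop: dict[str, float]
    prices_by_crop: dict[str, float]


@dataclass(frozen=True)
class Trajectory:
    outcomes: list[SeasonOutcome]
    config_fingerprint: str = ""

    def __len__(self) -> int:
        return len(self.outcomes)


def baseline_labor(region: RegionState) -> float:
    """Regional baseline labor: sized so the most labor-intensive crop could
    be fully harvested on every acre of the region (requirement per acre of
    that crop times total regional acreage)."""
    if not region.units or not region.crops:
        raise InvariantError("region needs at least one unit and one crop")
    total_acres = sum(u.total_acres for u in region.units)
    max_req = max(c.labor_requirement_per_acre for c in region.crops)
    return max_req * total_acres


def available_labor(
    season: int, schedule: ShockSchedule | None, baseline: float
) -> float:
    """Labor available to the region in ``season``: ``intensity * baseline``
    while the shock is active, the full baseline otherwise."""
    if season < 1:
        raise InvariantError(f"season must be >= 1, got {season}")
    if schedule is None:
        return baseline
    if schedule.start_season <= season < schedule.start_season + schedule.duration:
        return schedule.intensity * baseline
    return baseline


def step_season(
    region: RegionState,
    labor_available: float,
    mode: str = "strategy_constrained",
    backend: str = "enumerate",
    exit_floor: float | None = None,
) -> SeasonOutcome:
    """Advance the region by one season (mutates ``region``).

    Labor is split equally across active units. Units identical in strategy
    and land make identical decisions; their optimizations are shared, which
    changes nothing numerically.

    ``exit_floor``: optional funds level below which a unit exits production
    at the end of the season (off by default; under the packaged case
    parameterization no unit ever reaches it).
    """
    units = region.active_units
    if not units:
        raise InvariantError("no active units in region")
    share = labor_available / len(units)
    season = region.season + 1

    # plant + harvest, memoized over (strategy, land) signatures
    crops = region.crops
    economy = region.economy
    prices = region.market
    memo: dict[tuple, tuple[PlantingPlan, HarvestPlan]] = {}
    plans: list[tuple[PlantingPlan, HarvestPlan]] = []
    for unit in units:
        sig = (
            unit.strategy.crops,
            tuple(
                (p.size_acres, tuple(sorted(p.yield_by_crop.items())))
                for p in unit.plots
            ),
        )
        if sig not in memo:
            plan = plan_planting(unit, crops, prices, economy, mode=mode, backend=backend)
            unit.planting_plan = plan
            harvest = plan_harvest(unit, prices, share, crops, economy)
            memo[sig] = (plan, harvest)
        else:
            unit.planting_plan = memo[sig][0]
        plans.append(memo[sig])

    # aggregate regional harvest per crop
    regional: dict[str, float] = {c.name: 0.0 for c in crops}
    for _, harvest in plans:
        for crop_name, mass in harvest.harvested_mass.items():
            regional[crop_name] += mass

    # end-of-season prices from the aggregate harvest
    new_prices = {
        c.name: update_market_price(c, regional[c.name], economy) for c in crops
    }

    # realized profit at the new prices; funds update
    crop_by_name = region.crop_by_name
    outcomes: list[UnitOutcome] = []
    for unit, (plan, harvest) in zip(units, plans):
        revenue = sum(
            new_prices[crop_name] * mass
            for crop_name, mass in harvest.harvested_mass.items()
        )
        production = sum(
            crop_by_name[crop_name].production_cost_per_acre * plot.size_acres
            for crop_name, plot in plan.planted_cells(unit.plots)
        )
        profit = ProfitBreakdown(
            revenue=revenue,
            labor_cost=harvest.realized_cost,
            production_cost=production,
        )
        unit.funds += profit.profit
        unit.labor_share = share
        exited = exit_floor is not None and unit.funds < exit_floor
        if exited:
            unit.exited = True
        outcomes.append(
            UnitOutcome(
                unit_id=unit.unit_id,
                strategy_label=unit.strategy.label,
                plan=plan,
                harvest=harvest,
                profit=profit,
                funds_after=unit.funds,
                exited=exited,
            )
        )

    region.market.price_by_crop = new_prices
    region.market.last_total_harvest_by_crop = regional
    region.season = season
    return SeasonOutcome(
        season=season,
        labor_available=labor_available,
        unit_outcomes=outcomes,
        regional_harvest_by_crop=regional,
        prices_by_crop=new_prices,
    )


def run_simulation(
    region: RegionState,
    schedule: ShockSchedule | None,
    tau: int,
    mode: str = "strategy_constrained",
    backend: str = "enumerate",
    exit_floor: float | None = None,
    config_fingerprint: str = "",
) -> Trajectory:
    """Run ``tau`` seasons and return the full trajectory.

    Deterministic: identical inputs give bit-identical trajectories. In
    shock-experiment use, ``tau`` is the shock duration plus one recovery
    season.
    """
    if tau < 1:
        raise InvariantError(f"tau must be >= 1, got {tau}")
    base = region.baseline_labor_total
    outcomes = []
    for season in range(1, tau + 1):
        labor = available_labor(season, schedule, base)
        outcomes.append(
            step_season(
                region,
                labor,
                mode=mode,
                backend=backend,
                exit_floor=exit_floor,
            )
        )
    return Trajectory(outcomes=outcomes, config_fingerprint=config_fingerprint)


def trajectory_frame(trajectory: Trajectory) -> pd.DataFrame:
    """Tidy view of a trajectory: one row per (season, unit)."""
    rows = []
    for outcome in trajectory.outcomes:
        for u in outcome.unit_outcomes:
            row = {
                "season": outcome.season,
                "unit_id": u.unit_id,
                "strategy": u.strategy_label,
                "labor_available_region": outcome.labor_available,
                "labor_used": u.harvest.total_labor,
                "revenue": u.profit.revenue,
                "labor_cost": u.profit.labor_cost,
                "production_cost": u.profit.production_cost,
                "profit": u.profit.profit,
                "funds": u.funds_after,
                "exited": u.exited,
            }
            for crop_name, price in outcome.prices_by_crop.items():
                row[f"price_{crop_name}"] = price
                row[f"harvest_{crop_name}"] = u.harvest.harvested_mass.get(
                    crop_name, 0.0
                )
            rows.append(row)
    return pd.DataFrame(rows)
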