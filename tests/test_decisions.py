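"""Planting and harvest optimizers, checked against independent oracles:
brute-force enumeration of every feasible assignment for planting, and a
dense scipy LP solve for harvest labor allocation."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linprog

from cropshock.decisions import (
    HarvestPlan,
    InfeasibleStrategyError,
    PlantingPlan,
    expected_profit,
    plan_harvest,
    plan_planting,
)
from cropshock.model import (
    CropParams,
    EconomyParams,
    FarmingUnit,
    InvariantError,
    MarketState,
    PlotSpec,
    Strategy,
    harvest_capacity,
)
from cropshock.synthetic import sample_decision_instance


def make_crop(name="c", requirement=0.29, production=0.0, eps=-0.5):
    return CropParams(
        name=name,
        elasticity=eps,
        price_constant=1.0,
        production_cost_per_acre=production,
        labor_cost_per_acre=0.0,
        labor_requirement_per_acre=requirement,
    )


def free_economy(cl=0.0):
    return EconomyParams(labor_cost_per_laborer=cl, price_floor_harvest=1.0)


# ---------------------------------------------------------------- oracles


def brute_force_planting(unit, crops, prices, economy, mode):
    """Exhaustive search over all (m+1)^n assignments (including fallow),
    respecting the mode's constraints; returns the best objective."""
    if mode == "strategy_constrained":
        candidates = [c for c in crops if c.name in unit.strategy.crops]
    else:
        candidates = list(crops)
    options = [c.name for c in candidates] + [None]
    best = -np.inf
    for choice in itertools.product(options, repeat=len(unit.plots)):
        if mode == "strategy_constrained":
            if None in choice:
                continue
            if set(c.name for c in candidates) - set(choice):
                continue
        plan = PlantingPlan(crop_by_plot=choice)
        obj = expected_profit(plan, None, prices, unit, crops, economy).profit
        best = max(best, obj)
    return best


def lp_harvest_objective(unit, prices, budget, crops, economy):
    """Dense LP oracle for the harvest allocation objective."""
    crop_by_name = {c.name: c for c in crops}
    margins, caps = [], []
    for crop_name, plot in zip(unit.planting_plan.crop_by_plot, unit.plots):
        if crop_name is None:
            continue
        crop = crop_by_name[crop_name]
        margins.append(
            prices.price_by_crop[crop_name]
            * plot.crop_yield(crop_name)
            * crop.harvest_efficiency
            - economy.labor_cost_per_laborer
        )
        caps.append(harvest_capacity(plot, crop))
    if not margins:
        return 0.0
    res = linprog(
        c=-np.asarray(margins),
        A_ub=np.ones((1, len(margins))),
        b_ub=[budget],
        bounds=[(0, cap) for cap in caps],
        method="highs",
    )
    assert res.success
    return -res.fun


def harvest_objective(plan: HarvestPlan, unit, prices, crops, economy):
    crop_by_name = {c.name: c for c in crops}
    plot_by_id = {p.plot_id: p for p in unit.plots}
    total = 0.0
    for (crop_name, plot_id), lab in plan.labor.items():
        crop = crop_by_name[crop_name]
        plot = plot_by_id[plot_id]
        total += (
            prices.price_by_crop[crop_name]
            * plot.crop_yield(crop_name)
            * crop.harvest_efficiency
            - economy.labor_cost_per_laborer
        ) * lab
    return total


# ---------------------------------------------------------- expected_profit


class TestExpectedProfit:
    def test_unharvested_plot_costs_its_production(self):
        """Zero labor on a planted 100-acre plot at 10,078 USD/acre loses
        exactly the production cost."""
        crop = make_crop("tomato", production=10_078.0)
        plot = PlotSpec(plot_id="p1", size_acres=100.0, yield_by_crop={"tomato": 1.0})
        unit = FarmingUnit(
            unit_id="u", strategy=Strategy(crops=("tomato",)), funds=0.0, plots=[plot]
        )
        plan = PlantingPlan(crop_by_plot=("tomato",))
        zero_labor = HarvestPlan(labor={}, harvested_mass={}, realized_cost=0.0)
        breakdown = expected_profit(
            plan, zero_labor, MarketState(price_by_crop={"tomato": 1.0}),
            unit, [crop], free_economy(),
        )
        assert breakdown.profit == pytest.approx(-1_007_800.0)
        assert breakdown.revenue == 0.0

    def test_full_harvest_revenue_is_price_times_yield_times_acres(self):
        """V * Y * h * L at L = capacity equals price x yield x acreage:
        2 USD/kg x 10,000 kg/acre x 100 acres = 2,000,000 USD."""
        crop = make_crop("tomato", requirement=0.29)
        plot = PlotSpec(
            plot_id="p1", size_acres=100.0, yield_by_crop={"tomato": 10_000.0}
        )
        unit = FarmingUnit(
            unit_id="u", strategy=Strategy(crops=("tomato",)), funds=0.0, plots=[plot]
        )
        plan = PlantingPlan(crop_by_plot=("tomato",))
        breakdown = expected_profit(
            plan, None, MarketState(price_by_crop={"tomato": 2.0}),
            unit, [crop], free_economy(),
        )
        assert breakdown.revenue == pytest.approx(2_000_000.0)
        assert breakdown.profit == pytest.approx(2_000_000.0)

    def test_empty_plan_zero_profit(self):
        crop = make_crop()
        plot = PlotSpec(plot_id="p1", size_acres=10.0, yield_by_crop={"c": 1.0})
        unit = FarmingUnit(
            unit_id="u", strategy=Strategy(crops=("c",)), funds=0.0, plots=[plot]
        )
        plan = PlantingPlan(crop_by_plot=(None,))
        breakdown = expected_profit(
            plan, None, MarketState(price_by_crop={"c": 1.0}),
            unit, [crop], free_economy(),
        )
        assert breakdown.profit == 0.0

    def test_labor_on_unplanted_plot_rejected(self):
        crop = make_crop()
        plot = PlotSpec(plot_id="p1", size_acres=10.0, yield_by_crop={"c": 1.0})
        unit = FarmingUnit(
            unit_id="u", strategy=Strategy(crops=("c",)), funds=0.0, plots=[plot]
        )
        plan = PlantingPlan(crop_by_plot=(None,))
        stray = HarvestPlan(
            labor={("c", "p1"): 1.0}, harvested_mass={}, realized_cost=0.0
        )
        with pytest.raises(InvariantError):
            expected_profit(
                plan, stray, MarketState(price_by_crop={"c": 1.0}),
                unit, [crop], free_economy(),
            )


# ------------------------------------------------------------ plan_planting


class TestPlanPlanting:
    def two_plot_unit(self, strategy_crops, yields):
        plots = [
            PlotSpec(plot_id=f"p{j + 1}", size_acres=100.0, yield_by_crop=dict(yields))
            for j in range(2)
        ]
        return FarmingUnit(
            unit_id="u", strategy=Strategy(crops=strategy_crops), funds=0.0, plots=plots
        )

    def test_single_profitable_crop_fills_all_plots_free_mode(self):
        crop = make_crop("a", production=1.0)
        unit = self.two_plot_unit(("a",), {"a": 100.0})
        plan = plan_planting(
            unit, [crop], MarketState(price_by_crop={"a": 5.0}),
            free_economy(), mode="free",
        )
        assert plan.crop_by_plot == ("a", "a")

    def test_higher_margin_crop_wins_both_plots_free_mode(self):
        crops = [make_crop("a", production=10.0), make_crop("b", production=10.0)]
        prices = MarketState(price_by_crop={"a": 5.0, "b": 1.0})
        unit = self.two_plot_unit(("a", "b"), {"a": 100.0, "b": 100.0})
        plan = plan_planting(unit, crops, prices, free_economy(), mode="free")
        assert plan.crop_by_plot == ("a", "a")
        obj = expected_profit(plan, None, prices, unit, crops, free_economy()).profit
        assert obj == pytest.approx(
            brute_force_planting(unit, crops, prices, free_economy(), "free")
        )

    def test_diversified_tie_puts_lower_indexed_crop_on_lower_plot(self):
        """Two identical plots and symmetric crops: both assignments have the
        same objective; the tie rule picks crop 0 for plot 0."""
        crops = [make_crop("a"), make_crop("b")]
        prices = MarketState(price_by_crop={"a": 2.0, "b": 2.0})
        unit = self.two_plot_unit(("a", "b"), {"a": 50.0, "b": 50.0})
        plan = plan_planting(unit, crops, prices, free_economy())
        assert plan.crop_by_plot == ("a", "b")

    def test_strategy_constrained_plants_every_plot(self):
        crops = [make_crop("a", production=1e9), make_crop("b", production=1e9)]
        prices = MarketState(price_by_crop={"a": 1.0, "b": 1.0})
        unit = self.two_plot_unit(("a", "b"), {"a": 1.0, "b": 1.0})
        plan = plan_planting(unit, crops, prices, free_economy())
        # even at a loss, the strategy-constrained case plants everything
        assert None not in plan.crop_by_plot
        assert set(plan.crop_by_plot) == {"a", "b"}

    def test_unprofitable_plots_left_fallow_in_free_mode(self):
        crops = [make_crop("a", production=1e9)]
        prices = MarketState(price_by_crop={"a": 1.0})
        unit = self.two_plot_unit(("a",), {"a": 1.0})
        plan = plan_planting(unit, crops, prices, free_economy(), mode="free")
        assert plan.crop_by_plot == (None, None)

    def test_more_strategy_crops_than_plots_is_infeasible(self):
        crops = [make_crop(n) for n in ("a", "b", "c")]
        plots = [PlotSpec(plot_id="p1", size_acres=1.0, yield_by_crop={})]
        unit = FarmingUnit(
            unit_id="u", strategy=Strategy(crops=("a", "b", "c")),
            funds=0.0, plots=plots,
        )
        with pytest.raises(InfeasibleStrategyError):
            plan_planting(
                unit, crops, MarketState(price_by_crop={n: 1.0 for n in "abc"}),
                free_economy(),
            )

    @pytest.mark.parametrize("mode", ["free", "strategy_constrained"])
    @pytest.mark.parametrize("backend", ["enumerate", "milp"])
    def test_matches_brute_force_on_random_instances(self, rng, mode, backend):
        """Optimizer objective equals exhaustive search over all feasible
        assignments on random <=3 crop x <=3 plot instances."""
        for _ in range(120):
            unit, crops, prices, economy = sample_decision_instance(rng)
            plan = plan_planting(unit, crops, prices, economy, mode=mode, backend=backend)
            obj = expected_profit(plan, None, prices, unit, crops, economy).profit
            oracle = brute_force_planting(unit, crops, prices, economy, mode)
            assert obj == pytest.approx(oracle, rel=1e-6, abs=1e-6)


# ------------------------------------------------------------- plan_harvest


class TestPlanHarvest:
    def florida_like_unit(self, crop_names=("tomato", "tomato")):
        crops = [
            make_crop("tomato", requirement=0.29),
            make_crop("strawberry", requirement=0.95),
        ]
        plots = [
            PlotSpec(
                plot_id=f"p{j + 1}",
                size_acres=100.0,
                yield_by_crop={"tomato": 15_000.0, "strawberry": 10_000.0},
            )
            for j in range(2)
        ]
        unit = FarmingUnit(
            unit_id="u",
            strategy=Strategy(crops=tuple(dict.fromkeys(crop_names))),
            funds=0.0,
            plots=plots,
        )
        unit.planting_plan = PlantingPlan(crop_by_plot=tuple(crop_names))
        return unit, crops

    def test_zero_budget_harvests_nothing(self):
        unit, crops = self.florida_like_unit()
        plan = plan_harvest(
            unit, MarketState(price_by_crop={"tomato": 1.0, "strawberry": 2.0}),
            0.0, crops, free_economy(cl=100.0),
        )
        assert plan.total_labor == 0.0
        assert plan.harvested_mass == {}

    def test_monocropped_tomato_full_harvest_needs_58_laborers(self):
        unit, crops = self.florida_like_unit(("tomato", "tomato"))
        prices = MarketState(price_by_crop={"tomato": 1.0, "strawberry": 2.0})
        plan = plan_harvest(unit, prices, 100.0, crops, free_economy(cl=100.0))
        assert plan.total_labor == pytest.approx(58.0)
        assert plan.harvested_mass["tomato"] == pytest.approx(200 * 15_000.0)

    def test_diversified_split_matches_lp(self):
        """Strawberry margin made dominant; its plot is fully staffed and the
        remainder goes to tomato. Matches the two-variable LP by hand."""
        unit, crops = self.florida_like_unit(("strawberry", "tomato"))
        prices = MarketState(price_by_crop={"tomato": 1.0, "strawberry": 10.0})
        economy = free_economy(cl=8000.0)
        budget = 95.0 + 10.0
        plan = plan_harvest(unit, prices, budget, crops, economy)
        assert plan.labor[("strawberry", "p1")] == pytest.approx(95.0)
        assert plan.labor[("tomato", "p2")] == pytest.approx(10.0)
        assert harvest_objective(plan, unit, prices, crops, economy) == pytest.approx(
            lp_harvest_objective(unit, prices, budget, crops, economy)
        )

    def test_negative_budget_rejected(self):
        unit, crops = self.florida_like_unit()
        with pytest.raises(InvariantError):
            plan_harvest(
                unit, MarketState(price_by_crop={"tomato": 1.0, "strawberry": 1.0}),
                -1.0, crops, free_economy(),
            )

    def test_no_harvesting_at_a_loss(self, rng):
        """Cells whose per-laborer value does not cover the wage get zero."""
        for _ in range(200):
            unit, crops, prices, economy = sample_decision_instance(rng)
            plan = plan_planting(unit, crops, prices, economy)
            unit.planting_plan = plan
            hp = plan_harvest(unit, prices, float(rng.uniform(0, 300)), crops, economy)
            crop_by_name = {c.name: c for c in crops}
            plot_by_id = {p.plot_id: p for p in unit.plots}
            for (crop_name, plot_id), lab in hp.labor.items():
                margin = (
                    prices.price_by_crop[crop_name]
                    * plot_by_id[plot_id].crop_yield(crop_name)
                    * crop_by_name[crop_name].harvest_efficiency
                    - economy.labor_cost_per_laborer
                )
                if margin <= 0:
                    assert lab == 0.0

    def test_matches_lp_oracle_on_random_instances(self, rng):
        for _ in range(200):
            unit, crops, prices, economy = sample_decision_instance(rng)
            unit.planting_plan = plan_planting(unit, crops, prices, economy)
            budget = float(rng.uniform(0, 400))
            hp = plan_harvest(unit, prices, budget, crops, economy)
            assert hp.total_labor <= budget + 1e-9
            obj = harvest_objective(hp, unit, prices, crops, economy)
            oracle = lp_harvest_objective(unit, prices, budget, crops, economy)
            assert obj == pytest.approx(oracle, rel=1e-6, abs=1e-6)

    def test_objective_nondecreasing_in_budget(self, rng):
        for _ in range(50):
            unit, crops, prices, economy = sample_decision_instance(rng)
            unit.planting_plan = plan_planting(unit, crops, prices, economy)
            budgets = sorted(rng.uniform(0, 400, size=4))
            objs = [
                harvest_objective(
                    plan_harvest(unit, prices, b, crops, economy),
                    unit, prices, crops, economy,
                )
                for b in budgets
            ]
            assert all(b2 >= b1 - 1e-9 for b1, b2 in zip(objs, objs[1:]))

    def test_capacity_saturation_mass_exact(self):
        """Budget above total capacity with positive margins harvests exactly
        sum(Y_ij * S_j)."""
        unit, crops = self.florida_like_unit(("strawberry", "tomato"))
        prices = MarketState(price_by_crop={"tomato": 1.0, "strawberry": 2.0})
        plan = plan_harvest(unit, prices, 1000.0, crops, free_economy(cl=10.0))
        assert plan.harvested_mass["strawberry"] == pytest.approx(100 * 10_000.0)
        assert plan.harvested_mass["tomato"] == pytest.approx(100 * 15_000.0)
        assert plan.total_labor == pytest.approx(95.0 + 29.0)
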