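"""Seeded generators of randomized-but-valid regions and decision instances.

These emulate the *structure* of the case system — a handful of crops with
negative demand elasticities, per-acre costs and labor requirements, identical
units with a few plots — with parameters drawn uniformly from configurable
ranges. They exist to drive property tests and sensitivity exploration; they
do not emulate real price or yield series.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .config import (
    CompositionConfig,
    CropConfig,
    PlotConfig,
    RegionConfig,
    RunConfig,
)
from .model import (
    CropParams,
    EconomyParams,
    FarmingUnit,
    MarketState,
    PlotSpec,
    Strategy,
)


class SyntheticSpec(BaseModel):
    """Sampling ranges for synthetic regions. All ranges are inclusive
    (lo, hi) pairs; elasticity ranges must stay strictly negative."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_crops: tuple[int, int] = (2, 3)
    n_plots: tuple[int, int] = (2, 3)
    n_diversified: tuple[int, int] = (1, 4)
    n_mono_per_crop: tuple[int, int] = (1, 5)
    elasticity: tuple[float, float] = (-1.2, -0.2)
    production_cost_per_acre: tuple[float, float] = (500.0, 15_000.0)
    labor_cost_per_acre: tuple[float, float] = (200.0, 9_000.0)
    labor_requirement_per_acre: tuple[float, float] = (0.05, 1.5)
    plot_size_acres: tuple[float, float] = (10.0, 200.0)
    mean_yield_per_acre: tuple[float, float] = (2_000.0, 30_000.0)
    mean_price: tuple[float, float] = (0.2, 5.0)
    initial_funds: tuple[float, float] = (100_000.0, 3_000_000.0)

    @model_validator(mode="after")
    def _ranges_ordered(self) -> "SyntheticSpec":
        for name, value in self.__dict__.items():
            if isinstance(value, tuple):
                lo, hi = value
                if lo > hi:
                    raise ValueError(f"{name}: range minimum exceeds maximum")
        if self.elasticity[1] >= 0:
            raise ValueError("elasticity range must be strictly negative")
        if self.n_crops[0] < 2:
            raise ValueError("need at least two crops to diversify")
        return self


def _uniform(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    return float(rng.uniform(bounds[0], bounds[1]))


def _randint(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    return int(rng.integers(bounds[0], bounds[1] + 1))


def generate_synthetic_region(spec: SyntheticSpec) -> RunConfig:
    """A reproducible random region config: same spec (and seed) -> identical
    config. Unit counts are constructed so the monocropped remainder always
    splits evenly over the crops."""
    rng = np.random.default_rng(spec.seed)
    m = _randint(rng, spec.n_crops)
    crops = [
        CropConfig(
            name=f"crop{i + 1}",
            elasticity=_uniform(rng, spec.elasticity),
            production_cost_per_acre=_uniform(rng, spec.production_cost_per_acre),
            labor_cost_per_acre=_uniform(rng, spec.labor_cost_per_acre),
            labor_requirement_per_acre=_uniform(
                rng, spec.labor_requirement_per_acre
            ),
            mean_price=_uniform(rng, spec.mean_price),
            mean_yield_per_acre=_uniform(rng, spec.mean_yield_per_acre),
        )
        for i in range(m)
    ]
    n_plots = max(_randint(rng, spec.n_plots), m)  # diversification feasible
    plots = [
        PlotConfig(size_acres=_uniform(rng, spec.plot_size_acres))
        for _ in range(n_plots)
    ]
    n_div = _randint(rng, spec.n_diversified)
    n_units = n_div + m * _randint(rng, spec.n_mono_per_crop)
    return RunConfig(
        crops=crops,
        region=RegionConfig(
            n_units=n_units,
            plots_per_unit=plots,
            initial_funds=_uniform(rng, spec.initial_funds),
        ),
        composition=CompositionConfig(n_diversified=n_div),
    )


def sample_decision_instance(
    rng: np.random.Generator,
    n_crops: tuple[int, int] = (1, 3),
    n_plots: tuple[int, int] = (1, 3),
    zero_yield_prob: float = 0.15,
) -> tuple[FarmingUnit, list[CropParams], MarketState, EconomyParams]:
    """One small random planting/harvest instance for optimizer testing.

    Yields may be exactly zero with probability ``zero_yield_prob`` per cell,
    so instances exercise unprofitable cells and fallow choices. The unit's
    strategy is a random crop subset no larger than its plot count.
    """
    m = _randint(rng, n_crops)
    n = _randint(rng, n_plots)
    crops = [
        CropParams(
            name=f"c{i}",
            elasticity=float(rng.uniform(-1.2, -0.2)),
            price_constant=1.0,
            production_cost_per_acre=float(rng.uniform(0.0, 15_000.0)),
            labor_cost_per_acre=float(rng.uniform(0.0, 9_000.0)),
            labor_requirement_per_acre=float(rng.uniform(0.05, 1.5)),
        )
        for i in range(m)
    ]
    plots = [
        PlotSpec(
            plot_id=f"p{j}",
            size_acres=float(rng.uniform(1.0, 200.0)),
            yield_by_crop={
                c.name: (
                    0.0
                    if rng.random() < zero_yield_prob
                    else float(rng.uniform(100.0, 25_000.0))
                )
                for c in crops
            },
        )
        for j in range(n)
    ]
    prices = MarketState(
        price_by_crop={c.name: float(rng.uniform(0.1, 10.0)) for c in crops}
    )
    economy = EconomyParams(
        labor_cost_per_laborer=float(rng.uniform(0.0, 20_000.0)),
        price_floor_harvest=1.0,
    )
    k = int(rng.integers(1, min(m, n) + 1))
    chosen = sorted(rng.choice(m, size=k, replace=False).tolist())
    strategy = Strategy(crops=tuple(crops[i].name for i in chosen))
    unit = FarmingUnit(
        unit_id="u0", strategy=strategy, funds=0.0, plots=plots
    )
    return unit, crops, prices, economy
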