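"""Core domain types and market economics.

A *region* holds N farming units. Each unit owns a fixed set of plots and a
cropping strategy (monocropped on one crop, or diversified over two or more).
Units interact only through crop market prices, which respond to the regional
aggregate harvest via a constant-elasticity demand curve

    V_t = a * Y_t ** epsilon,    epsilon < 0,

where ``Y_t`` is the total mass of a crop harvested by all units in season t
and ``a`` is a constant calibrated so that the curve passes through a
historical (mean price, mean yield) point.

All quantities are kept in fixed internal units: USD, acres, kg, and
laborer-seasons. A "laborer" is the amount of labor one worker supplies over
one harvest season.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class CropShockError(Exception):
    """Base class for errors raised by this package."""


class CalibrationError(CropShockError, ValueError):
    """Invalid inputs to a price-curve calibration."""


class InvariantError(CropShockError, ValueError):
    """A domain-type invariant was violated."""


@dataclass(frozen=True)
class CropParams:
    """Economic parameters of one crop.

    Parameters
    ----------
    name:
        Crop label, unique within a region.
    elasticity:
        Demand elasticity (exponent of the price curve); strictly negative.
    price_constant:
        Calibration constant ``a`` of the price curve, in units such that the
        price is USD/kg when the aggregate harvest is in kg.
    production_cost_per_acre:
        Non-labor production cost (transplants, fertilizer, equipment, ...),
        USD per acre; incurred for every planted acre whether or not it is
        harvested.
    labor_cost_per_acre:
        Harvest labor cost, USD per acre at full harvest; used only to derive
        the per-laborer labor cost, see :func:`derive_labor_cost`.
    labor_requirement_per_acre:
        Laborers needed to fully harvest one acre in one season.
    """

    name: str
    elasticity: float
    price_constant: float
    production_cost_per_acre: float
    labor_cost_per_acre: float
    labor_requirement_per_acre: float

    def __post_init__(self) -> None:
        if not self.elasticity < 0:
            raise InvariantError(
                f"crop {self.name!r}: elasticity must be < 0, got {self.elasticity}"
            )
        if not self.price_constant > 0:
            raise InvariantError(
                f"crop {self.name!r}: price_constant must be > 0, got {self.price_constant}"
            )
        if self.production_cost_per_acre < 0 or self.labor_cost_per_acre < 0:
            raise InvariantError(f"crop {self.name!r}: costs must be >= 0")
        if not self.labor_requirement_per_acre > 0:
            raise InvariantError(
                f"crop {self.name!r}: labor_requirement_per_acre must be > 0"
            )

    @property
    def harvest_efficiency(self) -> float:
        """Acres one laborer can harvest in a season (h_i), the reciprocal of
        the per-acre labor requirement."""
        return 1.0 / self.labor_requirement_per_acre


@dataclass(frozen=True)
class EconomyParams:
    """Economy-wide parameters shared by all units.

    ``labor_cost_per_laborer`` is the seasonal wage C_L (USD per laborer per
    season). ``price_floor_harvest`` (kg) is the smallest aggregate harvest at
    which the price curve is evaluated; it keeps the constant-elasticity curve
    finite when nothing is harvested.
    """

    labor_cost_per_laborer: float
    price_floor_harvest: float

    def __post_init__(self) -> None:
        if self.labor_cost_per_laborer < 0:
            raise InvariantError("labor_cost_per_laborer must be >= 0")
        if not self.price_floor_harvest > 0:
            raise InvariantError("price_floor_harvest must be > 0")


@dataclass(frozen=True)
class PlotSpec:
    """One indivisible land parcel of ``size_acres`` acres (S_j).

    ``yield_by_crop`` maps crop name to the plot's yield for that crop
    (Y_ij, kg/acre). A crop absent from the map yields zero on the plot.
    """

    plot_id: str
    size_acres: float
    yield_by_crop: dict[str, float]

    def __post_init__(self) -> None:
        if not self.size_acres > 0:
            raise InvariantError(f"plot {self.plot_id!r}: size_acres must be > 0")
        for crop, y in self.yield_by_crop.items():
            if y < 0:
                raise InvariantError(
                    f"plot {self.plot_id!r}: yield for {crop!r} must be >= 0"
                )

    def crop_yield(self, crop_name: str) -> float:
        return self.yield_by_crop.get(crop_name, 0.0)


@dataclass(frozen=True)
class Strategy:
    """A unit's fixed cropping strategy: the set of crops it commits to.

    One crop means "monocropped"; two or more means "diversified". Strategies
    are constant over a simulation.
    """

    crops: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.crops) == 0:
            raise InvariantError("strategy must name at least one crop")
        if len(set(self.crops)) != len(self.crops):
            raise InvariantError("strategy crops must be distinct")

    @property
    def kind(self) -> str:
        return "monocropped" if len(self.crops) == 1 else "diversified"

    @property
    def label(self) -> str:
        """Aggregation label: the crop name for monocropped units,
        ``"diversified"`` otherwise."""
        return self.crops[0] if len(self.crops) == 1 else "diversified"


@dataclass
class FarmingUnit:
    """The simulated agent: a farm with plots, funds and a strategy."""

    unit_id: str
    strategy: Strategy
    funds: float
    plots: list[PlotSpec]
    planting_plan: object | None = None  # decisions.PlantingPlan
    labor_share: float = 0.0
    exited: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.funds):
            raise InvariantError(f"unit {self.unit_id!r}: funds must be finite")
        if not self.plots:
            raise InvariantError(f"unit {self.unit_id!r}: needs at least one plot")

    @property
    def total_acres(self) -> float:
        return sum(p.size_acres for p in self.plots)


@dataclass
class MarketState:
    """Current market prices (V_t, USD/kg) and the previous season's regional
    harvest (Y_t, kg) per crop."""

    price_by_crop: dict[str, float]
    last_total_harvest_by_crop: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for crop, v in self.price_by_crop.items():
            if not v > 0:
                raise InvariantError(f"price for {crop!r} must be > 0, got {v}")
        for crop, y in self.last_total_harvest_by_crop.items():
            if y < 0:
                raise InvariantError(f"harvest for {crop!r} must be >= 0")


@dataclass(frozen=True)
class ShockSchedule:
    """A labor shock: only fraction ``intensity`` of baseline labor is
    available for ``duration`` consecutive seasons starting at
    ``start_season``."""

    intensity: float
    duration: int
    start_season: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.intensity <= 1.0:
            raise InvariantError(f"intensity must be in [0, 1], got {self.intensity}")
        if self.duration < 1:
            raise InvariantError(f"duration must be >= 1, got {self.duration}")
        if self.start_season < 1:
            raise InvariantError(f"start_season must be >= 1, got {self.start_season}")


@dataclass
class RegionState:
    """The full mutable state of a simulated region."""

    units: list[FarmingUnit]
    crops: list[CropParams]
    economy: EconomyParams
    market: MarketState
    baseline_labor_total: float
    season: int = 0
    labor_split: str = "equal-per-unit"

    def __post_init__(self) -> None:
        if not self.baseline_labor_total > 0:
            raise InvariantError("baseline_labor_total must be > 0")
        if self.season < 0:
            raise InvariantError("season must be >= 0")
        names = [c.name for c in self.crops]
        if len(set(names)) != len(names):
            raise InvariantError("crop names must be unique")

    @property
    def crop_by_name(self) -> dict[str, CropParams]:
        return {c.name: c for c in self.crops}

    @property
    def active_units(self) -> list[FarmingUnit]:
        return [u for u in self.units if not u.exited]


def derive_price_constant(
    mean_price: float, mean_yield: float, elasticity: float
) -> float:
    """Calibrate the price-curve constant ``a`` from a historical mean.

    Solves ``mean_price = a * mean_yield ** elasticity`` for ``a``, so that the
    demand curve passes through the observed (mean_yield, mean_price) point.

    Raises
    ------
    CalibrationError
        If ``mean_price`` or ``mean_yield`` is not strictly positive.
    """
    if not mean_price > 0:
        raise CalibrationError(f"mean_price must be > 0, got {mean_price}")
    if not mean_yield > 0:
        raise CalibrationError(f"mean_yield must be > 0, got {mean_yield}")
    return mean_price / mean_yield**elasticity


def update_market_price(
    crop: CropParams, total_harvest: float, economy: EconomyParams
) -> float:
    """End-of-season market price for ``crop`` given the regional harvest.

    Evaluates ``a * Y ** epsilon`` with ``Y`` clamped from below at the
    economy's price floor harvest, so a zero harvest yields a finite (high)
    price instead of a divergence. Strictly decreasing in ``total_harvest``
    above the floor.
    """
    if total_harvest < 0:
        raise InvariantError(f"total_harvest must be >= 0, got {total_harvest}")
    y = max(total_harvest, economy.price_floor_harvest)
    return crop.price_constant * y**crop.elasticity


def derive_labor_cost(
    labor_cost_per_acre: float, labor_requirement_per_acre: float
) -> float:
    """Convert a per-acre harvest labor cost into the per-laborer wage C_L.

    One acre takes ``labor_requirement_per_acre`` laborers to harvest, so the
    cost of one laborer-season is the per-acre cost divided by the per-acre
    requirement.
    """
    if not labor_requirement_per_acre > 0:
        raise CalibrationError(
            f"labor_requirement_per_acre must be > 0, got {labor_requirement_per_acre}"
        )
    return labor_cost_per_acre / labor_requirement_per_acre


def harvest_capacity(plot: PlotSpec, crop: CropParams) -> float:
    """Laborers needed to fully harvest ``plot`` when planted with ``crop``:
    the upper bound on labor usefully assigned to the (crop, plot) cell."""
    return plot.size_acres * crop.labor_requirement_per_acre
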