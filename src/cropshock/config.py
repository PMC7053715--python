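"""Run configuration: schema, validation, YAML round-trip, the packaged
Florida strawberry/tomato case, and the price/yield CSV calibration loader.

Internal units are fixed (USD, acres, kg, laborer-seasons). Rates quoted per
100 acres in source tables are normalized to per-acre values here, at the
boundary.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .model import derive_labor_cost


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CropConfig(_StrictModel):
    """One crop's economics plus its calibration point.

    ``mean_price`` (USD/kg) and ``mean_yield_per_acre`` (kg/acre) are the
    historical means through which the demand curve is calibrated; the curve
    constant itself is derived at region-composition time against the region's
    expected harvest at that yield.
    """

    name: str
    elasticity: float = Field(lt=0)
    production_cost_per_acre: float = Field(ge=0)
    labor_cost_per_acre: float = Field(ge=0)
    labor_requirement_per_acre: float = Field(gt=0)
    mean_price: float = Field(gt=0)
    mean_yield_per_acre: float = Field(gt=0)


class PlotConfig(_StrictModel):
    size_acres: float = Field(gt=0)
    # crop name -> kg/acre; None means each crop yields its calibration mean
    yield_by_crop: dict[str, float] | None = None


class EconomyConfig(_StrictModel):
    # None -> mean of the per-crop derivations labor_cost_per_acre / requirement
    labor_cost_per_laborer: float | None = Field(default=None, ge=0)
    # price floor as a fraction of the smallest crop's calibration harvest
    price_floor_fraction: float = Field(default=0.01, gt=0, le=1)


class RegionConfig(_StrictModel):
    n_units: int = Field(default=30, ge=1)
    plots_per_unit: list[PlotConfig]
    initial_funds: float

    @field_validator("plots_per_unit")
    @classmethod
    def _nonempty(cls, v: list[PlotConfig]) -> list[PlotConfig]:
        if not v:
            raise ValueError("plots_per_unit must not be empty")
        return v


class CompositionConfig(_StrictModel):
    n_diversified: int = Field(default=2, ge=0)
    # crops a diversified unit grows (None -> all configured crops)
    diversified_crops: list[str] | None = None
    # crops over which monocropped units are split evenly (None -> all)
    mono_crops: list[str] | None = None


class ShockConfig(_StrictModel):
    intensity: float = Field(ge=0, le=1)
    duration: int = Field(ge=1)
    start_season: int = Field(default=1, ge=1)


class SweepGridConfig(_StrictModel):
    """The shock-sweep experiment grid: region compositions crossed with
    shock intensities and durations."""

    diversified_counts: list[int] = Field(
        default_factory=lambda: list(range(2, 29, 2))
    )
    intensity_grid: list[float] = Field(
        default_factory=lambda: [round(0.1 * k, 1) for k in range(1, 11)]
    )
    duration_grid: list[int] = Field(default_factory=lambda: list(range(1, 11)))
    include_zero_intensity: bool = False

    @field_validator("intensity_grid")
    @classmethod
    def _valid_intensities(cls, v: list[float]) -> list[float]:
        if not v or any(not 0 <= x <= 1 for x in v):
            raise ValueError("intensity_grid values must be in [0, 1]")
        return v

    @field_validator("duration_grid")
    @classmethod
    def _valid_durations(cls, v: list[int]) -> list[int]:
        if not v or any(d < 1 for d in v):
            raise ValueError("duration_grid values must be >= 1")
        return v

    def intensities(self) -> list[float]:
        grid = list(self.intensity_grid)
        if self.include_zero_intensity and 0.0 not in grid:
            grid = [0.0] + grid
        return grid


class ModeConfig(_StrictModel):
    strategy_constrained: bool = True
    backend: str = Field(default="enumerate", pattern="^(enumerate|milp)$")
    # funds level below which a unit exits production; None disables the hook
    exit_floor: float | None = None


class RunConfig(_StrictModel):
    """Everything needed to build a region and run simulations or sweeps."""

    schema_version: str = "1"
    crops: list[CropConfig]
    economy: EconomyConfig = Field(default_factory=EconomyConfig)
    region: RegionConfig
    composition: CompositionConfig = Field(default_factory=CompositionConfig)
    shock: ShockConfig | None = None
    sweep: SweepGridConfig = Field(default_factory=SweepGridConfig)
    mode: ModeConfig = Field(default_factory=ModeConfig)

    @model_validator(mode="after")
    def _cross_checks(self) -> "RunConfig":
        names = [c.name for c in self.crops]
        if len(set(names)) != len(names):
            raise ValueError("crop names must be unique")
        for group_name in ("diversified_crops", "mono_crops"):
            group = getattr(self.composition, group_name)
            if group is not None:
                unknown = set(group) - set(names)
                if unknown:
                    raise ValueError(f"{group_name} names unknown crops: {sorted(unknown)}")
        for plot in self.region.plots_per_unit:
            if plot.yield_by_crop is not None:
                unknown = set(plot.yield_by_crop) - set(names)
                if unknown:
                    raise ValueError(f"plot yields name unknown crops: {sorted(unknown)}")
        return self

    # -- convenience ------------------------------------------------------

    def crop(self, name: str) -> CropConfig:
        for c in self.crops:
            if c.name == name:
                return c
        raise KeyError(name)

    def labor_cost_per_laborer(self) -> float:
        """Economy-wide wage C_L: the configured value, or the mean of the
        per-crop derivations from per-acre labor cost and requirement."""
        if self.economy.labor_cost_per_laborer is not None:
            return self.economy.labor_cost_per_laborer
        derived = [
            derive_labor_cost(c.labor_cost_per_acre, c.labor_requirement_per_acre)
            for c in self.crops
        ]
        return sum(derived) / len(derived)

    def fingerprint(self) -> str:
        """Stable digest of the config, embedded in outputs for provenance."""
        payload = self.model_dump_json()
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    import yaml

    data = json.loads(config.model_dump_json())
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def florida_fixture() -> RunConfig:
    """The packaged Florida strawberry/tomato case.

    Cost, elasticity and labor-requirement rows follow published Florida
    production statistics; per-100-acre labor requirements are normalized to
    per-acre. The ``mean_price`` / ``mean_yield_per_acre`` pairs are
    *calibration placeholders*: round values consistent with Florida revenue
    statistics of the 2000s — strawberries ≈ $21,000/acre against ≈ $20,000
    of per-acre costs (a high-price, labor-intensive crop with thin margins),
    fresh tomatoes ≈ $15,000/acre against ≈ $12,500 (a cheaper crop with a
    sturdier margin). Replace them with series means from a price/yield CSV
    (see :func:`load_price_yield_csv`) to recalibrate.
    """
    return RunConfig(
        crops=[
            CropConfig(
                name="tomato",
                elasticity=-0.58,
                production_cost_per_acre=10_078.0,
                labor_cost_per_acre=2_408.0,
                labor_requirement_per_acre=0.29,  # 29 people per 100 acres
                mean_price=1.00,
                mean_yield_per_acre=15_000.0,
            ),
            CropConfig(
                name="strawberry",
                elasticity=-0.66,
                production_cost_per_acre=12_305.0,
                labor_cost_per_acre=7_788.0,
                labor_requirement_per_acre=0.95,  # 95 people per 100 acres
                mean_price=2.10,
                mean_yield_per_acre=10_000.0,
            ),
        ],
        region=RegionConfig(
            n_units=30,
            plots_per_unit=[
                PlotConfig(size_acres=100.0),
                PlotConfig(size_acres=100.0),
            ],
            initial_funds=1_871_571.0,
        ),
    )


def load_price_yield_csv(path: str | Path) -> tuple[float, float]:
    """Arithmetic mean (price, yield) from an annual series CSV.

    The file must have ``year``, ``price`` and ``yield`` columns (price in
    USD/kg, yield in kg); extra columns are ignored, row order is irrelevant.
    """
    frame = pd.read_csv(path)
    missing = {"year", "price", "yield"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    for col in ("price", "yield"):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        if numeric.isna().any():
            bad = frame.index[numeric.isna()][0]
            raise ValueError(f"{path}: non-numeric {col!r} in row {bad}")
        frame[col] = numeric
    return float(frame["price"].mean()), float(frame["yield"].mean())
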