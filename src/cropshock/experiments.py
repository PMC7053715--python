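"""Shock-sweep experiments: region composition, the (intensity, duration,
n_diversified) grid, robustness summaries, advantage fractions and crossover
intensities.

A sweep runs one deterministic simulation per grid point. Robustness is the
mean end-of-run funds of the units employing each strategy; the advantage
analysis asks, cell by cell, for what share of shock durations the diversified
units out-earn the monocropped ones, and at what shock intensity that
advantage first appears.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import RunConfig
from .model import (
    CropParams,
    CropShockError,
    EconomyParams,
    FarmingUnit,
    MarketState,
    PlotSpec,
    RegionState,
    ShockSchedule,
    Strategy,
    derive_price_constant,
)
from .simulate import run_simulation


class CompositionError(CropShockError, ValueError):
    """The requested strategy mix cannot be split over the units."""


DIVERSIFIED_LABEL = "diversified"


def _build_crop_params(
    config: RunConfig, expected_acres: dict[str, float], total_acres: float
) -> list[CropParams]:
    """Crop parameter sets with demand curves calibrated to the region.

    The curve constant is chosen so that the price at the region's expected
    full harvest of a crop (calibration yield per acre times the acreage that
    crop occupies under the baseline composition) equals the crop's historical
    mean price. A crop no strategy plants is scaled by the whole region's
    acreage instead, so its curve is still well defined.
    """
    params = []
    for crop in config.crops:
        acres = expected_acres.get(crop.name, 0.0)
        if acres <= 0:
            acres = total_acres
        calibration_harvest = crop.mean_yield_per_acre * acres
        a = derive_price_constant(
            crop.mean_price, calibration_harvest, crop.elasticity
        )
        params.append(
            CropParams(
                name=crop.name,
                elasticity=crop.elasticity,
                price_constant=a,
                production_cost_per_acre=crop.production_cost_per_acre,
                labor_cost_per_acre=crop.labor_cost_per_acre,
                labor_requirement_per_acre=crop.labor_requirement_per_acre,
            )
        )
    return params


def compose_region(
    n_units: int,
    n_diversified: int,
    template: RunConfig,
) -> RegionState:
    """Build a region of ``n_units`` otherwise-identical units in which
    ``n_diversified`` diversify and the remainder are split evenly between the
    monocrop strategies.

    Raises
    ------
    CompositionError
        If the monocropped remainder does not divide evenly between the
        monocrop strategies.
    """
    crop_names = [c.name for c in template.crops]
    div_crops = tuple(template.composition.diversified_crops or crop_names)
    mono_crops = list(template.composition.mono_crops or crop_names)
    if n_diversified > n_units or (n_diversified > 0 and len(div_crops) < 2):
        raise CompositionError(
            f"cannot place {n_diversified} diversified units over {div_crops}"
        )
    n_mono = n_units - n_diversified
    if n_mono % len(mono_crops) != 0:
        raise CompositionError(
            f"{n_mono} monocropped units do not split evenly over "
            f"{len(mono_crops)} monocrop strategies"
        )
    per_mono = n_mono // len(mono_crops)

    strategies = [Strategy(crops=div_crops)] * n_diversified
    for crop_name in mono_crops:
        strategies += [Strategy(crops=(crop_name,))] * per_mono

    plots = [
        PlotSpec(
            plot_id=f"p{j + 1}",
            size_acres=p.size_acres,
            yield_by_crop=(
                dict(p.yield_by_crop)
                if p.yield_by_crop is not None
                else {c.name: c.mean_yield_per_acre for c in template.crops}
            ),
        )
        for j, p in enumerate(template.region.plots_per_unit)
    ]
    unit_acres = sum(p.size_acres for p in plots)
    total_acres = unit_acres * n_units

    # acreage each crop occupies at the baseline composition: every unit
    # splits its land evenly over its strategy crops
    expected_acres: dict[str, float] = {}
    for strat in strategies:
        for crop_name in strat.crops:
            expected_acres[crop_name] = (
                expected_acres.get(crop_name, 0.0) + unit_acres / len(strat.crops)
            )

    crops = _build_crop_params(template, expected_acres, total_acres)
    crop_by_name = {c.name: c for c in template.crops}
    floor = template.economy.price_floor_fraction * min(
        crop_by_name[name].mean_yield_per_acre * acres
        for name, acres in expected_acres.items()
        if acres > 0
    )
    economy = EconomyParams(
        labor_cost_per_laborer=template.labor_cost_per_laborer(),
        price_floor_harvest=floor,
    )

    counters: dict[str, int] = {}
    units = []
    for strat in strategies:
        label = strat.label
        counters[label] = counters.get(label, 0) + 1
        units.append(
            FarmingUnit(
                unit_id=f"{label}-{counters[label]:02d}",
                strategy=strat,
                funds=template.region.initial_funds,
                plots=list(plots),
            )
        )

    market = MarketState(
        price_by_crop={c.name: c.mean_price for c in template.crops}
    )
    max_req = max(c.labor_requirement_per_acre for c in crops)
    return RegionState(
        units=units,
        crops=crops,
        economy=economy,
        market=market,
        baseline_labor_total=max_req * total_acres,
    )


@dataclass(frozen=True)
class SweepResult:
    """One row per (n_diversified, intensity, duration) grid point, with the
    mean end-of-run funds and unit count of each strategy group."""

    table: pd.DataFrame
    strategy_labels: tuple[str, ...]
    config_fingerprint: str


def run_sweep(config: RunConfig) -> SweepResult:
    """Run the full experiment grid defined by ``config.sweep``.

    Each grid point runs a fresh region for ``duration + 1`` seasons under a
    shock starting in season 1. Deterministic: rerunning yields an identical
    table.
    """
    grid = config.sweep
    mode = "strategy_constrained" if config.mode.strategy_constrained else "free"
    fingerprint = config.fingerprint()
    start = config.shock.start_season if config.shock is not None else 1

    rows = []
    labels: tuple[str, ...] | None = None
    for n_div in grid.diversified_counts:
        for intensity in grid.intensities():
            for duration in grid.duration_grid:
                try:
                    region = compose_region(
                        config.region.n_units, n_div, config
                    )
                    trajectory = run_simulation(
                        region,
                        ShockSchedule(
                            intensity=intensity,
                            duration=duration,
                            start_season=start,
                        ),
                        tau=duration + 1,
                        mode=mode,
                        backend=config.mode.backend,
                        exit_floor=config.mode.exit_floor,
                        config_fingerprint=fingerprint,
                    )
                except CropShockError as err:
                    raise CropShockError(
                        f"sweep failed at grid point (n_diversified={n_div}, "
                        f"i={intensity}, d={duration}): {err}"
                    ) from err
                final = trajectory.outcomes[-1].unit_outcomes
                funds: dict[str, list[float]] = {}
                for u in final:
                    funds.setdefault(u.strategy_label, []).append(u.funds_after)
                if labels is None:
                    labels = tuple(sorted(funds))
                row = {
                    "n_diversified": n_div,
                    "intensity": intensity,
                    "duration": duration,
                }
                for label in labels:
                    group = funds.get(label, [])
                    row[f"mean_funds_{label}"] = (
                        sum(group) / len(group) if group else float("nan")
                    )
                    row[f"count_{label}"] = len(group)
                rows.append(row)
    assert labels is not None
    return SweepResult(
        table=pd.DataFrame(rows),
        strategy_labels=labels,
        config_fingerprint=fingerprint,
    )


def robustness_summary(
    result: SweepResult, selector: dict[str, object] | None = None
) -> pd.Series:
    """Mean end-of-run funds per strategy over a slice of the sweep table.

    ``selector`` maps grid columns (``n_diversified``, ``intensity``,
    ``duration``) to a value or list of values; ``None`` averages everything.
    """
    table = result.table
    if selector:
        for col, wanted in selector.items():
            values = wanted if isinstance(wanted, (list, tuple, set)) else [wanted]
            table = table[table[col].isin(values)]
    if table.empty:
        raise CropShockError("robustness_summary: slice selects no grid points")
    return pd.Series(
        {
            label: table[f"mean_funds_{label}"].mean()
            for label in result.strategy_labels
        }
    )


def regional_wealth_spread(result: SweepResult) -> pd.DataFrame:
    """Relative spread of mean regional wealth across diversified counts.

    For each (intensity, duration), the all-unit mean funds is computed per
    diversified count; the spread is (max - min) / |mean| over counts.
    """
    table = result.table.copy()
    count_cols = [f"count_{label}" for label in result.strategy_labels]
    total_units = table[count_cols].sum(axis=1)
    wealth = sum(
        table[f"mean_funds_{label}"] * table[f"count_{label}"]
        for label in result.strategy_labels
    )
    table["regional_mean_funds"] = wealth / total_units
    rows = []
    for (intensity, duration), group in table.groupby(["intensity", "duration"]):
        vals = group["regional_mean_funds"]
        mean = vals.mean()
        spread = (vals.max() - vals.min()) / abs(mean) if mean != 0 else float("inf")
        rows.append(
            {
                "intensity": intensity,
                "duration": duration,
                "regional_mean_funds": mean,
                "relative_spread": spread,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AdvantageReport:
    """Where, on the experiment grid, diversification pays.

    ``cell_table``: per (n_diversified, intensity), the percentage of shock
    durations for which diversified mean funds exceed each monocrop group's
    (columns ``pct_gt_<label>``) and all of them (``pct_gt_all_mono``).

    ``thresholds_by_count``: per n_diversified, the crossover intensity for
    each comparison — the largest grid intensity at which the advantage still
    fails for some duration (0.0 when the advantage holds on the whole grid,
    the grid maximum when it fails even there). When the advantage region is
    contiguous from the top of the grid this matches the reading "diversified
    units are more robust for i > threshold".

    ``aggregate_means``: mean funds per strategy by intensity, averaged over
    durations and diversified counts (the summary-curve view).

    ``aggregate_thresholds``: crossover intensities computed from the
    aggregate curves, keyed by monocrop label plus ``"all_mono"``.

    ``aggregate_onsets``: the smallest grid intensity at which each aggregate
    advantage first appears (the "began to have an advantage" reading; the
    advantage may close again at higher intensities). ``inf`` when the
    advantage never appears.
    """

    cell_table: pd.DataFrame
    thresholds_by_count: pd.DataFrame
    aggregate_means: pd.DataFrame
    aggregate_thresholds: dict[str, float]
    aggregate_onsets: dict[str, float]


def _crossover(intensities: list[float], holds: dict[float, bool]) -> float:
    failing = [i for i in intensities if not holds[i]]
    return max(failing) if failing else 0.0


def _onset(intensities: list[float], holds: dict[float, bool]) -> float:
    holding = [i for i in intensities if holds[i]]
    return min(holding) if holding else float("inf")


def advantage_analysis(result: SweepResult) -> AdvantageReport:
    """Advantage fractions and crossover intensities for diversified units."""
    if DIVERSIFIED_LABEL not in result.strategy_labels:
        raise CropShockError("sweep has no diversified units to analyze")
    mono_labels = [l for l in result.strategy_labels if l != DIVERSIFIED_LABEL]
    table = result.table
    intensities = sorted(table["intensity"].unique())

    cell_rows = []
    holds_all: dict[tuple[int, str], dict[float, bool]] = {}
    for (n_div, intensity), group in table.groupby(["n_diversified", "intensity"]):
        div = group[f"mean_funds_{DIVERSIFIED_LABEL}"]
        row = {"n_diversified": n_div, "intensity": intensity}
        gt_each = {}
        for label in mono_labels:
            gt = div > group[f"mean_funds_{label}"]
            gt_each[label] = gt
            row[f"pct_gt_{label}"] = 100.0 * gt.mean()
            holds_all.setdefault((n_div, label), {})[intensity] = bool(gt.all())
        gt_all = pd.concat(gt_each, axis=1).all(axis=1)
        row["pct_gt_all_mono"] = 100.0 * gt_all.mean()
        holds_all.setdefault((n_div, "all_mono"), {})[intensity] = bool(gt_all.all())
        cell_rows.append(row)
    cell_table = pd.DataFrame(cell_rows)

    threshold_rows = []
    for n_div in sorted(table["n_diversified"].unique()):
        row = {"n_diversified": n_div}
        for key in mono_labels + ["all_mono"]:
            row[f"threshold_vs_{key}"] = _crossover(
                intensities, holds_all[(n_div, key)]
            )
        threshold_rows.append(row)
    thresholds_by_count = pd.DataFrame(threshold_rows)

    agg = (
        table.groupby("intensity")[
            [f"mean_funds_{label}" for label in result.strategy_labels]
        ]
        .mean()
        .reset_index()
    )
    aggregate_thresholds = {}
    aggregate_onsets = {}
    div_curve = agg[f"mean_funds_{DIVERSIFIED_LABEL}"]
    holds_each = {}
    for label in mono_labels:
        gt = (div_curve > agg[f"mean_funds_{label}"]).tolist()
        holds_each[label] = gt
        by_i = dict(zip(agg["intensity"], gt))
        aggregate_thresholds[label] = _crossover(intensities, by_i)
        aggregate_onsets[label] = _onset(intensities, by_i)
    gt_all = [all(h[k] for h in holds_each.values()) for k in range(len(agg))]
    by_i = dict(zip(agg["intensity"], gt_all))
    aggregate_thresholds["all_mono"] = _crossover(intensities, by_i)
    aggregate_onsets["all_mono"] = _onset(intensities, by_i)
    return AdvantageReport(
        cell_table=cell_table,
        thresholds_by_count=thresholds_by_count,
        aggregate_means=agg,
        aggregate_thresholds=aggregate_thresholds,
        aggregate_onsets=aggregate_onsets,
    )
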