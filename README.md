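# cropshock

A farm- and regional-scale simulator for asking when **crop diversification
makes farms robust to labor shortages**. It targets production systems of
high-value, hand-harvested crops — the packaged case is a stylized Florida
region growing strawberries (high price, 0.95 laborers/acre to harvest) and
fresh-market tomatoes (lower price, 0.29 laborers/acre) — where the binding
constraint in a bad season is not land or weather but people to pick the crop.

It is written for agricultural-systems modelers and extension economists who
want a transparent, fully deterministic testbed rather than a black-box
econometric model.

## The model

A region holds *N* identical farming units; each owns *P* plots of
S<sub>1</sub>, …, S<sub>P</sub> acres and a fixed strategy: *monocropped* (one
crop on every plot) or *diversified* (one strategy crop per plot). A season
runs planting → harvest → price formation → funds update.

**Prices.** Units interact only through a constant-elasticity demand curve per
crop: V<sub>t</sub> = a · Y<sub>t</sub><sup>ε</sup> (ε < 0), where
Y<sub>t</sub> is the regional aggregate harvest and *a* is calibrated so the
curve passes through a historical (mean yield, mean price) point. Prices from
season *t* act as expected prices for decisions in season *t + 1*; realized
revenue is booked at the price the region's own harvest produces.

**Planting** maximizes expected profit
Ψ(x) = Σ<sub>ij</sub> (V<sub>i</sub>Y<sub>ij</sub>h<sub>i</sub>L<sub>ij</sub> −
C<sub>L</sub>L<sub>ij</sub> − a<sub>ij</sub>) x<sub>ij</sub>
over the binary crop-to-plot assignment x<sub>ij</sub> (at most one crop per
plot), with h<sub>i</sub> the harvest efficiency (acres/laborer),
C<sub>L</sub> the seasonal wage and a<sub>ij</sub> the non-labor production
cost, assuming full-harvest labor L<sub>ij</sub> = S<sub>j</sub>/h<sub>i</sub>.

**Harvest** allocates the unit's equal share of the season's labor across its
planted cells, maximizing Σ (V<sub>i</sub>Y<sub>ij</sub>h<sub>i</sub> −
C<sub>L</sub>) L<sub>ij</sub> under the budget and per-cell capacities —
partial harvests are allowed, unprofitable ones are not taken.

**Shocks.** Baseline regional labor is sized so the most labor-intensive crop
could be fully harvested everywhere (0.95 × 6,000 acres = 5,700 laborers in
the Florida case). A shock makes only a fraction *i* of it available for *d*
consecutive seasons; runs last τ = d + 1 seasons. Robustness of a strategy is
the mean end-of-run funds of the units using it.

## Worked example

One no-shock run of the packaged Florida case (30 units, 2 diversified,
14 strawberry, 14 tomato; two 100-acre plots each; initial funds $1,871,571):

```bash
$ cropshock run --florida --out out/
{
  "config_fingerprint": "36517d251a5413f5",
  "seasons": 10,
  "final_mean_funds_by_strategy": {
    "diversified": 5257738.332123416,
    "strawberry": 3585295.1379310377,
    "tomato": 6930181.5263157915
  }
}
```

With full labor the region sits at the calibration fixed point: prices stay at
the calibration means and every unit gains its full-harvest profit each season
— $171,372/season for strawberry monocroppers (thin margins on a high-price
crop), $505,861 for tomato, and the average, $338,617, for diversified units.

Under a 6-season shock at 40% labor the ordering changes — strawberry
monocroppers can pick only a fraction of their crop while diversified units
finish their tomato plot first and put the rest into strawberries:

```bash
$ cropshock run --config shock.yaml --out out/   # shock: i=0.4, d=6
{
  "final_mean_funds_by_strategy": {
    "diversified": 5313303.137887775,
    "strawberry": 1779250.8766725268,
    "tomato": 5412598.3684210535
  }
}
```

The full experiment — 14 region compositions (2–28 diversified units) ×
10 intensities × 10 durations — and its advantage analysis:

```bash
$ cropshock sweep --florida --out out/
{
  "strawberry": 0.2,
  "tomato": 1.0,
  "all_mono": 1.0
}
```

The printed numbers are crossover intensities from the aggregated funds
curves: diversified units out-earn strawberry monocroppers at every shock
intensity above 0.2; against tomato monocroppers their advantage opens at
i = 0.5 but closes again near full labor (so no top-contiguous crossover
exists and 1.0 is reported). `out/advantage.json` holds the per-composition
thresholds, onset intensities and the regional-wealth spread;
`cropshock report --plot` renders the funds-versus-intensity curves and the
advantage grid.

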