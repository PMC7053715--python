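# Methods

## Model structure

The simulated world is a region of `N` farming units that differ only in
their cropping strategy. Time advances in seasons; one season is: every unit
allocates crops to plots (planting), allocates its labor share (harvest), the
regional aggregate harvest sets end-of-season prices, and each unit books the
season's profit into its funds. All state is explicit and every step is
deterministic, so identical configurations give bit-identical trajectories.

### Price formation

Each crop has a constant-elasticity inverse demand curve

    V_t = a * Y_t ** eps,    eps < 0,

with `Y_t` the regional harvest (kg) and `V_t` the price (USD/kg). The
constant `a` is derived from a historical mean point: `a = V̄ / Ȳ**eps`, so
the curve passes through (Ȳ, V̄). The calibration scale is the *simulated
region's* expected harvest — calibration yield per acre times the acreage the
crop occupies under the baseline composition — which makes the model
self-consistent at any region size: with full labor the region reproduces the
mean prices exactly, season after season (the calibration fixed point, tested
to 1e-9 relative).

Because `Y**eps` diverges as `Y → 0`, the curve is evaluated at
`max(Y, floor)`; the floor defaults to 1% of the smallest crop's calibration
harvest. In the two-crop case the floor only binds when a crop is (almost)
entirely abandoned for a season.

With the two case crops the balanced composition always allocates the same
total acreage (3,000 acres) to each crop regardless of how many units
diversify, so the calibrated constants are composition-independent on the
experiment grid.

### Decisions

*Planting* is a binary program over the crop-to-plot assignment with at most
one crop per plot, maximizing expected profit under the full-harvest labor
assumption `L_ij = S_j / h_i`. The assumption is a modeling choice: planting
happens before the season's labor supply is revealed, and units cannot
anticipate shocks. The objective is separable across plots, so the free-mode
optimum is a per-plot argmax (fallow only when every crop's net value is
strictly negative). In the strategy-constrained mode used by the case
experiments, every plot is planted, only strategy crops are allowed, and each
strategy crop must occupy at least one plot; this is solved by exact
enumeration (plot counts are small), with ties between equal-objective optima
broken lexicographically — lower-indexed crop on lower-indexed plot — so runs
are bit-reproducible. A mixed-integer backend (`scipy.optimize.milp`) is
available through configuration; it guarantees the same objective but not the
tie-break.

*Harvest* fixes the assignment and distributes the unit's labor share over
planted cells. The problem is a box-constrained LP with a single budget
constraint; the implementation fills cells greedily by descending marginal
profit per laborer `V_i * Y_ij * h_i - C_L`, which is exactly optimal. Cells
whose margin is non-positive receive no labor: units never harvest at a loss,
and partial harvests arise naturally when the budget binds. Labor is
continuous (fractional laborers), consistent with partial harvests; an
integer-labor mode is deliberately out of scope.

*Two-price accounting.* Both decisions use the previous season's realized
prices as expected prices; revenue is then booked at the price implied by the
season's actual aggregate harvest. A rational-expectations alternative
(re-optimizing against the same-season equilibrium price) would damp the
lagged-price dynamics described under "Limitations"; it is intentionally not
implemented, as the lagged contract is the point of the interaction channel.

### Labor supply and shocks

Baseline regional labor is the most labor-intensive crop's per-acre
requirement times total regional acreage — enough for every unit to fully
harvest even the hardest crop. A shock of intensity `i` and duration `d`
replaces the baseline with `i × baseline` for seasons 1..d; runs last
`τ = d + 1` seasons, so every run ends with one recovery season. Labor is
split equally among active units (a minimum-wage labor market with no
poaching); a unit's unused labor is idle, not transferable.

## Parameters of the packaged case

| Parameter | Tomato | Strawberry | Units |
|---|---|---|---|
| Demand elasticity ε | −0.58 | −0.66 | – |
| Production cost (non-labor) | 10,078 | 12,305 | USD/acre |
| Harvest labor cost | 2,408 | 7,788 | USD/acre |
| Labor requirement | 0.29 | 0.95 | laborers/acre |
| Calibration mean price | 1.00 | 2.10 | USD/kg |
| Calibration yield | 15,000 | 10,000 | kg/acre |

Region: 30 units × two 100-acre plots; initial funds $1,871,571 per unit;
monocropped remainder split evenly between the two crops. The per-laborer
wage C_L is the mean of the two per-crop derivations (2,408/0.29 ≈ 8,303 and
7,788/0.95 ≈ 8,198, i.e. ≈ 8,251 USD/laborer-season); the two derivations
disagree by about 1.3%, and a single economy-wide wage is used because the
profit function has one labor-cost term. A per-crop override is configurable.

**Calibration values are placeholders and are flagged as such in the
fixture.** Published cost and labor rows are well documented, but mean prices
and per-acre yields had to be set here. They are round values consistent with
Florida revenue statistics of the 2000s: strawberries ≈ $21,000/acre revenue
against ≈ $20,100/acre full costs (a high-price, labor-hungry crop with thin
margins), tomatoes ≈ $15,000/acre against ≈ $12,500 (cheaper but sturdier).
These choices pin the qualitative orderings the case is built around —
strawberry price per kg about twice tomato's; tomato the better margin both
per laborer (so labor-starved diversified units finish their tomato plot
first) and per acre (so tomato monocropping wins under full labor). Absolute
fund levels scale with these placeholders; the crossover structure is what
the package treats as its result. Users with access to annual price/yield
series can recalibrate via `load_price_yield_csv` and the `calibrate` CLI.

## Experiment design

The sweep crosses 14 region compositions (2, 4, …, 28 diversified units of
30) with intensities i = 0.1, …, 1.0 and durations d = 1, …, 10 — 100 shock
combinations per composition, 1,400 deterministic runs. (An `i = 0` column is
available behind a flag but excluded by default to keep the 10 × 10 grid.)
Each run reports mean end-of-run funds per strategy group.

The advantage analysis reports, per (composition, intensity) cell, the
percentage of durations in which the diversified mean exceeds (a) the
strawberry mean and (b) both monocrop means — duration is the remaining free
axis, so it is the natural replication dimension. Two intensity statistics
summarize each comparison on the 0.1-spaced grid:

- **crossover threshold** — the largest grid intensity at which the advantage
  still fails; when the advantage region is contiguous from the top of the
  grid this reads "diversified wins for i > threshold". 0.0 means the
  advantage holds everywhere, 1.0 that it fails even at full labor.
- **onset intensity** — the smallest grid intensity at which the advantage
  first appears; meaningful when the advantage occupies an interior window.

Under the packaged calibration the aggregated diversified-vs-strawberry
comparison has crossover threshold 0.2, and the diversified-vs-tomato
advantage opens at onset 0.5 but closes again near full labor — at `i = 1`
the diversified mean is *mathematically* the average of the two monocrop
means (full harvest at calibrated prices), so it can never exceed both in the
no-shock limit.

## Synthetic regions

`cropshock.synthetic` samples randomized-but-valid configurations (crop
economics, plot layouts, unit counts constructed so the monocropped remainder
always splits evenly) and small random planting/harvest instances, including
zero-yield cells so optimizer tests exercise fallow and no-harvest choices.
They emulate the structural envelope of the case system, not real data: no
serial correlation in anything, uniform parameter draws, yields independent
of costs. Property tests passing on them establishes the optimizers' and
accounting identities' correctness over the invariant space — it says nothing
about how closely any particular real production system is matched.

## Numerical choices

- Exact enumeration for planting (first strict maximum in lexicographic
  order); greedy fill for harvest with (margin, crop index, plot index)
  ordering — both bit-reproducible, both oracle-checked (brute force / dense
  LP) to 1e-6 relative objective on 500 random instances.
- Calibration round-trip asserted to 1e-9 relative; accounting identity and
  mass conservation to absolute 1e-6 USD / kg (floating-point summation
  order is fixed by construction).
- Identical units share one optimization per season (memoized by strategy and
  land signature); this is an exact speedup, not an approximation. The full
  1,400-run sweep takes a few seconds on one core.
- Problem sizes in tests: 30-unit regions, runs of up to 11 seasons, 500
  oracle instances — chosen to exercise every code path while keeping the
  whole suite fast.

## Known limitations

- **Lagged-price herding.** All diversified units are identical and decide
  simultaneously against last season's prices, so under strong shocks they
  herd onto whichever crop is momentarily dear, producing period-2 cobweb
  oscillations in some grid cells. End-of-run strategy rankings there depend
  on shock-duration parity, and the duration-invariance property holds only
  away from such cells; heterogeneous agents or rational expectations would
  damp this.
- **Regional wealth under extreme shocks.** At i ≤ 0.2 mean regional wealth
  is near zero and composition shifts aggregate harvest between crops with
  different revenue exponents (1 + ε), so the relative spread of regional
  wealth across compositions exceeds 5% there (it stays ≈ 7% or less at
  i ≥ 0.3). The composition-insensitivity of regional wealth is a mild-shock
  result in this model.
- One price per crop and one regional market: no storage, contracts,
  transport, or outside supply; no yield stochasticity, weather, pests, or
  crop seasonality; strategies are fixed for a run; farm exit is available as
  an off-by-default hook (no unit crosses any sensible floor under the
  packaged parameterization).
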