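# Methods

This note documents the models behind `treefolio`: what the synthetic
climate–economy generator emulates, how plantings are valued, how the
portfolio programs are formulated and solved, and the numerical and design
choices a user should know before trusting (or extending) the results.

## 1. The decision problem

A planner must deliver an annual carbon-sequestration target `Q`
(MtCO2e/yr, measured as the ensemble mean of delivered storage) by choosing
a set of grid cells to afforest, one species per chosen cell (a
representative fast conifer and slow broadleaf), optionally supplemented by
a riskless alternative CDR technology purchased at `gamma` per tCO2e/yr.
The value of any strategy depends on an unknown future: the social cost of
carbon, climate-driven tree growth, timber prices, and the farm profits
foregone on planted land. Uncertainty is represented by a finite ensemble
of equally likely climate–economy realizations (CERs); the planner's
attitude to risk selects the objective — expected value (P-EV) or
conditional value-at-risk (P-RA).

## 2. Synthetic climate–economy realizations

The generator stands in for a spatially explicit environment–economy model
and climate-projection archive. It reproduces the statistical *structure*
the portfolio analysis relies on, not any real geography:

- **Grid.** `n_cells` cells on an abstract plane. Mean summer temperature
  falls linearly from south to north (15.5 → 10 °C by default, ±0.4 °C
  noise); precipitation rises (650 → 1400 mm/yr). Farm productivity is an
  increasing function of temperature (clipped to [0.2, 1]), so the best
  agricultural land — and the highest opportunity cost of planting — sits
  in the warm south. Plantable area is 50–300 ha per cell.
- **CER draws.** Each realization draws independently and uniformly one of
  4 emissions pathways and one of 4 climate-model members. A
  temperature–damage coefficient `d` is lognormal (mean ≈ 1, sd 0.5 on the
  log scale); it is a parametric stand-in for an empirical damage
  distribution, retained only for the properties used downstream: the SCC
  path `SCC_t = SCC_0 (1 + g_path + kappa*d)^t` grows faster under
  higher-emissions pathways (`g_path` = 0.5–2 %/yr) and larger damage draws
  (`kappa` = 0.01), so it is positive, non-decreasing, and spreads across
  the ensemble. `SCC_0` = £40/tCO2e.
- **Climate anomalies.** National warming and drying trends scale with the
  pathway and member (0.012–0.045 °C/yr; −0.3 to −2.0 mm/yr), growing
  linearly to year 80 then flat. A per-CER north–south gradient coefficient
  (mean 0.3) makes the south warm and dry faster, which is what eventually
  differentiates optimal species by latitude.
- **Prices.** Timber prices follow a geometric random walk (£40/m³ start,
  0.2 %/yr drift); a single farm price index follows a walk whose drift
  rises with the emissions pathway (food prices up under high emissions).
  A richer treatment would co-evolve individual commodity and fertilizer
  prices; collapsing them to one index preserves the co-movement that
  matters for portfolio risk and nothing else.
- **Global shock.** A lognormal factor (sd 0.2, mean 1) multiplies *all*
  monetary flows of a realization (timber revenue, planting cost, farm
  profits). This is the "global risk factor" that keeps returns positively
  correlated across sites and species and therefore limits hedging.
- **Growth.** Net carbon storage per cell-year is
  `area * (peak * bell(T_eff) * wetness * maturity - soil_pulse)`: a
  Gaussian bell in effective temperature around the species optimum
  (conifer 9.5 ± 3.0 °C, broadleaf 13.5 ± 4.0 °C), a linear precipitation
  factor, a linear ramp to maturity (15 / 25 years), and a soil-disturbance
  emission of 4 tCO2e/ha/yr in the first 5 years. Badly matched sites can
  therefore be net emitters; pairs whose ensemble-mean storage is
  non-positive are excluded from the candidate set and logged. Timber
  volume accumulates with the mean climate response over the rotation and
  is sold in one harvest at rotation end; the only cost is planting in year
  1 (thinnings are deliberately omitted as second-order for the risk
  structure).
- **Seeding.** One master seed; each CER uses the substream keyed by
  `(seed, cer_id)`, so extending an ensemble never changes earlier draws.
  Site timber quality (lognormal, sd 0.1) uses a fixed side-stream so the
  same site is good or poor across all realizations.

What the generator does **not** emulate: real geography or projections,
weather extremes (fire, windthrow, drought years), pests, leakage,
mixed-species stands, price feedback from large-scale land-use change, or
an empirically calibrated damage function. Passing tests therefore show
that the *method* behaves correctly on data with the assumed structure —
not that any particular national planting plan is optimal.

## 3. Valuation

Rotations are chosen per (cell, species, realization) to maximize
annualized timber value over a discrete grid (conifer 20–80 y step 5,
broadleaf 40–120 y step 10), ties to the shortest. Annualization uses
`rho/(1-(1+rho)^-T)` with the zero-rate limit `1/T`, computed via
`expm1`/`log1p` so subnormal rates do not divide by zero. Carbon is valued
over the same single rotation as timber. The 30-year NPV `R` discounts the
annualized timber and carbon flows net of year-by-year foregone farm
profits at `rho` = 3.5 %/yr. Rotations may exceed the horizon: flows are
annualized over the full rotation, then discounted over the 30-year
planning window — the annuity makes the two horizons commensurable.
Discounting is applied uniformly in every NPV sum, including the cost lens
`V'` (below).

Money is in GBP at cell level; portfolio-level sequestration uses the fixed
conversion 1 MtCO2e = 10⁶ tCO2e, applied in exactly one place and tested.

## 4. Portfolio programs

All three programs share the constraints: at most one species per cell
(binary assignment), `z in [0, Q]`, and the ensemble-mean sequestration
target. Infeasible targets are rejected up front with the maximum
attainable sequestration reported.

- **Value forms.** `V_full` includes the monetized carbon value of both
  trees and the alternative technology and is the default for scenario,
  P-EV and P-RA runs. `V_prime` = timber − foregone farm − `z*gamma`
  (annualized, discounted) is the least-cost lens used for the technology
  sweep: because the target constraint pins delivered CDR, the carbon value
  is (approximately) constant across feasible solutions and can be dropped
  when comparing costs. Both forms are implemented and selectable.
- **CVaR.** `CVaR_beta` is minimized through the Rockafellar–Uryasev
  linearization (auxiliary `alpha` plus one shortfall variable per CER).
  On the discrete distribution, the quantile is the lower `(1-beta)`
  quantile with fractional splitting of a boundary atom; for equal weights
  and integer tail count `k = (1-beta)S` this is exactly minus the mean of
  the `k` smallest values, and it agrees with the RU program for *all*
  inputs (the tie convention at atoms is chosen precisely so these two
  definitions coincide). When `(1-beta)S` is not an integer the program
  interpolates between order statistics and a warning is issued.
  Descriptive percentiles elsewhere (cost tails, summary tables) use
  ordinary linear interpolation — two distinct, documented conventions.
- **Loss probabilities** use the strict inequality `V < -threshold`
  ("losses exceeding"), and species-group covariances use the unbiased
  `S-1` divisor.
- **Solver.** HiGHS through `scipy.optimize.milp`, relative MIP gap 1e-6
  (1e-9 in oracle tests). Internally the technology variable is expressed
  in tCO2e/yr and all money coefficients are normalized by their largest
  magnitude; without this rescaling the RU constraint matrix mixes unit
  coefficients with ~1e9 ones and HiGHS can misclassify feasible instances.
  Solutions are re-validated outside the solver (constraints re-checked,
  objectives recomputed from the per-CER value vector), and a binary
  solution's objective is also cross-checked against brute-force
  enumeration in the test suite.
- **Tie-breaking.** An epsilon penalty (1e-9 × cell id, plus half that per
  species index, plus an epsilon on `z`) prefers fewer planted cells, then
  lower cell ids, then the conifer, then less technology — making optima
  reproducible across solver versions when the objective has ties.
- **Relaxation.** A continuous relaxation (`x in [0,1]`) is available; its
  objective bounds the binary one from above, which the tests assert.

## 5. The demonstration scenario

The packaged demo uses 60 cells and 40 CERs — small enough that every run
(including two full determinism re-runs) completes in seconds, large
enough for the species/latitude structure to emerge — with a target of
0.04 MtCO2e/yr (roughly two thirds of what planting every cell could
deliver), β = 0.9, and a £10M loss-reporting threshold. The demo economics
(`SCC_0` = £40/t, farm profit £900/ha/yr at full productivity) were chosen
so that, as in the motivating setting, planting is close to actuarially
fair: NPV distributions straddle zero, the risk-neutral optimum is barely
positive in expectation, and the downside tail is material.

A deliberate variant (`costly_planting_config`, farm profit £1,200/ha/yr)
makes planting a net cost for *every* pair under the cost lens; it is used
for the technology-sweep boundary demonstrations, whose premises (zero
planting when the riskless technology is free; no technology when it costs
several times the costliest tree option per tonne) require that property.
At this desk scale cell integrality means a moderately expensive
technology can retain a tiny residual `z` (a few tCO2e/yr) that is cheaper
than rounding up to one more whole cell; "far above the costliest tree
option" is therefore implemented as a multiple of the costliest retained
pair's gamma-equivalent cost, at which the residual vanishes exactly.

Known desk-scale limitation: with only 60 lumpy cells and a strong common
shock, the risk-averse portfolio's gains are modest — it reliably lowers
CVaR and shifts planting toward the lower-variance species, but its loss
probability at a fixed threshold can match or slightly exceed the
risk-neutral portfolio's. The hedging mechanism itself (covariance and
loss-probability reduction) is demonstrated on a constructed instance with
two anti-correlated site groups in the acceptance tests.

## 6. Numerical conventions and degenerate inputs

- `rho = 0` is handled as the exact `1/T` annuity limit; empty rotation
  grids, horizons shorter than rotations-plus-planning, non-positive cell
  counts, malformed ranges, and 4-pathway/4-member violations raise typed
  errors.
- All delimited outputs are written at 12 significant digits and round-trip
  losslessly at that precision; manifests carry SHA-256 hashes and no
  timestamps, so a fixed config and seed yield byte-identical artifacts.
- Excluded (net-emitting) pairs are zeroed *and* masked; strategies
  referencing them are rejected rather than silently valued at zero.
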