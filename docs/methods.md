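# Methods

This note documents the models, numerical choices and limitations behind
`dietghg`, in the order of the pipeline.

## Data model

A food-balance table is one row per (country, year): 11 food-group calorie
supplies plus the total, all in kcal/cap/day. The 11 groups (animal products,
cereals, pulses, starchy roots, oilcrops, vegetable oils, vegetables, fruits,
sugar-sweeteners, sugarcrops, alcoholic beverages) cover most but not all of
the food supply; the residual is "Others" and must be non-negative, so the
group sum may exceed the total only within a 1 kcal absolute slack (rounding
noise), never beyond. Impact tables carry, per country-year, the agricultural
energy output/input ratio R, non-CO₂ emissions from crop and livestock
production (g CO₂eq/cap/day), produced crop and animal calories, feed supply
and population. Any impact field may be missing; missing values are flagged
and excluded from averages rather than dropped or imputed — a pattern with no
data for a variable reports N/A (never infinity), mirroring real inventories
where whole country groups lack energy-input data. Validation is total: each
input row yields either a record or a located diagnostic.

## Synthetic world generator

The generator emulates the statistical shape of a global food-balance
panel — roughly 50–200 countries × 47 years — without attempting geographic
realism. Its moving parts:

* **16 archetypes.** Anchored to the published per-pattern values: archetype
  mean totals are the per-pattern crop + animal consumption sums (1,873 …
  3,429 kcal/cap/day), spanning the four calorie classes (low < 2,100;
  moderate 2,100–2,400; high 2,400–2,800; very high ≥ 2,800). Composition
  share vectors are designed along three latent axes — calorie level, staple
  type (cereal vs roots/mixed), animal/alcohol richness — and follow the
  patterns' qualitative identities (cereal-dominated #1, root-based #2,
  rice-based #4, pulses-rich #5, island fruit/oilcrop #9, meat-rich #14,
  sweetener/alcohol-rich #15, Mediterranean #16). Pairwise prototype
  separation was audited against within-cluster spread (minimum ratio 1.25)
  so that the archetypes are recoverable in principle.
* **HDI trajectories.** Logistic growth toward a ceiling of 0.97 with
  country-specific relative rates U(0.005, 0.04)/yr and initial values
  U(0.20, 0.90): most countries develop slowly (several never leave their
  archetype within the window), a few undergo a full nutrition transition.
* **HDI–consumption link.** Total calories follow ln(total) = a + b·HDI +
  ε with defaults (a, b) = (7.26, 1.0) — anchored to observed magnitudes
  (~1,900 kcal at HDI 0.3, ~3,400 at HDI 0.9) — and lognormal noise
  σ = 0.03. Each archetype's "HDI center" is the HDI at which the law
  yields its mean total, so the law holds *exactly* for totals while
  archetype occupancy tracks development. The four other linked components
  (animal products, sweeteners, vegetable oils, vegetables) inherit their
  exponential HDI relations through the archetype composition structure
  rather than by construction; their fitted slopes are positive and steeper
  than the total's, but only the total's slope equals a configured
  parameter exactly — tests assert exact slope recovery for the total and
  direction for the components.
* **Archetype dynamics.** Each year a country moves one step along the
  calorie-ordered archetype chain toward the archetype whose center is
  nearest its current HDI, with probability `transition_rate` (default
  0.25). Transitions are logged, giving a second bookkeeping path that
  tests cross-check against the labels.
* **Compositions.** Group shares are a Dirichlet perturbation of the
  archetype's share vector (plus Others) with concentration 300 — per-group
  relative noise of roughly 5–10%, comparable to within-pattern variation in
  real food-balance panels; non-negativity and the sum constraint hold by
  construction. `concentration=None` switches noise off exactly.
* **Impacts.** R, feed, and intensities are archetype means (the published
  per-pattern values) times lognormal noise (σ = 0.05); archetype 9's
  intensity fields are generated missing, reproducing the published table's
  N/A row. Population grows exponentially per country from 10^U(6,8).
* **Randomness.** One global seed spawns per-country substreams
  (`SeedSequence.spawn`), so adding countries never perturbs existing ones.

What the generator does **not** emulate: real FAOSTAT marginals, trade,
country entry/exit (USSR-style succession), HDI data gaps, or correlated
measurement error. Passing recovery tests therefore shows the pipeline is
correct and well-conditioned on data of this shape — not that real-world
archetypes are this cleanly separated.

## SOM training and topology diagnostics

Classical online Kohonen updates: for each presented vector the BMU and its
lattice neighbors move toward it with Gaussian weights over Euclidean
lattice distance. Defaults: learning rate 0.5 → 0.01 and neighborhood radius
(half the largest grid extent) → 0.1, both decaying exponentially over 100
epochs; weights initialised from a seeded random sample of rows; inputs
z-scored per variable (without scaling the total-calorie column dominates
the metric). The small final radius matters: ending the schedule at radius
0.5 leaves enough neighbor smoothing to blur adjacent prototypes (planted-
archetype recovery stuck near ARI 0.75 even on noise-free data); finishing
in a near-independent competitive phase sharpens prototypes to the cluster
means, like a k-means refinement that keeps the SOM's ordered global
arrangement. On the default world (50 countries × 47 years, seed 1) BMU
labels recover planted archetypes at ARI ≈ 0.85; over other world seeds this
ranges roughly 0.71–0.86 (density imbalance between archetypes is the main
driver — the SOM spends nodes where the data are).

Ties in BMU assignment and in neighbor ranking break toward the lower node
index, identically in both metrics, making all diagnostics deterministic.
The topographic product uses natural logarithms and raises an error on
duplicate weight vectors (zero weight-space distance). It is scale-free in
the weights. One caveat found in testing: permutations of a 1-D chain whose
lattice and weight rankings are mutually inverse (e.g. weights 0,2,1,3)
cancel exactly and give P = 0 — P measures dimensional mismatch, not every
ordering violation. Variance explained is 1 − Σ‖x_i − w_bmu(i)‖²/Σ‖x_i −
x̄‖² in scaled space; the same statistic is sometimes called the data
reconstruction rate, and we expose one definition under both names.

`select_dimension` trains one map per candidate lattice under the same seed
policy and recommends the minimal |P|, breaking ties toward fewer
dimensions, then fewer nodes. On the default synthetic world the 4×2×2
lattice wins (P ≈ +0.001) against 16×1 (P ≈ −0.07) and 4×4 (P ≈ −0.006).
For a uniform box the 2-D/3-D margin is genuinely narrow (a sheet folds
through a thin box with little distortion); the test fixture therefore
uses Gaussian clusters centered on a 4×2×2 spatial lattice, where the 3-D
preference is by construction.

Pattern ids 1..N are assigned by ascending node mean total calories, so the
numbering is stable across retrainings and pattern #1 is always the
lowest-calorie diet. Calorie-class intervals are half-open and
lower-inclusive ([2,100, 2,400) is moderate, etc.). Transition counts use a
country's own consecutive calendar years only; gaps contribute no pair. The
transition graph keeps off-diagonal cells with count ≥ 10 by default.

## Emission accounting

Intensities are per produced kcal: e_c = crop non-CO₂ / produced crop
calories, e_a = livestock non-CO₂ / produced animal calories. PC is total
consumption minus animal products (Others included in PC); feed is charged
to animal products at the pattern's own crop intensity (EA = (PA·e_a +
F·e_c)/1000). Fossil energy FE = (PC + F)/R is converted to CO₂ with the
diesel intensity e_d = 0.36 g CO₂eq/kcal (overridable). Unit discipline:
intensities g CO₂eq/kcal, energies kcal/cap/day, emissions kg CO₂eq/cap/day;
the /1000 conversions appear only in the equation functions.

Averaging order is ambiguous in principle: averaging inputs per pattern and
then applying the equations (the default columns) differs from applying the
equations per country-year and averaging the results (the `*_cl` columns),
because FE is nonlinear in R. Both variants are first-class outputs; they
coincide exactly when members are identical and differ by a few percent on
noisy worlds. Per-variable member counts (`n_*`) accompany every average.
The packaged reference table's pattern-16 fossil cell is internally
inconsistent with FE·e_d (1.35 printed vs 1.24 computed); we reproduce the
computation, not the cell.

## HDI model and scenarios

`fit_hdi_relation` is OLS of ln(consumption) on HDI (statsmodels), fitted on
pattern-year mean points; it refuses non-positive consumption and degenerate
HDI spread. Projections per country from a base-year baseline (PC, PA, feed,
e_c, e_a, R):

* **A** freezes everything per capita; totals are exactly linear in
  population.
* **B** scales total and animal-product consumption by
  exp(b·(HDI_t − HDI_base)) using the fitted slopes — a ratio form, so B
  degenerates exactly to A when HDI is frozen and is anchored to each
  country's observed base-year diet rather than to the fitted intercept.
  Crop consumption is the residual total − animal; feed scales with animal
  products at the base-year feed-to-animal ratio. Projected totals are
  capped at 3,460 kcal/cap/day (just above the highest observed diet)
  because the exponential is unbounded as HDI → 1; a base-year diet already
  above the cap is kept, not cut. Countries without a full HDI series fall
  back to Scenario-A behavior (logged).
* **C** is B with (e_c, e_a, R) replaced by a best-practice policy, by
  default the base-year means of the very-high-calorie pattern group — the
  most emission-efficient per produced kcal. An identity policy makes C
  degenerate exactly to B. Scenario B evolves component quantities only; it
  does not re-cluster countries into new patterns (the alternative would
  need a dynamic membership model the data do not constrain).

Aggregation: Gt CO₂eq/yr = Σ_c percap_c · pop_c · 365 / 10¹²; fossil energy
in EJ/yr uses 4,184 J/kcal. Components (livestock non-CO₂, crop non-CO₂,
fossil CO₂) sum to the total exactly every year.

The projection tests verify laws, not levels: population linearity,
degenerate equalities (B→A, C→B), scenario ordering on rising-HDI worlds,
and closed-form demand recovery within 1% on a world with a noise-free
HDI-total link (with observation noise, the base-year anchor legitimately
carries that noise into the projection, and a heavy-tailed population
distribution keeps it from averaging out globally). Reproducing published
2050 levels (≈20 Gt CO₂eq/yr) would require the real food-balance, HDI and
population inputs, which are out of scope.

## Problem sizes and determinism

Default test and example sizes — 50 countries × 47 years (2,350 records),
16-node maps, 100 epochs — train in a few seconds each; the full test suite
runs in well under a minute. Every stochastic component (generator, SOM
initialisation and presentation order) is driven by explicit integer seeds;
identical configuration implies byte-identical outputs.
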