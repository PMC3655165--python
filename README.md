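# dietghg

Dietary-pattern clustering and embodied greenhouse-gas accounting for
country-level food-balance data.

Global diets differ enormously — from ~1,900 kcal/cap/day cereal-dominated
diets to >3,400 kcal/cap/day meat-rich ones — and they carry very different
climate burdens. `dietghg` implements an analysis pipeline for researchers in
food-systems and climate-impact modelling who want to:

1. **cluster** country-year dietary compositions (11 food-group calorie
   supplies + total, kcal/cap/day) into archetypal *dietary patterns* with a
   self-organizing map (SOM) whose lattice dimensionality is selected by the
   Bauer–Pawelzik **topographic product**;
2. **attribute** embodied fossil energy and agricultural non-CO₂ emissions to
   each pattern through a per-pattern accounting chain;
3. **fit** the exponential relation between consumption and the Human
   Development Index, and **project** global agricultural emissions to 2050
   under population / diet / technology scenarios.

A bundled synthetic-world generator with planted archetypes makes the whole
pipeline testable without external data.

## The model

**Clustering.** Each country-year is a 12-vector (11 food groups + total,
z-scored). A Kohonen SOM with N nodes on a 1–3-dimensional lattice is trained
online; each observation's best-matching unit (BMU) defines its pattern. The
topographic product

P = (1 / N(N−1)) Σ_j Σ_k ln [ Π_{l≤k} Q₁(j,l) Q₂(j,l) ]^{1/2k}

compares each node's k-th nearest neighbors in lattice space and weight
space; P ≈ 0 means the lattice dimensionality matches the data manifold
(P < 0: too few dimensions; P > 0: too many).

**Emission accounting.** Per pattern z, with PC/PA crop/animal-product
consumption, F feed, e_c/e_a non-CO₂ emission intensities (g CO₂eq/kcal of
produced crop/animal calories) and R the agricultural energy output/input
ratio, all averaged over the pattern members with data:

    EC_z = PC_z · e_c,z / 1000                       crop non-CO₂
    EA_z = (PA_z · e_a,z + F_z · e_c,z) / 1000       livestock non-CO₂ (incl. feed)
    FE_z = (PC_z + F_z) / R_z                        fossil energy input
    E_fossil,z = FE_z · e_d / 1000,  e_d = 0.36 g CO₂eq/kcal (diesel)
    ET_z = EC_z + EA_z + E_fossil,z                  total, kg CO₂eq/cap/day

**Projection.** ln(consumption) = a + b·HDI is fitted by OLS for total food,
animal products, sweeteners, vegetable oils and vegetables. Scenario A scales
base-year per-capita emissions with population; B additionally evolves each
country's diet along its HDI path; C additionally replaces intensities with a
best-practice policy (very-high-calorie group means).

## Worked example

```sh
python examples/03_pattern_emissions.py
```

prints, for the packaged reference per-pattern table:

```
pattern  EC      EA      fossil  ET (kg CO2eq/cap/day)
      1  1.42    2.04    0.05    3.51
      2  0.81    0.59    0.03    1.43
      7  1.18    1.99    0.11    3.29
     13  1.36    1.78    0.64    3.78
     14  1.03    3.87    1.19    6.10
```

Pattern 1 (a 1,873 kcal low-calorie diet) carries total emissions of 3.51 kg
CO₂eq/cap/day — as much as far richer diets — because its livestock intensity
is very high (12.48 g CO₂eq/kcal); pattern 14 (meat-rich, 3,110 kcal) reaches
6.10 kg mainly through animal products and feed. `examples/01–04` walk
through world simulation, clustering and dimensionality selection (the
16-node 4×2×2 lattice wins with P = +0.0012 against 16×1 and 4×4), pattern
transition counting, and the A/B/C projections (on the default synthetic
world: 7.2 / 9.2 / 8.0 Gt CO₂eq/yr in 2050 — diet change raises emissions,
best practice lowers non-CO₂ while needing more fossil energy).

There is also a thin CLI: `dietghg run --seed 1 --out outdir` executes
simulate → cluster → patterns → impacts → project and writes a manifest;
each stage is available as its own subcommand.

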