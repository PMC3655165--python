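"""Generate a synthetic world of country-year diets and inspect its structure.

The generator plants 16 dietary archetypes (from a 1,873 kcal/cap/day
cereal-dominated diet up to a 3,429 kcal/cap/day Mediterranean-style one) and
moves countries between them as their Human Development Index rises.
"""

import dietghg as dg

world = dg.simulate_world(dg.WorldConfig(n_countries=50, seed=1))

print(f"food records:   {len(world.food)} (countries x years)")
print(f"impact records: {len(world.impacts)}")
print(f"archetype transitions logged: {len(world.transition_log)}")

truth = world.labels["archetype"]
print("\nperson-year counts per planted archetype:")
print(truth.value_counts().sort_index().to_string())

# every archetype pins a calorie class; the four classes are all present
arch = {a.id: a for a in world.config.archetypes}
classes = {z: dg.calorie_class(arch[z].total_kcal_mean) for z in sorted(arch)}
print("\narchetype calorie classes:", classes)
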