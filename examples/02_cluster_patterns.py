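"""Cluster diet data with a self-organizing map and pick its dimensionality.

Candidate lattices are ranked by the topographic product P: P < 0 flags a
lattice with too few dimensions, P > 0 too many, |P| minimal wins. The chosen
map's nodes become the dietary patterns (numbered by ascending calories).
"""

import dietghg as dg

world = dg.simulate_world(dg.WorldConfig(n_countries=50, seed=1))
data = world.food[list(dg.FOOD_GROUPS) + ["total_kcal"]].to_numpy(float)

best, rows = dg.select_dimension(
    data, [(16,), (4, 4), (4, 2, 2)], dg.SOMConfig(seed=1)
)
print("grid     P         variance explained")
for r in rows:
    print(f"{r['grid']:<8} {r['topographic_product']:+.4f}   {r['variance_explained']:.3f}")
print("recommended lattice:", "x".join(map(str, best)))

som = dg.train_som(data, dg.SOMConfig(grid_dims=best, seed=1))
labels = dg.assign_patterns(som, world.food)
summaries, _ = dg.summarize_patterns(labels, world.food)
print("\npattern  members  mean kcal  class")
for s in summaries:
    if s.n_members:
        print(f"{s.pattern_id:>7}  {s.n_members:>7}  {s.mean_total_kcal:>9.0f}  {s.calorie_class}")

mat = dg.transition_matrix(labels, n_patterns=som.n_nodes)
edges = dg.transition_graph(mat, min_count=10)
print(f"\n{mat.sum()} consecutive-year transitions; frequent (>=10) off-diagonal moves:")
for src, dst, count in edges:
    print(f"  pattern {src} -> {dst}: {count} times")
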