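import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dietghg as dg
from dietghg.som import lattice_coords

from conftest import random_som_map
from helpers import brute_force_topographic_product


def chain_map(weights_1d):
    """A 1-D chain whose node k has weight (w_k, 0)."""
    w = np.column_stack([np.asarray(weights_1d, float), np.zeros(len(weights_1d))])
    n = len(weights_1d)
    return dg.SOMMap(
        grid_dims=(n,),
        node_coords=lattice_coords((n,)),
        weights=w,
        scale_mean=np.zeros(2),
        scale_sd=np.ones(2),
    )


class TestTraining:
    def test_single_point_is_fixed_point(self):
        data = np.tile([1.0, 2.0, 3.0], (50, 1))
        som = dg.train_som(data, dg.SOMConfig(grid_dims=(2, 2), seed=0, scaling_mode="none"))
        assert np.allclose(som.weights, [1.0, 2.0, 3.0], atol=1e-6)

    def test_three_clusters_match_kmeans_oracle(self):
        """On 3 well-separated blobs, a 3x1 map's prototypes pair off with the
        k-means cluster means up to relabeling."""
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(0)
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        data = np.vstack([c + rng.normal(0, 0.3, size=(60, 2)) for c in centers])
        som = dg.train_som(data, dg.SOMConfig(grid_dims=(3, 1), seed=0, scaling_mode="none"))
        km = KMeans(3, n_init=5, random_state=0).fit(data)
        dists = np.linalg.norm(som.weights[:, None] - km.cluster_centers_[None], axis=2)
        assignment = dists.argmin(axis=1)
        assert sorted(assignment) == [0, 1, 2]
        assert (dists.min(axis=1) < 1.0).all()

    def test_errors(self):
        with pytest.raises(dg.SOMError, match="rows"):
            dg.train_som(np.zeros((3, 2)), dg.SOMConfig(grid_dims=(2, 2), seed=0))
        bad = np.zeros((10, 2))
        bad[0, 0] = np.nan
        with pytest.raises(dg.SOMError, match="finite"):
            dg.train_som(bad, dg.SOMConfig(grid_dims=(2, 1), seed=0))

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(100, 3))
        cfg = dg.SOMConfig(grid_dims=(2, 2), seed=9, epochs=10)
        assert np.array_equal(dg.train_som(data, cfg).weights, dg.train_som(data, cfg).weights)


class TestBMU:
    def test_own_weight_returns_node(self):
        m = chain_map([0.0, 1.0, 2.0, 3.0])
        for k in range(4):
            assert dg.bmu(m, m.weights[k], scaled=True) == k

    def test_tie_breaks_to_lowest_index(self):
        m = chain_map([0.0, 1.0, 2.0, 3.0])
        assert dg.bmu(m, [1.5, 0.0], scaled=True) == 1

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(2)
        m = random_som_map(rng)
        for _ in range(50):
            v = rng.normal(size=m.weights.shape[1])
            brute = min(
                range(m.n_nodes), key=lambda i: (np.linalg.norm(m.weights[i] - v), i)
            )
            assert dg.bmu(m, v) == brute

    def test_dimension_mismatch(self):
        m = chain_map([0.0, 1.0, 2.0])
        with pytest.raises(dg.SOMError, match="dimension"):
            dg.bmu(m, [1.0, 2.0, 3.0])


class TestVarianceExplained:
    def test_perfect_reconstruction(self):
        m = chain_map([0.0, 1.0, 2.0, 3.0])
        data = m.weights[[0, 1, 2, 3, 0, 2]]
        assert dg.variance_explained(m, data) == pytest.approx(1.0)

    def test_one_node_map_explains_nothing(self):
        data = np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 0.0]])
        m = dg.SOMMap(
            grid_dims=(1,),
            node_coords=np.zeros((1, 1)),
            weights=data.mean(axis=0, keepdims=True),
            scale_mean=np.zeros(2),
            scale_sd=np.ones(2),
        )
        assert dg.variance_explained(m, data) == pytest.approx(0.0)

    def test_degenerate_data_is_error(self):
        m = chain_map([0.0, 1.0])
        with pytest.raises(dg.SOMError, match="variance"):
            dg.variance_explained(m, np.ones((5, 2)))


class TestTopographicProduct:
    def test_order_preserving_chain_is_zero(self):
        assert dg.topographic_product(chain_map([0.0, 1.0, 2.0, 3.0])) == pytest.approx(0.0)

    def test_scrambled_chain_negative_and_matches_oracle(self):
        # note: the swap (0,2,1,3) cancels exactly (lattice and weight
        # rankings are inverse permutations), giving P = 0; this permutation
        # genuinely folds the chain
        m = chain_map([0.0, 2.0, 4.0, 1.0, 3.0])
        p = dg.topographic_product(m)
        assert p < 0
        ref = brute_force_topographic_product(m.node_coords, m.weights)
        assert p == pytest.approx(ref, abs=1e-12)

    def test_matches_brute_force_on_random_maps(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            m = random_som_map(rng)
            assert dg.topographic_product(m) == pytest.approx(
                brute_force_topographic_product(m.node_coords, m.weights), abs=1e-12
            )

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_brute_force_agreement_property(self, seed):
        rng = np.random.default_rng(seed)
        m = random_som_map(rng)
        assert dg.topographic_product(m) == pytest.approx(
            brute_force_topographic_product(m.node_coords, m.weights), abs=1e-12
        )

    def test_invariant_under_weight_scaling(self):
        rng = np.random.default_rng(4)
        m = random_som_map(rng)
        p = dg.topographic_product(m)
        m.weights = m.weights * 37.5
        assert dg.topographic_product(m) == pytest.approx(p, abs=1e-12)

    def test_duplicate_weights_error_names_pair(self):
        m = chain_map([0.0, 1.0, 1.0, 3.0])
        with pytest.raises(dg.SOMError, match="nodes 1 and 2"):
            dg.topographic_product(m)

    def test_sign_convention_on_mismatched_dimensions(self):
        """A lattice with too few dimensions gives P < 0, too many gives P > 0."""
        rng = np.random.default_rng(5)
        cfg = dict(seed=0, epochs=30, scaling_mode="none")
        data3 = rng.uniform(0, 1, size=(600, 3)) * [4, 2, 2]
        m1 = dg.train_som(data3, dg.SOMConfig(grid_dims=(16,), **cfg))
        assert dg.topographic_product(m1) < 0
        data1 = np.column_stack([np.linspace(0, 10, 600), np.zeros(600), np.zeros(600)])
        data1 += rng.normal(0, 0.01, size=data1.shape)
        m3 = dg.train_som(data1, dg.SOMConfig(grid_dims=(4, 2, 2), **cfg))
        assert dg.topographic_product(m3) > 0


class TestSelectDimension:
    def test_single_candidate_is_returned(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(50, 3))
        best, rows = dg.select_dimension(data, [(2, 2)], dg.SOMConfig(seed=0, epochs=10))
        assert best == (2, 2) and len(rows) == 1

    def test_three_dimensional_manifold_prefers_3d_grid(self):
        """Clusters arranged on a 4x2x2 spatial lattice: the 3-D candidate
        preserves their neighborhood structure, the 1-D/2-D ones must fold."""
        rng = np.random.default_rng(7)
        centers = lattice_coords((4, 2, 2)) * 2.0
        data = np.vstack([c + rng.normal(0, 0.25, size=(50, 3)) for c in centers])
        best, rows = dg.select_dimension(
            data,
            [(16,), (4, 4), (4, 2, 2)],
            dg.SOMConfig(seed=0, epochs=60, scaling_mode="none"),
        )
        assert best == (4, 2, 2)
        by_grid = {r["grid"]: r["topographic_product"] for r in rows}
        assert by_grid["16"] < 0
        assert abs(by_grid["4x2x2"]) == min(abs(v) for v in by_grid.values())


class TestSerialization:
    def test_json_round_trip(self, default_map):
        back = dg.SOMMap.from_json(default_map.to_json())
        assert back.grid_dims == default_map.grid_dims
        assert np.allclose(back.weights, default_map.weights)
        assert back.diagnostics["variance_explained"] == pytest.approx(
            default_map.diagnostics["variance_explained"]
        )


class TestOnDefaultWorld:
    def test_variance_explained_floor(self, default_map):
        assert default_map.diagnostics["variance_explained"] >= 0.6

    def test_planted_archetype_recovery(self, default_world, default_labels):
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(
            default_world.labels["archetype"], default_labels["pattern"]
        )
        assert ari >= 0.8
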