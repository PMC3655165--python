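"""Self-organizing map training and the topographic product diagnostic.

A Kohonen SOM maps the 12-variable diet data onto a small rectangular
lattice (1-, 2- or 3-dimensional); each lattice node's weight vector becomes
one dietary pattern prototype and each observation is assigned to its
best-matching unit (BMU). The Bauer–Pawelzik topographic product P measures
how faithfully the lattice preserves the neighborhood structure of the data
manifold: P ≈ 0 when the lattice dimensionality matches the manifold,
P < 0 when the lattice has too few dimensions, P > 0 when too many.
Scanning candidate lattices and picking the one with |P| minimal selects the
map dimensionality.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np


class SOMError(ValueError):
    pass


@dataclass(frozen=True)
class SOMConfig:
    """Training hyperparameters.

    Defaults follow standard Kohonen practice: Gaussian neighborhood over
    Euclidean lattice distance, neighborhood radius decaying exponentially
    from half the largest grid extent down to 0.1 (so training ends in a
    near-independent competitive refinement phase that sharpens the
    prototypes), learning rate 0.5 → 0.01, 100 epochs of online
    (per-sample) updates, weights initialised from a seeded random sample of
    data rows, per-variable z-scoring of the inputs (without which the
    total-calorie column dominates the metric).
    """

    grid_dims: tuple[int, ...] = (4, 2, 2)
    epochs: int = 100
    lr_initial: float = 0.5
    lr_final: float = 0.01
    radius_initial: float | None = None
    radius_final: float = 0.1
    init_mode: str = "sample"  # "sample" | "pca"
    scaling_mode: str = "zscore"  # "zscore" | "none"
    seed: int = 0

    def __post_init__(self):
        dims = tuple(int(d) for d in self.grid_dims)
        if len(dims) < 1 or len(dims) > 3 or any(d < 1 for d in dims):
            raise SOMError(f"grid_dims must be 1–3 positive integers, got {dims}")
        if int(np.prod(dims)) < 2:
            raise SOMError("the lattice needs at least 2 nodes")
        if not (0 < self.lr_final <= self.lr_initial):
            raise SOMError("learning rate must decay monotonically and stay positive")
        if self.radius_initial is not None and self.radius_final > self.radius_initial:
            raise SOMError("neighborhood radius must decay monotonically")
        if self.init_mode not in ("sample", "pca"):
            raise SOMError(f"unknown init_mode {self.init_mode!r}")
        if self.scaling_mode not in ("zscore", "none"):
            raise SOMError(f"unknown scaling_mode {self.scaling_mode!r}")
        object.__setattr__(self, "grid_dims", dims)


def lattice_coords(grid_dims: tuple[int, ...]) -> np.ndarray:
    """Integer lattice coordinates of all nodes, row-major node order."""
    return np.array(list(itertools.product(*(range(d) for d in grid_dims))), dtype=float)


@dataclass
class SOMMap:
    """A trained map: lattice geometry, prototypes and diagnostics."""

    grid_dims: tuple[int, ...]
    node_coords: np.ndarray  # (N, ndim) integer lattice positions
    weights: np.ndarray  # (N, d) prototypes in scaled space
    scale_mean: np.ndarray  # (d,)
    scale_sd: np.ndarray  # (d,)
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def scale(self, data: np.ndarray) -> np.ndarray:
        return (np.asarray(data, dtype=float) - self.scale_mean) / self.scale_sd

    def unscale_weights(self) -> np.ndarray:
        """Prototypes back in original units."""
        return self.weights * self.scale_sd + self.scale_mean

    def to_json(self) -> str:
        return json.dumps(
            dict(
                grid_dims=list(self.grid_dims),
                node_coords=self.node_coords.tolist(),
                weights=self.weights.tolist(),
                scale_mean=self.scale_mean.tolist(),
                scale_sd=self.scale_sd.tolist(),
                diagnostics=self.diagnostics,
            )
        )

    @classmethod
    def from_json(cls, text: str) -> "SOMMap":
        d = json.loads(text)
        return cls(
            grid_dims=tuple(d["grid_dims"]),
            node_coords=np.array(d["node_coords"], dtype=float),
            weights=np.array(d["weights"], dtype=float),
            scale_mean=np.array(d["scale_mean"], dtype=float),
            scale_sd=np.array(d["scale_sd"], dtype=float),
            diagnostics=d.get("diagnostics", {}),
        )


def _fit_scaling(data: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray]:
    d = data.shape[1]
    if mode == "none":
        return np.zeros(d), np.ones(d)
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant columns contribute nothing either way
    return mean, sd


def _init_weights(
    scaled: np.ndarray, n_nodes: int, mode: str, rng: np.random.Generator
) -> np.ndarray:
    if mode == "sample":
        idx = rng.choice(scaled.shape[0], size=n_nodes, replace=False)
        return scaled[idx].copy()
    # pca: spread nodes along the span of the two leading principal axes
    centered = scaled - scaled.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    t = np.linspace(-1, 1, n_nodes)
    comp = min(2, vt.shape[0])
    w = scaled.mean(axis=0) + np.outer(t, vt[0]) * s[0] / np.sqrt(len(scaled))
    if comp > 1:
        w = w + np.outer(np.sin(np.pi * t), vt[1]) * s[1] / np.sqrt(len(scaled))
    return w


def train_som(data: np.ndarray, config: SOMConfig) -> SOMMap:
    """Train a SOM with classical online Kohonen updates.

    For each presented vector the BMU and its lattice neighbors move toward
    it, weighted by a Gaussian over lattice distance; radius and learning
    rate decay exponentially over the presentation schedule. Deterministic
    for a fixed config (seeded initialisation and presentation order).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise SOMError("data must be a 2-D matrix")
    if not np.isfinite(data).all():
        raise SOMError("data contains non-finite values")
    coords = lattice_coords(config.grid_dims)
    n_nodes = coords.shape[0]
    if data.shape[0] < n_nodes:
        raise SOMError(f"need at least {n_nodes} rows to train a {config.grid_dims} map")

    mean, sd = _fit_scaling(data, config.scaling_mode)
    scaled = (data - mean) / sd
    rng = np.random.default_rng(config.seed)
    weights = _init_weights(scaled, n_nodes, config.init_mode, rng)

    # pairwise squared lattice distances, node i vs all nodes
    lat_sq = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)

    r0 = config.radius_initial
    if r0 is None:
        r0 = max(max(config.grid_dims) / 2.0, config.radius_final)
    r1 = config.radius_final
    lr0, lr1 = config.lr_initial, config.lr_final

    n = scaled.shape[0]
    total = config.epochs * n
    step = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for i in order:
            frac = step / max(total - 1, 1)
            lr = lr0 * (lr1 / lr0) ** frac
            sigma = r0 * (r1 / r0) ** frac
            x = scaled[i]
            d2 = ((weights - x) ** 2).sum(axis=1)
            b = int(np.argmin(d2))
            h = np.exp(-lat_sq[b] / (2.0 * sigma * sigma))
            weights += (lr * h)[:, None] * (x - weights)
            step += 1

    m = SOMMap(
        grid_dims=config.grid_dims,
        node_coords=coords,
        weights=weights,
        scale_mean=mean,
        scale_sd=sd,
    )
    m.diagnostics["quantization_error"] = quantization_error(m, data)
    try:
        m.diagnostics["variance_explained"] = variance_explained(m, data)
    except SOMError:  # constant data has no variance to explain
        m.diagnostics["variance_explained"] = float("nan")
    if n_nodes >= 3:
        try:
            m.diagnostics["topographic_product"] = topographic_product(m)
        except SOMError:
            m.diagnostics["topographic_product"] = float("nan")
    return m


def bmu(som: SOMMap, vector: np.ndarray, scaled: bool = False) -> int:
    """Best-matching unit: node minimising Euclidean distance in scaled space.

    Ties break toward the lowest node index. ``scaled=True`` skips the map's
    stored input scaling.
    """
    v = np.asarray(vector, dtype=float)
    if v.shape != (som.weights.shape[1],):
        raise SOMError(
            f"vector has dimension {v.shape}, map expects ({som.weights.shape[1]},)"
        )
    if not scaled:
        v = som.scale(v)
    d2 = ((som.weights - v) ** 2).sum(axis=1)
    return int(np.argmin(d2))


def bmu_labels(som: SOMMap, data: np.ndarray) -> np.ndarray:
    """Vectorised BMU assignment for a data matrix (original units)."""
    scaled = som.scale(data)
    d2 = ((scaled[:, None, :] - som.weights[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def quantization_error(som: SOMMap, data: np.ndarray) -> float:
    scaled = som.scale(data)
    d2 = ((scaled[:, None, :] - som.weights[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min(axis=1)).mean())


def variance_explained(som: SOMMap, data: np.ndarray) -> float:
    """Fraction of (scaled) data variance captured by the BMU prototypes.

    1 − Σ‖x_i − w_bmu(i)‖² / Σ‖x_i − x̄‖². Also called the data
    reconstruction rate of the map.
    """
    scaled = som.scale(data)
    d2 = ((scaled[:, None, :] - som.weights[None, :, :]) ** 2).sum(axis=2)
    resid = d2.min(axis=1).sum()
    tot = ((scaled - scaled.mean(axis=0)) ** 2).sum()
    if tot <= 0:
        raise SOMError("degenerate data: zero total variance")
    return float(1.0 - resid / tot)


def _neighbor_ranks(dist: np.ndarray) -> np.ndarray:
    """For each row, the other nodes ordered by distance (ties by node index)."""
    n = dist.shape[0]
    out = np.empty((n, n - 1), dtype=int)
    for j in range(n):
        others = np.array([i for i in range(n) if i != j])
        order = np.lexsort((others, dist[j, others]))
        out[j] = others[order]
    return out


def topographic_product(som: SOMMap) -> float:
    """Bauer–Pawelzik topographic product of a trained map.

    For node j and neighbor order k, with n_k^A(j) / n_k^V(j) the k-th
    nearest neighbor of j in the lattice / weight-space metric:

        Q1(j,k) = d^V(w_j, w_{n_k^A(j)}) / d^V(w_j, w_{n_k^V(j)})
        Q2(j,k) = d^A(j, n_k^A(j))     / d^A(j, n_k^V(j))
        P3(j,k) = (Π_{l=1..k} Q1(j,l) Q2(j,l))^{1/(2k)}
        P       = Σ_j Σ_{k=1..N−1} ln P3(j,k) / (N(N−1))

    P is scale-free in the weights (Q1 is a ratio). Duplicate weight vectors
    make d^V vanish and raise an error naming the node pair.
    """
    n = som.n_nodes
    if n < 3:
        raise SOMError("topographic product needs at least 3 nodes")
    w = som.weights
    c = som.node_coords
    dv = np.sqrt(((w[:, None, :] - w[None, :, :]) ** 2).sum(axis=2))
    da = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(axis=2))
    off = ~np.eye(n, dtype=bool)
    if (dv[off] == 0).any():
        j, i = np.argwhere((dv == 0) & off)[0]
        raise SOMError(f"duplicate weight vectors at nodes {j} and {i}")

    rank_a = _neighbor_ranks(da)
    rank_v = _neighbor_ranks(dv)

    total = 0.0
    for j in range(n):
        lq = (
            np.log(dv[j, rank_a[j]]) - np.log(dv[j, rank_v[j]])
            + np.log(da[j, rank_a[j]]) - np.log(da[j, rank_v[j]])
        )
        cum = np.cumsum(lq)
        k = np.arange(1, n)
        total += (cum / (2.0 * k)).sum()
    return float(total / (n * (n - 1)))


def select_dimension(
    data: np.ndarray,
    candidate_grids: list[tuple[int, ...]],
    config: SOMConfig | None = None,
) -> tuple[tuple[int, ...], list[dict]]:
    """Train one map per candidate lattice and rank them by |P|.

    Returns (recommended grid, diagnostics rows). Ties in |P| break toward
    fewer lattice dimensions, then fewer nodes. All candidates are trained
    under the same seed policy so the comparison is like-for-like.
    """
    if len(candidate_grids) < 1:
        raise SOMError("need at least one candidate grid")
    base = config or SOMConfig()
    rows = []
    for grid in candidate_grids:
        cfg = SOMConfig(
            grid_dims=tuple(grid),
            epochs=base.epochs,
            lr_initial=base.lr_initial,
            lr_final=base.lr_final,
            radius_initial=base.radius_initial,
            radius_final=base.radius_final,
            init_mode=base.init_mode,
            scaling_mode=base.scaling_mode,
            seed=base.seed,
        )
        try:
            m = train_som(data, cfg)
        except SOMError as exc:
            raise SOMError(f"training failed for grid {grid}: {exc}") from exc
        rows.append(
            dict(
                grid="x".join(str(d) for d in cfg.grid_dims),
                grid_dims=cfg.grid_dims,
                n_nodes=m.n_nodes,
                topographic_product=m.diagnostics.get("topographic_product", float("nan")),
                variance_explained=m.diagnostics["variance_explained"],
                quantization_error=m.diagnostics["quantization_error"],
            )
        )
    best = min(
        rows,
        key=lambda r: (
            abs(r["topographic_product"]),
            len(r["grid_dims"]),
            r["n_nodes"],
        ),
    )
    return best["grid_dims"], rows
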