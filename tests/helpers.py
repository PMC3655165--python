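"""Independent brute-force oracles used to cross-check the implementation."""

import math


def brute_force_topographic_product(coords, weights):
    """Topographic product via explicit loops and list sorts, independent of
    the vectorised implementation."""
    n = len(weights)

    def d(a, b):
        return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))

    total = 0.0
    for j in range(n):
        others = [i for i in range(n) if i != j]
        by_lattice = sorted(others, key=lambda i: (d(coords[j], coords[i]), i))
        by_weight = sorted(others, key=lambda i: (d(weights[j], weights[i]), i))
        log_sum = 0.0
        for k in range(1, n):
            na, nv = by_lattice[k - 1], by_weight[k - 1]
            q1 = d(weights[j], weights[na]) / d(weights[j], weights[nv])
            q2 = d(coords[j], coords[na]) / d(coords[j], coords[nv])
            log_sum += math.log(q1) + math.log(q2)
            total += log_sum / (2.0 * k)
    return total / (n * (n - 1))


def count_consecutive_pairs(labels_df):
    """Number of (country, year, year+1) pairs present in a label table."""
    keys = set(zip(labels_df["country"], labels_df["year"]))
    return sum(1 for c, y in keys if (c, y + 1) in keys)
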