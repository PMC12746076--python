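"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from raptormech import synthetic


@pytest.fixture
def jcurve_params():
    """Reference J-curve tendon model (noise-free, no pre-tension)."""
    return synthetic.TendonModelParams(
        a=0.5, b=20.0, eps_max=0.10, A0=5.0, L0=15.0,
        resilience=0.75, pretension=0.0, noise_sd=0.0, seed=1,
    )


def enumerate_mwu_pvalue(x, y) -> tuple[float, float]:
    """Brute-force exact Mann–Whitney test by full label enumeration.

    Enumerates all C(n1+n2, n1) assignments of the pooled (tie-free)
    values to the first sample, builds the exact null distribution of
    U = #{x_i > y_j}, and returns (U_obs, two-sided p) with
    p = min(1, 2 * min(P(U <= u), P(U >= u))).
    """
    x = list(x)
    y = list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1 for xi in xs for yj in ys if xi > yj)

    u_obs = u_stat(x, y)
    null = []
    idx = range(len(pooled))
    for pick in combinations(idx, n1):
        xs = [pooled[i] for i in pick]
        ys = [pooled[i] for i in idx if i not in pick]
        null.append(u_stat(xs, ys))
    null = np.asarray(null)
    cdf = float(np.mean(null <= u_obs))
    sf = float(np.mean(null >= u_obs))
    return float(u_obs), min(1.0, 2.0 * min(cdf, sf))


def vcv_path_oracle(tree) -> np.ndarray:
    """Phylogenetic VCV by explicit path intersection.

    For each tip pair, walks the root-to-tip node paths and sums the edge
    lengths shared by both paths — an implementation independent of the
    recursive fill used in the library.
    """
    leaves = list(tree.leaf_node_iter())

    def root_path(leaf):
        path = []
        node = leaf
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        return list(reversed(path))  # root-adjacent first

    paths = [root_path(leaf) for leaf in leaves]
    n = len(leaves)
    base = tree.seed_node.edge.length or 0.0  # stem edge, if any
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            shared = base
            for a, b in zip(paths[i], paths[j]):
                if a is not b:
                    break
                shared += a.edge.length or 0.0
            C[i, j] = C[j, i] = shared
    return C
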