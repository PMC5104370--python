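"""Shared fixtures and independent brute-force oracles.

The oracle helpers here deliberately avoid the package's own algorithms:
clustering via explicit neighbour-pair enumeration, distances via
Floyd-Warshall dynamic programming, betweenness via exhaustive enumeration of
shortest paths, connectivity via union-find. They exist so the fast
implementations can be checked against first-principles computations.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import metabnet as m


@pytest.fixture(scope="session")
def regions90() -> m.RegionTable:
    return m.load_regions()


@pytest.fixture(scope="session")
def regions20(regions90) -> m.RegionTable:
    return regions90.subset(20)


@pytest.fixture(scope="session")
def default_cohort(regions90) -> m.Cohort:
    spec = m.SimulationSpec(base_cov=m.two_block_cov(90, 0.3, 0.1), seed=7)
    return m.generate_cohort(spec, regions90)


@pytest.fixture(scope="session")
def default_norm(default_cohort) -> m.NormalizedMatrix:
    return m.normalize_and_adjust(default_cohort)


def make_cohort(covariates: pd.DataFrame, metabolism: np.ndarray,
                region_names: list[str]) -> m.Cohort:
    """Assemble a Cohort from raw pieces (for hand-built statistical cases)."""
    return m.Cohort(covariates.copy(),
                    pd.DataFrame(np.asarray(metabolism, float), columns=region_names))


# ---------------------------------------------------------------------------
# graph helpers and oracles
# ---------------------------------------------------------------------------


def adjacency_to_net(a: np.ndarray, sparsity: float = 0.5) -> m.BinaryNetwork:
    a = np.asarray(a)
    names = [f"n{i}" for i in range(len(a))]
    return m.BinaryNetwork(a, sparsity, names)


def random_connected_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Erdos-Renyi adjacency, resampled until connected (union-find check)."""
    while True:
        a = (rng.random((n, n)) < p).astype(np.int8)
        a = np.triu(a, 1)
        a = a + a.T
        if union_find_components(a) == 1 and a.sum() > 0:
            return a


def union_find_components(a: np.ndarray) -> int:
    n = len(a)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    comps = n
    for i, j in zip(*np.nonzero(np.triu(a, 1))):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[ri] = rj
            comps -= 1
    return comps


def brute_clustering(a: np.ndarray) -> np.ndarray:
    """C_i by counting connected neighbour pairs directly."""
    n = len(a)
    c = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        d = len(nbrs)
        if d < 2:
            continue
        tri = sum(a[u, v] for u, v in itertools.combinations(nbrs, 2))
        c[i] = tri / (d * (d - 1) / 2)
    return c


def floyd_warshall(a: np.ndarray) -> np.ndarray:
    """All-pairs distances by dynamic programming over intermediate nodes."""
    n = len(a)
    d = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


def brute_betweenness(a: np.ndarray) -> np.ndarray:
    """B_i by exhaustively enumerating every shortest path of every pair.

    Uses Floyd-Warshall distances only to bound the search depth; path
    enumeration itself is plain DFS over simple paths.
    """
    n = len(a)
    dist = floyd_warshall(a)
    adj = [np.flatnonzero(a[i]).tolist() for i in range(n)]
    b = np.zeros(n)
    for j, k in itertools.combinations(range(n), 2):
        if not np.isfinite(dist[j, k]):
            continue
        target = int(dist[j, k])
        paths: list[tuple[int, ...]] = []

        def dfs(node, path):
            if len(path) - 1 > target:
                return
            if node == k:
                if len(path) - 1 == target:
                    paths.append(tuple(path))
                return
            for w in adj[node]:
                if w not in path:
                    dfs(w, path + [w])

        dfs(j, [j])
        sigma = len(paths)
        interior = [p[1:-1] for p in paths]
        for i in range(n):
            if i in (j, k):
                continue
            through = sum(1 for mid in interior if i in mid)
            if through:
                b[i] += through / sigma
    return b
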