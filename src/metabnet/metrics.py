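"""Nodal and global topology of binary brain networks.

Implements the classical small-world toolkit on undirected, unweighted graphs:

* clustering coefficient C_i = 2 E_i / (D_i (D_i - 1)), with E_i the edge count
  among node i's neighbours (C_i = 0 for degree < 2, where the ratio is 0/0);
  C_p is the mean over all nodes;
* per-node path length L_i = mean shortest-path distance from i to every other
  node (breadth-first distances); the characteristic path length L_p is the
  mean of L_i over nodes, which for undirected graphs equals the all-pairs mean;
* betweenness centrality B_i = sum over unordered pairs (j, k), j != k != i, of
  the fraction of shortest j-k paths passing through i (unnormalized; Brandes'
  accumulation);
* small-world ratios gamma = C_p / C_random and lambda = L_p / L_random against
  an ensemble of degree-preserving random rewirings (Maslov-Sneppen double edge
  swaps), with sigma = gamma / lambda;
* hubs: nodes whose betweenness exceeds twice the network mean.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .network import BinaryNetwork, component_sizes, is_connected


class DisconnectedNetworkError(ValueError):
    """Path-length metrics are undefined on a disconnected graph."""

    def __init__(self, sizes: list[int]):
        self.component_sizes = sizes
        super().__init__(
            f"network is disconnected (component sizes {sorted(sizes, reverse=True)}); "
            "path length undefined"
        )


def clustering(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their mean C_p."""
    a = net.A.astype(float)
    deg = a.sum(axis=0)
    # (A^3)_ii = 2 * (#triangles at i) = 2 * E_i for a simple graph
    e_i = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, e_i / denom, 0.0)
    return c, float(c.mean())


def _bfs_distances(net: BinaryNetwork) -> np.ndarray:
    return shortest_path(csr_matrix(net.A), method="D", unweighted=True, directed=False)


def path_length(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node mean shortest-path distance L_i and their mean L_p.

    Rejects disconnected input (component sizes reported) rather than silently
    folding infinite distances into the average.
    """
    if not is_connected(net):
        raise DisconnectedNetworkError(component_sizes(net))
    d = _bfs_distances(net)
    n = net.n_nodes
    l_i = d.sum(axis=1) / (n - 1)
    return l_i, float(l_i.mean())


def betweenness(net: BinaryNetwork, normalized: bool = False) -> np.ndarray:
    """Brandes betweenness over unordered pairs, endpoints excluded, unnormalized.

    Pairs with no connecting path contribute zero, so the measure is defined on
    disconnected graphs too. ``normalized=True`` divides by (N-1)(N-2)/2.
    """
    n = net.n_nodes
    adj = [np.flatnonzero(net.A[i]).tolist() for i in range(n)]
    b = np.zeros(n)
    for s in range(n):
        stack: list[int] = []
        preds: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                b[w] += delta[w]
    b /= 2.0  # each unordered pair counted from both endpoints
    if normalized:
        b /= (n - 1) * (n - 2) / 2.0
    return b


@dataclass
class NodalMetrics:
    """Degree, clustering, path length, and betweenness per node."""

    regions: list[str]
    degree: np.ndarray
    clustering: np.ndarray
    path_length: np.ndarray
    betweenness: np.ndarray

    def to_frame(self, hubs: "HubSet | None" = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "region": self.regions,
                "degree": self.degree,
                "clustering": self.clustering,
                "path_length": self.path_length,
                "betweenness": self.betweenness,
            }
        )
        if hubs is not None:
            df["hub"] = df["region"].isin(hubs.regions)
        return df


def nodal_metrics(net: BinaryNetwork) -> NodalMetrics:
    c, _ = clustering(net)
    l_i, _ = path_length(net)
    b = betweenness(net)
    return NodalMetrics(
        list(net.regions), net.A.sum(axis=0).astype(int), c, l_i, b
    )


# ---------------------------------------------------------------------------
# degree-preserving null ensemble
# ---------------------------------------------------------------------------


def rewire_degree_preserving(
    net: BinaryNetwork,
    rng: np.random.Generator,
    swap_factor: int = 10,
    require_connected: bool = True,
    max_retries: int = 100,
) -> BinaryNetwork:
    """One Maslov-Sneppen randomization of ``net``.

    Attempts ``swap_factor * E`` double edge swaps, rejecting any swap that
    would create a self-loop or duplicate edge. If ``require_connected``, the
    rewired graph is re-randomized from scratch (bounded retries) until it is
    connected, so that path-based null metrics are always defined.
    """
    base_edges = net.edges()
    e = len(base_edges)
    n = net.n_nodes
    if e < 2:
        return BinaryNetwork(net.A.copy(), net.sparsity, list(net.regions))
    n_attempts = swap_factor * e
    for _ in range(max_retries):
        edges = base_edges.copy()
        present = net.A.astype(bool).copy()
        idx = rng.integers(0, e, size=(n_attempts, 2))
        flip = rng.integers(0, 2, size=n_attempts)
        for t in range(n_attempts):
            p, q = idx[t]
            if p == q:
                continue
            a, b = edges[p]
            c, d = edges[q]
            if flip[t]:
                c, d = d, c
            # propose (a, c) and (b, d)
            if a == c or b == d or present[a, c] or present[b, d]:
                continue
            present[a, b] = present[b, a] = False
            present[c, d] = present[d, c] = False
            present[a, c] = present[c, a] = True
            present[b, d] = present[d, b] = True
            edges[p] = (a, c) if a < c else (c, a)
            edges[q] = (b, d) if b < d else (d, b)
        a_new = np.zeros((n, n), dtype=np.int8)
        a_new[present] = 1
        out = BinaryNetwork(a_new, net.sparsity, list(net.regions))
        if not require_connected or is_connected(out):
            return out
    raise ValueError(
        f"could not obtain a connected degree-matched rewiring in {max_retries} tries"
    )


@dataclass
class NullEnsemble:
    """Degree-matched random-network ensemble with per-draw C_p and L_p."""

    c_values: np.ndarray
    l_values: np.ndarray
    n_rand: int
    seed: int
    swap_factor: int

    @property
    def C_random(self) -> float:
        return float(self.c_values.mean())

    @property
    def L_random(self) -> float:
        return float(self.l_values.mean())

    def summary(self) -> dict:
        return {
            "n_rand": self.n_rand,
            "seed": self.seed,
            "swap_factor": self.swap_factor,
            "C_random": self.C_random,
            "C_random_sd": float(self.c_values.std(ddof=1)) if self.n_rand > 1 else 0.0,
            "L_random": self.L_random,
            "L_random_sd": float(self.l_values.std(ddof=1)) if self.n_rand > 1 else 0.0,
        }


def random_null_ensemble(
    net: BinaryNetwork,
    n_rand: int = 1000,
    seed: int = 0,
    swap_factor: int = 10,
) -> NullEnsemble:
    """C_random and L_random from ``n_rand`` connected degree-matched rewirings."""
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if not is_connected(net):
        raise DisconnectedNetworkError(component_sizes(net))
    rng = np.random.default_rng(seed)
    c_vals = np.empty(n_rand)
    l_vals = np.empty(n_rand)
    for k in range(n_rand):
        null = rewire_degree_preserving(net, rng, swap_factor=swap_factor)
        _, c_vals[k] = clustering(null)
        _, l_vals[k] = path_length(null)
    return NullEnsemble(c_vals, l_vals, n_rand, seed, swap_factor)


@dataclass
class GlobalMetrics:
    """Global topology with small-world normalization against the null ensemble."""

    C_p: float
    L_p: float
    C_random: float
    L_random: float
    gamma: float
    lambda_: float
    sigma: float | None
    null_summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "C_p": self.C_p,
            "L_p": self.L_p,
            "C_random": self.C_random,
            "L_random": self.L_random,
            "gamma": self.gamma,
            "lambda": self.lambda_,
            "sigma": self.sigma,
            "null": self.null_summary,
        }


def small_world(net: BinaryNetwork, nulls: NullEnsemble) -> GlobalMetrics:
    """gamma = C_p / C_random, lambda = L_p / L_random, sigma = gamma / lambda."""
    _, c_p = clustering(net)
    _, l_p = path_length(net)
    c_rand, l_rand = nulls.C_random, nulls.L_random
    lam = float(l_p / l_rand)
    if c_rand == 0:
        # null ensemble has no clustering: gamma (and hence sigma) undefined
        return GlobalMetrics(c_p, l_p, c_rand, l_rand, float("nan"), lam, None,
                             nulls.summary())
    gamma = float(c_p / c_rand)
    return GlobalMetrics(c_p, l_p, c_rand, l_rand, gamma, lam, gamma / lam,
                         nulls.summary())


@dataclass
class HubSet:
    """Nodes whose betweenness strictly exceeds twice the network mean."""

    regions: list[str]
    threshold: float

    def __contains__(self, name: str) -> bool:
        return name in self.regions

    @property
    def count(self) -> int:
        return len(self.regions)


def find_hubs(b: np.ndarray, regions: list[str]) -> HubSet:
    """Hub rule: B_i > 2 * mean(B). All-zero betweenness yields an empty set."""
    b = np.asarray(b, dtype=float)
    thr = 2.0 * b.mean()
    idx = np.flatnonzero(b > thr)
    return HubSet([regions[i] for i in idx], float(thr))
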