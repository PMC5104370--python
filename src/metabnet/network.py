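"""Group covariance-network construction and sparsity-based binarization.

A group's network is the N x N matrix of Pearson correlations between regional
metabolism values across that group's subjects (one network per group, not per
subject). The matrix is reduced to an undirected, unweighted graph by keeping
the E = round(S * N(N-1)/2) strongest pairwise correlations, where the sparsity
S in (0, 1) is the fraction of realized edges among all possible node pairs —
a data-driven threshold that equates edge counts across groups.

Ranking is by signed correlation by default (an edge exists where R_ij exceeds
the data-derived threshold); an "absolute" ranking mode is available. Ties are
broken deterministically by ascending (i, j) index order, and the edge count
uses round-half-away-from-zero, so results are reproducible to the bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .stats import NormalizedMatrix

RANKINGS = ("signed", "absolute")


@dataclass
class CorrelationNetwork:
    """Symmetric inter-regional Pearson matrix with unit diagonal."""

    R: np.ndarray
    n_subjects: int
    group: str
    regions: list[str]

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if R.shape != (len(self.regions), len(self.regions)):
            raise ValueError("R shape does not match region list")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ValueError("R diagonal must be 1")
        if np.nanmax(np.abs(R)) > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")
        if self.n_subjects < 4:
            raise ValueError("need at least 4 subjects (n - 3 > 0 for Fisher SE)")
        self.R = R

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.R, index=self.regions, columns=self.regions).to_csv(path)


@dataclass
class BinaryNetwork:
    """Undirected, unweighted adjacency at a stated sparsity (zero diagonal)."""

    A: np.ndarray
    sparsity: float
    regions: list[str]

    def __post_init__(self) -> None:
        A = np.asarray(self.A)
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.diag(A).any():
            raise ValueError("adjacency diagonal must be 0")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        self.A = A.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return len(self.A)

    @property
    def edge_count(self) -> int:
        return int(np.triu(self.A, 1).sum())

    def edges(self) -> np.ndarray:
        """(E, 2) array of upper-triangular edge index pairs."""
        return np.column_stack(np.nonzero(np.triu(self.A, 1)))

    def to_edge_tsv(self, path: str | Path) -> None:
        e = self.edges()
        pd.DataFrame(
            {
                "region_a": [self.regions[i] for i in e[:, 0]],
                "region_b": [self.regions[j] for j in e[:, 1]],
            }
        ).to_csv(path, sep="\t", index=False)

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.regions)
        for i, j in self.edges():
            g.add_edge(self.regions[i], self.regions[j])
        nx.write_graphml(g, path)


def correlation_network(norm: NormalizedMatrix, group: str) -> CorrelationNetwork:
    """Pearson correlation of every region pair across one group's subjects."""
    x = norm.group_values(group)
    n = len(x)
    if n < 4:
        raise ValueError(f"group {group!r} has {n} subjects; need >= 4")
    spread = np.ptp(x, axis=0)
    if (spread == 0).any():
        bad = [norm.region_names[j] for j in np.flatnonzero(spread == 0)]
        raise ValueError(f"constant region column(s) in group {group!r}: {bad}")
    R = np.corrcoef(x, rowvar=False)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return CorrelationNetwork(R, n, group, list(norm.region_names))


def edge_count_at_sparsity(n_nodes: int, sparsity: float) -> int:
    """E = round-half-away-from-zero(S * N(N-1)/2)."""
    m = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(sparsity * m + 0.5))


def _ranked_pairs(net: CorrelationNetwork, ranking: str) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangular pairs ordered strongest-first with (i, j) tie-break."""
    if ranking not in RANKINGS:
        raise ValueError(f"unknown ranking {ranking!r}")
    ii, jj = np.triu_indices(net.n_regions, k=1)
    vals = net.R[ii, jj]
    if ranking == "absolute":
        vals = np.abs(vals)
    # primary key: descending value; ties: ascending (i, j)
    order = np.lexsort((jj, ii, -vals))
    return ii[order], jj[order]


def binarize_at_sparsity(
    net: CorrelationNetwork, sparsity: float, ranking: str = "signed"
) -> BinaryNetwork:
    """Adjacency keeping the E strongest correlation pairs at the given sparsity."""
    if not 0 < sparsity < 1:
        raise ValueError("sparsity must lie strictly between 0 and 1")
    e = edge_count_at_sparsity(net.n_regions, sparsity)
    ii, jj = _ranked_pairs(net, ranking)
    a = np.zeros((net.n_regions, net.n_regions), dtype=np.int8)
    a[ii[:e], jj[:e]] = 1
    a += a.T
    return BinaryNetwork(a, sparsity, list(net.regions))


def sparsity_grid(s_min: float, s_max: float, step: float) -> np.ndarray:
    if s_min > s_max or step <= 0:
        raise ValueError("need s_min <= s_max and step > 0")
    k = int(np.floor((s_max - s_min) / step + 1e-9))
    return s_min + step * np.arange(k + 1)


def sparsity_sweep(
    net: CorrelationNetwork,
    s_min: float = 0.24,
    s_max: float = 0.50,
    step: float = 0.01,
    ranking: str = "signed",
) -> list[BinaryNetwork]:
    """One binary network per grid point; edge sets nest as S grows."""
    return [binarize_at_sparsity(net, s, ranking) for s in sparsity_grid(s_min, s_max, step)]


def is_connected(net: BinaryNetwork) -> bool:
    """True iff a single component spans all nodes."""
    n_comp, _ = connected_components(csr_matrix(net.A), directed=False)
    return n_comp == 1


def component_sizes(net: BinaryNetwork) -> list[int]:
    _, labels = connected_components(csr_matrix(net.A), directed=False)
    return np.bincount(labels).tolist()


def min_connected_sparsity(net: CorrelationNetwork, ranking: str = "signed") -> float:
    """Smallest sparsity E/M at which the thresholded graph is fully connected.

    Adds ranked edges one at a time and reports the first edge count that
    yields a spanning component, expressed as a fraction of all pairs.
    """
    n = net.n_regions
    m = n * (n - 1) // 2
    ii, jj = _ranked_pairs(net, ranking)
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    n_comp = n
    for k in range(m):
        ra, rb = find(ii[k]), find(jj[k])
        if ra != rb:
            parent[ra] = rb
            n_comp -= 1
            if n_comp == 1:
                return (k + 1) / m
    raise ValueError("graph never connects (isolated node in correlation matrix)")
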