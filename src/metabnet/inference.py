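"""Between-group inference on network quantities.

Global metrics (C_p, L_p) are compared with a label-shuffling permutation test:
subjects from both groups are pooled and randomly reassigned into two groups of
the original sizes, both covariance networks are rebuilt at every sparsity, and
the observed difference (patients minus controls) is referred to the resulting
permutation distribution. The two-sided p uses the add-one estimator
p = (#{|delta_perm| >= |delta_obs|} + 1) / (B_valid + 1), and the 95% interval
is the empirical 2.5-97.5 percentile band of the permutation draws. Covariate
adjustment is done once on the pooled sample before permuting: the fit uses
only age and gender, never group labels, so refitting inside each draw would
reproduce identical residuals.

Edge-wise comparison uses Fisher's r-to-z transform: for each region pair,
Z = (z_patient - z_control) / sqrt(1/(n_p - 3) + 1/(n_c - 3)) with a two-sided
normal p, uncorrected by default. Significant pairs are classed as increases or
decreases and as long-range (centroid Euclidean distance > 75 mm) or
short-range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .atlas import RegionTable
from .metrics import HubSet, betweenness, clustering, path_length
from .network import (
    BinaryNetwork,
    CorrelationNetwork,
    _ranked_pairs,
    edge_count_at_sparsity,
)
from .simulate import CANCER
from .stats import NormalizedMatrix

GLOBAL_METRICS = ("C_p", "L_p")
DEFAULT_LONG_RANGE_MM = 75.0


@dataclass
class PermutationResult:
    """Observed group difference of one metric with its permutation distribution."""

    metric: str
    sparsity: float
    observed: float
    draws: np.ndarray
    p: float
    ci: tuple[float, float]
    n_permutations: int
    n_invalid: int
    seed: int

    @property
    def outside_ci(self) -> bool:
        """Alternative significance reading: observed outside the 95% null band."""
        return not (self.ci[0] <= self.observed <= self.ci[1])

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "sparsity": self.sparsity,
            "delta": self.observed,
            "p": self.p,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "n_permutations": self.n_permutations,
            "n_invalid": self.n_invalid,
            "seed": self.seed,
        }


def _corr(x: np.ndarray) -> np.ndarray:
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def _grid_metric(x: np.ndarray, s_list: np.ndarray, metric: str, ranking: str,
                 regions: list[str]) -> np.ndarray:
    """Metric value at each sparsity for one group's subject matrix.

    Builds the adjacency incrementally along the ranked pair order so the
    sweep costs one sort. Disconnected graphs yield NaN for L_p.
    """
    n = x.shape[1]
    net = CorrelationNetwork.__new__(CorrelationNetwork)  # skip revalidation
    net.R = _corr(x)
    net.n_subjects = len(x)
    net.group = ""
    net.regions = regions
    ii, jj = _ranked_pairs(net, ranking)
    order = np.argsort(s_list)
    a = np.zeros((n, n), dtype=np.int8)
    e_prev = 0
    out = np.empty(len(s_list))
    for k in order:
        e = edge_count_at_sparsity(n, s_list[k])
        sel = slice(e_prev, e)
        a[ii[sel], jj[sel]] = 1
        a[jj[sel], ii[sel]] = 1
        e_prev = max(e_prev, e)
        bnet = BinaryNetwork(a.copy(), float(s_list[k]), regions)
        if metric == "C_p":
            out[k] = clustering(bnet)[1]
        elif metric == "L_p":
            try:
                out[k] = path_length(bnet)[1]
            except ValueError:
                out[k] = np.nan
        else:
            raise ValueError(f"unknown global metric {metric!r}")
    return out


def _perm_p_and_ci(observed: float, draws: np.ndarray) -> tuple[float, tuple[float, float], int]:
    valid = draws[np.isfinite(draws)]
    n_invalid = len(draws) - len(valid)
    if len(valid) == 0:
        return float("nan"), (float("nan"), float("nan")), n_invalid
    p = (np.sum(np.abs(valid) >= abs(observed)) + 1) / (len(valid) + 1)
    lo, hi = np.percentile(valid, [2.5, 97.5])
    return float(p), (float(lo), float(hi)), n_invalid


def permute_metric(
    norm: NormalizedMatrix,
    metric: str,
    s_grid,
    n_permutations: int = 1000,
    seed: int = 0,
    ranking: str = "signed",
) -> list[PermutationResult]:
    """Group-difference permutation test for a global metric across sparsities.

    Returns one :class:`PermutationResult` per sparsity, each with the observed
    patients-minus-controls difference, the full permutation distribution, the
    add-one two-sided p, and the 95% permutation interval. Draws where a
    permuted group's network disconnects (path-based metrics only) are recorded
    as invalid and excluded from p and interval, with the count reported.
    """
    if metric not in GLOBAL_METRICS:
        raise ValueError(f"metric must be one of {GLOBAL_METRICS}")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    s_list = np.atleast_1d(np.asarray(s_grid, dtype=float))
    values = norm.values.to_numpy(dtype=float)
    labels = norm.covariates["group"].to_numpy()
    mask_cancer = labels == CANCER
    regions = list(norm.region_names)

    def delta_for(mask: np.ndarray, vals: np.ndarray) -> np.ndarray:
        return _grid_metric(vals[mask], s_list, metric, ranking, regions) - _grid_metric(
            vals[~mask], s_list, metric, ranking, regions
        )

    observed = delta_for(mask_cancer, values)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_permutations, len(s_list)))
    for b in range(n_permutations):
        perm = rng.permutation(len(labels))
        perm_mask = np.zeros(len(labels), dtype=bool)
        perm_mask[perm[: mask_cancer.sum()]] = True
        draws[b] = delta_for(perm_mask, values)

    results = []
    for k, s in enumerate(s_list):
        p, ci, n_inv = _perm_p_and_ci(observed[k], draws[:, k])
        results.append(
            PermutationResult(metric, float(s), float(observed[k]), draws[:, k].copy(),
                              p, ci, n_permutations, n_inv, seed)
        )
    return results


# ---------------------------------------------------------------------------
# edge-wise Fisher-z comparison
# ---------------------------------------------------------------------------


@dataclass
class EdgeComparison:
    """Per-pair Fisher-z comparison with long/short-range classification.

    ``table`` has one row per region pair (upper triangle): correlations and z
    values in both groups, the Z statistic, two-sided p, significance at alpha,
    direction (increase/decrease in patients), centroid distance and range
    class. ``involvement`` counts, per region, the significant pairs it touches.
    """

    table: pd.DataFrame
    involvement: pd.Series
    alpha: float
    long_range_mm: float
    n_excluded: int


def compare_edges(
    net_nc: CorrelationNetwork,
    net_cancer: CorrelationNetwork,
    regions: RegionTable,
    alpha: float = 0.01,
    long_range_mm: float = DEFAULT_LONG_RANGE_MM,
    fdr: bool = False,
) -> EdgeComparison:
    """Fisher r-to-z comparison of every inter-regional correlation pair."""
    if net_nc.regions != net_cancer.regions or net_nc.regions != regions.names:
        raise ValueError("both networks must be defined over the given region table")
    n = regions.n_regions
    ii, jj = np.triu_indices(n, k=1)
    r_n = net_nc.R[ii, jj]
    r_c = net_cancer.R[ii, jj]
    finite = (np.abs(r_n) < 1.0) & (np.abs(r_c) < 1.0)
    n_excluded = int((~finite).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} pair(s) with |r| = 1 excluded (infinite Fisher z)"
        )
    se = np.sqrt(1.0 / (net_cancer.n_subjects - 3) + 1.0 / (net_nc.n_subjects - 3))
    z_n = np.where(finite, np.arctanh(np.where(finite, r_n, 0.0)), np.nan)
    z_c = np.where(finite, np.arctanh(np.where(finite, r_c, 0.0)), np.nan)
    z_stat = (z_c - z_n) / se
    p = 2.0 * sps.norm.sf(np.abs(z_stat))
    p_eff = multipletests(p[finite], method="fdr_bh")[1] if fdr else p[finite]
    sig = np.zeros(len(ii), dtype=bool)
    sig[finite] = p_eff < alpha
    dist = regions.distance_matrix()[ii, jj]
    names = regions.names
    table = pd.DataFrame(
        {
            "region_a": [names[i] for i in ii],
            "region_b": [names[j] for j in jj],
            "r_nc": r_n,
            "r_cancer": r_c,
            "z_nc": z_n,
            "z_cancer": z_c,
            "Z": z_stat,
            "p": p,
            "significant": sig,
            "direction": np.where(z_stat > 0, "increase", "decrease"),
            "distance_mm": dist,
            "range": np.where(dist > long_range_mm, "long", "short"),
        }
    )
    counts = pd.Series(0, index=names, dtype=int)
    sig_rows = table[table["significant"]]
    for col in ("region_a", "region_b"):
        counts = counts.add(sig_rows[col].value_counts(), fill_value=0)
    return EdgeComparison(table, counts.astype(int), alpha, long_range_mm, n_excluded)


# ---------------------------------------------------------------------------
# hubs and nodal betweenness
# ---------------------------------------------------------------------------


@dataclass
class HubComparison:
    """Partition of two groups' hubs into control-only, patient-only, shared."""

    nc_only: list[str]
    cancer_only: list[str]
    shared: list[str]

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.nc_only), len(self.cancer_only), len(self.shared))


def hub_overlap(hubs_nc: HubSet, hubs_cancer: HubSet) -> HubComparison:
    a, b = set(hubs_nc.regions), set(hubs_cancer.regions)
    return HubComparison(sorted(a - b), sorted(b - a), sorted(a & b))


@dataclass
class NodalPermutationResult:
    """Per-node betweenness differences with permutation p and signed labels."""

    table: pd.DataFrame
    sparsity: float
    n_permutations: int
    alpha: float
    seed: int


def nodal_betweenness_differences(
    norm: NormalizedMatrix,
    sparsity: float = 0.24,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    ranking: str = "signed",
) -> NodalPermutationResult:
    """Permutation test of per-node betweenness (patients minus controls).

    Betweenness is defined on disconnected graphs (unreachable pairs contribute
    zero), so every permutation draw is valid. Nodes significant at ``alpha``
    are labelled "higher" or "lower" in patients by the sign of the observed
    difference.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    values = norm.values.to_numpy(dtype=float)
    labels = norm.covariates["group"].to_numpy()
    mask_cancer = labels == CANCER
    regions = list(norm.region_names)
    n = len(regions)

    def nodal_b(vals: np.ndarray, mask: np.ndarray) -> np.ndarray:
        out = np.empty((2, n))
        for row, m in enumerate((mask, ~mask)):
            net = CorrelationNetwork.__new__(CorrelationNetwork)
            net.R = _corr(vals[m])
            net.n_subjects = int(m.sum())
            net.group = ""
            net.regions = regions
            ii, jj = _ranked_pairs(net, ranking)
            e = edge_count_at_sparsity(n, sparsity)
            a = np.zeros((n, n), dtype=np.int8)
            a[ii[:e], jj[:e]] = 1
            a += a.T
            out[row] = betweenness(BinaryNetwork(a, sparsity, regions))
        return out[0] - out[1]

    observed = nodal_b(values, mask_cancer)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_permutations, n))
    for b in range(n_permutations):
        perm = rng.permutation(len(labels))
        perm_mask = np.zeros(len(labels), dtype=bool)
        perm_mask[perm[: mask_cancer.sum()]] = True
        draws[b] = nodal_b(values, perm_mask)

    p = (np.sum(np.abs(draws) >= np.abs(observed)[None, :], axis=0) + 1) / (
        n_permutations + 1
    )
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    sig = p < alpha
    label = np.where(sig & (observed > 0), "higher",
                     np.where(sig & (observed < 0), "lower", "ns"))
    table = pd.DataFrame(
        {
            "region": regions,
            "delta_betweenness": observed,
            "p": p,
            "ci_low": lo,
            "ci_high": hi,
            "label": label,
        }
    )
    return NodalPermutationResult(table, float(sparsity), n_permutations, alpha, seed)
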