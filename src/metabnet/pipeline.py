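"""End-to-end orchestration: cohort -> normalization -> networks -> inference.

``run_pipeline`` executes every stage in order and writes all intermediate
artifacts (correlation matrices, edge lists, metric tables, inference JSON)
plus a single summary (JSON + Markdown) stamped with the config hash, package
version, and the per-stage seeds, so an identical config reproduces
byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import RegionTable, load_regions
from .config import AnalysisConfig
from .inference import (
    compare_edges,
    hub_overlap,
    nodal_betweenness_differences,
    permute_metric,
)
from .metrics import (
    DisconnectedNetworkError,
    betweenness,
    clustering,
    find_hubs,
    path_length,
    random_null_ensemble,
    small_world,
)
from .network import (
    binarize_at_sparsity,
    correlation_network,
    is_connected,
    min_connected_sparsity,
    sparsity_grid,
)
from .simulate import CANCER, GROUPS, NC, Cohort
from .stats import bdi_correlation, demographics_table, group_region_test, normalize_and_adjust

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Input table violates the cohort schema."""


class ConnectivityError(RuntimeError):
    """A group network is disconnected at the fixed analysis sparsity."""

    def __init__(self, group: str, sparsity: float, min_connected: float):
        self.group = group
        self.sparsity = sparsity
        self.min_connected = min_connected
        super().__init__(
            f"group {group!r} network disconnected at sparsity {sparsity:.2f}; "
            f"minimum connected sparsity is {min_connected:.4f}"
        )


def validate_cohort(path: str | Path, regions: RegionTable) -> list[dict]:
    """Schema check for a cohort CSV; returns a machine-readable issue list."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed file is an I/O problem, not schema
        raise OSError(f"cannot read cohort CSV {path}: {exc}") from exc
    issues: list[dict] = []
    for col in ("subject_id", "group", "age", "gender", "bdi"):
        if col not in df.columns:
            issues.append({"code": "missing_column", "column": col,
                           "message": f"required column {col!r} absent"})
    for name in regions.names:
        if name not in df.columns:
            issues.append({"code": "missing_region", "column": name,
                           "message": f"region column {name!r} absent"})
    if issues:
        return issues
    bad_groups = sorted(set(df["group"].unique()) - set(GROUPS))
    if bad_groups:
        issues.append({"code": "bad_group_label", "message":
                       f"unknown group labels {bad_groups}; expected {list(GROUPS)}"})
    for g in GROUPS:
        if (df["group"] == g).sum() < 4:
            issues.append({"code": "group_too_small",
                           "message": f"group {g!r} has fewer than 4 subjects"})
    x = df[regions.names]
    if x.isna().any().any():
        rows, cols = np.nonzero(x.isna().to_numpy())
        issues.append({"code": "missing_metabolism", "row": int(rows[0]),
                       "column": regions.names[cols[0]],
                       "message": "missing metabolism value(s)"})
    elif (x.to_numpy(dtype=float) < 0).any():
        rows, cols = np.nonzero(x.to_numpy(dtype=float) < 0)
        issues.append({"code": "negative_metabolism", "row": int(rows[0]),
                       "column": regions.names[cols[0]],
                       "message": "negative metabolism value(s)"})
    patient_bdi = df.loc[df["group"] == CANCER, "bdi"]
    if patient_bdi.isna().any():
        issues.append({"code": "missing_bdi",
                       "message": "BDI absent for some patient-group subjects; "
                                  "depression analyses unavailable"})
    return issues


@dataclass
class PipelineReport:
    """Locations and headline numbers of a completed run."""

    output_dir: Path
    summary: dict
    artifacts: dict = field(default_factory=dict)


def run_pipeline(config: AnalysisConfig) -> PipelineReport:
    """Run the full analysis described by ``config`` and write all artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    regions = load_regions(config.regions_csv)

    if config.cohort_csv is None:
        raise SchemaError("config.cohort_csv is required (use `metabnet simulate` first)")
    issues = validate_cohort(config.cohort_csv, regions)
    fatal = [i for i in issues if i["code"] != "missing_bdi"]
    if fatal:
        raise SchemaError(f"cohort schema violations: {fatal}")
    cohort = Cohort.from_csv(config.cohort_csv, regions)
    bdi_available = not any(i["code"] == "missing_bdi" for i in issues)

    artifacts: dict[str, str] = {}

    def save(name: str, writer) -> Path:
        p = out / name
        writer(p)
        artifacts[name] = str(p)
        return p

    # --- regional statistics ----------------------------------------------
    norm = normalize_and_adjust(cohort, mode=config.normalization)
    demo = demographics_table(cohort)
    save("demographics.csv", lambda p: demo.table.to_csv(p))
    group_stats = group_region_test(norm, alpha=config.fdr_alpha)
    save("region_group_test.csv", group_stats.to_csv)
    bdi_stats = None
    if bdi_available:
        bdi_stats = bdi_correlation(norm, alpha=config.fdr_alpha)
        save("region_bdi_correlation.csv", bdi_stats.to_csv)
    else:
        logger.warning("BDI missing for some patients; skipping depression analysis")

    # --- networks ----------------------------------------------------------
    nets = {g: correlation_network(norm, g) for g in GROUPS}
    for g, net in nets.items():
        save(f"correlation_{g}.csv", net.to_csv)
    fixed = {}
    connectivity = {}
    for g, net in nets.items():
        bnet = binarize_at_sparsity(net, config.fixed_sparsity, config.ranking)
        fixed[g] = bnet
        connectivity[g] = {
            "connected": is_connected(bnet),
            "min_connected_sparsity": min_connected_sparsity(net, config.ranking),
        }
        if not connectivity[g]["connected"]:
            raise ConnectivityError(
                g, config.fixed_sparsity, connectivity[g]["min_connected_sparsity"]
            )
        save(f"edges_{g}_S{config.fixed_sparsity:.2f}.tsv", bnet.to_edge_tsv)
        save(f"network_{g}_S{config.fixed_sparsity:.2f}.graphml", bnet.to_graphml)

    # --- metrics and small-world normalization -----------------------------
    s_grid = sparsity_grid(config.sparsity_min, config.sparsity_max, config.sparsity_step)
    sweep_rows = []
    for g, net in nets.items():
        for s in s_grid:
            bn = binarize_at_sparsity(net, float(s), config.ranking)
            _, c_p = clustering(bn)
            try:
                _, l_p = path_length(bn)
            except DisconnectedNetworkError:
                l_p = float("nan")
            sweep_rows.append({"group": g, "sparsity": float(s), "C_p": c_p, "L_p": l_p})
    sweep_df = pd.DataFrame(sweep_rows)
    save("global_metrics_sweep.csv", lambda p: sweep_df.to_csv(p, index=False))

    null_seed = config.substream_seed("nulls")
    small_world_results = {}
    hubs = {}
    for g, bnet in fixed.items():
        nulls = random_null_ensemble(
            bnet, n_rand=config.n_random_networks, seed=null_seed
        )
        gm = small_world(bnet, nulls)
        small_world_results[g] = gm.to_dict()
        b = betweenness(bnet)
        hubs[g] = find_hubs(b, list(bnet.regions))
        metrics_df = pd.DataFrame(
            {
                "region": bnet.regions,
                "degree": bnet.A.sum(axis=0),
                "clustering": clustering(bnet)[0],
                "path_length": path_length(bnet)[0],
                "betweenness": b,
                "hub": [r in hubs[g] for r in bnet.regions],
            }
        )
        save(f"nodal_metrics_{g}.csv", lambda p, df=metrics_df: df.to_csv(p, index=False))
    save(
        "small_world.json",
        lambda p: p.write_text(json.dumps(small_world_results, indent=2)),
    )
    overlap = hub_overlap(hubs[NC], hubs[CANCER])

    # --- inference ----------------------------------------------------------
    perm_seed = config.substream_seed("permutations")
    perm_rows = []
    for metric in ("C_p", "L_p"):
        for res in permute_metric(
            norm, metric, s_grid, config.n_permutations, perm_seed, config.ranking
        ):
            perm_rows.append(res.to_dict())
    perm_df = pd.DataFrame(perm_rows)
    save("permutation_global.csv", lambda p: perm_df.to_csv(p, index=False))

    nodal = nodal_betweenness_differences(
        norm,
        sparsity=config.fixed_sparsity,
        n_permutations=config.n_permutations,
        seed=config.substream_seed("nodal"),
        alpha=config.nodal_alpha,
        ranking=config.ranking,
    )
    save("nodal_betweenness_diff.csv", lambda p: nodal.table.to_csv(p, index=False))

    edges = compare_edges(
        nets[NC], nets[CANCER], regions,
        alpha=config.edge_alpha, long_range_mm=config.long_range_mm,
    )
    save("edge_comparison.tsv",
         lambda p: edges.table.to_csv(p, sep="\t", index=False))

    # --- summary ------------------------------------------------------------
    sig_perm = perm_df[perm_df["p"] < 0.05]
    summary = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": {k: v for k, v in config.__dict__.items() if k != "output_dir"},
        "seeds": {name: config.substream_seed(name)
                  for name in ("cohort", "nulls", "permutations", "nodal")},
        "n_subjects": {g: int(cohort.group_mask(g).sum()) for g in GROUPS},
        "demographics": {"gender_chi2_p": demo.gender_p, "age_t_p": demo.age_p},
        "regions_flagged_group_test": group_stats.flagged,
        "regions_flagged_bdi": bdi_stats.flagged if bdi_stats is not None else None,
        "connectivity": connectivity,
        "small_world": small_world_results,
        "hubs": {
            NC: hubs[NC].regions,
            CANCER: hubs[CANCER].regions,
            "nc_only": overlap.nc_only,
            "cancer_only": overlap.cancer_only,
            "shared": overlap.shared,
        },
        "significant_global_permutations": sig_perm.to_dict(orient="records"),
        "edge_comparison": {
            "n_significant": int(edges.table["significant"].sum()),
            "n_long_range_significant": int(
                (edges.table["significant"] & (edges.table["range"] == "long")).sum()
            ),
            "n_excluded": edges.n_excluded,
        },
        "nodal_betweenness": {
            "higher_in_cancer": nodal.table.loc[nodal.table["label"] == "higher",
                                                "region"].tolist(),
            "lower_in_cancer": nodal.table.loc[nodal.table["label"] == "lower",
                                               "region"].tolist(),
        },
    }
    save("summary.json",
         lambda p: p.write_text(json.dumps(summary, indent=2, default=float)))
    save("summary.md", lambda p: p.write_text(_summary_markdown(summary, demo)))
    return PipelineReport(out, summary, artifacts)


def _summary_markdown(summary: dict, demo) -> str:
    sw = summary["small_world"]
    lines = [
        "# Metabolic covariance network analysis",
        "",
        f"- version: {summary['version']}",
        f"- config hash: {summary['config_hash']}",
        f"- seeds: {summary['seeds']}",
        "",
        "## Demographics",
        "",
        demo.to_markdown(),
        "",
        "## Small-world topology (fixed sparsity)",
        "",
        "| group | C_p | L_p | gamma | lambda | sigma |",
        "|---|---|---|---|---|---|",
    ]
    for g, d in sw.items():
        sigma = "n/a" if d["sigma"] is None else f"{d['sigma']:.3f}"
        lines.append(
            f"| {g} | {d['C_p']:.4f} | {d['L_p']:.4f} | {d['gamma']:.3f} "
            f"| {d['lambda']:.3f} | {sigma} |"
        )
    hubs = summary["hubs"]
    lines += [
        "",
        "## Hubs (betweenness > 2 x mean)",
        "",
        f"- control-only: {', '.join(hubs['nc_only']) or 'none'}",
        f"- patient-only: {', '.join(hubs['cancer_only']) or 'none'}",
        f"- shared: {', '.join(hubs['shared']) or 'none'}",
        "",
        "## Group inference",
        "",
        f"- regions FDR-flagged (group test): "
        f"{', '.join(summary['regions_flagged_group_test']) or 'none'}",
        f"- regions FDR-flagged (BDI correlation): "
        f"{', '.join(summary['regions_flagged_bdi'] or []) or 'none'}",
        f"- significant edge pairs: {summary['edge_comparison']['n_significant']} "
        f"(long-range: {summary['edge_comparison']['n_long_range_significant']})",
        f"- nodal betweenness higher in patients: "
        f"{', '.join(summary['nodal_betweenness']['higher_in_cancer']) or 'none'}",
        f"- nodal betweenness lower in patients: "
        f"{', '.join(summary['nodal_betweenness']['lower_in_cancer']) or 'none'}",
        "",
    ]
    return "\n".join(lines)
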