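"""Region-level statistics: normalization, group tests, BDI correlations, demographics.

Regional metabolism is first made unit-free by dividing each subject's profile
by that subject's global (whole-brain) mean, then linear age and gender effects
are removed by per-region ordinary least squares on the pooled sample; the
retained output is residual + intercept, so values stay on an interpretable
level while being exactly orthogonal to the covariates. Group differences use
Welch two-sample t tests per region; depression-metabolism association uses
Pearson correlation against the BDI-II score within the patient group. Both
region-level families are corrected with Benjamini-Hochberg FDR (default
alpha 0.01).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .simulate import CANCER, NC, Cohort

logger = logging.getLogger(__name__)

NORMALIZATION_MODES = ("global-mean", "none")


@dataclass
class NormalizedMatrix:
    """Covariate-adjusted regional metabolism with fit provenance.

    ``values`` matches the source cohort's shape (subjects x regions);
    ``coefficients`` holds the per-region OLS fit (intercept, age, gender
    slopes); ``covariates`` is carried along for grouping downstream.
    """

    values: pd.DataFrame
    covariates: pd.DataFrame
    mode: str
    coefficients: pd.DataFrame
    dropped_covariates: tuple[str, ...] = ()

    @property
    def region_names(self) -> list[str]:
        return list(self.values.columns)

    def group_values(self, group: str) -> np.ndarray:
        mask = (self.covariates["group"] == group).to_numpy()
        return self.values.to_numpy(dtype=float)[mask]

    def group_size(self, group: str) -> int:
        return int((self.covariates["group"] == group).sum())


@dataclass
class RegionStatResult:
    """Per-region statistics with BH-FDR adjustment.

    ``table`` columns: region, the statistic (t or r), p, p_adj, flag, and for
    signed analyses a sign column; ``excluded`` lists regions dropped from the
    FDR family (e.g. zero-variance degenerate regions).
    """

    table: pd.DataFrame
    alpha: float
    excluded: tuple[str, ...] = ()

    @property
    def flagged(self) -> list[str]:
        return self.table.loc[self.table["flag"], "region"].tolist()

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _gender_codes(gender: pd.Series) -> np.ndarray:
    # male=0, female=1; any affine coding yields identical residuals
    return (gender.to_numpy() == "female").astype(float)


def normalize_and_adjust(cohort: Cohort, mode: str = "global-mean") -> NormalizedMatrix:
    """Global-mean scale (optional) then regress out age and gender per region.

    Step 1 ("global-mean" mode): divide each subject's regional values by that
    subject's mean over all regions. Step 2: per region, OLS of the scaled
    value on [1, age, gender] over the pooled sample; the output is residual
    plus intercept, with fitted coefficients retained. A constant covariate
    column (e.g. single-gender cohort) is dropped with a logged warning.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    x = cohort.metabolism.to_numpy(dtype=float)
    if mode == "global-mean":
        x = x / x.mean(axis=1, keepdims=True)

    cols = {"age": cohort.covariates["age"].to_numpy(dtype=float),
            "gender": _gender_codes(cohort.covariates["gender"])}
    dropped = tuple(k for k, v in cols.items() if np.ptp(v) == 0)
    for k in dropped:
        logger.warning("covariate %r is constant; dropped from adjustment", k)
    kept = [k for k in cols if k not in dropped]
    design = np.column_stack([np.ones(len(x))] + [cols[k] for k in kept])

    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ beta
    adjusted = resid + beta[0]  # keep the grand level interpretable

    coef = pd.DataFrame(
        beta.T, columns=["intercept"] + kept, index=cohort.metabolism.columns
    )
    for k in dropped:
        coef[k] = np.nan
    values = pd.DataFrame(
        adjusted, columns=cohort.metabolism.columns, index=cohort.metabolism.index
    )
    return NormalizedMatrix(values, cohort.covariates.copy(), mode, coef, dropped)


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    return multipletests(pvals, method="fdr_bh")[1]


def group_region_test(norm: NormalizedMatrix, alpha: float = 0.01) -> RegionStatResult:
    """Welch two-sample t test per region (patients vs controls), BH-FDR across regions.

    Regions with zero within-group variance in both groups have no defined t
    statistic; they are excluded from the FDR family with a warning.
    """
    a = norm.group_values(CANCER)
    b = norm.group_values(NC)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2 for a two-sample test")
    regions = np.array(norm.region_names)
    degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    if degenerate.any():
        warnings.warn(
            f"regions with zero variance in both groups excluded from FDR: "
            f"{regions[degenerate].tolist()}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(a, b, axis=0, equal_var=False)
    ok = ~degenerate
    p_adj = np.full_like(p, np.nan)
    p_adj[ok] = _bh_adjust(p[ok])
    flag = np.zeros(len(regions), dtype=bool)
    flag[ok] = p_adj[ok] < alpha
    table = pd.DataFrame(
        {"region": regions, "statistic": t, "p": p, "p_adj": p_adj, "flag": flag}
    )
    return RegionStatResult(table, alpha, tuple(regions[degenerate]))


def bdi_correlation(norm: NormalizedMatrix, alpha: float = 0.01) -> RegionStatResult:
    """Pearson correlation of each region with BDI within the patient group.

    Two-sided p per region, BH-FDR across regions, and signed significance
    flags (+1 / -1 for FDR-significant positive / negative correlations).
    """
    mask = (norm.covariates["group"] == CANCER).to_numpy()
    bdi = norm.covariates.loc[mask, "bdi"].to_numpy(dtype=float)
    if np.isnan(bdi).any():
        raise ValueError("BDI missing for some patient-group subjects")
    if np.ptp(bdi) == 0:
        raise ValueError("BDI is constant; correlation undefined")
    x = norm.values.to_numpy(dtype=float)[mask]
    regions = np.array(norm.region_names)
    r = np.empty(len(regions))
    p = np.empty(len(regions))
    for j in range(len(regions)):
        if np.ptp(x[:, j]) == 0:
            r[j], p[j] = np.nan, np.nan
        else:
            r[j], p[j] = sps.pearsonr(x[:, j], bdi)
    ok = ~np.isnan(p)
    p_adj = np.full_like(p, np.nan)
    p_adj[ok] = _bh_adjust(p[ok])
    flag = np.zeros(len(regions), dtype=bool)
    flag[ok] = p_adj[ok] < alpha
    sign = np.where(flag, np.sign(r), 0.0)
    table = pd.DataFrame(
        {"region": regions, "r": r, "p": p, "p_adj": p_adj, "flag": flag, "sign": sign}
    )
    return RegionStatResult(table, alpha, tuple(regions[~ok]))


@dataclass
class DemographicsReport:
    """Group demographic summary with chi-square (gender) and t-test (age) p values."""

    table: pd.DataFrame
    gender_chi2: float
    gender_p: float
    age_t: float
    age_p: float

    def to_markdown(self) -> str:
        lines = ["| | " + " | ".join(self.table.columns) + " |",
                 "|" + "---|" * (len(self.table.columns) + 1)]
        for idx, row in self.table.iterrows():
            lines.append(f"| {idx} | " + " | ".join(str(v) for v in row) + " |")
        return "\n".join(lines)


def demographics_table(cohort: Cohort) -> DemographicsReport:
    """Gender 2x2 Pearson chi-square (1 df, no continuity correction) and age t test."""
    cov = cohort.covariates
    groups = [NC, CANCER]
    counts = np.array(
        [
            [(cov["group"].eq(g) & cov["gender"].eq(s)).sum() for s in ("male", "female")]
            for g in groups
        ]
    )
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("empty chi-square margin; gender table degenerate")
    chi2, gender_p, _, _ = sps.chi2_contingency(counts, correction=False)
    ages = {g: cov.loc[cov["group"] == g, "age"].to_numpy(dtype=float) for g in groups}
    age_t, age_p = sps.ttest_ind(ages[CANCER], ages[NC], equal_var=False)

    def _fmt_age(a):
        return f"{a.mean():.1f} +/- {a.std(ddof=1):.1f}"

    bdi = cov.loc[cov["group"] == CANCER, "bdi"].to_numpy(dtype=float)
    table = pd.DataFrame(
        {
            f"{NC} (n={len(ages[NC])})": {
                "Gender (male/female)": f"{counts[0, 0]}/{counts[0, 1]}",
                "Age (mean +/- SD)": _fmt_age(ages[NC]),
                "BDI-II (mean +/- SD)": "--",
            },
            f"{CANCER} (n={len(ages[CANCER])})": {
                "Gender (male/female)": f"{counts[1, 0]}/{counts[1, 1]}",
                "Age (mean +/- SD)": _fmt_age(ages[CANCER]),
                "BDI-II (mean +/- SD)": (
                    f"{np.nanmean(bdi):.1f} +/- {np.nanstd(bdi, ddof=1):.1f}"
                    if np.isfinite(bdi).any()
                    else "--"
                ),
            },
            "P value": {
                "Gender (male/female)": f"{gender_p:.3f}",
                "Age (mean +/- SD)": f"{age_p:.3f}",
                "BDI-II (mean +/- SD)": "--",
            },
        }
    )
    return DemographicsReport(table, float(chi2), float(gender_p), float(age_t), float(age_p))
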