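"""Synthetic cohort generator for group-level metabolic covariance analyses.

Emulates an FDG-PET study design with two groups — healthy controls ("NC") and
pre-treatment cancer patients with depressive symptoms — at the region level
only: each subject is a vector of 90 regional glucose-uptake values drawn from
a group-specific multivariate normal around a common positive baseline, with
additive linear age and gender confounds, independent residual noise, and an
optional linear coupling between chosen regions and the patient group's
depression (BDI-II) score.

Defaults mirror the emulated study's printed demographics: n = 80 controls and
78 patients; gender splits 45/35 and 43/35; ages drawn from normal(49, 7) and
normal(51, 11) truncated at 18 years; patient BDI-II scores from a three-part
severity mixture (minimal/mild/moderate-severe with weights 44:16:18, means 6,
15, 26 and SDs 3, 1, 6), truncated to the 0-63 scale.

All randomness flows through a single ``numpy.random.Generator`` seeded from
``SimulationSpec.seed``, so an identical spec reproduces the cohort bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import RegionTable

NC = "NC"
CANCER = "cancer"
GROUPS = (NC, CANCER)

#: Default BDI-II severity mixture: (weight, mean, sd) per stratum.
BDI_STRATA = ((44 / 78, 6.0, 3.0), (16 / 78, 15.0, 1.0), (18 / 78, 26.0, 6.0))
BDI_RANGE = (0.0, 63.0)

#: Default linear BDI->metabolism coupling slope (uptake units per BDI point).
#: With unit regional variance and the default BDI mixture (SD ~ 9) this puts
#: the coupled region's population correlation with BDI near 0.7.
DEFAULT_COUPLING_STRENGTH = 0.15

_MIN_GROUP_SIZE = 4  # Pearson + Fisher SE need n - 3 > 0 downstream


def _as_sign(s) -> float:
    if s in (1, +1.0, "+", "positive", "pos"):
        return 1.0
    if s in (-1, -1.0, "-", "negative", "neg"):
        return -1.0
    raise ValueError(f"coupling sign must be +/- (got {s!r})")


def check_psd(cov: np.ndarray, tol: float = 1e-8) -> None:
    """Reject asymmetric or non-positive-semidefinite covariance matrices."""
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"covariance must be square, got shape {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance matrix is not symmetric")
    w = np.linalg.eigvalsh(cov)
    if w[0] < -tol * max(1.0, w[-1]):
        raise ValueError(
            f"covariance is not positive semidefinite (min eigenvalue {w[0]:.3g})"
        )


def two_block_cov(
    n_regions: int,
    within_r: float,
    between_r: float,
    variance: float = 1.0,
) -> np.ndarray:
    """Covariance with two equal blocks: ``within_r`` inside, ``between_r`` across.

    Provides a ground-truth clustering contrast: groups generated from a
    high-within / low-between structure yield more triangle-rich covariance
    networks than groups with uniform inter-regional correlation.
    """
    if n_regions < 2 or n_regions % 2:
        raise ValueError("n_regions must be even and >= 2")
    if not (-1.0 < between_r <= within_r < 1.0):
        raise ValueError(
            f"need -1 < between_r <= within_r < 1, got {between_r}, {within_r}"
        )
    if variance <= 0:
        raise ValueError("variance must be positive")
    half = n_regions // 2
    corr = np.full((n_regions, n_regions), between_r)
    for b in (slice(0, half), slice(half, n_regions)):
        corr[b, b] = within_r
    np.fill_diagonal(corr, 1.0)
    cov = variance * corr
    check_psd(cov)
    return cov


def modular_cov(
    n_regions: int,
    block_size: int,
    within_r: float,
    between_r: float,
    variance: float = 1.0,
) -> np.ndarray:
    """Covariance with many equal communities: ``within_r`` inside each block.

    A many-block structure raises network clustering while leaving enough
    between-community correlation for short paths — the generator-side analogue
    of a small-world covariance topology. ``n_regions`` must be divisible by
    ``block_size``.
    """
    if n_regions % block_size or block_size < 2:
        raise ValueError("block_size must divide n_regions and be >= 2")
    if not (-1.0 < between_r <= within_r < 1.0):
        raise ValueError(
            f"need -1 < between_r <= within_r < 1, got {between_r}, {within_r}"
        )
    corr = np.full((n_regions, n_regions), between_r)
    for i in range(n_regions // block_size):
        s = slice(i * block_size, (i + 1) * block_size)
        corr[s, s] = within_r
    np.fill_diagonal(corr, 1.0)
    cov = variance * corr
    check_psd(cov)
    return cov


@dataclass(frozen=True)
class SimulationSpec:
    """Full parameterisation of a synthetic two-group cohort.

    ``base_cov`` is the inter-regional covariance of the control group;
    ``cov_cancer`` overrides it for the patient group (defaults to the same
    structure). ``age_effect`` / ``gender_effect`` are per-region slopes (scalar
    broadcasts): metabolism gains ``age * age_effect`` and, for female subjects,
    ``gender_effect``. ``bdi_coupling`` lists ``(region_name, sign, strength)``
    triples; each coupled patient region is shifted by
    ``sign * strength * (bdi - mean bdi)``.
    """

    n_nc: int = 80
    n_cancer: int = 78
    base_cov: np.ndarray | None = None
    cov_cancer: np.ndarray | None = None
    mean_level: float = 100.0
    age_effect: float | np.ndarray = 0.0
    gender_effect: float | np.ndarray = 0.0
    bdi_coupling: Sequence[tuple[str, object, float]] = ()
    noise_sd: float = 1.0
    seed: int = 0
    male_frac_nc: float = 45 / 80
    male_frac_cancer: float = 43 / 78
    age_dist_nc: tuple[float, float] = (49.0, 7.0)
    age_dist_cancer: tuple[float, float] = (51.0, 11.0)
    min_age: float = 18.0

    def replace(self, **kwargs) -> "SimulationSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass
class Cohort:
    """Subjects-by-regions metabolism matrix with per-subject covariates.

    ``covariates`` has one row per subject (subject_id, group, age, gender,
    bdi — NaN where not assessed); ``metabolism`` is indexed identically with
    one column per region, in region-table order.
    """

    covariates: pd.DataFrame
    metabolism: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.covariates) != len(self.metabolism):
            raise ValueError("covariates and metabolism row counts differ")
        if self.metabolism.isna().any().any():
            raise ValueError("missing metabolism values")
        counts = self.covariates["group"].value_counts()
        for g in GROUPS:
            if counts.get(g, 0) and counts[g] < _MIN_GROUP_SIZE:
                raise ValueError(
                    f"group {g!r} has {counts[g]} subjects; need >= {_MIN_GROUP_SIZE}"
                )

    @property
    def region_names(self) -> list[str]:
        return list(self.metabolism.columns)

    def group_mask(self, group: str) -> np.ndarray:
        return (self.covariates["group"] == group).to_numpy()

    def to_csv(self, path: str | Path) -> None:
        """Tidy CSV: subject_id, group, age, gender, bdi, then region columns."""
        out = pd.concat(
            [self.covariates.reset_index(drop=True), self.metabolism.reset_index(drop=True)],
            axis=1,
        )
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, regions: RegionTable | None = None) -> "Cohort":
        df = pd.read_csv(path)
        meta_cols = ["subject_id", "group", "age", "gender", "bdi"]
        missing = [c for c in meta_cols if c not in df.columns]
        if missing:
            raise ValueError(f"cohort CSV missing columns: {missing}")
        region_cols = [c for c in df.columns if c not in meta_cols]
        if regions is not None:
            missing_r = [n for n in regions.names if n not in region_cols]
            if missing_r:
                raise ValueError(f"cohort CSV missing region columns: {missing_r}")
            region_cols = regions.names
        return cls(df[meta_cols].copy(), df[region_cols].astype(float))


def _truncated_normal(rng: np.random.Generator, mean, sd, low, size) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = out < low
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = out < low
    return out


def _draw_bdi(rng: np.random.Generator, n: int) -> np.ndarray:
    weights = np.array([w for w, _, _ in BDI_STRATA])
    strata = rng.choice(len(BDI_STRATA), size=n, p=weights / weights.sum())
    means = np.array([m for _, m, _ in BDI_STRATA])[strata]
    sds = np.array([s for _, _, s in BDI_STRATA])[strata]
    return np.clip(rng.normal(means, sds), *BDI_RANGE)


def generate_cohort(spec: SimulationSpec, regions: RegionTable) -> Cohort:
    """Draw a two-group cohort from ``spec`` over the given region table.

    Each subject's regional profile is
    ``mean_level + MVN(0, cov_group) + age * age_effect
    + 1[female] * gender_effect + N(0, noise_sd)``;
    patient BDI scores come from the severity mixture, after which each coupled
    region is shifted by ``sign * strength * (bdi - mean bdi)``. Deterministic
    under ``spec.seed``.
    """
    n_regions = regions.n_regions
    if spec.n_nc < _MIN_GROUP_SIZE or spec.n_cancer < _MIN_GROUP_SIZE:
        raise ValueError(f"group sizes must be >= {_MIN_GROUP_SIZE}")
    cov_nc = np.eye(n_regions) if spec.base_cov is None else np.asarray(spec.base_cov, float)
    cov_ca = cov_nc if spec.cov_cancer is None else np.asarray(spec.cov_cancer, float)
    for cov in (cov_nc, cov_ca):
        if cov.shape != (n_regions, n_regions):
            raise ValueError(
                f"covariance shape {cov.shape} does not match {n_regions} regions"
            )
        check_psd(cov)
    age_eff = np.broadcast_to(np.asarray(spec.age_effect, float), (n_regions,))
    gen_eff = np.broadcast_to(np.asarray(spec.gender_effect, float), (n_regions,))

    rng = np.random.default_rng(spec.seed)
    frames, mats = [], []
    for group, n, cov, male_frac, (age_mu, age_sd) in (
        (NC, spec.n_nc, cov_nc, spec.male_frac_nc, spec.age_dist_nc),
        (CANCER, spec.n_cancer, cov_ca, spec.male_frac_cancer, spec.age_dist_cancer),
    ):
        n_male = int(round(male_frac * n))
        gender = np.array(["male"] * n_male + ["female"] * (n - n_male))
        rng.shuffle(gender)
        age = _truncated_normal(rng, age_mu, age_sd, spec.min_age, n)
        draw = rng.multivariate_normal(np.zeros(n_regions), cov, size=n, method="svd")
        noise = rng.normal(0.0, spec.noise_sd, (n, n_regions)) if spec.noise_sd else 0.0
        x = (
            spec.mean_level
            + draw
            + age[:, None] * age_eff[None, :]
            + (gender == "female")[:, None] * gen_eff[None, :]
            + noise
        )
        if group == CANCER:
            bdi = _draw_bdi(rng, n)
            centred = bdi - bdi.mean()
            name_to_col = {nm: j for j, nm in enumerate(regions.names)}
            for region_name, sign, strength in spec.bdi_coupling:
                if region_name not in name_to_col:
                    raise ValueError(f"unknown coupled region {region_name!r}")
                x[:, name_to_col[region_name]] += _as_sign(sign) * strength * centred
        else:
            bdi = np.full(n, np.nan)
        prefix = "NC" if group == NC else "CA"
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"{prefix}{i + 1:03d}" for i in range(n)],
                    "group": group,
                    "age": age,
                    "gender": gender,
                    "bdi": bdi,
                }
            )
        )
        mats.append(x)

    covariates = pd.concat(frames, ignore_index=True)
    metabolism = pd.DataFrame(np.vstack(mats), columns=regions.names)
    return Cohort(covariates, metabolism)
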