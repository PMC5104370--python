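"""Brain parcellation table: region names, hemispheres, and MNI centroids.

The default parcellation is the 90-region cerebral AAL scheme (45 regions per
hemisphere). The packaged fixture ``data/aal90_synthetic_centroids.csv`` carries
the standard AAL abbreviations but *synthetic*, approximate, mirror-symmetric
centroid coordinates: they are stand-ins with realistic anatomical geometry, not
the published atlas centroids. Centroids feed only the Euclidean long-range /
short-range edge classification, so users with the real atlas can supply their
own CSV (columns: region_id, name, hemisphere, x_mm, y_mm, z_mm).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

_REQUIRED_COLUMNS = ["region_id", "name", "hemisphere", "x_mm", "y_mm", "z_mm"]


@dataclass(frozen=True)
class RegionTable:
    """Ordered table of brain regions with MNI centroid coordinates (mm)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"region table missing columns: {missing}")
        if df["name"].duplicated().any():
            dups = df.loc[df["name"].duplicated(), "name"].tolist()
            raise ValueError(f"duplicate region names: {dups}")
        bad_hemi = set(df["hemisphere"].unique()) - {"L", "R"}
        if bad_hemi:
            raise ValueError(f"hemisphere labels must be L or R, got {bad_hemi}")
        coords = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            raise ValueError("non-finite centroid coordinates")
        if len(df) == 90:
            counts = df["hemisphere"].value_counts()
            if counts.get("L", 0) != 45 or counts.get("R", 0) != 45:
                raise ValueError(
                    "a 90-region table must have exactly 45 regions per hemisphere"
                )

    @property
    def n_regions(self) -> int:
        return len(self.frame)

    @property
    def names(self) -> list[str]:
        return self.frame["name"].tolist()

    @property
    def centroids(self) -> np.ndarray:
        """(N, 3) array of centroid coordinates in MNI mm."""
        return self.frame[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean centroid distances (mm), shape (N, N)."""
        c = self.centroids
        diff = c[:, None, :] - c[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))

    def subset(self, n: int) -> "RegionTable":
        """First ``n`` regions, for reduced-size analyses and tests."""
        return RegionTable(self.frame.iloc[:n].reset_index(drop=True))

    def to_csv(self, path: str | Path) -> None:
        self.frame[_REQUIRED_COLUMNS].to_csv(path, index=False)


def load_regions(path: str | Path | None = None) -> RegionTable:
    """Load a region table CSV; with no path, the packaged 90-region fixture.

    The packaged fixture uses standard AAL-90 abbreviations with synthetic
    approximate centroids (see module docstring).
    """
    if path is None:
        ref = resources.files("metabnet.data") / "aal90_synthetic_centroids.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return RegionTable(df)
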