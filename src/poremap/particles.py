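"""Planar particle sets and the analysis region.

Coordinates are in nanometres, origin at the lower-left corner of the
region, x to the right and y up.  Particle tables round-trip through CSV
with columns ``id, x_nm, y_nm, tier, condition``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ioutils import atomic_write

__all__ = ["Region", "ParticleSet"]


@dataclass(frozen=True)
class Region:
    """Rectangular analysis region (nm), origin at lower-left, y up."""

    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("region width and height must be positive")

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        return (
            (xy[:, 0] >= 0)
            & (xy[:, 0] <= self.width)
            & (xy[:, 1] >= 0)
            & (xy[:, 1] <= self.height)
        )


@dataclass
class ParticleSet:
    """Pore-center positions with a per-particle confidence tier.

    Tier semantics follow the detection confidence sets: tier 1 is the most
    stringent; the tier-k set is ``positions[tier <= k]``, so the three sets
    are nested by construction.
    """

    positions: np.ndarray
    tier: np.ndarray | None = None
    condition: str = ""
    region: Region | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if self.tier is None:
            self.tier = np.ones(len(self.positions), dtype=int)
        else:
            self.tier = np.asarray(self.tier, dtype=int).reshape(-1)
        if len(self.tier) != len(self.positions):
            raise ValueError("tier must have one entry per particle")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n(self) -> int:
        return len(self.positions)

    def at_tier(self, tier: int) -> "ParticleSet":
        """Particles passing the given stringency (tier <= ``tier``)."""
        keep = self.tier <= tier
        return ParticleSet(
            self.positions[keep], self.tier[keep], self.condition, self.region
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "x_nm": self.positions[:, 0],
                "y_nm": self.positions[:, 1],
                "tier": self.tier,
                "condition": self.condition,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        with atomic_write(path) as tmp:
            self.to_frame().to_csv(tmp, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParticleSet":
        df = pd.read_csv(path)
        condition = ""
        if "condition" in df.columns and len(df):
            vals = df["condition"].dropna().unique()
            if len(vals):
                condition = str(vals[0])
        tier = df["tier"].to_numpy() if "tier" in df.columns else None
        return cls(df[["x_nm", "y_nm"]].to_numpy(), tier, condition)

    def pairwise_distances(self) -> np.ndarray:
        """Condensed pairwise distance vector (brute force, nm)."""
        from scipy.spatial.distance import pdist

        return pdist(self.positions)
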