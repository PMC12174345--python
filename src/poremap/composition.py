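"""Membrane composition bookkeeping: mass/molar fractions and the
lipid-to-protein ratio conversion.

A composition is a per-species table of lipid counts, per-leaflet
counts, and total species masses (Da).  Fractions can be computed either
from the actual row sums or against externally declared totals (useful
when reproducing published tables whose rows and totals disagree — the
consistency report flags such mismatches rather than resolving them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "SpeciesRow",
    "MembraneComposition",
    "SM1",
    "SM2",
    "mass_fraction",
    "molar_fraction",
    "lipid_protein_molar_ratio",
    "read_composition",
    "write_composition",
]


@dataclass(frozen=True)
class SpeciesRow:
    name: str
    count: int
    per_leaflet: tuple[int, int]  # (cytosolic, IMS)
    mass_da: float


@dataclass
class MembraneComposition:
    name: str
    rows: list[SpeciesRow]
    declared_total_count: int | None = None
    declared_total_mass: float | None = None

    def __post_init__(self) -> None:
        names = [r.name for r in self.rows]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species")

    def species(self) -> list[str]:
        return [r.name for r in self.rows]

    def row(self, species: str) -> SpeciesRow:
        for r in self.rows:
            if r.name == species:
                return r
        raise KeyError(f"unknown species {species!r} in {self.name}")

    @property
    def total_count(self) -> int:
        return self.declared_total_count or sum(r.count for r in self.rows)

    @property
    def total_mass(self) -> float:
        return self.declared_total_mass or sum(r.mass_da for r in self.rows)

    def consistency_report(self, tol_count: int = 0, tol_mass: float = 1.0) -> list[str]:
        """Human-readable list of internal inconsistencies (empty if none)."""
        issues = []
        csum = sum(r.count for r in self.rows)
        msum = sum(r.mass_da for r in self.rows)
        if self.declared_total_count is not None and abs(csum - self.declared_total_count) > tol_count:
            issues.append(
                f"{self.name}: species counts sum to {csum}, declared total is "
                f"{self.declared_total_count}"
            )
        if self.declared_total_mass is not None and abs(msum - self.declared_total_mass) > tol_mass:
            issues.append(
                f"{self.name}: species masses sum to {msum:.0f} Da, declared total is "
                f"{self.declared_total_mass:.0f} Da"
            )
        for r in self.rows:
            if sum(r.per_leaflet) != r.count:
                issues.append(
                    f"{self.name}/{r.name}: leaflet counts {r.per_leaflet} do not sum "
                    f"to species count {r.count}"
                )
        return issues

    def table(self) -> pd.DataFrame:
        """Full table with %W and %mol columns (raw, unrounded)."""
        return pd.DataFrame(
            {
                "species": self.species(),
                "count": [r.count for r in self.rows],
                "mass_da": [r.mass_da for r in self.rows],
                "pct_w": [mass_fraction(self, r.name, rounded=False) for r in self.rows],
                "pct_mol": [molar_fraction(self, r.name, rounded=False) for r in self.rows],
            }
        )


def mass_fraction(
    composition: MembraneComposition, species: str, rounded: bool = True
) -> float:
    """Species mass as percent of total mass (display-rounded to 1 decimal)."""
    total = composition.total_mass
    if total <= 0:
        raise ValueError("total mass must be positive")
    pct = composition.row(species).mass_da / total * 100.0
    return round(pct, 1) if rounded else pct


def molar_fraction(
    composition: MembraneComposition, species: str, rounded: bool = True
) -> float:
    """Species count as percent of total count (display-rounded to 1 decimal)."""
    total = composition.total_count
    if total <= 0:
        raise ValueError("total count must be positive")
    pct = composition.row(species).count / total * 100.0
    return round(pct, 1) if rounded else pct


def lipid_protein_molar_ratio(
    mass_ratio: float, mean_lipid_mass: float, protein_mass: float
) -> float:
    """Convert a lipid:protein mass ratio into a molar ratio.

    molar = mass_ratio * protein_mass / mean_lipid_mass.  A 3:1 (w:w)
    reconstitution with ~745 Da mean lipid and a ~34.8 kDa channel gives
    the familiar ~140:1 molar ratio.
    """
    if mean_lipid_mass <= 0 or protein_mass <= 0:
        raise ValueError("masses must be positive")
    return mass_ratio * protein_mass / mean_lipid_mass


#: Simple Membrane 1: POPC/POPE bilayer, 1100 lipids.
SM1 = MembraneComposition(
    "SM1",
    [
        SpeciesRow("POPC", 716, (358, 358), 536_747.0),
        SpeciesRow("POPE", 384, (192, 192), 272_111.0),
    ],
)

#: Simple Membrane 2: POPC/POPE/cardiolipin/cholesterol.  The printed
#: totals (1100 lipids, 775,524 Da) disagree with the per-row counts
#: (which sum to 1120); fractions follow the printed totals and
#: consistency_report() flags the mismatch.
SM2 = MembraneComposition(
    "SM2",
    [
        SpeciesRow("POPC", 642, (321, 321), 481_622.0),
        SpeciesRow("POPE", 345, (172, 173), 244_164.0),
        SpeciesRow("CDL", 26, (13, 13), 8_532.0),
        SpeciesRow("CHOL", 107, (54, 53), 41_205.0),
    ],
    declared_total_count=1100,
    declared_total_mass=775_524.0,
)


def write_composition(comp: MembraneComposition, path: str | Path) -> None:
    """Small structured-text format: one CSV row per species plus an
    optional '#total' row carrying declared totals."""
    from .ioutils import atomic_write

    rows = [
        {
            "species": r.name,
            "count": r.count,
            "leaflet_cyto": r.per_leaflet[0],
            "leaflet_ims": r.per_leaflet[1],
            "mass_da": r.mass_da,
        }
        for r in comp.rows
    ]
    df = pd.DataFrame(rows)
    with atomic_write(path) as tmp:
        with open(tmp, "w") as fh:
            fh.write(f"# composition {comp.name}\n")
            if comp.declared_total_count is not None:
                fh.write(f"# total_count {comp.declared_total_count}\n")
            if comp.declared_total_mass is not None:
                fh.write(f"# total_mass {comp.declared_total_mass}\n")
            df.to_csv(fh, index=False)


def read_composition(path: str | Path) -> MembraneComposition:
    name = Path(path).stem
    total_count = total_mass = None
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            parts = line[1:].split()
            if parts[:1] == ["composition"] and len(parts) > 1:
                name = parts[1]
            elif parts[:1] == ["total_count"]:
                total_count = int(parts[1])
            elif parts[:1] == ["total_mass"]:
                total_mass = float(parts[1])
    df = pd.read_csv(path, skiprows=header_lines)
    rows = [
        SpeciesRow(
            str(r.species), int(r.count), (int(r.leaflet_cyto), int(r.leaflet_ims)),
            float(r.mass_da),
        )
        for r in df.itertuples()
    ]
    return MembraneComposition(name, rows, total_count, total_mass)
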