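"""PDB-format I/O for coarse-grained templates and assembly models.

Conventions: coordinates are stored in Angstrom (the package works in
nm); lipid species go in the residue name (PC, PE, CHL for cholesterol,
CDL), the leaflet in the chain identifier (C = cytosolic, I = IMS),
protein beads on chain P with residue name BB; first-shell lipids carry
B-factor 1.0.  Assembly models additionally store the instance id in
the residue id.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .assembly import AssemblyModel
from .ioutils import atomic_write
from .synthetic import Template

__all__ = ["template_to_pdb", "template_from_pdb", "model_to_pdb"]

_SPECIES_TO_RES = {"PC": "PC", "PE": "PE", "CHOL": "CHL", "CDL": "CDL"}
_RES_TO_SPECIES = {v: k for k, v in _SPECIES_TO_RES.items()}
_LEAFLET_TO_CHAIN = {"cytosolic": "C", "IMS": "I"}
_CHAIN_TO_LEAFLET = {v: k for k, v in _LEAFLET_TO_CHAIN.items()}


def _atoms(n: int) -> struc.AtomArray:
    arr = struc.AtomArray(n)
    arr.set_annotation("b_factor", np.zeros(n))
    arr.atom_name = np.full(n, "BB", "U6")
    arr.element = np.full(n, "C", "U2")
    arr.hetero = np.ones(n, bool)
    return arr


def template_to_pdb(template: Template, path: str | Path) -> None:
    n = len(template.protein_beads) + len(template.lipid_beads)
    arr = _atoms(n)
    m = len(template.protein_beads)
    coords = np.concatenate([template.protein_beads, template.lipid_beads]) * 10.0
    arr.coord = coords.astype(np.float32)
    arr.chain_id[:m] = "P"
    arr.res_name[:m] = "BB"
    arr.res_id[:m] = np.arange(1, m + 1)
    arr.hetero[:m] = False
    for k in range(len(template.lipid_beads)):
        i = m + k
        arr.chain_id[i] = _LEAFLET_TO_CHAIN[str(template.leaflet[k])]
        arr.res_name[i] = _SPECIES_TO_RES.get(str(template.species[k]), str(template.species[k])[:3])
        arr.res_id[i] = k + 1
        arr.b_factor[i] = 1.0 if template.first_shell[k] else 0.0
    pdb = PDBFile()
    pdb.set_structure(arr)
    with atomic_write(path) as tmp:
        pdb.write(str(tmp))


def template_from_pdb(path: str | Path, cylinder_radius: float = 5.0) -> Template:
    arr = PDBFile.read(str(path)).get_structure(model=1, extra_fields=["b_factor"])
    is_protein = arr.chain_id == "P"
    protein = arr.coord[is_protein] / 10.0
    lip = arr.coord[~is_protein] / 10.0
    species = np.array(
        [_RES_TO_SPECIES.get(r, r) for r in arr.res_name[~is_protein]], "U8"
    )
    leaflet = np.array(
        [_CHAIN_TO_LEAFLET.get(c, "cytosolic") for c in arr.chain_id[~is_protein]], "U16"
    )
    shell = arr.b_factor[~is_protein] > 0.5
    return Template(protein, lip, species, leaflet, shell, cylinder_radius)


def model_to_pdb(model: AssemblyModel, path: str | Path, retained_only: bool = True) -> None:
    """Write a placed assembly: all instances, retained lipids only by default."""
    lip_pos, species, leaflet, owner = model.lipid_table(retained_only)
    prot = [inst.protein for inst in model.instances if len(inst.protein)]
    prot_pos = np.concatenate(prot) if prot else np.empty((0, 3))
    prot_owner = (
        np.concatenate(
            [np.full(len(inst.protein), k) for k, inst in enumerate(model.instances)]
        )
        if prot else np.empty(0, int)
    )
    n = len(prot_pos) + len(lip_pos)
    arr = _atoms(n)
    arr.coord = (np.concatenate([prot_pos, lip_pos]) * 10.0).astype(np.float32)
    m = len(prot_pos)
    arr.chain_id[:m] = "P"
    arr.res_name[:m] = "BB"
    arr.res_id[:m] = prot_owner + 1
    arr.hetero[:m] = False
    for k in range(len(lip_pos)):
        i = m + k
        arr.chain_id[i] = _LEAFLET_TO_CHAIN[str(leaflet[k])]
        arr.res_name[i] = _SPECIES_TO_RES.get(str(species[k]), str(species[k])[:3])
        arr.res_id[i] = int(owner[k]) + 1
    pdb = PDBFile()
    pdb.set_structure(arr)
    with atomic_write(path) as tmp:
        pdb.write(str(tmp))
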