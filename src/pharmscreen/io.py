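"""Readers for the standard input formats: SDF, SMILES lists, PDB complexes,
and labeled-library tables."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .chem import Atom, Molecule3D


def read_sdf(path) -> list[Molecule3D]:
    """Read a multi-record SDF with 3D coordinates (hydrogens added if absent)."""
    from rdkit import Chem

    out = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        mol = Chem.AddHs(mol, addCoords=True)
        out.append(Molecule3D.from_rdkit(mol, mol_id=f"sdf-{i+1}"))
    return out


def read_smiles_file(path, seed: int = 7) -> list[Molecule3D]:
    """Read a SMILES file (one ``SMILES [id]`` per line) and embed 3D."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smi = parts[0]
            mid = parts[1] if len(parts) > 1 else f"smi-{i+1}"
            out.append(Molecule3D.from_smiles(smi, mol_id=mid, seed=seed + i))
    return out


def read_pdb_complex(
    path,
    ligand_resname: str,
    receptor_chain: Optional[str] = None,
) -> tuple[Molecule3D, Molecule3D]:
    """Extract (receptor, ligand) from one PDB file.

    The ligand is selected by HETATM residue name; the receptor is the
    polymer (optionally restricted to one chain).  Bonds are inferred by
    interatomic distances.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    arr = f.get_structure(model=1)

    lig_mask = arr.res_name == ligand_resname
    rec_mask = ~arr.hetero
    if receptor_chain is not None:
        rec_mask &= arr.chain_id == receptor_chain
    if not lig_mask.any():
        raise ValueError(f"no HETATM residue named {ligand_resname!r}")
    if not rec_mask.any():
        raise ValueError("no receptor atoms found")

    def to_mol(sub, mol_id):
        bonds = []
        bl = struc.connect_via_distances(sub)
        for i, j, _ in bl.as_array():
            bonds.append((int(i), int(j), 1.0))
        atoms = [
            Atom(
                element=str(sub.element[k]).capitalize(),
                coords=tuple(float(x) for x in sub.coord[k]),
                res_name=str(sub.res_name[k]),
                res_id=int(sub.res_id[k]),
                name=str(sub.atom_name[k]),
            )
            for k in range(sub.array_length())
        ]
        return Molecule3D(id=mol_id, atoms=atoms, bonds=bonds)

    return to_mol(arr[rec_mask], "receptor"), to_mol(arr[lig_mask], ligand_resname)


def read_label_table(path) -> dict[str, bool]:
    """TSV of (id, active in {0,1}[, ic50_nM]); the customary activity
    criterion (IC50 below 100 nM) is metadata, not recomputed here."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return {str(r["id"]): bool(int(r["active"])) for _, r in df.iterrows()}
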