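"""Structure readers/writers: XYZ, SDF/MOL V2000, and per-ligand SMILES.

XYZ files carry element + Cartesian Angstrom lines (single or multi-frame).
SDF/MOL goes through RDKit; bonds present in the file are honoured, otherwise
they are perceived by the covalent-radius rule.  SMILES export excises the
metal and canonicalises each ligand for novelty/uniqueness comparisons.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem import RWMol
from rdkit.Geometry import Point3D

from .complexes import Ligand, TMComplex, partition_ligands, perceive_bonds
from .config import DEFAULTS, Config
from .elements import is_metal


def write_xyz(path: str | Path, complexes: TMComplex | Iterable[TMComplex]) -> None:
    if isinstance(complexes, TMComplex):
        complexes = [complexes]
    with open(path, "w") as fh:
        for cx in complexes:
            fh.write(f"{cx.n_atoms}\n{cx.source_id}\n")
            for el, (x, y, z) in zip(cx.elements, cx.coords):
                fh.write(f"{el:<3s} {x:14.8f} {y:14.8f} {z:14.8f}\n")


def read_xyz(path: str | Path, config: Config = DEFAULTS) -> list[TMComplex]:
    """Read one or more frames; hydrogens are stripped, ligands partitioned."""
    lines = Path(path).read_text().splitlines()
    out = []
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1].strip()
        elements, coords = [], []
        for ln in lines[i + 2: i + 2 + n]:
            parts = ln.split()
            if parts[0] != "H":
                elements.append(parts[0])
                coords.append([float(v) for v in parts[1:4]])
        metal_idx = [k for k, e in enumerate(elements) if is_metal(e)]
        if len(metal_idx) != 1:
            raise ValueError(
                f"frame {frame} of {path}: expected one metal, found {len(metal_idx)}"
            )
        cx = TMComplex(
            elements=elements,
            coords=np.array(coords),
            metal_index=metal_idx[0],
            source_id=comment or f"{Path(path).stem}#{frame}",
        )
        partition_ligands(cx, config.bond_tolerance, config.metal_tolerance)
        out.append(cx)
        i += 2 + n
        frame += 1
    return out


def _mol_from_block(
    elements: list[str],
    coords: np.ndarray,
    bonds: Iterable[tuple[int, int]],
) -> Chem.Mol:
    mol = RWMol()
    for el in elements:
        mol.AddAtom(Chem.Atom(el))
    for i, j in bonds:
        mol.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    conf = Chem.Conformer(len(elements))
    for k, (x, y, z) in enumerate(coords):
        conf.SetAtomPosition(k, Point3D(float(x), float(y), float(z)))
    mol.AddConformer(conf)
    return mol.GetMol()


def complex_to_mol(cx: TMComplex, config: Config = DEFAULTS) -> Chem.Mol:
    """Whole complex as an RDKit mol with perceived single bonds (unsanitized)."""
    bonds = perceive_bonds(cx, config.bond_tolerance)
    mol = _mol_from_block(cx.elements, cx.coords, bonds)
    mol.UpdatePropertyCache(strict=False)
    return mol


def write_sdf(path: str | Path, complexes: TMComplex | Iterable[TMComplex],
              config: Config = DEFAULTS) -> None:
    if isinstance(complexes, TMComplex):
        complexes = [complexes]
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for cx in complexes:
        mol = complex_to_mol(cx, config)
        mol.SetProp("_Name", cx.source_id)
        writer.write(mol)
    writer.close()


def read_sdf(path: str | Path, config: Config = DEFAULTS) -> list[TMComplex]:
    """Read SDF/MOL; file bonds are honoured for ligand partitioning when
    present, otherwise bonds are perceived geometrically."""
    out = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"unparseable record {idx} in {path}")
        conf = mol.GetConformer()
        keep = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() != "H"]
        elements = [mol.GetAtomWithIdx(k).GetSymbol() for k in keep]
        coords = np.array([list(conf.GetAtomPosition(k)) for k in keep])
        metal_idx = [k for k, e in enumerate(elements) if is_metal(e)]
        if len(metal_idx) != 1:
            raise ValueError(f"record {idx} in {path}: need exactly one metal")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"{Path(path).stem}#{idx}"
        cx = TMComplex(elements=elements, coords=coords,
                       metal_index=metal_idx[0], source_id=name)
        if mol.GetNumBonds() > 0:
            remap = {old: new for new, old in enumerate(keep)}
            import networkx as nx

            g = nx.Graph()
            g.add_nodes_from(range(len(elements)))
            for b in mol.GetBonds():
                a, c = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
                if a in remap and c in remap:
                    g.add_edge(remap[a], remap[c])
            g.remove_node(cx.metal_index)
            from .complexes import donor_indices

            comps = sorted((sorted(c) for c in nx.connected_components(g)),
                           key=lambda c: c[0])
            cx.ligands = [
                Ligand(tuple(comp), donor_indices(cx, comp, config.metal_tolerance))
                for comp in comps
            ]
        else:
            partition_ligands(cx, config.bond_tolerance, config.metal_tolerance)
        out.append(cx)
    return out


def ligand_smiles(
    cx: TMComplex,
    ligand: Ligand,
    config: Config = DEFAULTS,
) -> str:
    """Canonical hydrogen-free SMILES of one ligand (metal excised).

    Falls back to an unsanitized canonical form when valence sanitization
    fails, so every generated ligand still gets a comparable string.
    """
    elements = cx.ligand_elements(ligand)
    coords = cx.ligand_coords(ligand)
    sub = _mol_from_block(
        elements, coords,
        _ligand_bonds(elements, coords, config.bond_tolerance),
    )
    try:
        mol = Chem.Mol(sub)
        Chem.SanitizeMol(mol)
        return Chem.MolToSmiles(mol)
    except Exception:
        sub.UpdatePropertyCache(strict=False)
        return Chem.MolToSmiles(sub)


def _ligand_bonds(elements, coords, tolerance):
    from .elements import covalent_radius

    coords = np.asarray(coords)
    radii = np.array([covalent_radius(e) for e in elements])
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    cut = radii[:, None] + radii[None, :] + tolerance
    ii, jj = np.nonzero(np.triu(d <= cut, k=1))
    return list(zip(ii.tolist(), jj.tolist()))
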