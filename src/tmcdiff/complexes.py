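"""Domain model for mononuclear transition-metal complexes.

A :class:`TMComplex` is a single d-block metal centre plus hydrogen-free
ligand atoms with 3D coordinates in Angstrom.  Ligands are the connected
components of the perceived bond graph once the metal vertex is removed; a
ligand's denticity is the number of its atoms inside the metal-donor cutoff.

Bond perception uses the classic covalent-radius heuristic: atoms *i,j* are
bonded iff ``d(i,j) <= r_cov(i) + r_cov(j) + tolerance``.  Metal-donor
(dative) bonds are longer than covalent single bonds, so the metal cutoff
uses a larger tolerance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .config import DEFAULTS
from .elements import (
    CORPUS_METALS,
    UnknownElementError,
    covalent_radius,
    is_metal,
)

MAX_HEAVY_ATOMS = 200


@dataclass(frozen=True)
class Ligand:
    """One ligand of a complex: atom indices into the parent plus donor info."""

    atom_indices: tuple[int, ...]
    coordinating_atom_indices: tuple[int, ...]

    @property
    def denticity(self) -> int:
        return len(self.coordinating_atom_indices)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_indices)


@dataclass
class TMComplex:
    """Metal centre + ligand atoms with coordinates in Angstrom.

    ``metal_index`` marks the metal inside ``elements``/``coords``; all other
    atoms are ligand atoms.  ``ligands`` is filled by :func:`partition_ligands`.
    """

    elements: list[str]
    coords: np.ndarray                      # (N, 3) float64, Angstrom
    metal_index: int = 0
    source_id: str = ""
    ligands: Optional[list[Ligand]] = None
    # indices (into .ligands) of ligands produced by the generator, if any
    generated_ligand_indices: Optional[tuple[int, ...]] = None
    target_cn: Optional[int] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError("coords must be (N, 3) matching elements")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        sym = self.elements[self.metal_index]
        if not is_metal(sym):
            raise ValueError(f"metal_index points at non-metal {sym!r}")
        n_metals = sum(1 for e in self.elements if is_metal(e))
        if n_metals != 1:
            raise ValueError(f"expected exactly one metal atom, found {n_metals}")
        if any(e == "H" for e in self.elements):
            raise ValueError("hydrogens must be stripped before constructing TMComplex")
        if len(self.elements) > MAX_HEAVY_ATOMS:
            raise ValueError(
                f"complex has {len(self.elements)} heavy atoms (limit {MAX_HEAVY_ATOMS})"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def metal(self) -> str:
        return self.elements[self.metal_index]

    @property
    def metal_coord(self) -> np.ndarray:
        return self.coords[self.metal_index]

    @property
    def is_corpus_metal(self) -> bool:
        return self.metal in CORPUS_METALS

    def ligand_elements(self, ligand: Ligand) -> list[str]:
        return [self.elements[i] for i in ligand.atom_indices]

    def ligand_coords(self, ligand: Ligand) -> np.ndarray:
        return self.coords[list(ligand.atom_indices)]

    @property
    def coordination_number(self) -> int:
        if self.ligands is None:
            raise ValueError("ligands not partitioned; call partition_ligands first")
        return sum(lig.denticity for lig in self.ligands)

    def copy(self) -> "TMComplex":
        return dataclasses.replace(
            self,
            elements=list(self.elements),
            coords=self.coords.copy(),
            ligands=list(self.ligands) if self.ligands is not None else None,
        )


def pair_cutoff(el_i: str, el_j: str, tolerance: float) -> float:
    return covalent_radius(el_i) + covalent_radius(el_j) + tolerance


def perceive_bonds(
    complex: TMComplex, tolerance: float = DEFAULTS.bond_tolerance
) -> list[tuple[int, int]]:
    """Perceive bonds by the covalent-radius-sum rule.

    Returns a sorted list of index pairs (i < j).  Raises
    :class:`UnknownElementError` on unrecognised symbols.
    """
    radii = np.array([covalent_radius(e) for e in complex.elements])
    d = np.linalg.norm(complex.coords[:, None, :] - complex.coords[None, :, :], axis=-1)
    cut = radii[:, None] + radii[None, :] + tolerance
    bonded = d <= cut
    np.fill_diagonal(bonded, False)
    ii, jj = np.nonzero(np.triu(bonded))
    return [(int(i), int(j)) for i, j in zip(ii, jj)]


def _metal_cutoffs(complex: TMComplex, metal_tolerance: float) -> np.ndarray:
    r_m = covalent_radius(complex.metal)
    return np.array(
        [r_m + covalent_radius(e) + metal_tolerance for e in complex.elements]
    )


def donor_indices(
    complex: TMComplex,
    atom_indices: Sequence[int],
    metal_tolerance: float = DEFAULTS.metal_tolerance,
) -> tuple[int, ...]:
    """Atoms (among ``atom_indices``) within the metal-donor cutoff."""
    idx = np.asarray(atom_indices, dtype=int)
    d = np.linalg.norm(complex.coords[idx] - complex.metal_coord, axis=-1)
    cut = _metal_cutoffs(complex, metal_tolerance)[idx]
    return tuple(int(i) for i, ok in zip(idx, d <= cut) if ok)


def partition_ligands(
    complex: TMComplex,
    tolerance: float = DEFAULTS.bond_tolerance,
    metal_tolerance: float = DEFAULTS.metal_tolerance,
) -> list[Ligand]:
    """Partition non-metal atoms into ligands.

    Ligands are the connected components of the bond graph with the metal
    vertex deleted, ordered by their smallest atom index.  Each ligand's
    donors are its atoms within the metal cutoff; a component with no donor
    is kept with denticity 0 (flagged invalid downstream).

    The result is also stored on ``complex.ligands``.
    """
    bonds = perceive_bonds(complex, tolerance)
    g = nx.Graph()
    g.add_nodes_from(range(complex.n_atoms))
    g.add_edges_from(bonds)
    g.remove_node(complex.metal_index)
    components = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    ligands = []
    for comp in components:
        donors = donor_indices(complex, comp, metal_tolerance)
        ligands.append(
            Ligand(atom_indices=tuple(comp), coordinating_atom_indices=donors)
        )
    complex.ligands = ligands
    return ligands


def ligand_denticity(
    ligand: Ligand,
    complex: TMComplex,
    metal_tolerance: float = DEFAULTS.metal_tolerance,
) -> int:
    """Number of ligand atoms coordinated to the metal (0 is legal)."""
    if not ligand.atom_indices:
        raise ValueError("ligand has no atoms")
    return len(donor_indices(complex, ligand.atom_indices, metal_tolerance))


def subcomplex(complex: TMComplex, keep_ligands: Sequence[int]) -> TMComplex:
    """Extract metal + a subset of ligands as a new partitioned complex.

    Coordinates are copied verbatim (no re-centring), so the context block of
    a generation run stays byte-identical to the parent complex.
    """
    if complex.ligands is None:
        partition_ligands(complex)
    keep = sorted(keep_ligands)
    atom_idx = [complex.metal_index]
    for li in keep:
        atom_idx.extend(complex.ligands[li].atom_indices)
    remap = {old: new for new, old in enumerate(atom_idx)}
    ligands = []
    for li in keep:
        lig = complex.ligands[li]
        ligands.append(
            Ligand(
                atom_indices=tuple(remap[i] for i in lig.atom_indices),
                coordinating_atom_indices=tuple(
                    remap[i] for i in lig.coordinating_atom_indices
                ),
            )
        )
    return TMComplex(
        elements=[complex.elements[i] for i in atom_idx],
        coords=complex.coords[atom_idx].copy(),
        metal_index=0,
        source_id=complex.source_id,
        ligands=ligands,
    )
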