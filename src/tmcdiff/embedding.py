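"""Point-cloud embedding x = [r, h_a, h_L, h_c] consumed by the diffusion model.

Per atom the embedding carries coordinates ``r`` (Angstrom, metal at the
origin), a one-hot atom type ``h_a`` over the 15 heavy elements, a one-hot
ligand code ``h_L`` (slot 0 reserved for the metal centre) and a one-hot
coordination code ``h_c`` encoding the denticity class (1-6) of the owning
ligand (slot 0 = metal).  ``h_L`` and ``h_c`` together form the fixed
conditioning channel h_Lc; only ``r`` and ``h_a`` are diffused.

Feature scaling (0.1, 0.25, 1.0) for (r, h_a, h_Lc) is recorded on the
embedding and applied when the denoiser featurizes its input — the arrays
themselves stay in physical units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .complexes import Ligand, TMComplex, partition_ligands
from .config import DEFAULTS, Config
from .elements import HEAVY_ELEMENTS, heavy_index
from .masking import LDgSpec

N_DENTICITY_CLASSES = 6
HC_DIM = 1 + N_DENTICITY_CLASSES  # slot 0 = metal centre


class ContextOverflowError(ValueError):
    """More ligand codes requested than h_L slots available."""


class DenticityBudgetError(ValueError):
    """Sum of requested denticities does not match the freed coordination number."""


@dataclass
class PointCloudEmbedding:
    r: np.ndarray            # (N, 3) Angstrom, metal at origin
    h_a: np.ndarray          # (N, m) one-hot over HEAVY_ELEMENTS
    h_L: np.ndarray          # (N, l_max) one-hot ligand code, slot 0 = metal
    h_c: np.ndarray          # (N, 7) one-hot denticity class, slot 0 = metal
    masked_flags: np.ndarray  # (N,) bool, True = atom being diffused/generated
    metal_index: int = 0
    scaling: tuple[float, float, float] = (
        DEFAULTS.scale_r, DEFAULTS.scale_ha, DEFAULTS.scale_hlc,
    )
    # bookkeeping: per-ligand-code (atom indices, assigned denticity)
    ligand_atoms: dict[int, tuple[int, ...]] = field(default_factory=dict)
    generated_codes: tuple[int, ...] = ()

    @property
    def n_atoms(self) -> int:
        return self.r.shape[0]

    @property
    def h_lc(self) -> np.ndarray:
        """Concatenated ligand/coordination conditioning channel."""
        return np.concatenate([self.h_L, self.h_c], axis=1)

    @property
    def context_indices(self) -> np.ndarray:
        return np.nonzero(~self.masked_flags)[0]

    @property
    def masked_indices(self) -> np.ndarray:
        return np.nonzero(self.masked_flags)[0]

    def copy(self) -> "PointCloudEmbedding":
        return PointCloudEmbedding(
            r=self.r.copy(), h_a=self.h_a.copy(), h_L=self.h_L.copy(),
            h_c=self.h_c.copy(), masked_flags=self.masked_flags.copy(),
            metal_index=self.metal_index, scaling=self.scaling,
            ligand_atoms=dict(self.ligand_atoms),
            generated_codes=self.generated_codes,
        )

    def decode_elements(self) -> list[str]:
        """Argmax decode of h_a (ties -> lowest channel index)."""
        return [HEAVY_ELEMENTS[int(k)] for k in np.argmax(self.h_a, axis=1)]

    def decode_ligand_codes(self) -> np.ndarray:
        return np.argmax(self.h_L, axis=1)


@dataclass(frozen=True)
class Context:
    """The frozen part of a generation run: metal + kept ligands.

    Immutable throughout sampling; the sampler asserts its atoms come back
    byte-identical.
    """

    complex: TMComplex            # metal + context ligands only, partitioned

    @property
    def cn_c(self) -> int:
        return self.complex.coordination_number

    def cn_g(self, total_cn: int = 6) -> int:
        return total_cn - self.cn_c


def _one_hot(n: int, dim: int, hot: int) -> np.ndarray:
    v = np.zeros(dim)
    v[hot] = 1.0
    return v


def build_embedding(
    complex: TMComplex,
    masked_ligands: Sequence[int],
    ldg: Optional[LDgSpec] = None,
    sizes: Optional[Sequence[int]] = None,
    config: Config = DEFAULTS,
    total_cn: int = 6,
) -> PointCloudEmbedding:
    """Tensorize a complex for diffusion.

    Two modes share this entry point:

    * **training** (``ldg is None``): the masked ligands keep their real atoms
      and true denticity codes; their atoms are flagged for noising.
    * **generation** (``ldg`` given): each masked/generated ligand is replaced
      by ``sizes[k]`` placeholder atoms with NaN coordinates and zero ``h_a``
      (initialised later by the sampler); ``h_c`` carries the assigned
      denticity from ``ldg``.

    Coordinates are translated so the metal sits at the origin.
    """
    if complex.ligands is None:
        partition_ligands(complex)
    ligands = complex.ligands
    masked = sorted(set(masked_ligands))
    if any(li < 0 or li >= len(ligands) for li in masked):
        raise IndexError("masked ligand index out of range")
    context_ligs = [i for i in range(len(ligands)) if i not in masked]

    # freed coordination number: denticities of the masked ligands, or (for a
    # bare context with nothing masked) whatever the target CN leaves open
    if masked:
        cn_g = sum(ligands[i].denticity for i in masked)
    else:
        cn_g = total_cn - sum(lig.denticity for lig in ligands)
    if ldg is not None:
        if sizes is None or len(sizes) != len(ldg.partition):
            raise ValueError("sizes must have one entry per generated ligand")
        if sum(ldg.partition) != cn_g:
            raise DenticityBudgetError(
                f"denticity budget mismatch: sum(LD_g)={sum(ldg.partition)} != CN_g={cn_g}"
            )
        if cn_g == 0:
            raise DenticityBudgetError("nothing to generate: masked set frees CN_g=0")
        for k, (dent, size) in enumerate(zip(ldg.partition, sizes)):
            # undersized polydentate requests are a known failure mode: the
            # model tends to realise a lower denticity than assigned
            if size < dent or (dent >= 2 and size <= 3):
                warnings.warn(
                    f"ligand size below denticity budget: generated ligand {k} "
                    f"has {size} atoms for denticity {dent}",
                    stacklevel=2,
                )
    elif not masked:
        raise ValueError("masked ligand set is empty: nothing to diffuse")

    n_codes = 1 + len(context_ligs) + (len(ldg.partition) if ldg is not None else len(masked))
    if n_codes > config.l_max:
        raise ContextOverflowError(
            f"{n_codes} ligand codes needed but l_max={config.l_max}"
        )

    origin = complex.metal_coord.copy()
    rows_r, rows_ha, rows_hl, rows_hc, rows_mask = [], [], [], [], []
    ligand_atoms: dict[int, tuple[int, ...]] = {}

    def _dent_class(d: int) -> int:
        if not 1 <= d <= N_DENTICITY_CLASSES:
            raise ValueError(
                f"ligand denticity {d} outside the encodable classes 1..{N_DENTICITY_CLASSES}"
            )
        return d

    # metal: code 0 in both h_L and h_c
    rows_r.append(complex.metal_coord - origin)
    rows_ha.append(_one_hot(0, len(HEAVY_ELEMENTS), heavy_index(complex.metal)))
    rows_hl.append(_one_hot(0, config.l_max, 0))
    rows_hc.append(_one_hot(0, HC_DIM, 0))
    rows_mask.append(False)

    code = 1
    for li in context_ligs:
        lig = ligands[li]
        dent = _dent_class(lig.denticity)
        atoms_here = []
        for ai in lig.atom_indices:
            atoms_here.append(len(rows_r))
            rows_r.append(complex.coords[ai] - origin)
            rows_ha.append(
                _one_hot(0, len(HEAVY_ELEMENTS), heavy_index(complex.elements[ai]))
            )
            rows_hl.append(_one_hot(0, config.l_max, code))
            rows_hc.append(_one_hot(0, HC_DIM, dent))
            rows_mask.append(False)
        ligand_atoms[code] = tuple(atoms_here)
        code += 1

    generated_codes = []
    if ldg is None:
        for li in masked:
            lig = ligands[li]
            dent = _dent_class(lig.denticity)
            atoms_here = []
            for ai in lig.atom_indices:
                atoms_here.append(len(rows_r))
                rows_r.append(complex.coords[ai] - origin)
                rows_ha.append(
                    _one_hot(0, len(HEAVY_ELEMENTS), heavy_index(complex.elements[ai]))
                )
                rows_hl.append(_one_hot(0, config.l_max, code))
                rows_hc.append(_one_hot(0, HC_DIM, dent))
                rows_mask.append(True)
            ligand_atoms[code] = tuple(atoms_here)
            generated_codes.append(code)
            code += 1
    else:
        for k, (dent, size) in enumerate(zip(ldg.partition, sizes)):
            atoms_here = []
            for _ in range(int(size)):
                atoms_here.append(len(rows_r))
                rows_r.append(np.full(3, np.nan))          # set by the sampler
                rows_ha.append(np.zeros(len(HEAVY_ELEMENTS)))
                rows_hl.append(_one_hot(0, config.l_max, code))
                rows_hc.append(_one_hot(0, HC_DIM, _dent_class(dent)))
                rows_mask.append(True)
            ligand_atoms[code] = tuple(atoms_here)
            generated_codes.append(code)
            code += 1

    return PointCloudEmbedding(
        r=np.array(rows_r, dtype=np.float64),
        h_a=np.array(rows_ha, dtype=np.float64),
        h_L=np.array(rows_hl, dtype=np.float64),
        h_c=np.array(rows_hc, dtype=np.float64),
        masked_flags=np.array(rows_mask, dtype=bool),
        metal_index=0,
        scaling=(config.scale_r, config.scale_ha, config.scale_hlc),
        ligand_atoms=ligand_atoms,
        generated_codes=tuple(generated_codes),
    )


def embedding_to_complex(
    emb: PointCloudEmbedding,
    metal: str,
    source_id: str = "",
    config: Config = DEFAULTS,
) -> TMComplex:
    """Decode an embedding back into a partition-annotated TMComplex.

    Elements come from argmax(h_a) for masked atoms (context atoms keep their
    exact one-hots, which decode losslessly); the ligand assignment comes from
    the stored ligand codes.  Donors are re-perceived geometrically.
    """
    elements = emb.decode_elements()
    elements[emb.metal_index] = metal
    cx = TMComplex(
        elements=elements,
        coords=emb.r.copy(),
        metal_index=emb.metal_index,
        source_id=source_id,
    )
    from .complexes import donor_indices  # local import to avoid cycle at module load

    ligands = []
    gen_lig_indices = []
    for k, code in enumerate(sorted(emb.ligand_atoms)):
        atoms = emb.ligand_atoms[code]
        donors = donor_indices(cx, atoms, config.metal_tolerance)
        ligands.append(Ligand(atom_indices=atoms, coordinating_atom_indices=donors))
        if code in emb.generated_codes:
            gen_lig_indices.append(k)
    cx.ligands = ligands
    cx.generated_ligand_indices = tuple(gen_lig_indices)
    return cx
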