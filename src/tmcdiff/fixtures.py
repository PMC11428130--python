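"""Deterministic synthetic transition-metal-complex corpora.

These toy complexes stand in for a curated crystal-structure corpus: they are
hydrogen-free mononuclear complexes with 3-6 coordinate geometries, built
from a small library of template ligands (denticities 1-4, N/O/C/P/S/Cl
donors).  Donor atoms sit on ideal coordination vectors at element-typical
metal-donor distances; chelate backbones are placed with verified margins
(>= 0.2 A) against every bond-perception and metal-cutoff rule, so the
default 0.05 A jitter can never flip connectivity or denticity.

The fixtures make no claim of chemical realism beyond structural sanity:
they exist so that masking enumeration, diffusion training, sampling and all
generation metrics can run deterministically offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .complexes import TMComplex, partition_ligands
from .config import DEFAULTS, Config
from .elements import CORPUS_METALS
from .masking import MaskingSample, expand_training_set

# ideal coordination unit vectors, ordered so consecutive sites are cis
# (~90 deg) wherever the geometry allows polydentate placement
_S3 = 1.0 / np.sqrt(3.0)
GEOMETRIES: dict[str, np.ndarray] = {
    "octahedral": np.array(
        [[0, 0, 1], [1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0], [0, 0, -1]],
        dtype=float,
    ),
    "trigonal_planar": np.array(
        [[1, 0, 0], [-0.5, np.sqrt(3) / 2, 0], [-0.5, -np.sqrt(3) / 2, 0]]
    ),
    "tetrahedral": np.array(
        [[_S3, _S3, _S3], [_S3, -_S3, -_S3], [-_S3, _S3, -_S3], [-_S3, -_S3, _S3]]
    ),
    "square_planar": np.array([[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]], dtype=float),
    "trigonal_bipyramidal": np.array(
        [[0, 0, 1], [1, 0, 0], [-0.5, np.sqrt(3) / 2, 0], [-0.5, -np.sqrt(3) / 2, 0], [0, 0, -1]]
    ),
    "square_pyramidal": np.array(
        [[0, 0, 1], [1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]], dtype=float
    ),
}

#: geometries whose consecutive sites are all ~90 deg apart (safe for chelates)
CIS_ORDERED = ("octahedral", "square_planar", "square_pyramidal")

#: metal-donor placement distance by donor element (A)
DONOR_DISTANCE = {"O": 2.0, "N": 2.0, "C": 2.0, "P": 2.0, "S": 2.3, "Cl": 2.3}


@dataclass(frozen=True)
class LigandTemplate:
    """A template ligand described relative to its coordination sites.

    ``donors`` lists the donor elements (one per occupied site); monodentate
    templates may carry a ``tail`` of extra atoms stacked radially outward
    from the donor; polydentate templates get two carbon bridge atoms per
    consecutive donor pair plus optional radial ``decor`` carbons.
    """

    name: str
    donors: tuple[str, ...]
    tail: tuple[str, ...] = ()        # monodentate only: atoms outward from donor
    n_decor: int = 0                  # polydentate only: extra C atoms on bridges

    @property
    def denticity(self) -> int:
        return len(self.donors)

    @property
    def n_atoms(self) -> int:
        if self.denticity == 1:
            return 1 + len(self.tail)
        return self.denticity + 2 * (self.denticity - 1) + self.n_decor


#: hand-built template library spanning denticities 1-4
TEMPLATES: dict[str, LigandTemplate] = {
    t.name: t
    for t in [
        LigandTemplate("aqua", ("O",)),
        LigandTemplate("ammine", ("N",)),
        LigandTemplate("chloro", ("Cl",)),
        LigandTemplate("methyl", ("C",)),
        LigandTemplate("carbonyl", ("C",), tail=("O",)),
        LigandTemplate("cyano", ("C",), tail=("N",)),
        LigandTemplate("thioether", ("S",), tail=("C",)),
        LigandTemplate("amine_chain", ("N",), tail=("C", "C")),
        LigandTemplate("diphos", ("P", "P")),
        LigandTemplate("diphos_methyl", ("P", "P"), n_decor=1),
        LigandTemplate("triphos", ("P", "P", "P")),
        LigandTemplate("triphos_methyl", ("P", "P", "P"), n_decor=1),
        LigandTemplate("tetraphos", ("P", "P", "P", "P")),
    ]
}

# chelate backbone constants (A): bridge = a*u1 + b*m_hat + h*w_hat, where
# u1 is the donor site direction, m_hat the in-shell tangent toward the
# partner site and w_hat the out-of-shell normal (sign alternates per pair)
_BR_RADIAL, _BR_TANGENT, _BR_LIFT = 2.75, 1.55, 0.8
_TAIL_BOND = 1.45


def _bridge_positions(u1: np.ndarray, u2: np.ndarray, w: np.ndarray) -> list[np.ndarray]:
    b1 = _BR_RADIAL * u1 + _BR_TANGENT * u2 + _BR_LIFT * w
    b2 = _BR_TANGENT * u1 + _BR_RADIAL * u2 + _BR_LIFT * w
    return [b1, b2]


def make_toy_complex(
    metal: str,
    templates: Sequence[LigandTemplate | str],
    geometry: str = "octahedral",
    seed: int = 0,
    jitter: Optional[float] = None,
    config: Config = DEFAULTS,
    source_id: str = "",
) -> TMComplex:
    """Assemble a complex from template ligands on an ideal coordination shell.

    The template denticities must sum to the geometry's coordination number;
    polydentate templates are only accepted on geometries whose consecutive
    sites are cis (~90 deg).  Deterministic for a given seed.
    """
    if geometry not in GEOMETRIES:
        raise ValueError(f"unknown geometry {geometry!r}; known: {sorted(GEOMETRIES)}")
    sites = GEOMETRIES[geometry]
    tmpl = [TEMPLATES[t] if isinstance(t, str) else t for t in templates]
    total_dent = sum(t.denticity for t in tmpl)
    if total_dent != len(sites):
        raise ValueError(
            f"denticity sum {total_dent} incompatible with {geometry} (CN={len(sites)})"
        )
    if any(t.denticity > 1 for t in tmpl) and geometry not in CIS_ORDERED:
        raise ValueError(
            f"polydentate templates require a cis-ordered geometry {CIS_ORDERED}, got {geometry}"
        )
    rng = np.random.default_rng(seed)
    jitter = config.jitter if jitter is None else jitter

    elements: list[str] = [metal]
    coords: list[np.ndarray] = [np.zeros(3)]
    site_cursor = 0
    for t in tmpl:
        occ = sites[site_cursor: site_cursor + t.denticity]
        site_cursor += t.denticity
        if t.denticity == 1:
            u = occ[0]
            d0 = DONOR_DISTANCE[t.donors[0]]
            elements.append(t.donors[0])
            coords.append(d0 * u)
            for k, el in enumerate(t.tail):
                elements.append(el)
                coords.append((d0 + _TAIL_BOND * (k + 1)) * u)
        else:
            donor_pos = []
            for el, u in zip(t.donors, occ):
                elements.append(el)
                donor_pos.append(DONOR_DISTANCE[el] * u)
                coords.append(donor_pos[-1])
            bridges = []
            for p in range(t.denticity - 1):
                u1, u2 = occ[p], occ[p + 1]
                w = np.cross(u1, u2)
                w /= np.linalg.norm(w)
                if p % 2 == 1:
                    w = -w
                bridges.extend(_bridge_positions(u1, u2, w))
            for b in bridges:
                elements.append("C")
                coords.append(b)
            for k in range(t.n_decor):
                b = bridges[k % len(bridges)]
                elements.append("C")
                coords.append(b + _TAIL_BOND * b / np.linalg.norm(b))
    xyz = np.array(coords)
    if jitter > 0:
        # metal stays exactly at the origin; ligand atoms get uniform jitter
        xyz[1:] += rng.uniform(-jitter, jitter, size=(len(coords) - 1, 3))
    cx = TMComplex(
        elements=elements,
        coords=xyz,
        metal_index=0,
        source_id=source_id or f"toy-{metal}-{geometry}-{seed}",
    )
    cx.target_cn = len(sites)
    partition_ligands(cx, config.bond_tolerance, config.metal_tolerance)
    expected = sorted(t.denticity for t in tmpl)
    got = sorted(l.denticity for l in cx.ligands)
    if got != expected:
        raise AssertionError(
            f"fixture construction broke denticities: wanted {expected}, got {got}"
        )
    return cx


_MONO = ("aqua", "ammine", "chloro", "methyl", "carbonyl", "cyano", "thioether",
         "amine_chain")
# octahedral ligand compositions by denticity pattern
_OCTA_PATTERNS = [
    (1, 1, 1, 1, 1, 1), (2, 1, 1, 1, 1), (2, 2, 1, 1), (2, 2, 2),
    (3, 1, 1, 1), (3, 2, 1), (3, 3), (4, 1, 1), (4, 2),
]
_BY_DENT = {
    1: _MONO,
    2: ("diphos", "diphos_methyl"),
    3: ("triphos", "triphos_methyl"),
    4: ("tetraphos",),
}


def make_corpus(
    n: int,
    seed: int = 0,
    monodentate_only: bool = False,
    config: Config = DEFAULTS,
) -> tuple[list[TMComplex], list[MaskingSample]]:
    """Draw ``n`` toy complexes and expand them by multi-ligand masking.

    Complexes mix metals, geometries and template compositions; the joint
    ligand-size/denticity distribution follows the corpus rule that
    polydentate ligands are larger.  ``monodentate_only`` restricts to
    octahedral complexes with six monodentate ligands (63 maskings each).
    Bit-reproducible for a given (n, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    complexes = []
    for i in range(n):
        metal = CORPUS_METALS[int(rng.integers(len(CORPUS_METALS)))]
        if monodentate_only:
            geometry, pattern = "octahedral", (1,) * 6
        elif rng.random() < 0.7:
            geometry = "octahedral"
            pattern = _OCTA_PATTERNS[int(rng.integers(len(_OCTA_PATTERNS)))]
        else:
            geometry = ("trigonal_planar", "tetrahedral", "square_planar",
                        "trigonal_bipyramidal", "square_pyramidal")[int(rng.integers(5))]
            pattern = (1,) * len(GEOMETRIES[geometry])
        names = [
            _BY_DENT[d][int(rng.integers(len(_BY_DENT[d])))] for d in pattern
        ]
        complexes.append(
            make_toy_complex(
                metal, names, geometry, seed=int(rng.integers(2**31)),
                config=config, source_id=f"corpus-{seed}-{i:05d}",
            )
        )
    samples = expand_training_set(complexes)
    return complexes, samples


def make_recovery_task(
    seed: int = 0,
    n: int = 500,
    masked_element: str = "N",
    target_distance: float = 2.0,
) -> list[tuple[TMComplex, MaskingSample]]:
    """Parameter-recovery corpus: the masked ligand is always a single
    ``masked_element`` atom at exactly ``target_distance`` A from the metal,
    trans to the unique sulfur marker donor in the context.

    Context = 4 equatorial O donors + 1 axial S marker; the whole complex gets
    a random global rotation per sample (the placement rule is the only thing
    to learn, and it is rotation-covariant).  Balanced across 3 metals.
    """
    rng = np.random.default_rng(seed)
    metals = ("Fe", "Co", "Ni")
    out = []
    for i in range(n):
        metal = metals[i % 3]
        # S marker at +z (2.3 A), target N at -z (2.0 A), O's equatorial
        elements = [metal, "S", "O", "O", "O", "O", masked_element]
        coords = np.array([
            [0.0, 0.0, 0.0],
            [0.0, 0.0, 2.3],
            [2.0, 0.0, 0.0],
            [0.0, 2.0, 0.0],
            [-2.0, 0.0, 0.0],
            [0.0, -2.0, 0.0],
            [0.0, 0.0, -target_distance],
        ])
        # random proper rotation
        q = rng.standard_normal(4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        cx = TMComplex(
            elements=elements,
            coords=coords @ R.T,
            metal_index=0,
            source_id=f"recovery-{seed}-{i:05d}",
        )
        partition_ligands(cx)
        # the masked ligand is the one holding the target atom (index 6)
        masked = [k for k, lig in enumerate(cx.ligands) if 6 in lig.atom_indices]
        assert len(masked) == 1 and cx.ligands[masked[0]].n_atoms == 1
        out.append((cx, MaskingSample(cx.source_id, (masked[0],), cn_g=1)))
    return out


def recovery_context(seed: int = 0, metal: str = "Fe"):
    """A fresh 5-donor context (CN_c = 5) for evaluating recovery training."""
    from .embedding import Context
    from .complexes import subcomplex

    pairs = make_recovery_task(seed=seed, n=1)
    cx, sample = pairs[0]
    cx2 = TMComplex(
        elements=[metal] + cx.elements[1:],
        coords=cx.coords.copy(),
        metal_index=0,
        source_id=f"recovery-context-{seed}",
    )
    partition_ligands(cx2)
    keep = [i for i in range(len(cx2.ligands)) if i != sample.masked_ligands[0]]
    return Context(subcomplex(cx2, keep))
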