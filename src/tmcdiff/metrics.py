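"""Generation metrics: validity, connectivity, complex validity, novelty,
uniqueness, plus metal-donor bond-length statistics and conformer RMSD.

All ratios are reported with exact integer numerators and denominators so
that ratios of concatenated batches equal count-weighted means.  The
connectivity ratio is defined over *valid* ligands only, so its denominator
equals the validity numerator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit.rdBase import BlockLogs
from scipy.spatial.transform import Rotation

from .complexes import Ligand, TMComplex, pair_cutoff, perceive_bonds
from .config import DEFAULTS, Config
from .elements import covalent_radius
from .io import _ligand_bonds, _mol_from_block


@dataclass(frozen=True)
class Ratio:
    numerator: int
    denominator: int

    @property
    def value(self) -> float:
        if self.denominator == 0:
            raise ZeroDivisionError("ratio over an empty set")
        return self.numerator / self.denominator

    def __float__(self) -> float:
        return self.value


@dataclass
class GenerationReport:
    """The five generation metrics with counts and per-item diagnostics."""

    p_l_val: Ratio
    p_l_con: Ratio
    p_c_val: Ratio
    p_l_nov: Optional[Ratio] = None
    p_l_uniq: Optional[Ratio] = None
    diagnostics: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        out = {}
        for key in ("p_l_val", "p_l_con", "p_c_val", "p_l_nov", "p_l_uniq"):
            r = getattr(self, key)
            if r is not None:
                out[key] = {"value": r.value, "numerator": r.numerator,
                            "denominator": r.denominator}
        return out


LigandBlock = tuple[list[str], np.ndarray]   # (elements, coords)


def _as_block(item, config: Config) -> LigandBlock:
    if isinstance(item, tuple) and len(item) == 2 and isinstance(item[1], np.ndarray):
        return item
    raise TypeError("expected (elements, coords) ligand block")


def ligand_is_valid(elements: Sequence[str], coords: np.ndarray,
                    config: Config = DEFAULTS) -> bool:
    """Chemically valid iff RDKit sanitization accepts the perceived bond
    graph (single bonds, implicit hydrogens fill remaining valences)."""
    if len(elements) == 0:
        return False
    mol = _mol_from_block(list(elements), np.asarray(coords),
                          _ligand_bonds(elements, coords, config.bond_tolerance))
    try:
        with BlockLogs():
            Chem.SanitizeMol(mol)
        return True
    except Exception:
        return False


def ligand_is_connected(elements: Sequence[str], coords: np.ndarray,
                        config: Config = DEFAULTS) -> bool:
    g = nx.Graph()
    g.add_nodes_from(range(len(elements)))
    g.add_edges_from(_ligand_bonds(elements, coords, config.bond_tolerance))
    return nx.is_connected(g) if len(elements) > 0 else False


def ligand_validity(ligands: Sequence[LigandBlock], config: Config = DEFAULTS) -> Ratio:
    """p_l^val: chemically valid ligands / all generated ligands."""
    if not ligands:
        raise ValueError("ligand_validity over an empty set")
    ok = sum(ligand_is_valid(e, c, config) for e, c in ligands)
    return Ratio(ok, len(ligands))


def ligand_connectivity(valid_ligands: Sequence[LigandBlock],
                        config: Config = DEFAULTS) -> Ratio:
    """p_l^con: single-component ligands / all valid ligands."""
    ok = sum(ligand_is_connected(e, c, config) for e, c in valid_ligands)
    return Ratio(ok, len(valid_ligands))


def check_complex(
    cx: TMComplex,
    config: Config = DEFAULTS,
    target_cn: Optional[int] = None,
    checks: Sequence[str] = ("ligands", "cn", "clash", "donor"),
) -> tuple[bool, dict]:
    """The four complex-validity rules, individually toggleable:

    (a) ``ligands``: every generated ligand is valid and connected;
    (b) ``cn``: realized total denticity equals the target CN;
    (c) ``clash``: no inter-atomic distance < clash_factor x covalent sum;
    (d) ``donor``: every generated ligand has >= 1 donor within metal cutoff.
    """
    if cx.ligands is None:
        from .complexes import partition_ligands

        partition_ligands(cx, config.bond_tolerance, config.metal_tolerance)
    gen = (cx.generated_ligand_indices
           if cx.generated_ligand_indices is not None
           else tuple(range(len(cx.ligands))))
    target = target_cn if target_cn is not None else cx.target_cn
    detail = {}
    if "ligands" in checks:
        ok = True
        for gi in gen:
            lig = cx.ligands[gi]
            el, co = cx.ligand_elements(lig), cx.ligand_coords(lig)
            if not (ligand_is_valid(el, co, config) and ligand_is_connected(el, co, config)):
                ok = False
                break
        detail["ligands"] = ok
    if "cn" in checks and target is not None:
        # only checkable when a target CN is known (generation runs record it)
        detail["cn"] = cx.coordination_number == target
    if "clash" in checks:
        d = np.linalg.norm(cx.coords[:, None] - cx.coords[None, :], axis=-1)
        radii = np.array([covalent_radius(e) for e in cx.elements])
        lim = config.clash_factor * (radii[:, None] + radii[None, :])
        np.fill_diagonal(d, np.inf)
        detail["clash"] = bool(np.all(d >= lim))
    if "donor" in checks:
        detail["donor"] = all(cx.ligands[gi].denticity >= 1 for gi in gen)
    return all(detail.values()), detail


def complex_validity(
    complexes: Sequence[TMComplex],
    config: Config = DEFAULTS,
    target_cn: Optional[int] = None,
    checks: Sequence[str] = ("ligands", "cn", "clash", "donor"),
) -> Ratio:
    """p_c^val: valid complexes / all generated complexes."""
    ok = sum(check_complex(cx, config, target_cn, checks)[0] for cx in complexes)
    return Ratio(ok, len(complexes))


def novelty(generated_smiles: Sequence[str], training_smiles: Iterable[str]) -> Ratio:
    """p_l^nov: generated ligand strings absent from the training set."""
    train = set(training_smiles)
    new = sum(s not in train for s in generated_smiles)
    return Ratio(new, len(generated_smiles))


def uniqueness(generated_smiles: Sequence[str]) -> Ratio:
    """p_l^uniq: distinct ligand strings / all generated ligands."""
    return Ratio(len(set(generated_smiles)), len(generated_smiles))


def bond_length_profile(cx: TMComplex, spin_label: str = "") -> float:
    """Arithmetic mean metal-donor distance (A).

    HS geometries typically run ~0.2 A longer than LS ones; batch histograms
    of these means visualise that shift."""
    if cx.ligands is None:
        raise ValueError("ligands not partitioned")
    donors = [i for lig in cx.ligands for i in lig.coordinating_atom_indices]
    if not donors:
        raise ValueError(f"complex {cx.source_id} has zero donors")
    d = np.linalg.norm(cx.coords[donors] - cx.metal_coord, axis=-1)
    return float(np.mean(d))


def bond_length_histogram(
    complexes: Sequence[TMComplex],
    bins: int = 20,
    range_: tuple[float, float] = (1.6, 2.8),
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (counts, edges) of per-complex mean metal-donor distances."""
    means = [bond_length_profile(cx) for cx in complexes]
    return np.histogram(means, bins=bins, range=range_)


def conformer_rmsd(complex_a: TMComplex, complex_b: TMComplex) -> float:
    """Least-squares RMSD (A) after optimal rigid superposition (Kabsch),
    with atom correspondence given by input order."""
    if complex_a.n_atoms != complex_b.n_atoms:
        raise ValueError("atom count mismatch")
    if sorted(complex_a.elements) != sorted(complex_b.elements):
        raise ValueError("element multiset mismatch")
    a = complex_a.coords - complex_a.coords.mean(axis=0)
    b = complex_b.coords - complex_b.coords.mean(axis=0)
    rot, rssd = Rotation.align_vectors(a, b)
    return float(rssd / np.sqrt(a.shape[0]))


def aggregate_reports(reports: Sequence[GenerationReport]) -> dict:
    """Mean +/- std of each metric across independent runs."""
    out = {}
    for key in ("p_l_val", "p_l_con", "p_c_val", "p_l_nov", "p_l_uniq"):
        vals = [getattr(r, key).value for r in reports if getattr(r, key) is not None]
        if vals:
            out[key] = {"mean": float(np.mean(vals)), "std": float(np.std(vals)),
                        "n_runs": len(vals)}
    return out


def evaluate_generated(
    complexes: Sequence[TMComplex],
    training_smiles: Optional[Iterable[str]] = None,
    config: Config = DEFAULTS,
    target_cn: Optional[int] = None,
) -> GenerationReport:
    """Full metric bundle over a batch of generated complexes."""
    from .io import ligand_smiles

    blocks, smiles, diags = [], [], []
    for cx in complexes:
        gen = (cx.generated_ligand_indices
               if cx.generated_ligand_indices is not None
               else tuple(range(len(cx.ligands or []))))
        for gi in gen:
            lig = cx.ligands[gi]
            blocks.append((cx.ligand_elements(lig), cx.ligand_coords(lig)))
            smiles.append(ligand_smiles(cx, lig, config))
    p_val = ligand_validity(blocks, config)
    valid_blocks = [b for b in blocks if ligand_is_valid(*b, config)]
    p_con = ligand_connectivity(valid_blocks, config) if valid_blocks else Ratio(0, 0)
    p_cval = complex_validity(complexes, config, target_cn)
    for cx in complexes:
        ok, detail = check_complex(cx, config, target_cn)
        diags.append({"id": cx.source_id, "valid": ok, **detail})
    report = GenerationReport(
        p_l_val=p_val, p_l_con=p_con, p_c_val=p_cval,
        p_l_uniq=uniqueness(smiles) if smiles else None,
        diagnostics=diags,
    )
    if training_smiles is not None and smiles:
        report.p_l_nov = novelty(smiles, training_smiles)
    return report
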