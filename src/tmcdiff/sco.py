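"""Spin-crossover candidate screening pipeline.

Workflow: enumerate ligand-generation variations from reference complexes,
generate the missing ligands by reverse diffusion, validate structures, run
the (pluggable) hydrogen/charge hooks, optimize both spin states through an
energy backend, classify the ground state and keep candidates whose
high-spin/low-spin gap is at most 10 kcal/mol (inclusive).  Quantum-chemistry
engines are represented only as a backend interface; the bundled mock backend
makes the whole pipeline testable offline.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Protocol, Sequence

import numpy as np

from .complexes import TMComplex, partition_ligands
from .config import DEFAULTS, Config
from .masking import (
    LDgSpec,
    MaskingSample,
    enumerate_ldg,
    enumerate_maskings,
    sample_ligand_sizes,
)

log = logging.getLogger(__name__)

HARTREE_TO_KCAL = 627.509474


@dataclass
class SpinPair:
    """HS/LS energies (kcal/mol, common reference) for one complex."""

    complex_id: str
    e_hs: Optional[float] = None
    e_ls: Optional[float] = None
    hs_converged: bool = True
    ls_converged: bool = True

    @property
    def gap(self) -> float:
        """E_HS - E_LS; finite only when both optimizations succeeded."""
        if not (self.hs_converged and self.ls_converged):
            return float("nan")
        if self.e_hs is None or self.e_ls is None:
            return float("nan")
        return self.e_hs - self.e_ls


class EnergyBackend(Protocol):
    """Interface to an external optimizer/energy engine.

    Implementations must be deterministic for fixed input and settings.
    ``optimize`` returns (coords, energy_kcal, converged)."""

    name: str

    def optimize(self, cx: TMComplex, charge: int, multiplicity: int
                 ) -> tuple[np.ndarray, float, bool]: ...


class MockBackend:
    """Deterministic stand-in backend (synthetic energies, no chemistry).

    Energies come from a lookup table (JSON fixture mapping complex id to
    ``{"e_hs": .., "e_ls": .., "hs_converged": .., "ls_converged": ..}``,
    values in kcal/mol) or, for ids not in the table, from a stable hash of
    (id, multiplicity) so that any generated complex gets a reproducible
    pseudo-energy.  Geometries are passed through unchanged.
    """

    name = "mock"

    def __init__(self, table: Optional[dict | str | Path] = None,
                 units: str = "kcal/mol", gap_scale: float = 30.0):
        if isinstance(table, (str, Path)):
            table = json.loads(Path(table).read_text())
        self.table = table or {}
        self.units = units
        self.gap_scale = gap_scale

    def _to_kcal(self, e: float) -> float:
        return e * HARTREE_TO_KCAL if self.units == "hartree" else e

    def optimize(self, cx: TMComplex, charge: int, multiplicity: int):
        entry = self.table.get(cx.source_id)
        state = "hs" if multiplicity > 2 else "ls"
        if entry is not None:
            energy = self._to_kcal(float(entry[f"e_{state}"]))
            converged = bool(entry.get(f"{state}_converged", True))
            return cx.coords.copy(), energy, converged
        h = hashlib.sha256(f"{cx.source_id}|{multiplicity}".encode()).digest()
        u = int.from_bytes(h[:8], "big") / 2**64
        return cx.coords.copy(), self.gap_scale * (u - 0.5), True


def enumerate_sco_variations(
    references: Sequence[TMComplex],
    max_ligand_size: int = 10,
    seed: int = 0,
) -> list[tuple[MaskingSample, LDgSpec]]:
    """All maskings x legal LD_g partitions per reference, with sizes drawn
    at most ``max_ligand_size`` heavy atoms (the screening cap).

    A reference with two tridentate ligands yields 3 + 3 + 11 = 17 variations.
    """
    rng = np.random.default_rng(seed)
    out = []
    for cx in references:
        if cx.ligands is None:
            partition_ligands(cx)
        for sample in enumerate_maskings(cx):
            for ldg in enumerate_ldg(sample.cn_g):
                sizes = sample_ligand_sizes(ldg.partition, rng,
                                            max_size=max_ligand_size)
                out.append((sample, LDgSpec(ldg.partition, sizes)))
    return out


def classify_ground_state(pair: SpinPair) -> str:
    """"HS" iff E_HS < E_LS, else "LS" (ties -> LS with a warning)."""
    if pair.e_hs is None or pair.e_ls is None:
        raise ValueError(f"missing energy for {pair.complex_id}")
    if pair.e_hs == pair.e_ls:
        log.warning("degenerate spin states for %s; classifying as LS",
                    pair.complex_id)
        return "LS"
    return "HS" if pair.e_hs < pair.e_ls else "LS"


def spin_gap_filter(
    pairs: Sequence[SpinPair],
    threshold: float = DEFAULTS.spin_gap_threshold,
) -> list[SpinPair]:
    """Retain candidates with |E_HS - E_LS| <= threshold (boundary inclusive);
    NaN gaps (failed optimizations) are dropped."""
    return [p for p in pairs if np.isfinite(p.gap) and abs(p.gap) <= threshold]


@dataclass
class StageCount:
    name: str
    n_in: int
    retained: int
    dropped: int


@dataclass
class ScreeningReport:
    stages: list[StageCount] = field(default_factory=list)
    candidates: list[dict] = field(default_factory=list)
    n_hs_ground: int = 0
    n_ls_ground: int = 0

    def add_stage(self, name: str, n_in: int, retained: int):
        self.stages.append(StageCount(name, n_in, retained, n_in - retained))

    def to_json(self, path: str | Path):
        Path(path).write_text(json.dumps({
            "stages": [vars(s) for s in self.stages],
            "n_hs_ground": self.n_hs_ground,
            "n_ls_ground": self.n_ls_ground,
            "candidates": self.candidates,
        }, indent=2))

    def to_tsv(self, path: str | Path):
        with open(path, "w") as fh:
            fh.write("stage\tn_in\tretained\tdropped\n")
            for s in self.stages:
                fh.write(f"{s.name}\t{s.n_in}\t{s.retained}\t{s.dropped}\n")


def _passthrough_hook(cx: TMComplex) -> tuple[TMComplex, int]:
    """Default hydrogen/charge hook: no chemistry, total charge 0."""
    return cx, 0


def run_workflow(
    references: Sequence[TMComplex],
    backend: EnergyBackend,
    model,
    seed: int = 0,
    config: Config = DEFAULTS,
    max_ligand_size: int = 10,
    multiplicities: tuple[int, int] = (5, 1),   # (HS, LS); Fe(II)-like default
    hydrogen_charge_hook: Callable[[TMComplex], tuple[TMComplex, int]] = _passthrough_hook,
    threshold: Optional[float] = None,
    schedule=None,
    max_variations: Optional[int] = None,
) -> ScreeningReport:
    """The full screening pipeline with per-stage attrition accounting.

    Stage conservation (input = retained + dropped) holds at every stage;
    backend failures flag the item and the pipeline continues.
    ``max_variations`` truncates the enumeration for desk-scale runs.
    """
    from .diffusion import sample_ligands
    from .embedding import Context
    from .complexes import subcomplex
    from .metrics import check_complex

    threshold = config.spin_gap_threshold if threshold is None else threshold
    report = ScreeningReport()
    rng = np.random.default_rng(seed)

    variations = enumerate_sco_variations(references, max_ligand_size, seed)
    by_id = {cx.source_id: cx for cx in references}
    if max_variations is not None:
        variations = variations[: max_variations]
    report.add_stage("enumerate", len(variations), len(variations))

    generated: list[TMComplex] = []
    for sample, ldg in variations:
        parent = by_id[sample.parent_id]
        keep = [i for i in range(len(parent.ligands))
                if i not in sample.masked_ligands]
        ctx = Context(subcomplex(parent, keep))
        try:
            cx = sample_ligands(ctx, ldg, ldg.sizes, model,
                                seed=int(rng.integers(2**31)),
                                schedule=schedule, config=config)
            generated.append(cx)
        except Exception as exc:
            log.warning("generation failed for %s %s: %s",
                        sample.parent_id, ldg.label, exc)
    report.add_stage("generate", len(variations), len(generated))

    valid = [cx for cx in generated if check_complex(cx, config)[0]]
    report.add_stage("validate", len(generated), len(valid))

    hooked = []
    for cx in valid:
        cx2, charge = hydrogen_charge_hook(cx)
        hooked.append((cx2, charge))
    report.add_stage("hydrogen_charge_hook", len(valid), len(hooked))

    pairs: list[SpinPair] = []
    for cx, charge in hooked:
        mult_hs, mult_ls = multiplicities
        _, e_hs, ok_hs = backend.optimize(cx, charge, mult_hs)
        _, e_ls, ok_ls = backend.optimize(cx, charge, mult_ls)
        pairs.append(SpinPair(cx.source_id, e_hs, e_ls, ok_hs, ok_ls))
    converged = [p for p in pairs if np.isfinite(p.gap)]
    report.add_stage("optimize", len(pairs), len(converged))

    retained = spin_gap_filter(converged, threshold)
    report.add_stage("spin_gap_filter", len(converged), len(retained))

    for p in retained:
        state = classify_ground_state(p)
        if state == "HS":
            report.n_hs_ground += 1
        else:
            report.n_ls_ground += 1
        report.candidates.append(
            {"id": p.complex_id, "gap_kcal_mol": p.gap, "ground_state": state}
        )
    return report
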