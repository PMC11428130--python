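"""Multi-ligand masking combinatorics and denticity-partition enumeration.

Training-set expansion masks every non-empty subset of a complex's ligands
(``2^l - 1`` samples per complex, so an octahedral complex with six
monodentate ligands yields 63).  Each masking frees a coordination number
CN_g = 6 - CN_c, and the denticities assigned to the ligands to be generated
form an integer partition of CN_g, written by concatenating digits
("21" = one bidentate + one monodentate).  There are p(6) = 11 partitions
for total generation and sum(p(1..5)) = 18 for partial generation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .complexes import TMComplex, partition_ligands

OCTAHEDRAL_CN = 6


@dataclass(frozen=True)
class MaskingSample:
    """A reference complex plus the ligand subset chosen for regeneration."""

    parent_id: str
    masked_ligands: tuple[int, ...]
    cn_g: int

    def __post_init__(self):
        if not self.masked_ligands:
            raise ValueError("masked ligand set must be non-empty")


@dataclass(frozen=True)
class LDgSpec:
    """An ordered multiset of target denticities: an integer partition of CN_g."""

    partition: tuple[int, ...]
    sizes: Optional[tuple[int, ...]] = None   # heavy atoms per generated ligand

    def __post_init__(self):
        if not self.partition or any(d < 1 for d in self.partition):
            raise ValueError("partition parts must be positive")
        if tuple(sorted(self.partition, reverse=True)) != self.partition:
            raise ValueError("partition must be in canonical non-increasing form")
        if self.sizes is not None and len(self.sizes) != len(self.partition):
            raise ValueError("one size per generated ligand required")

    @property
    def cn_g(self) -> int:
        return sum(self.partition)

    @property
    def label(self) -> str:
        """Concatenated-digit notation, e.g. (2, 1) -> "21"."""
        return "".join(str(d) for d in self.partition)

    @classmethod
    def from_label(cls, label: str, sizes: Optional[Sequence[int]] = None) -> "LDgSpec":
        parts = tuple(sorted((int(ch) for ch in label), reverse=True))
        return cls(parts, tuple(sizes) if sizes is not None else None)


def enumerate_maskings(complex: TMComplex) -> list[MaskingSample]:
    """One sample per non-empty ligand subset, 2^l - 1 in total.

    Identical ligands are distinguishable by position (the corpus expansion
    counts an all-monodentate octahedron as 63 samples, i.e. by subset, not
    by multiset).  Order: subset size ascending, then lexicographic.
    """
    if complex.ligands is None:
        partition_ligands(complex)
    l = len(complex.ligands)
    if l == 0:
        raise ValueError("no ligands to mask")
    dents = [lig.denticity for lig in complex.ligands]
    samples = []
    for k in range(1, l + 1):
        for subset in combinations(range(l), k):
            samples.append(
                MaskingSample(
                    parent_id=complex.source_id,
                    masked_ligands=subset,
                    cn_g=sum(dents[i] for i in subset),
                )
            )
    return samples


def enumerate_ldg(cn_g: int) -> list[LDgSpec]:
    """All integer partitions of ``cn_g`` in descending lexicographic order.

    For an octahedral parent 1 <= cn_g <= 6; larger values are allowed (with a
    warning) for non-octahedral transfer inputs.
    """
    if cn_g <= 0:
        raise ValueError(f"CN_g must be positive, got {cn_g}")
    if cn_g > OCTAHEDRAL_CN:
        import warnings

        warnings.warn(
            f"CN_g={cn_g} exceeds the octahedral coordination number 6",
            stacklevel=2,
        )

    def _parts(n: int, cap: int) -> Iterable[tuple[int, ...]]:
        if n == 0:
            yield ()
            return
        for head in range(min(n, cap), 0, -1):
            for tail in _parts(n - head, head):
                yield (head,) + tail

    return [LDgSpec(p) for p in _parts(cn_g, cn_g)]


def partition_count(n: int) -> int:
    return len(enumerate_ldg(n)) if n > 0 else 1


def count_partial_ldg(total_cn: int = OCTAHEDRAL_CN) -> int:
    """Number of LD_g choices available for partial generation (CN_g < 6): 18."""
    return sum(partition_count(n) for n in range(1, total_cn))


def count_variations(complex: TMComplex) -> int:
    """Total generation variations: sum over maskings of p(CN_g).

    A reference with two tridentate ligands gives 3 + 3 + 11 = 17.
    Invariant under ligand relabeling (depends only on the denticity multiset).
    """
    return sum(partition_count(s.cn_g) for s in enumerate_maskings(complex))


def sample_ligand_sizes(
    partition: Sequence[int],
    rng: np.random.Generator,
    max_size: Optional[int] = None,
) -> tuple[int, ...]:
    """Training-expansion size policy: uniform <=10 heavy atoms for denticity
    < 3, uniform 10-30 for denticity >= 3 (mirroring the corpus size/denticity
    correlation).  ``max_size`` caps sizes (screening uses <=10)."""
    sizes = []
    for dent in partition:
        if dent < 3:
            lo, hi = max(dent, 1), 10
        else:
            lo, hi = 10, 30
        if max_size is not None:
            hi = min(hi, max_size)
            lo = min(max(lo, dent), hi)
        sizes.append(int(rng.integers(lo, hi + 1)))
    return tuple(sizes)


def expand_training_set(
    complexes: Iterable[TMComplex],
    on_error: str = "skip",
) -> list[MaskingSample]:
    """Concatenated masking enumeration over a corpus, with stable provenance.

    Complexes that fail partitioning are skipped and logged (``on_error="skip"``)
    or re-raised (``on_error="raise"``).
    """
    import logging

    log = logging.getLogger(__name__)
    out: list[MaskingSample] = []
    for cx in complexes:
        try:
            out.extend(enumerate_maskings(cx))
        except Exception as exc:
            if on_error == "raise":
                raise
            log.warning("skipping complex %s: %s", cx.source_id, exc)
    return out


# --- JSON-lines manifests ---------------------------------------------------

def write_manifest(
    path: str | Path,
    entries: Iterable[tuple[MaskingSample, LDgSpec]],
    seed: Optional[int] = None,
) -> int:
    n = 0
    with open(path, "w") as fh:
        for sample, ldg in entries:
            fh.write(json.dumps({
                "complex_id": sample.parent_id,
                "masked_ligands": list(sample.masked_ligands),
                "cn_g": sample.cn_g,
                "ldg": ldg.label,
                "sizes": list(ldg.sizes) if ldg.sizes else None,
                "seed": seed,
            }) + "\n")
            n += 1
    return n


def read_manifest(path: str | Path) -> list[tuple[MaskingSample, LDgSpec]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        out.append((
            MaskingSample(d["complex_id"], tuple(d["masked_ligands"]), d["cn_g"]),
            LDgSpec.from_label(d["ldg"], d["sizes"]),
        ))
    return out
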