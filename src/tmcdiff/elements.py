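"""Element vocabulary and covalent-radius lookups.

The training corpus is restricted to the element set
``S = {H, C, N, O, F, P, S, Cl, Br, Cr, Mn, Fe, Co, Ni, Cu, Zn}``;
hydrogens are stripped on ingest, leaving 15 heavy-element channels for the
one-hot atom-type embedding.  Covalent radii are taken from RDKit's periodic
table (Cordero et al. compilation).
"""

from __future__ import annotations

from functools import lru_cache

from rdkit import Chem

#: full curated element set (including hydrogen, removed on ingest)
ELEMENT_SET_S = (
    "H", "C", "N", "O", "F", "P", "S", "Cl", "Br",
    "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
)

#: heavy-atom vocabulary used for the one-hot h_a channels (m = 15)
HEAVY_ELEMENTS = tuple(e for e in ELEMENT_SET_S if e != "H")

#: transition metals appearing as centres in the curated corpus
CORPUS_METALS = ("Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn")

#: all d-block symbols accepted as centres for transferability inputs
D_BLOCK = (
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd",
    "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
)

_PT = Chem.GetPeriodicTable()


class UnknownElementError(ValueError):
    """Raised when an element symbol is not recognised."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(f"unknown element symbol: {symbol!r}")


@lru_cache(maxsize=None)
def covalent_radius(symbol: str) -> float:
    """Covalent radius in Angstrom for an element symbol."""
    try:
        z = _PT.GetAtomicNumber(symbol)
    except Exception:
        raise UnknownElementError(symbol) from None
    if z <= 0:
        raise UnknownElementError(symbol)
    return float(_PT.GetRcovalent(z))


def is_metal(symbol: str) -> bool:
    return symbol in D_BLOCK


def heavy_index(symbol: str) -> int:
    """Index of a heavy element in the one-hot vocabulary."""
    try:
        return HEAVY_ELEMENTS.index(symbol)
    except ValueError:
        raise UnknownElementError(symbol) from None
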