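"""Interface size ratio R, interface hydrophobicity H, and the
two-state/three-state boundary classification.

For a chain pair (x, y) with residue-level contact counts::

    R(xy) = N_inter(xy) / (0.5 * (N_intra(x) + N_intra(y)))

R is a proxy for the size of the interface relative to the monomer cores.
H averages a residue hydrophobicity factor h_i in [0, 1] over the
2 * N_inter residue *incidences* of the inter-chain contacts -- a residue
participating in k contacts is counted k times::

    H(xy) = sum_incidences(h_i) / (2 * N_inter(xy))

Homodimers with high H and R fold in a two-state manner (directly from
unfolded monomers to the folded dimer); low values go with three-state
folding through an intermediate.  An empirical straight line in (R, H)
space, H/0.5 + R/1.8 = 1, separates the two groups and is used here as a
reference boundary.

The hydrophobicity scale is swappable; the default is the Kyte-Doolittle
sidechain scale rescaled to [0, 1] by min-max normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

from .contacts import ContactSet
from .structures import ChainModel

__all__ = [
    "HydrophobicityScale", "KD_NORMALIZED", "DEFAULT_NONPOLAR",
    "InterfaceRecord", "ratio_R", "hydrophobicity_H", "nonpolar_fraction",
    "classify_fold_regime", "interface_record", "UndefinedMetricError",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is empty (no contacts)."""


_KD_RAW = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}


@dataclass(frozen=True)
class HydrophobicityScale:
    table: dict[str, float]
    scale_name: str = "custom"

    def __post_init__(self) -> None:
        missing = set(_KD_RAW) - set(self.table)
        if missing:
            raise ValueError(f"scale lacks standard residues: {sorted(missing)}")
        bad = {k: v for k, v in self.table.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"scale values outside [0, 1]: {bad}")

    def __getitem__(self, residue: str) -> float:
        return self.table[residue]

    def __contains__(self, residue: str) -> bool:
        return residue in self.table


def _minmax(raw: dict[str, float]) -> dict[str, float]:
    lo, hi = min(raw.values()), max(raw.values())
    return {k: (v - lo) / (hi - lo) for k, v in raw.items()}


#: Kyte-Doolittle rescaled so the most hydrophobic residue (ILE) is 1 and the
#: least (ARG) is 0.
KD_NORMALIZED = HydrophobicityScale(_minmax(_KD_RAW), "kyte_doolittle_minmax")

#: Default non-polar residue set for interface composition summaries.
DEFAULT_NONPOLAR = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "GLY"})

ALL_ONES = HydrophobicityScale({k: 1.0 for k in _KD_RAW}, "all_ones")


@dataclass
class InterfaceRecord:
    pair_id: tuple[str, str]
    interface_class: str
    n_inter: int
    n_intra_x: int
    n_intra_y: int
    R: float
    H: float | None
    nonpolar_fraction: float | None
    fold_regime: str
    conformers: tuple[str, str] = ("unknown", "unknown")


def ratio_R(contacts: ContactSet) -> float:
    """Inter- to mean-intra-chain residue contact ratio (interface size)."""
    denom = 0.5 * (contacts.n_intra_x + contacts.n_intra_y)
    if denom == 0:
        raise UndefinedMetricError(
            f"pair {contacts.pair_id}: both intra-chain contact counts are zero")
    return contacts.n_inter / denom


def _residue_names(chain: ChainModel) -> dict[int, str]:
    return {r.index: r.name for r in chain.residues}


def _incidences(contacts: ContactSet, chain_x: ChainModel,
                chain_y: ChainModel) -> list[str]:
    """Residue names of the 2*n_inter incidences (one per side per contact)."""
    nx, ny = _residue_names(chain_x), _residue_names(chain_y)
    out = []
    for i, j in sorted(contacts.residue_pairs_inter):
        out.append(nx[i])
        out.append(ny[j])
    return out


def hydrophobicity_H(contacts: ContactSet, chain_x: ChainModel,
                     chain_y: ChainModel,
                     scale: HydrophobicityScale = KD_NORMALIZED,
                     on_unknown: str = "error") -> float:
    """Average hydrophobicity factor over interface residue incidences.

    ``on_unknown``: 'error' raises for residue codes absent from the scale,
    'skip' drops those incidences with a warning.
    """
    if contacts.n_inter == 0:
        raise UndefinedMetricError(
            f"pair {contacts.pair_id}: H undefined without inter-chain contacts")
    names = _incidences(contacts, chain_x, chain_y)
    known = [n for n in names if n in scale]
    if len(known) < len(names):
        unknown = sorted(set(names) - set(known))
        if on_unknown == "skip":
            warnings.warn(f"residues missing from scale skipped: {unknown}")
        else:
            raise KeyError(f"residues missing from hydrophobicity scale: {unknown}")
    if not known:
        raise UndefinedMetricError("no scored incidences left")
    return sum(scale[n] for n in names) / len(names) if len(known) == len(names) \
        else sum(scale[n] for n in known) / len(known)


def nonpolar_fraction(contacts: ContactSet, chain_x: ChainModel,
                      chain_y: ChainModel,
                      nonpolar: frozenset[str] | set[str] = DEFAULT_NONPOLAR) -> float:
    """Fraction of interface residue incidences with a non-polar residue."""
    if contacts.n_inter == 0:
        raise UndefinedMetricError(
            f"pair {contacts.pair_id}: fraction undefined without contacts")
    names = _incidences(contacts, chain_x, chain_y)
    return sum(1 for n in names if n in nonpolar) / len(names)


def classify_fold_regime(H: float, R: float, tol: float = 1e-9) -> str:
    """Position relative to the boundary line H/0.5 + R/1.8 = 1.

    Points above the line (value > 1) lie with the two-state folding
    dimers; points below with the three-state folders.
    """
    value = H / 0.5 + R / 1.8
    if value > 1.0 + tol:
        return "two_state_side"
    if value < 1.0 - tol:
        return "three_state_side"
    return "on_line"


def interface_record(contacts: ContactSet, chain_x: ChainModel,
                     chain_y: ChainModel, interface_class: str = "unclassified",
                     scale: HydrophobicityScale = KD_NORMALIZED,
                     nonpolar: frozenset[str] = DEFAULT_NONPOLAR) -> InterfaceRecord:
    """Assemble the full per-interface record; H is None when n_inter = 0."""
    R = ratio_R(contacts)
    if contacts.n_inter > 0:
        H = hydrophobicity_H(contacts, chain_x, chain_y, scale)
        npf = nonpolar_fraction(contacts, chain_x, chain_y, nonpolar)
        regime = classify_fold_regime(H, R)
    else:
        H, npf, regime = None, None, "no_interface"
    return InterfaceRecord(
        pair_id=contacts.pair_id, interface_class=interface_class,
        n_inter=contacts.n_inter, n_intra_x=contacts.n_intra_x,
        n_intra_y=contacts.n_intra_y, R=R, H=H, nonpolar_fraction=npf,
        fold_regime=regime,
        conformers=(chain_x.conformer, chain_y.conformer))
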