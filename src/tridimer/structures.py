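"""Capsid structure containers and I/O.

A T=3 icosahedral capsid is built from 180 copies of a single coat protein
(CP) occupying three quasi-equivalent conformations (A, B, C).  The minimal
unit that exhibits every distinct CP-CP interface is the *tri-dimer*: one
icosahedral asymmetric unit (IAU, an A/B/C triple) plus, for each IAU chain,
its partner across the (quasi-)two-fold dimerization axis.

This module reads deposited PDB/mmCIF files (via gemmi), expands an
asymmetric unit with rotation operators when only the IAU plus BIOMT
matrices are deposited, extracts tri-dimers, and writes results back out.
Coordinates are in Angstrom throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "ChainModel",
    "CapsidAssembly",
    "TriDimer",
    "StructureError",
    "EmptyAssemblyError",
    "OperatorError",
    "ExtractionError",
    "read_structure",
    "read_biomt_operators",
    "expand_assembly",
    "extract_tridimer",
    "write_assembly",
    "write_tridimer",
]


class StructureError(ValueError):
    """Base error for structure parsing and manipulation."""


class EmptyAssemblyError(StructureError):
    """Raised when a file contains no usable protein chains."""


class OperatorError(StructureError):
    """Raised for invalid symmetry-expansion operators."""


class ExtractionError(StructureError):
    """Raised when a tri-dimer cannot be located in an assembly."""


@dataclass
class AtomRecord:
    atom_name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    residue_index: int
    alt_loc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"non-finite coordinates for atom {self.atom_name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    name: str  # 3-letter code
    index: int  # author numbering
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None


@dataclass
class ChainModel:
    chain_id: str
    conformer: str = "unknown"  # one of A, B, C, unknown
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise StructureError(
                f"chain {self.chain_id}: residue indices not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coords(self) -> np.ndarray:
        """All atom coordinates, shape (n_atoms, 3)."""
        if not self.residues:
            return np.empty((0, 3))
        return np.array([a.coords for r in self.residues for a in r.atoms])

    def atom_residue_indices(self) -> np.ndarray:
        """Author residue index of each atom, aligned with :meth:`coords`."""
        return np.array([r.index for r in self.residues for _ in r.atoms], dtype=int)

    def ca_map(self) -> dict[int, np.ndarray]:
        """Residue index -> CA coordinate for residues that have a CA atom."""
        out = {}
        for r in self.residues:
            ca = r.atom("CA")
            if ca is not None:
                out[r.index] = ca.coords
        return out

    def centroid(self) -> np.ndarray:
        return self.coords().mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    chain_id: str | None = None) -> "ChainModel":
        rot = np.asarray(rotation, float)
        tr = np.asarray(translation, float)
        residues = [
            Residue(r.name, r.index, [
                AtomRecord(a.atom_name, a.element, rot @ a.coords + tr,
                           a.residue_index, a.alt_loc, a.occupancy)
                for a in r.atoms
            ])
            for r in self.residues
        ]
        return ChainModel(chain_id or self.chain_id, self.conformer, residues)


@dataclass
class CapsidAssembly:
    chains: list[ChainModel]
    source_id: str = ""
    provenance: str = "deposited_assembly"  # or biomt_expanded / synthetic

    def __post_init__(self) -> None:
        labels = [c.chain_id for c in self.chains]
        if len(set(labels)) != len(labels):
            raise StructureError("chain labels are not unique")

    def __len__(self) -> int:
        return len(self.chains)

    def chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)


@dataclass
class TriDimer:
    """One IAU (A, B, C) plus the two-fold partner of each IAU chain.

    ``roles`` maps chain_id to one of IAU-A, IAU-B, IAU-C, FLANK-of-A,
    FLANK-of-B, FLANK-of-C.
    """

    iau_chains: list[ChainModel]
    flank_chains: list[ChainModel]
    roles: dict[str, str]
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.iau_chains) != 3 or len(self.flank_chains) != 3:
            raise StructureError("tri-dimer requires exactly 3 IAU + 3 flank chains")

    @property
    def chains(self) -> list[ChainModel]:
        return list(self.iau_chains) + list(self.flank_chains)

    def as_assembly(self) -> CapsidAssembly:
        return CapsidAssembly(self.chains, source_id=self.source_id,
                              provenance="deposited_assembly")


# ---------------------------------------------------------------------------
# reading


def _resolve_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy alt-loc per atom name; ties by label."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for at in res:
        by_name.setdefault(at.name, []).append(at)
    picked = []
    for name, group in by_name.items():
        group.sort(key=lambda a: (-a.occ, a.altloc or ""))
        picked.append(group[0])
    return picked


def read_structure(path: str | Path, model_index: int = 0,
                   source_id: str | None = None) -> CapsidAssembly:
    """Read a PDB or mmCIF file into a :class:`CapsidAssembly`.

    Keeps protein chains only; waters, heteroatoms, nucleic acids and
    hydrogens are dropped.  Alternate locations are resolved to the
    highest-occupancy conformer (ties broken by first alt-loc label).
    Residues left with no heavy atom are removed.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if model_index >= len(st):
        raise StructureError(
            f"model index {model_index} out of range ({len(st)} models)")
    model = st[model_index]

    chains = []
    for ch in model:
        residues = []
        last_idx = None
        for res in ch:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            atoms = []
            for at in _resolve_altloc(res):
                if at.element.is_hydrogen:
                    continue
                atoms.append(AtomRecord(
                    atom_name=at.name,
                    element=at.element.name,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    residue_index=res.seqid.num,
                    alt_loc=at.altloc or "",
                    occupancy=min(max(at.occ, 0.0), 1.0),
                ))
            if not atoms:
                continue  # zero heavy atoms: drop the residue
            if last_idx is not None and res.seqid.num <= last_idx:
                continue  # duplicated/inserted numbering: keep first occurrence
            last_idx = res.seqid.num
            residues.append(Residue(res.name, res.seqid.num, atoms))
        if residues:
            label = ch.name
            if label in ("A", "B", "C"):
                conformer = label
            elif label and label[0] in "ABC" and label[1:].isdigit():
                conformer = label[0]  # e.g. synthetic "B07" or expanded "A_3"
            elif len(label) > 2 and label[0] in "ABC" and label[1] == "_":
                conformer = label[0]
            else:
                conformer = "unknown"
            chains.append(ChainModel(label, conformer, residues))

    if not chains:
        raise EmptyAssemblyError(f"{path}: no protein chains after filtering")
    return CapsidAssembly(chains, source_id=source_id or path.stem,
                          provenance="deposited_assembly")


def read_biomt_operators(path: str | Path) -> list[tuple[np.ndarray, np.ndarray]]:
    """Rotation/translation operators of the first biological assembly.

    Returns a list of (3x3 rotation, 3-vector translation) pairs taken from
    BIOMT records (PDB) or pdbx_struct_assembly categories (mmCIF).
    """
    st = gemmi.read_structure(str(path))
    ops: list[tuple[np.ndarray, np.ndarray]] = []
    if st.assemblies:
        asm = st.assemblies[0]
        for gen in asm.generators:
            for oper in gen.operators:
                t = oper.transform
                rot = np.array(t.mat.tolist(), dtype=float)
                tr = np.array(t.vec.tolist(), dtype=float)
                ops.append((rot, tr))
    return ops


# ---------------------------------------------------------------------------
# symmetry expansion


def expand_assembly(asym: CapsidAssembly,
                    operators: Sequence[tuple[np.ndarray, np.ndarray]],
                    rtol: float = 1e-6) -> CapsidAssembly:
    """Apply rotation/translation operators to every chain.

    Output has ``len(asym.chains) * len(operators)`` chains named
    ``<label>_<k>``.  Rotations must be orthonormal within ``rtol``.
    """
    if not operators:
        raise OperatorError("empty operator list")
    for k, (rot, _) in enumerate(operators):
        rot = np.asarray(rot, float)
        if rot.shape != (3, 3) or not np.allclose(rot @ rot.T, np.eye(3), atol=rtol):
            raise OperatorError(f"operator {k}: rotation is not orthonormal")
    chains = []
    for k, (rot, tr) in enumerate(operators):
        rot = np.asarray(rot, float)
        tr = np.asarray(tr, float).reshape(3)
        for ch in asym.chains:
            chains.append(ch.transformed(rot, tr, chain_id=f"{ch.chain_id}_{k}"))
    return CapsidAssembly(chains, source_id=asym.source_id,
                          provenance="biomt_expanded")


# ---------------------------------------------------------------------------
# tri-dimer extraction


def _contact_graph(capsid: CapsidAssembly, contact_params) -> dict[tuple[str, str], int]:
    """Residue-contact counts for all chain pairs close enough to touch.

    Pairs are pre-filtered by centroid distance so that a 180-chain capsid
    does not require all-vs-all atomic work.
    """
    from .contacts import atomic_contacts, project_to_residue_contacts

    cents = np.array([c.centroid() for c in capsid.chains])
    radii = np.array([
        np.linalg.norm(c.coords() - cent, axis=1).max()
        for c, cent in zip(capsid.chains, cents)
    ])
    graph: dict[tuple[str, str], int] = {}
    n = len(capsid.chains)
    from scipy.spatial import cKDTree

    tree = cKDTree(cents)
    reach = radii.max() * 2 + contact_params.cutoff
    for i, j in tree.query_pairs(reach):
        ci, cj = capsid.chains[i], capsid.chains[j]
        if np.linalg.norm(cents[i] - cents[j]) > radii[i] + radii[j] + contact_params.cutoff:
            continue
        pairs = atomic_contacts(ci, cj, contact_params)
        cs = project_to_residue_contacts(pairs, ci, cj, contact_params)
        if cs.n_inter > 0:
            key = tuple(sorted((ci.chain_id, cj.chain_id)))
            graph[key] = cs.n_inter
    return graph


def extract_tridimer(capsid: CapsidAssembly, contact_params=None,
                     angle_tol: float = 12.0) -> TriDimer:
    """Extract the six-chain tri-dimer from an assembled capsid.

    The IAU is the mutually contacting chain triple (one chain per conformer
    label where labels exist) with the largest total inter-chain residue
    contact count; ties are broken by lexicographic chain labels.  Each flank
    chain is the contacting partner of an IAU chain whose relative rotation
    is within ``angle_tol`` of 180 degrees (the quasi-two-fold dimerization
    relation), again choosing the partner with the most contacts.
    """
    from .contacts import ContactParams
    from .symmetry import relative_transform

    if contact_params is None:
        contact_params = ContactParams()
    if len(capsid) < 12:
        raise ExtractionError(
            "need the IAU plus its neighborhood (>= 12 chains); "
            f"got {len(capsid)} chains")

    graph = _contact_graph(capsid, contact_params)
    if not graph:
        raise ExtractionError("no inter-chain contacts found")
    neighbors: dict[str, set[str]] = {}
    for (x, y) in graph:
        neighbors.setdefault(x, set()).add(y)
        neighbors.setdefault(y, set()).add(x)

    def contacts_of(x: str, y: str) -> int:
        return graph.get(tuple(sorted((x, y))), 0)

    by_conf: dict[str, list[str]] = {}
    for ch in capsid.chains:
        by_conf.setdefault(ch.conformer, []).append(ch.chain_id)
    labelled = all(k in by_conf for k in "ABC")

    best: tuple[int, tuple[str, str, str]] | None = None  # (-score, sorted ids)
    ids = sorted(neighbors)
    if labelled:
        candidates = (
            (a, b, c)
            for a in sorted(by_conf["A"]) if a in neighbors
            for b in sorted(neighbors[a]) if capsid.chain(b).conformer == "B"
            for c in sorted(neighbors[a] & neighbors[b])
            if capsid.chain(c).conformer == "C"
        )
    else:
        candidates = (
            (a, b, c)
            for a in ids
            for b in sorted(neighbors[a]) if b > a
            for c in sorted(neighbors[a] & neighbors[b]) if c > b
        )
    angle_cache: dict[tuple[str, str], float] = {}

    def pair_angle(x: str, y: str) -> float | None:
        key = tuple(sorted((x, y)))
        if key not in angle_cache:
            try:
                angle_cache[key] = relative_transform(
                    capsid.chain(key[0]), capsid.chain(key[1])).rotation_angle
            except ValueError:
                angle_cache[key] = float("nan")
        a = angle_cache[key]
        return None if a != a else a

    def is_trimer_triple(trip) -> bool:
        for u, v in ((0, 1), (0, 2), (1, 2)):
            a = pair_angle(trip[u], trip[v])
            if a is None or abs(a - 120.0) > angle_tol:
                return False
        return True

    # The IAU is a quasi-three-fold triple: all three internal rotations
    # must be ~120 degrees; among those, take the most strongly contacting.
    iau_ids: tuple[str, str, str] | None = None
    fallback: tuple[str, str, str] | None = None
    fallback_key = None
    for trip in candidates:
        score = (contacts_of(trip[0], trip[1]) + contacts_of(trip[0], trip[2])
                 + contacts_of(trip[1], trip[2]))
        key = (-score, tuple(sorted(trip)))
        if fallback_key is None or key < fallback_key:
            fallback_key = key
            fallback = trip
        if is_trimer_triple(trip) and (best is None or key < best):
            best = key
            iau_ids = trip
    if iau_ids is None:
        iau_ids = fallback
    if iau_ids is None:
        raise ExtractionError("no mutually contacting chain triple found")

    iau = [capsid.chain(cid) for cid in iau_ids]
    flanks = []
    roles: dict[str, str] = {}
    for ch in iau:
        tag = ch.conformer if ch.conformer != "unknown" else ch.chain_id
        roles[ch.chain_id] = f"IAU-{tag}"
    for ch in iau:
        cand: list[tuple[int, str]] = []
        for other_id in sorted(neighbors.get(ch.chain_id, ())):
            if other_id in iau_ids:
                continue
            other = capsid.chain(other_id)
            try:
                t = relative_transform(ch, other)
            except ValueError:
                continue
            if abs(t.rotation_angle - 180.0) <= angle_tol:
                cand.append((contacts_of(ch.chain_id, other_id), other_id))
        if not cand:
            raise ExtractionError(
                f"chain {ch.chain_id}: no two-fold partner in the assembly "
                "(incomplete neighborhood)")
        cand.sort(key=lambda t: (-t[0], t[1]))
        partner = capsid.chain(cand[0][1])
        flanks.append(partner)
        tag = ch.conformer if ch.conformer != "unknown" else ch.chain_id
        roles[partner.chain_id] = f"FLANK-of-{tag}"

    if len({c.chain_id for c in flanks}) != 3:
        raise ExtractionError("flank chains are not distinct; malformed lattice")
    return TriDimer(iau, flanks, roles, source_id=capsid.source_id)


# ---------------------------------------------------------------------------
# writing


def _to_gemmi(chains: Iterable[ChainModel], name: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    for ch in chains:
        gch = gemmi.Chain(ch.chain_id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.index, " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.atom_name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_assembly(assembly: CapsidAssembly, path: str | Path,
                   remarks: Sequence[str] = ()) -> None:
    """Write an assembly as PDB (.pdb) or mmCIF (.cif), chosen by suffix.

    PDB output is limited to assemblies whose chain labels fit the
    single-character chain field; large expanded capsids should use mmCIF.
    """
    path = Path(path)
    st = _to_gemmi(assembly.chains, assembly.source_id or "assembly")
    if path.suffix in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
        return
    if any(len(c.chain_id) > 1 for c in assembly.chains):
        # remap to unique single characters when possible
        alphabet = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                    "abcdefghijklmnopqrstuvwxyz0123456789")
        if len(assembly.chains) > len(alphabet):
            raise StructureError(
                "too many chains for PDB output; write mmCIF instead")
        st = _to_gemmi(
            [c.transformed(np.eye(3), np.zeros(3), chain_id=alphabet[i])
             for i, c in enumerate(assembly.chains)],
            assembly.source_id or "assembly")
    body = st.make_pdb_string()
    header = "".join(f"REMARK 999 {r}\n" for r in remarks)
    path.write_text(header + body)


def write_tridimer(td: TriDimer, path: str | Path) -> None:
    """Write a tri-dimer as a PDB file with role-annotation REMARK lines."""
    remarks = [f"TRIDIMER CHAIN {cid} ROLE {role}"
               for cid, role in sorted(td.roles.items())]
    write_assembly(td.as_assembly(), path, remarks=remarks)
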