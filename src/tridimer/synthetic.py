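"""Download-free synthetic fixtures with exact ground truth.

Two generators back the test suite and the examples:

* an exact icosahedral T=3 lattice of 180 placeholder coat proteins whose
  contact graph and (quasi-)rotation relations are known by construction --
  every dimerization (180 deg), trimerization (120 deg), pentamerization
  (72 deg) and hexamerization (60 deg) interface of a real T=3 capsid is
  present with the designed multiplicity;
* toy two-chain dimers with planted intra- and inter-chain residue contact
  counts and controllable residue composition, for exact arithmetic checks
  of the interface metrics.

The placeholder chains are compact polyalanine-like atom clouds, not folded
proteins; they exercise geometry and counting, not energetics.

Lattice construction.  Chain positions live on slot lines of the icosahedral
asymmetric unit (vertex -> face-center and face-center -> edge-midpoint
lines, with a small in-face lateral offset that removes accidental mirror
degeneracies in the distance spectrum).  Chain orientations for the B and C
conformers were solved once, numerically, so that all six quasi-symmetry
constraints hold exactly (trimer pairs at 120 deg, the A-B dimer at 180 deg,
hexamer pairs at 60 deg); the exact-symmetry pairs (C-C dimer at the C2
axis, pentamer neighbours at 72 deg) are exact by group theory regardless.
The solved rotation vectors are frozen below and re-validated by the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structures import AtomRecord, CapsidAssembly, ChainModel, Residue, StructureError

__all__ = [
    "SyntheticSpec", "icosahedral_operators", "make_t3_lattice",
    "make_t3_lattice_with_truth", "make_toy_dimer", "make_sbm_test_dimer",
    "FeasibilityError", "GeometryError",
]


class FeasibilityError(ValueError):
    """Planted contact request is geometrically impossible."""


class GeometryError(ValueError):
    """Generated lattice has steric clashes."""


_PHI = (1 + 5 ** 0.5) / 2

# chain-center unit vectors (circumradius 1) and solved conformer rotation
# vectors; see module docstring.  Frozen output of a one-off numerical
# design: positions maximize the gap between designed-neighbour and spurious
# distances, orientations minimize the deviation of the six quasi-symmetry
# angles from their canonical values (residuals stay below one degree).
_SLOT_POS = {
    "A": np.array([0.08961130100152835, 0.6928543933249406, 0.7154876689245888]),
    "B": np.array([0.3437920145170647, 0.654128650194535, 0.6737379013748402]),
    "C": np.array([0.18043267707523075, 0.8225007903052124, 0.5393852973438991]),
}
_ROTVEC_B = np.array([0.744346316800426, 1.753187353242587, 0.8879941388692998])
_ROTVEC_C = np.array([-0.31378629668223645, -1.8636459433422885, -0.9412457076503995])


@dataclass(frozen=True)
class SyntheticSpec:
    n_residues: int = 30              # body residues per placeholder chain
    lattice_radius: float = 72.0      # circumradius, Angstrom
    body_radius: float = 7.0          # placeholder chain body radius, Angstrom
    conformer_perturbation: float = 0.25  # deterministic distortion, Angstrom
    composition: dict = field(default_factory=lambda: {"ALA": 1.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 5:
            raise ValueError("n_residues must be >= 5")
        if self.lattice_radius < 68.0:
            raise ValueError(
                "lattice_radius too small: chains would overlap "
                "(designed neighbour spacing scales with the radius)")


def _vertices() -> np.ndarray:
    v = []
    for a in (1, -1):
        for b in (_PHI, -_PHI):
            v += [(0, a, b), (a, b, 0), (b, 0, a)]
    v = np.array(v, float)
    return v / np.linalg.norm(v[0])


def _rot(axis: np.ndarray, deg: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    return Rotation.from_rotvec(np.deg2rad(deg) * axis / np.linalg.norm(axis)).as_matrix()


@lru_cache(maxsize=1)
def _reference_frame():
    """Reference vertex/face geometry and the designed group elements.

    v0 is a reference five-fold vertex, (v0, v1, v2) and (v0, v1, v3) the
    two faces sharing the reference edge, m01 that edge's midpoint (a C2
    axis).  g5 is the five-fold rotation about v0 oriented so it maps the
    first face onto the second; g2 is the two-fold about m01.
    """
    verts = _vertices()
    v0 = verts[0]
    d = np.linalg.norm(verts - v0, axis=1)
    v1 = verts[np.argsort(d)[1]]
    edge = np.linalg.norm(v0 - v1)
    common = [i for i in range(12)
              if 1e-6 < np.linalg.norm(verts[i] - v0) < edge * 1.01
              and 1e-6 < np.linalg.norm(verts[i] - v1) < edge * 1.01]
    v2, v3 = verts[common[0]], verts[common[1]]
    f = (v0 + v1 + v2) / 3.0
    f2 = (v0 + v1 + v3) / 3.0
    m01 = (v0 + v1) / 2.0
    g2 = _rot(m01, 180.0)
    g5 = _rot(v0, 72.0)
    if np.linalg.norm(g5 @ f - f2) > np.linalg.norm(_rot(v0, -72.0) @ f - f2):
        g5 = _rot(v0, -72.0)
    return verts, v0, v1, v2, v3, f, f2, m01, g5, g2


@lru_cache(maxsize=1)
def _operators_tuple():
    *_, g5, g2 = _reference_frame()
    elems = [np.eye(3)]
    seen = {tuple(np.round(np.eye(3), 9).ravel())}
    changed = True
    while changed:
        changed = False
        for g in list(elems):
            for h in (g5, g2):
                p = g @ h
                k = tuple(np.round(p, 9).ravel())
                if k not in seen:
                    seen.add(k)
                    elems.append(p)
                    changed = True
    assert len(elems) == 60
    return tuple(e.copy() for e in elems)


def icosahedral_operators() -> list[np.ndarray]:
    """The 60 proper rotations of the icosahedral group I.

    Generated by closure from a five-fold rotation about a vertex and a
    two-fold rotation about an adjacent edge midpoint; deterministic order,
    identity first.
    """
    return [e.copy() for e in _operators_tuple()]


def _slot_positions() -> dict[str, np.ndarray]:
    return {k: v.copy() for k, v in _SLOT_POS.items()}


def _orientations() -> dict[str, np.ndarray]:
    return {
        "A": np.eye(3),
        "B": Rotation.from_rotvec(_ROTVEC_B).as_matrix(),
        "C": Rotation.from_rotvec(_ROTVEC_C).as_matrix(),
    }


def _designed_pairs():
    """Reference designed pairs {(identity, X), (g, Y)} with their classes.

    The two hexamerization entries are distinct pair orbits: around each
    quasi-six-fold ring the B and C chains of six different asymmetric
    units alternate, so ring-adjacent contacts come in two flavours.
    """
    *_, g5, g2 = _reference_frame()
    eye = np.eye(3)
    return [
        ("A", "B", eye, "trimerization"),
        ("A", "C", eye, "trimerization"),
        ("B", "C", eye, "trimerization"),
        ("A", "B", g5, "dimerization"),        # quasi-two-fold A-B
        ("C", "C", g2, "dimerization"),        # exact C2 C-C
        ("A", "A", g5, "pentamerization"),
        ("C", "B", g5, "hexamerization"),
        ("B", "C", g2, "hexamerization"),
    ]


@lru_cache(maxsize=1)
def _arm_partners() -> dict[str, list[np.ndarray]]:
    """Designed-partner positions (unit scale) for each conformer template.

    Every chain touches exactly five neighbours: two trimer partners, one
    dimerization partner, and either two pentamer ring neighbours (A) or
    two hexamer ring neighbours (B, C).
    """
    *_, g5, g2 = _reference_frame()
    p = _slot_positions()
    return {
        "A": [p["B"], p["C"], g5 @ p["B"], g5 @ p["A"], g5.T @ p["A"]],
        "B": [p["A"], p["C"], g5.T @ p["A"], g5.T @ p["C"], g2 @ p["C"]],
        "C": [p["A"], p["B"], g2 @ p["C"], g5 @ p["B"], g2 @ p["B"]],
    }


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.c_[np.sin(phi) * np.cos(theta),
                 np.sin(phi) * np.sin(theta),
                 np.cos(phi)]


def _draw_names(n: int, composition: dict, rng: np.random.Generator) -> list[str]:
    names = sorted(composition)
    w = np.array([composition[k] for k in names], float)
    w = w / w.sum()
    return [names[i] for i in rng.choice(len(names), size=n, p=w)]


_ARM_BASE = {"A": 101, "B": 201, "C": 301}
_TIP_BACK = 1.75  # Angstrom from the pair midpoint back toward the chain


def _build_templates(spec: SyntheticSpec):
    """The three conformer templates as absolute reference-frame atom sets.

    Returns {type: list of (residue_name, residue_index, [(atom_name, xyz)])}.
    """
    slots = _slot_positions()
    orients = _orientations()
    S = spec.lattice_radius
    rng = np.random.default_rng(spec.seed)

    # identical body for the three conformers (local frame), then a small
    # deterministic per-conformer distortion so quasi-axes are measurably
    # inexact, as in real capsids
    body_local = _fibonacci_sphere(spec.n_residues) * spec.body_radius
    phases = {"A": 0.0, "B": 2.1, "C": 4.2}
    names = _draw_names(spec.n_residues, spec.composition, rng)

    templates = {}
    for t in "ABC":
        center = slots[t] * S
        O = orients[t]
        residues = []
        for i in range(spec.n_residues):
            k = np.arange(3) * 0.9 + i * 0.7 + phases[t]
            distort = spec.conformer_perturbation * np.sin(k) / math.sqrt(3)
            pos = center + O @ (body_local[i] + distort)
            residues.append((names[i], i + 1, [("CA", pos)]))
        # arms toward each designed partner: one residue of three atoms whose
        # tip sits 1.75 A short of the pair midpoint, so partnered tips meet
        # at 3.5 A -- inside the 4.5 A contact cutoff, outside clash range
        arm_idx = _ARM_BASE[t]
        for partner in _arm_partners()[t]:
            dvec = partner * S - center
            dist = np.linalg.norm(dvec)
            u = dvec / dist
            tip = center + (dist / 2.0 - _TIP_BACK) * u
            # two offset atoms make the tip contact robust to noise
            perp = np.cross(u, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(u, [0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            perp2 = np.cross(u, perp)
            atoms = [("CA", tip), ("CB", tip + perp), ("CG", tip + perp2)]
            residues.append(("ALA", arm_idx, atoms))
            arm_idx += 1
        templates[t] = residues
    return templates


def _assemble(spec: SyntheticSpec):
    templates = _build_templates(spec)
    ops = icosahedral_operators()
    chains = []
    for k, g in enumerate(ops):
        for t in "ABC":
            residues = [
                Residue(name, idx, [AtomRecord(an, "C", g @ xyz, idx)
                                    for an, xyz in atoms])
                for name, idx, atoms in templates[t]
            ]
            chains.append(ChainModel(f"{t}{k:02d}", conformer=t, residues=residues))
    return CapsidAssembly(chains, source_id="synthetic_t3",
                          provenance="synthetic")


def make_t3_lattice(spec: SyntheticSpec | None = None) -> CapsidAssembly:
    """Exact synthetic T=3 lattice: 60 operators x 3 conformers = 180 chains.

    Raises :class:`GeometryError` if any two chains clash (atoms closer
    than 2.0 A), which can only happen for off-design parameters.
    """
    spec = spec or SyntheticSpec()
    capsid = _assemble(spec)
    coords = np.vstack([c.coords() for c in capsid.chains])
    owner = np.concatenate([
        np.full(c.n_atoms, i) for i, c in enumerate(capsid.chains)])
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(2.0):
        if owner[i] != owner[j]:
            raise GeometryError("inter-chain steric clash in generated lattice")
    return capsid


def make_t3_lattice_with_truth(spec: SyntheticSpec | None = None):
    """Lattice plus its ground truth (designed classes, angles, counts)."""
    spec = spec or SyntheticSpec()
    capsid = make_t3_lattice(spec)
    truth = {
        "n_chains": 180,
        "designed_classes": {
            "dimerization": 90, "trimerization": 180,
            "pentamerization": 60, "hexamerization": 60},
        "tridimer_classes": {
            "dimerization": 3, "trimerization": 3,
            "pentamerization": 1, "hexamerization": 2},
        "canonical_angles": {"dimerization": 180.0, "trimerization": 120.0,
                             "pentamerization": 72.0, "hexamerization": 60.0},
        "seed": spec.seed,
        "lattice_radius": spec.lattice_radius,
    }
    return capsid, truth


# ---------------------------------------------------------------------------
# toy dimers with planted contacts


def _planted_pairs(n_res: int, n_pairs: int, min_seq_sep: int,
                   rng: np.random.Generator) -> list[tuple[int, int]]:
    all_pairs = [(i, j) for i in range(1, n_res + 1)
                 for j in range(i + min_seq_sep, n_res + 1)]
    if n_pairs > len(all_pairs):
        raise FeasibilityError(
            f"cannot plant {n_pairs} intra pairs in {n_res} residues "
            f"with separation >= {min_seq_sep}")
    sel = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    return [all_pairs[i] for i in sorted(sel)]


def make_toy_dimer(n_res: int, planted_inter: int, planted_intra: int,
                   composition: dict | None = None, seed: int = 0,
                   min_seq_sep: int = 3):
    """Two-chain assembly whose residue contact counts are planted exactly.

    Residue "homes" sit on a wide grid so no accidental contact arises; each
    planted contact is realised by a dedicated pair of satellite atoms 4.0 A
    apart in its own far-away pocket.  Returns ``(assembly, truth)`` where
    truth records the planted counts and compositions.
    """
    composition = composition or {"ALA": 1.0}
    rng = np.random.default_rng(seed)
    if planted_inter > n_res * n_res:
        raise FeasibilityError("more inter pairs than residue pairs available")

    names = {cid: _draw_names(n_res, composition, rng) for cid in ("X", "Y")}
    intra = {cid: _planted_pairs(n_res, planted_intra, min_seq_sep, rng)
             for cid in ("X", "Y")}
    all_inter = [(i, j) for i in range(1, n_res + 1) for j in range(1, n_res + 1)]
    sel = rng.choice(len(all_inter), size=planted_inter, replace=False)
    inter = [all_inter[i] for i in sorted(sel)]

    home_z = {"X": 0.0, "Y": 40.0}
    extra: dict[tuple[str, int], list[np.ndarray]] = {}
    pocket = 0

    def add_pocket(key_a, key_b):
        nonlocal pocket
        base = np.array([25.0 * (pocket % 40), 80.0 + 25.0 * (pocket // 40), 20.0])
        pocket += 1
        extra.setdefault(key_a, []).append(base + [-2.0, 0.0, 0.0])
        extra.setdefault(key_b, []).append(base + [2.0, 0.0, 0.0])

    for cid in ("X", "Y"):
        for (i, j) in intra[cid]:
            add_pocket((cid, i), (cid, j))
    for (i, j) in inter:
        add_pocket(("X", i), ("Y", j))

    chains = []
    for cid in ("X", "Y"):
        residues = []
        for i in range(1, n_res + 1):
            atoms = [AtomRecord("CA", "C",
                                np.array([10.0 * i, 0.0, home_z[cid]]), i)]
            for k, xyz in enumerate(extra.get((cid, i), ())):
                atoms.append(AtomRecord(f"S{k + 1}", "C", xyz, i))
            residues.append(Residue(names[cid][i - 1], i, atoms))
        chains.append(ChainModel(cid, "unknown", residues))

    truth = {
        "n_inter": planted_inter,
        "n_intra_x": planted_intra,
        "n_intra_y": planted_intra,
        "inter_pairs": inter,
        "intra_pairs_x": intra["X"],
        "intra_pairs_y": intra["Y"],
        "names_x": names["X"],
        "names_y": names["Y"],
        "seed": seed,
    }
    return CapsidAssembly(chains, source_id="toy_dimer",
                          provenance="synthetic"), truth


# ---------------------------------------------------------------------------
# minimal rigid dimers for the coarse-grained simulator


def _helix_trace(n_res: int) -> np.ndarray:
    """Ideal alpha-helix CA trace along z: 2.3 A radius, 1.5 A rise, 100 deg."""
    k = np.arange(n_res)
    theta = np.deg2rad(100.0) * k
    return np.c_[2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * k]


def make_sbm_test_dimer(kind: str = "parallel", n_res: int = 30,
                        separation: float = 9.0,
                        hinge_angle: float = 12.0) -> CapsidAssembly:
    """Minimal two-chain dimer for structure-based-model tests.

    ``parallel``: two helices side by side -- a broad interface running the
    whole length (stiff dimer).  ``hinge``: the second helix is tilted away
    about a pivot at the first residues, so only the near ends stay in
    contact (floppy dimer).  CA-only chains; use a CA-distance cutoff
    (~8 A) when deriving native contacts.
    """
    first = _helix_trace(n_res)
    second = _helix_trace(n_res) + np.array([separation, 0.0, 0.0])
    if kind == "hinge":
        pivot = second[0]
        R = _rot(np.array([0.0, 1.0, 0.0]), hinge_angle)
        second = (second - pivot) @ R.T + pivot
    elif kind != "parallel":
        raise ValueError(f"unknown dimer kind {kind!r}")
    chains = []
    for cid, trace in (("X", first), ("Y", second)):
        residues = [Residue("ALA", i + 1, [AtomRecord("CA", "C", xyz, i + 1)])
                    for i, xyz in enumerate(trace)]
        chains.append(ChainModel(cid, "unknown", residues))
    return CapsidAssembly(chains, source_id=f"sbm_{kind}_dimer",
                          provenance="synthetic")
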