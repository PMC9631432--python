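"""Single-bead-per-residue structure-based (Go-type) model of a CP2 dimer.

The coat-protein dimer is coarse-grained to one bead per residue at the CA
position.  The potential is minimized by construction at the native (input)
configuration:

* harmonic bonds between consecutive residues, ``V = k_b (r - r0)^2`` with
  ``k_b = 100 eps/A^2``;
* harmonic angles, ``V = k_a (theta - theta0)^2``, ``k_a = 20 eps/rad^2``;
* two-term cosine dihedrals,
  ``V = k_d [1 - cos(phi - phi0)] + (k_d/2) [1 - cos 3(phi - phi0)]`` with
  ``k_d = 1 eps``;
* 10-12 attractive native contacts,
  ``V = eps [5 (sigma_ij/r)^12 - 6 (sigma_ij/r)^10]`` where ``sigma_ij`` is
  the native bead distance, for every residue contact of the native
  structure (intra- and inter-chain);
* an ``eps (sigma_rep/r)^12`` repulsion (``sigma_rep = 4 A``) between all
  remaining pairs, truncated and force-shifted to zero at ``r_c = 7 A``.
  Pairs already within ``r_c`` in the native structure are part of the
  native environment and carry no repulsion, which makes the native
  configuration an exact stationary point of the total potential.

Units are reduced: energies in eps, lengths in Angstrom, masses 1, k_B = 1,
so the time unit is tau = sqrt(m A^2 / eps).  Center-of-mass (COM)
distances are reported in nm.

Dynamics are Langevin (BAOAB splitting); with friction 0 the integrator
reduces to velocity Verlet and conserves energy, which the tests exploit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactParams, contact_set
from .structures import CapsidAssembly, ChainModel

from . import _kernels

__all__ = [
    "SBMTopology", "SimParams", "SimResult", "COMTrace",
    "build_sbm", "run_langevin", "com_distance_trace",
    "potential_energy", "forces", "estimate_folding_temperature",
    "InstabilityError", "DEFAULT_TEMPERATURE",
]

KB_BOND = 100.0      # eps / A^2
KA_ANGLE = 20.0      # eps / rad^2
KD_DIHEDRAL = 1.0    # eps
SIGMA_REP = 4.0      # A
R_CUT_REP = 7.0      # A, repulsion truncation (force-shifted)
MIN_CONTACT_SEP = 4  # |i-j| below which intra-chain contacts are bonded terms

#: Reduced sampling temperature for folded-basin flexibility runs; about half
#: the folding temperature of typical CA Go-model proteins with eps = 1.
DEFAULT_TEMPERATURE = 0.5


class InstabilityError(RuntimeError):
    """Numerical blow-up; reduce the timestep."""


@dataclass
class SBMTopology:
    positions: np.ndarray        # (n, 3) native CA coordinates, A
    chain_ids: list[str]
    chain_of: np.ndarray         # (n,) chain index per bead
    residue_index: np.ndarray    # (n,) author residue numbers
    bonds: np.ndarray            # (nb, 2) int
    bond_r0: np.ndarray
    angles: np.ndarray           # (na, 3) int
    angle_t0: np.ndarray
    dihedrals: np.ndarray        # (nd, 4) int
    dihedral_p0: np.ndarray
    contacts: np.ndarray         # (nc, 2) int, native pairs
    contact_sigma: np.ndarray
    repulsive: np.ndarray        # (nr, 2) int, candidate non-native pairs
    repulsive_radius: float = SIGMA_REP
    energy_scale: float = 1.0

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_inter_contacts(self) -> int:
        ci = self.chain_of[self.contacts[:, 0]] != self.chain_of[self.contacts[:, 1]]
        return int(ci.sum())

    def to_flat_file(self, path) -> None:
        """Human-readable topology export."""
        with open(path, "w") as fh:
            fh.write(f"# CA structure-based model, {self.n_beads} beads\n")
            fh.write("[beads]\n# index chain residue x y z\n")
            for i, p in enumerate(self.positions):
                fh.write(f"{i}\t{self.chain_ids[self.chain_of[i]]}\t"
                         f"{self.residue_index[i]}\t{p[0]:.3f}\t{p[1]:.3f}\t{p[2]:.3f}\n")
            fh.write("[bonds]\n# i j r0\n")
            for (i, j), r0 in zip(self.bonds, self.bond_r0):
                fh.write(f"{i}\t{j}\t{r0:.4f}\n")
            fh.write("[angles]\n# i j k theta0_deg\n")
            for (i, j, k), t0 in zip(self.angles, self.angle_t0):
                fh.write(f"{i}\t{j}\t{k}\t{np.degrees(t0):.3f}\n")
            fh.write("[dihedrals]\n# i j k l phi0_deg\n")
            for (i, j, k, l), p0 in zip(self.dihedrals, self.dihedral_p0):
                fh.write(f"{i}\t{j}\t{k}\t{l}\t{np.degrees(p0):.3f}\n")
            fh.write("[contacts]\n# i j sigma\n")
            for (i, j), s in zip(self.contacts, self.contact_sigma):
                fh.write(f"{i}\t{j}\t{s:.4f}\n")


@dataclass(frozen=True)
class SimParams:
    temperature: float = DEFAULT_TEMPERATURE  # reduced (eps / k_B)
    timestep: float = 0.0005                  # tau
    friction: float = 1.0                     # 1 / tau; 0 selects NVE
    n_steps: int = 100_000
    save_interval: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0 or self.n_steps < 0 or self.save_interval <= 0:
            raise ValueError(
                "timestep and save_interval must be positive, n_steps >= 0 "
                "(0 selects the frozen native-structure smoke mode)")
        if self.friction < 0 or self.temperature < 0:
            raise ValueError("friction and temperature must be >= 0")


@dataclass
class SimResult:
    frames: np.ndarray        # (n_frames, n, 3)
    velocities: np.ndarray    # (n_frames, n, 3)
    potential: np.ndarray     # (n_frames,)
    kinetic: np.ndarray       # (n_frames,)
    params: SimParams

    @property
    def total_energy(self) -> np.ndarray:
        return self.potential + self.kinetic


@dataclass
class COMTrace:
    values: np.ndarray        # nm, per frame
    bin_edges: np.ndarray     # nm, width exactly 0.01, anchored at 0
    histogram: np.ndarray     # normalized counts (sums to 1)
    mean: float               # nm
    sd: float                 # nm
    native_value: float       # nm

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("frame\tcom_distance_nm\n")
            for k, v in enumerate(self.values):
                fh.write(f"{k}\t{v:.6f}\n")


def _ca_beads(chain: ChainModel) -> tuple[np.ndarray, np.ndarray]:
    pos, idx = [], []
    for r in chain.residues:
        ca = r.atom("CA")
        if ca is None:
            warnings.warn(f"chain {chain.chain_id} residue {r.index}: no CA, skipped")
            continue
        pos.append(ca.coords)
        idx.append(r.index)
    return np.asarray(pos), np.asarray(idx, dtype=int)


def build_sbm(dimer: CapsidAssembly, contact_params: ContactParams | None = None) -> SBMTopology:
    """Build the CA structure-based model of a two-chain dimer.

    Native contacts are the residue-level contacts of the input structure
    (via the contact map module); intra-chain contacts additionally require
    ``|i - j| >= 4`` so they do not overlap the bonded terms.
    """
    if len(dimer.chains) != 2:
        raise ValueError(f"need exactly 2 chains, got {len(dimer.chains)}")
    params = contact_params or ContactParams()
    cx, cy = dimer.chains
    if len(cx) < 30 or len(cy) < 30:
        raise ValueError("each chain needs >= 30 residues for a meaningful model")

    pos_x, idx_x = _ca_beads(cx)
    pos_y, idx_y = _ca_beads(cy)
    positions = np.vstack([pos_x, pos_y])
    n_x = len(pos_x)
    n = len(positions)
    chain_of = np.concatenate([np.zeros(n_x, int), np.ones(n - n_x, int)])
    residue_index = np.concatenate([idx_x, idx_y])

    bead_of = {}  # (chain slot, author residue) -> bead id
    for b, (c, r) in enumerate(zip(chain_of, residue_index)):
        bead_of[(int(c), int(r))] = b

    bonds, angles, dihedrals = [], [], []
    for c, count in ((0, n_x), (1, n - n_x)):
        offset = 0 if c == 0 else n_x
        for i in range(count - 1):
            bonds.append((offset + i, offset + i + 1))
        for i in range(count - 2):
            angles.append((offset + i, offset + i + 1, offset + i + 2))
        for i in range(count - 3):
            dihedrals.append((offset + i, offset + i + 1, offset + i + 2, offset + i + 3))
    bonds = np.asarray(bonds, dtype=np.int64)
    angles = np.asarray(angles, dtype=np.int64)
    dihedrals = np.asarray(dihedrals, dtype=np.int64)

    cs = contact_set(cx, cy, params)
    pairs = set()
    for (i, j) in cs.residue_pairs_intra_x:
        if abs(i - j) >= MIN_CONTACT_SEP and (0, i) in bead_of and (0, j) in bead_of:
            pairs.add(tuple(sorted((bead_of[(0, i)], bead_of[(0, j)]))))
    for (i, j) in cs.residue_pairs_intra_y:
        if abs(i - j) >= MIN_CONTACT_SEP and (1, i) in bead_of and (1, j) in bead_of:
            pairs.add(tuple(sorted((bead_of[(1, i)], bead_of[(1, j)]))))
    for (i, j) in cs.residue_pairs_inter:
        if (0, i) in bead_of and (1, j) in bead_of:
            pairs.add((bead_of[(0, i)], bead_of[(1, j)]))
    contacts = np.asarray(sorted(pairs), dtype=np.int64)
    if len(contacts) == 0:
        contacts = contacts.reshape(0, 2)
    sigma = np.linalg.norm(positions[contacts[:, 0]] - positions[contacts[:, 1]], axis=1) \
        if len(contacts) else np.empty(0)

    # candidate repulsive pairs: everything not bonded/native with |i-j| >= 4
    # within a chain, excluding pairs already inside the truncation radius in
    # the native structure (native environment; keeps the native state an
    # exact stationary point)
    native_set = {tuple(p) for p in contacts}
    repulsive = []
    for i in range(n):
        for j in range(i + 1, n):
            if chain_of[i] == chain_of[j] and j - i < MIN_CONTACT_SEP:
                continue
            if (i, j) in native_set:
                continue
            if np.linalg.norm(positions[i] - positions[j]) < R_CUT_REP:
                continue
            repulsive.append((i, j))
    repulsive = np.asarray(repulsive, dtype=np.int64)

    r0 = np.linalg.norm(positions[bonds[:, 0]] - positions[bonds[:, 1]], axis=1)
    t0 = np.array([_angle(positions[i], positions[j], positions[k])
                   for i, j, k in angles])
    p0 = np.array([_dihedral(positions[i], positions[j], positions[k], positions[l])
                   for i, j, k, l in dihedrals])

    return SBMTopology(
        positions=positions.copy(), chain_ids=[cx.chain_id, cy.chain_id],
        chain_of=chain_of, residue_index=residue_index,
        bonds=bonds, bond_r0=r0, angles=angles, angle_t0=t0,
        dihedrals=dihedrals, dihedral_p0=p0,
        contacts=contacts, contact_sigma=sigma, repulsive=repulsive)


def _angle(a, b, c):
    u, v = a - b, c - b
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosv, -1, 1)))


def _dihedral(a, b, c, d):
    b1, b2, b3 = b - a, c - b, d - c
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))


def _kernel_args(top: SBMTopology):
    return (top.bonds, top.bond_r0, top.angles, top.angle_t0,
            top.dihedrals, top.dihedral_p0, top.contacts, top.contact_sigma,
            top.repulsive, float(top.repulsive_radius), R_CUT_REP,
            float(top.energy_scale))


def potential_energy(top: SBMTopology, positions: np.ndarray | None = None) -> float:
    pos = top.positions if positions is None else np.asarray(positions, float)
    e, _ = _kernels.energy_forces(np.ascontiguousarray(pos), *_kernel_args(top))
    return float(e)


def forces(top: SBMTopology, positions: np.ndarray | None = None) -> np.ndarray:
    pos = top.positions if positions is None else np.asarray(positions, float)
    _, f = _kernels.energy_forces(np.ascontiguousarray(pos), *_kernel_args(top))
    return f


def run_langevin(top: SBMTopology, params: SimParams,
                 initial_velocities: np.ndarray | None = None) -> SimResult:
    """Langevin dynamics from the native configuration.

    With ``friction == 0`` no thermostat is applied (NVE); otherwise BAOAB
    Langevin at ``params.temperature``.  Velocities start from the
    Maxwell-Boltzmann distribution at the run temperature unless given.
    Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    if initial_velocities is None:
        if params.friction > 0 and params.temperature > 0:
            vel = rng.normal(0.0, np.sqrt(params.temperature),
                             size=top.positions.shape)
        else:
            vel = np.zeros_like(top.positions)
    else:
        vel = np.asarray(initial_velocities, float).copy()

    frames, vels, pot, kin, ok = _kernels.integrate(
        np.ascontiguousarray(top.positions.astype(float)),
        np.ascontiguousarray(vel),
        *_kernel_args(top),
        float(params.timestep), float(params.friction), float(params.temperature),
        int(params.n_steps), int(params.save_interval), int(params.seed))
    if not ok:
        raise InstabilityError(
            "coordinates exceeded 1e6 A; reduce the timestep or temperature")
    return SimResult(frames, vels, pot, kin, params)


def com_distance_trace(frames: np.ndarray, chain_split: int,
                       native_positions: np.ndarray | None = None) -> COMTrace:
    """Inter-chain center-of-mass distance per frame, in nm.

    ``chain_split`` is the bead index where the second chain starts.  The
    histogram uses 0.01 nm bins with edges anchored at 0.00 nm.
    """
    frames = np.asarray(frames, float)
    if frames.ndim != 3 or len(frames) == 0:
        raise ValueError("need a nonempty (n_frames, n_beads, 3) trajectory")
    com1 = frames[:, :chain_split].mean(axis=1)
    com2 = frames[:, chain_split:].mean(axis=1)
    values = np.linalg.norm(com1 - com2, axis=1) / 10.0  # A -> nm
    if native_positions is not None:
        n1 = native_positions[:chain_split].mean(axis=0)
        n2 = native_positions[chain_split:].mean(axis=0)
        native = float(np.linalg.norm(n1 - n2) / 10.0)
    else:
        native = float(values[0])
    lo = np.floor(values.min() / 0.01)
    hi = np.ceil(values.max() / 0.01 + 1e-12)
    if hi <= lo:
        hi = lo + 1
    edges = np.arange(lo, hi + 1) * 0.01
    hist, _ = np.histogram(values, bins=edges)
    hist = hist / hist.sum()
    return COMTrace(values=values, bin_edges=edges, histogram=hist,
                    mean=float(values.mean()), sd=float(values.std()),
                    native_value=native)


def save_trajectory_xyz(frames: np.ndarray, path, comment: str = "") -> None:
    """Write a trajectory as plain xyz-per-frame text (coordinates in A)."""
    frames = np.asarray(frames, float)
    with open(path, "w") as fh:
        for k, frame in enumerate(frames):
            fh.write(f"{len(frame)}\n{comment} frame {k}\n")
            for x, y, z in frame:
                fh.write(f"CA {x:.3f} {y:.3f} {z:.3f}\n")


def estimate_folding_temperature(top: SBMTopology,
                                 temperatures: np.ndarray | None = None,
                                 n_steps: int = 50_000,
                                 seed: int = 0) -> float:
    """Locate the heat-capacity peak on a short temperature scan.

    A scaled-down estimate: short Langevin runs on a temperature grid,
    Cv(T) = var(E) / T^2 from the second half of each run, peak position
    returned.  Intended for choosing a folded-basin sampling temperature,
    not for thermodynamics.
    """
    if temperatures is None:
        temperatures = np.arange(0.6, 1.7, 0.1)
    cvs = []
    for k, T in enumerate(temperatures):
        res = run_langevin(top, SimParams(
            temperature=float(T), n_steps=n_steps,
            save_interval=max(n_steps // 200, 1), seed=seed + k))
        e = res.total_energy[len(res.total_energy) // 2:]
        cvs.append(e.var() / T ** 2)
    return float(temperatures[int(np.argmax(cvs))])
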