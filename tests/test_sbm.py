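"""Structure-based model: topology, forces, integrator, observables."""

import numpy as np
import pytest

from tridimer.contacts import ContactParams
from tridimer.sbm import (InstabilityError, SBMTopology, SimParams,
                          build_sbm, com_distance_trace, forces,
                          potential_energy, run_langevin)
from tridimer.synthetic import make_sbm_test_dimer

CA8 = ContactParams(cutoff=8.0, min_seq_sep=3)


def _free_beads(n=40):
    """Topology with no interactions (ideal gas of beads)."""
    e0 = np.empty(0)
    E2 = np.empty((0, 2), np.int64)
    rng = np.random.default_rng(0)
    return SBMTopology(
        positions=rng.uniform(0, 100, (n, 3)), chain_ids=["X"],
        chain_of=np.zeros(n, int), residue_index=np.arange(1, n + 1),
        bonds=E2, bond_r0=e0, angles=np.empty((0, 3), np.int64), angle_t0=e0,
        dihedrals=np.empty((0, 4), np.int64), dihedral_p0=e0,
        contacts=E2, contact_sigma=e0, repulsive=E2)


def test_topology_counts(parallel_top, parallel_dimer):
    n_res = sum(len(c) for c in parallel_dimer.chains)
    assert parallel_top.n_beads == n_res
    assert len(parallel_top.bonds) == n_res - 2      # residues minus chains
    assert len(parallel_top.angles) == n_res - 4
    assert len(parallel_top.dihedrals) == n_res - 6
    assert parallel_top.n_inter_contacts > 0


def test_bonds_connect_consecutive_beads_within_chains(parallel_top):
    for (i, j) in parallel_top.bonds:
        assert j == i + 1
        assert parallel_top.chain_of[i] == parallel_top.chain_of[j]


def test_native_configuration_is_stationary(parallel_top, hinge_top):
    for top in (parallel_top, hinge_top):
        assert potential_energy(top) == pytest.approx(
            -len(top.contacts) * top.energy_scale, rel=1e-9)
        assert np.abs(forces(top)).max() < 1e-6


def test_forces_match_numerical_gradient(parallel_top, rng):
    pos = parallel_top.positions + rng.normal(0, 0.3, parallel_top.positions.shape)
    f = forces(parallel_top, pos)
    h = 1e-6
    for _ in range(25):
        i = rng.integers(parallel_top.n_beads)
        d = rng.integers(3)
        p1, p2 = pos.copy(), pos.copy()
        p1[i, d] += h
        p2[i, d] -= h
        num = -(potential_energy(parallel_top, p1)
                - potential_energy(parallel_top, p2)) / (2 * h)
        assert num == pytest.approx(f[i, d], abs=5e-5)


def test_potential_invariant_under_rigid_motion(parallel_top, rng):
    from tridimer.synthetic import _rot
    pos = parallel_top.positions + rng.normal(0, 0.2, parallel_top.positions.shape)
    e0 = potential_energy(parallel_top, pos)
    R = _rot(np.array([1.0, 2.0, 3.0]), 37.0)
    moved = pos @ R.T + np.array([11.0, -5.0, 3.0])
    assert potential_energy(parallel_top, moved) == pytest.approx(e0, abs=1e-9)


def test_single_free_bead_stays_put():
    top = _free_beads(1)
    res = run_langevin(top, SimParams(temperature=0.0, friction=0.0,
                                      n_steps=1000, save_interval=100, seed=0))
    assert np.allclose(res.frames[-1], top.positions)


def test_two_bonded_beads_oscillate_at_harmonic_period():
    """V = k (r - r0)^2 with k = 100, reduced mass 1/2 -> omega = 20 / tau."""
    e0 = np.empty(0)
    top = SBMTopology(
        positions=np.array([[0.0, 0, 0], [4.1, 0, 0]]), chain_ids=["X"],
        chain_of=np.zeros(2, int), residue_index=np.array([1, 2]),
        bonds=np.array([[0, 1]], np.int64), bond_r0=np.array([4.0]),
        angles=np.empty((0, 3), np.int64), angle_t0=e0,
        dihedrals=np.empty((0, 4), np.int64), dihedral_p0=e0,
        contacts=np.empty((0, 2), np.int64), contact_sigma=e0,
        repulsive=np.empty((0, 2), np.int64))
    dt = 0.0005
    res = run_langevin(top, SimParams(temperature=0.0, friction=0.0,
                                      n_steps=40000, save_interval=1,
                                      seed=0))
    r = np.linalg.norm(res.frames[:, 1] - res.frames[:, 0], axis=1)
    # energy conserved
    drift = np.abs(res.total_energy - res.total_energy[0]).max()
    assert drift < 1e-4
    # dominant frequency ~ omega = sqrt(2 k / mu) = sqrt(400) = 20 rad/tau
    spectrum = np.abs(np.fft.rfft(r - r.mean()))
    freqs = np.fft.rfftfreq(len(r), d=dt)
    omega = 2 * np.pi * freqs[np.argmax(spectrum)]
    assert omega == pytest.approx(20.0, rel=0.02)


def test_nve_energy_drift_small(parallel_top, rng):
    vel = rng.normal(0, np.sqrt(0.5), parallel_top.positions.shape)
    res = run_langevin(parallel_top,
                       SimParams(temperature=0.5, friction=0.0,
                                 n_steps=100_000, save_interval=1000, seed=0),
                       initial_velocities=vel)
    drift = np.abs(res.total_energy - res.total_energy[0]).max()
    assert drift < 0.01


def test_thermostat_equipartition_on_ideal_beads():
    top = _free_beads(60)
    T = 0.7
    res = run_langevin(top, SimParams(temperature=T, friction=1.0,
                                      n_steps=100_000, save_interval=50, seed=3))
    ke_per_dof = res.kinetic.mean() / (3 * top.n_beads)
    assert ke_per_dof == pytest.approx(T / 2, rel=0.02)


def test_same_seed_reproduces_trajectory(parallel_top):
    p = SimParams(temperature=0.5, friction=1.0, n_steps=20_000,
                  save_interval=500, seed=11)
    r1 = run_langevin(parallel_top, p)
    r2 = run_langevin(parallel_top, p)
    assert np.array_equal(r1.frames, r2.frames)


def test_instability_reported():
    top = _free_beads(5)
    with pytest.raises(InstabilityError):
        # absurd temperature with tiny friction blows coordinates up
        run_langevin(top, SimParams(temperature=1e26, friction=1.0,
                                    n_steps=20_000, save_interval=100, seed=0))


def test_frozen_trajectory_com_trace(parallel_top):
    frames = np.repeat(parallel_top.positions[None], 5, axis=0)
    tr = com_distance_trace(frames, 30, parallel_top.positions)
    assert tr.sd == 0.0
    assert tr.mean == pytest.approx(tr.native_value)


def test_com_histogram_normalized_and_binned(parallel_top):
    res = run_langevin(parallel_top, SimParams(temperature=0.5, friction=1.0,
                                               n_steps=50_000, save_interval=100,
                                               seed=5))
    tr = com_distance_trace(res.frames, 30, parallel_top.positions)
    assert tr.histogram.sum() == pytest.approx(1.0, abs=1e-9)
    widths = np.diff(tr.bin_edges)
    assert np.allclose(widths, 0.01, atol=1e-12)
    # edges anchored at integer multiples of 0.01 nm
    assert np.allclose(np.round(tr.bin_edges / 0.01) * 0.01, tr.bin_edges,
                       atol=1e-12)


def test_native_com_within_three_sd_of_sampled_mean(parallel_top):
    res = run_langevin(parallel_top, SimParams(temperature=0.5, friction=1.0,
                                               n_steps=150_000, save_interval=300,
                                               seed=7))
    tr = com_distance_trace(res.frames[20:], 30, parallel_top.positions)
    assert abs(tr.native_value - tr.mean) < 3 * max(tr.sd, 1e-3)


def test_floppy_dimer_has_broader_com_distribution(parallel_top, hinge_top):
    """Fewer interface contacts -> wider COM distance distribution."""
    p = SimParams(temperature=0.5, friction=1.0, n_steps=150_000,
                  save_interval=300, seed=9)
    tr_stiff = com_distance_trace(run_langevin(parallel_top, p).frames[20:],
                                  30, parallel_top.positions)
    tr_floppy = com_distance_trace(run_langevin(hinge_top, p).frames[20:],
                                   30, hinge_top.positions)
    assert tr_floppy.sd > 1.5 * tr_stiff.sd


def test_independent_seeds_agree_on_mean(parallel_top):
    p1 = SimParams(temperature=0.5, friction=1.0, n_steps=600_000,
                   save_interval=500, seed=21)
    p2 = SimParams(temperature=0.5, friction=1.0, n_steps=600_000,
                   save_interval=500, seed=22)
    t1 = com_distance_trace(run_langevin(parallel_top, p1).frames[120:], 30)
    t2 = com_distance_trace(run_langevin(parallel_top, p2).frames[120:], 30)
    def block_se(values, n_blocks=6):
        blocks = np.array_split(values, n_blocks)
        means = np.array([b.mean() for b in blocks])
        return means.std(ddof=1) / np.sqrt(n_blocks)

    se = np.hypot(block_se(t1.values), block_se(t2.values))
    assert abs(t1.mean - t2.mean) < 3 * se


def test_topology_flat_file_export(tmp_path, parallel_top):
    path = tmp_path / "top.dat"
    parallel_top.to_flat_file(path)
    text = path.read_text()
    for section in ("[beads]", "[bonds]", "[angles]", "[dihedrals]", "[contacts]"):
        assert section in text


def test_trajectory_xyz_export(tmp_path, parallel_top):
    from tridimer.sbm import save_trajectory_xyz
    frames = np.repeat(parallel_top.positions[None], 3, axis=0)
    path = tmp_path / "traj.xyz"
    save_trajectory_xyz(frames, path, comment="native")
    lines = path.read_text().splitlines()
    assert lines[0] == str(parallel_top.n_beads)
    assert len(lines) == 3 * (parallel_top.n_beads + 2)
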