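"""Structure I/O, symmetry expansion, tri-dimer extraction."""

import numpy as np
import pytest

from tridimer.contacts import ContactParams
from tridimer.structures import (CapsidAssembly, EmptyAssemblyError,
                                 ExtractionError, OperatorError,
                                 expand_assembly, extract_tridimer,
                                 read_structure, write_assembly, write_tridimer)
from tridimer.synthetic import (SyntheticSpec, icosahedral_operators,
                                make_t3_lattice, make_toy_dimer)


def test_write_read_roundtrip_preserves_structure(tmp_path):
    asm, _ = make_toy_dimer(12, planted_inter=4, planted_intra=5, seed=0)
    path = tmp_path / "toy.pdb"
    write_assembly(asm, path)
    back = read_structure(path)
    assert len(back) == 2
    for orig, re_read in zip(asm.chains, back.chains):
        assert len(re_read) == len(orig)
        assert re_read.n_atoms == orig.n_atoms
        assert np.allclose(re_read.coords(), orig.coords(), atol=1e-3)


def test_read_structure_synthetic_provenance_and_filtering(tmp_path):
    asm, _ = make_toy_dimer(8, 2, 2, seed=1)
    path = tmp_path / "toy.pdb"
    write_assembly(asm, path)
    back = read_structure(path, source_id="toy")
    assert back.source_id == "toy"
    assert all(len(r.atoms) >= 1 for c in back.chains for r in c.residues)


def test_rna_only_file_raises_empty_assembly(tmp_path):
    pdb = "\n".join(
        f"ATOM  {i+1:5d}  P     G A{i+1:4d}    {float(i):8.3f}{0.0:8.3f}{0.0:8.3f}"
        f"{1.0:6.2f}{0.0:6.2f}           P"
        for i in range(5)) + "\nEND\n"
    path = tmp_path / "rna.pdb"
    path.write_text(pdb)
    with pytest.raises(EmptyAssemblyError):
        read_structure(path)


def test_garbage_file_raises_format_error(tmp_path):
    path = tmp_path / "junk.cif"
    path.write_text("this is not a structure\n")
    with pytest.raises(Exception):
        read_structure(path)


def test_altloc_resolution_keeps_highest_occupancy(tmp_path):
    lines = [
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C",
        "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60  0.00           C",
    ]
    # pad a few more residues so the chain is kept
    for k in range(2, 6):
        lines.append(
            f"ATOM  {k+1:5d}  CA  ALA A{k:4d}    {k*3.8:8.3f}{0.0:8.3f}{0.0:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}           C")
    path = tmp_path / "alt.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    asm = read_structure(path)
    first = asm.chains[0].residues[0]
    assert len(first.atoms) == 1
    assert first.atoms[0].coords[0] == pytest.approx(5.0, abs=1e-3)  # occ 0.60 wins


def test_expand_assembly_counts_and_provenance():
    asm, _ = make_toy_dimer(8, 2, 2, seed=0)
    ops = [(np.eye(3), np.zeros(3)),
           (np.diag([-1.0, -1.0, 1.0]), np.array([50.0, 0.0, 0.0]))]
    out = expand_assembly(asm, ops)
    assert len(out) == 4
    assert out.provenance == "biomt_expanded"
    labels = [c.chain_id for c in out.chains]
    assert len(set(labels)) == 4


def test_expand_with_identity_keeps_coordinates():
    asm, _ = make_toy_dimer(8, 2, 2, seed=0)
    out = expand_assembly(asm, [(np.eye(3), np.zeros(3))])
    for a, b in zip(asm.chains, out.chains):
        assert np.allclose(a.coords(), b.coords())


def test_expand_rejects_non_orthonormal_rotation():
    asm, _ = make_toy_dimer(8, 2, 2, seed=0)
    with pytest.raises(OperatorError):
        expand_assembly(asm, [(np.eye(3) * 1.01, np.zeros(3))])


def test_iau_times_sixty_operators_gives_full_capsid():
    """3-chain asymmetric unit x 60 icosahedral rotations = 180 chains."""
    lattice = make_t3_lattice()
    iau = CapsidAssembly(lattice.chains[:3], source_id="iau",
                         provenance="synthetic")
    ops = [(g, np.zeros(3)) for g in icosahedral_operators()]
    full = expand_assembly(iau, ops)
    assert len(full) == 180


def test_expansion_maps_lattice_onto_itself(lattice):
    """The icosahedral group permutes the synthetic chain set (point set)."""
    ops = icosahedral_operators()
    centers = np.array([c.centroid() for c in lattice.chains])
    g = ops[7]
    rotated = centers @ g.T
    d = np.linalg.norm(rotated[:, None, :] - centers[None, :, :], axis=-1)
    assert d.min(axis=1).max() < 1e-6


def test_two_chain_symmetric_expansion_distance_matrix():
    asm, _ = make_toy_dimer(8, 2, 2, seed=0)
    single = CapsidAssembly([asm.chains[0]], source_id="one",
                            provenance="synthetic")
    R = np.diag([-1.0, -1.0, 1.0])  # 180 degrees about z
    out = expand_assembly(single, [(np.eye(3), np.zeros(3)), (R, np.zeros(3))])
    ca = out.chains[0].coords()
    cb = out.chains[1].coords()
    d_ab = np.linalg.norm(ca[:, None] - cb[None, :], axis=-1)
    # |a_i - R a_j| = |a_j - R a_i| for an involution R
    assert np.allclose(d_ab, d_ab.T, atol=1e-9)


def test_extract_tridimer_roles_and_conformers(lattice, tridimer):
    assert len(tridimer.chains) == 6
    confs = sorted(c.conformer for c in tridimer.iau_chains)
    assert confs == ["A", "B", "C"]
    flank_confs = sorted(c.conformer for c in tridimer.flank_chains)
    assert flank_confs == ["A", "B", "C"]
    roles = set(tridimer.roles.values())
    assert roles == {"IAU-A", "IAU-B", "IAU-C",
                     "FLANK-of-A", "FLANK-of-B", "FLANK-of-C"}
    # flank pairing: A pairs with a B, B with an A, C with a C
    by_role = {r: cid for cid, r in tridimer.roles.items()}
    sub = tridimer.as_assembly()
    assert sub.chain(by_role["FLANK-of-A"]).conformer == "B"
    assert sub.chain(by_role["FLANK-of-B"]).conformer == "A"
    assert sub.chain(by_role["FLANK-of-C"]).conformer == "C"


def test_extract_tridimer_is_deterministic(lattice):
    td1 = extract_tridimer(lattice)
    td2 = extract_tridimer(lattice)
    assert td1.roles == td2.roles


def test_extract_tridimer_rejects_degenerate_input():
    lattice = make_t3_lattice()
    three = CapsidAssembly(lattice.chains[:3], source_id="iau_only",
                           provenance="synthetic")
    with pytest.raises(ExtractionError):
        extract_tridimer(three)


def test_tridimer_pdb_has_role_remarks(tmp_path, tridimer):
    path = tmp_path / "td.pdb"
    write_tridimer(tridimer, path)
    text = path.read_text()
    assert "ROLE IAU-A" in text
    assert "ROLE FLANK-of-C" in text
    back = read_structure(path)
    assert len(back) == 6
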