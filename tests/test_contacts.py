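"""Contact detection and residue projection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tridimer.contacts import (AtomPair, ContactParams, atomic_contacts,
                               contact_set, project_to_residue_contacts)
from tridimer.structures import AtomRecord, ChainModel, Residue
from tridimer.synthetic import make_toy_dimer


def _chain(cid, coords, res_per_atom=None, sep=1):
    """Chain of single-atom residues at the given coordinates."""
    residues = []
    for k, xyz in enumerate(coords):
        idx = (k + 1) * sep
        residues.append(Residue("ALA", idx, [AtomRecord("CA", "C", np.asarray(xyz, float), idx)]))
    return ChainModel(cid, "unknown", residues)


def brute_force_pairs(chain_x, chain_y, params):
    """Independent O(n^2) oracle for atomic_contacts."""
    ax = [(r.index, a) for r in chain_x.residues for a in r.atoms if a.element != "H"]
    ay = [(r.index, a) for r in chain_y.residues for a in r.atoms if a.element != "H"]
    intra = chain_x is chain_y
    out = set()
    for i, (ri, ai) in enumerate(ax):
        for j, (rj, aj) in enumerate(ay):
            if intra and j <= i:
                continue
            if intra and abs(ri - rj) < params.min_seq_sep:
                continue
            d = float(np.linalg.norm(ai.coords - aj.coords))
            if d <= params.cutoff:
                if intra and (ri > rj or (ri == rj and i > j)):
                    ri2, rj2, ai2, aj2 = rj, ri, aj, ai
                else:
                    ri2, rj2, ai2, aj2 = ri, rj, ai, aj
                out.add((ri2, rj2, ai2.atom_name, aj2.atom_name))
    return out


@pytest.mark.parametrize("distance,expected", [(4.0, 1), (5.0, 0)])
def test_single_atom_pair_cutoff(distance, expected):
    x = _chain("X", [(0.0, 0.0, 0.0)])
    y = _chain("Y", [(distance, 0.0, 0.0)])
    pairs = atomic_contacts(x, y, ContactParams(cutoff=4.5))
    assert len(pairs) == expected


def test_grid_matches_bruteforce_on_random_clouds(rng):
    params = ContactParams(cutoff=4.5)
    for trial in range(10):
        nx, ny = rng.integers(20, 120, 2)
        cx = rng.uniform(0, 25, (nx, 3))
        cy = rng.uniform(0, 25, (ny, 3))
        x, y = _chain("X", cx), _chain("Y", cy)
        got = {(p.res_x, p.res_y, p.atom_x, p.atom_y)
               for p in atomic_contacts(x, y, params)}
        assert got == brute_force_pairs(x, y, params)


def test_intra_chain_respects_min_seq_sep(rng):
    coords = rng.uniform(0, 10, (30, 3))
    ch = _chain("X", coords)
    params = ContactParams(cutoff=6.0, min_seq_sep=3)
    pairs = atomic_contacts(ch, ch, params)
    assert pairs, "dense cloud should have intra contacts"
    assert all(abs(p.res_x - p.res_y) >= 3 for p in pairs)
    got = {(p.res_x, p.res_y, p.atom_x, p.atom_y) for p in pairs}
    assert got == brute_force_pairs(ch, ch, params)


def test_projection_collapses_atom_multiplicity():
    x = ChainModel("X", "unknown", [Residue("ALA", 5, [
        AtomRecord("CA", "C", [0, 0, 0], 5),
        AtomRecord("CB", "C", [1, 0, 0], 5),
        AtomRecord("CG", "C", [0, 1, 0], 5)])])
    y = ChainModel("Y", "unknown", [Residue("LEU", 12, [
        AtomRecord("CA", "C", [2, 0, 0], 12)])])
    pairs = atomic_contacts(x, y, ContactParams(cutoff=4.5))
    assert len(pairs) == 3  # three supporting atom pairs
    cs = project_to_residue_contacts(pairs, x, y)
    assert cs.n_inter == 1
    assert cs.residue_pairs_inter == {(5, 12)}


def test_no_contacts_gives_zero():
    x = _chain("X", [(0, 0, 0)])
    y = _chain("Y", [(50, 0, 0)])
    cs = project_to_residue_contacts(atomic_contacts(x, y), x, y)
    assert cs.n_inter == 0


def test_swapping_chains_swaps_intra_and_keeps_inter():
    asm, truth = make_toy_dimer(15, planted_inter=5, planted_intra=4, seed=3)
    x, y = asm.chains
    cs = contact_set(x, y)
    sw = contact_set(y, x)
    assert cs.n_inter == sw.n_inter == truth["n_inter"]
    assert (cs.n_intra_x, cs.n_intra_y) == (sw.n_intra_y, sw.n_intra_x)
    assert cs.swapped().residue_pairs_inter == sw.residue_pairs_inter


def test_planted_toy_dimer_counts_match_ground_truth():
    for seed in (0, 7):
        asm, truth = make_toy_dimer(20, planted_inter=6, planted_intra=9, seed=seed)
        cs = contact_set(*asm.chains)
        assert cs.n_inter == truth["n_inter"]
        assert cs.n_intra_x == truth["n_intra_x"]
        assert cs.n_intra_y == truth["n_intra_y"]
        assert cs.residue_pairs_inter == set(map(tuple, truth["inter_pairs"]))


@settings(derandomize=True, max_examples=20, deadline=None)
@given(cut1=st.floats(2.0, 6.0), cut2=st.floats(2.0, 6.0))
def test_contact_count_monotone_in_cutoff(cut1, cut2):
    rng = np.random.default_rng(99)
    cx = rng.uniform(0, 15, (40, 3))
    cy = rng.uniform(0, 15, (40, 3))
    x, y = _chain("X", cx), _chain("Y", cy)
    lo, hi = sorted((cut1, cut2))
    n_lo = len(atomic_contacts(x, y, ContactParams(cutoff=lo)))
    n_hi = len(atomic_contacts(x, y, ContactParams(cutoff=hi)))
    assert n_lo <= n_hi


def test_empty_chain_warns_not_raises():
    x = _chain("X", [(0, 0, 0)])
    empty = ChainModel("E", "unknown", [])
    with pytest.warns(UserWarning):
        assert atomic_contacts(x, empty) == []


def test_shadow_method_is_explicitly_unimplemented():
    with pytest.raises(NotImplementedError):
        ContactParams(method="shadow")


def test_contactset_tsv_roundtrip(tmp_path):
    asm, _ = make_toy_dimer(10, planted_inter=3, planted_intra=2, seed=1)
    cs = contact_set(*asm.chains)
    path = tmp_path / "contacts.tsv"
    cs.to_tsv(path)
    lines = path.read_text().strip().splitlines()
    assert lines[0].split("\t") == ["chain_a", "res_a", "chain_b", "res_b", "class"]
    n_inter = sum(1 for l in lines[1:] if l.endswith("inter"))
    assert n_inter == cs.n_inter
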