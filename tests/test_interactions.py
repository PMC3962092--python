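"""Salt bridges, phosphate environments, clashes, burial depth, torsions."""

import networkx as nx
import numpy as np
import pytest

from conftest import random_rigid_transform

from wedgemap import interactions as ia
from wedgemap import structio as st
from wedgemap import synthetic_data as sd
from wedgemap.structio import Atom, Residue, StructureModel


def _res(name, num, chain, atom_name, pos):
    return Residue(name=name, number=num, chain=chain,
                   atoms=[Atom(atom_name, atom_name[0], np.array(pos, float))])


def _model(residues):
    chains = {}
    for r in residues:
        chains.setdefault(r.chain, []).append(r)
    return StructureModel(chains=chains,
                          roles={c: c for c in chains if c in "abc"})


class TestSaltBridges:
    def test_pair_below_cutoff_detected(self):
        m = _model([_res("LYS", 1, "a", "NZ", [0, 0, 0]),
                    _res("GLU", 2, "a", "OE1", [0, 0, 3.0])])
        bridges = ia.detect_salt_bridges(m)
        assert len(bridges) == 1
        assert bridges[0].distance == pytest.approx(3.0)

    def test_pair_beyond_cutoff_ignored(self):
        m = _model([_res("LYS", 1, "a", "NZ", [0, 0, 0]),
                    _res("GLU", 2, "a", "OE1", [0, 0, 5.0])])
        assert ia.detect_salt_bridges(m) == []

    def test_three_cations_two_anions_all_pairs(self):
        # exhaustive pair enumeration: 3 x 2 = 6 bridges
        residues = [
            _res("LYS", 1, "a", "NZ", [0, 0, 0]),
            _res("ARG", 2, "a", "NH1", [2, 0, 0]),
            _res("LYS", 3, "b", "NZ", [0, 2, 0]),
            _res("GLU", 4, "a", "OE1", [1, 1, 0]),
            _res("ASP", 5, "b", "OD1", [1, 0, 1]),
        ]
        assert len(ia.detect_salt_bridges(_model(residues))) == 6

    def test_no_self_pairs_and_symmetry(self, bundle):
        b = bundle("equine")
        for br in ia.detect_salt_bridges(b.model):
            assert (br.cation[0], br.cation[1]) != (br.anion[0], br.anion[1])


class TestNeutralization:
    def test_equine_bridged_lysine_neutralized(self, bundle):
        b = bundle("equine")
        assert ia.neutralization_status(b.model, ("b", 389)) == "neutralized"

    def test_murine_lysine_with_distant_anion_free(self, bundle):
        b = bundle("murine")
        assert ia.neutralization_status(b.model, ("b", 367)) == "free"

    def test_isolated_cation_free(self):
        m = _model([_res("LYS", 1, "a", "NZ", [0, 0, 0])])
        assert ia.neutralization_status(m, ("a", 1)) == "free"

    def test_neutral_residue_rejected(self):
        m = _model([_res("SER", 1, "a", "OG", [0, 0, 0])])
        with pytest.raises(ia.InteractionError):
            ia.neutralization_status(m, ("a", 1))


class TestPhosphateEnvironment:
    def test_empty_shell_gives_zero_net(self, bundle):
        b = bundle("murine")
        far = b.ligand.transformed(np.eye(3), np.array([500.0, 0, 0]))
        rep = ia.phosphate_environment(b.model, far)
        assert rep.net_score("P1") == 0 and rep.net_score("P2") == 0
        assert rep.contacts("P1") == []

    def test_murine_p1_cluster(self, bundle):
        rep = bundle("murine").report
        assert rep.net_score("P1") >= 3
        assert len(rep.contacts("P1", "attractive", chain_role="b")) >= 2

    def test_human_p2_net_repulsion(self, bundle):
        rep = bundle("human").report
        assert rep.net_score("P2") <= -2
        neutralized = {(c.chain_role, c.number)
                       for c in rep.contacts("P1", "neutralized")}
        assert ("b", 388) in neutralized

    def test_partition_no_overlaps(self, bundle):
        for sp in ("murine", "human", "equine"):
            rep = bundle(sp).report
            for which in ("P1", "P2"):
                seen = [(c.chain, c.number) for c in rep.contacts(which)]
                assert len(seen) == len(set(seen))
                for c in rep.contacts(which):
                    assert c.status in ("attractive", "repulsive", "neutralized")

    def test_rigid_transform_invariance(self, bundle):
        # all detectors are geometric: moving the whole complex rigidly
        # must not change any classification (50 random transforms)
        b = bundle("murine")
        ref = [(c.chain, c.number, c.status)
               for c in b.report.contacts("P1")]
        ref_bridges = {(br.cation, br.anion)
                       for br in ia.detect_salt_bridges(b.model)}
        ref_clash = ia.clash_score(b.model, b.ligand).count
        rng = np.random.default_rng(42)
        for _ in range(50):
            R, t = random_rigid_transform(rng)
            m2 = b.model.transformed(R, t)
            l2 = b.ligand.transformed(R, t)
            rep2 = ia.phosphate_environment(m2, l2)
            assert [(c.chain, c.number, c.status)
                    for c in rep2.contacts("P1")] == ref
            assert {(br.cation, br.anion)
                    for br in ia.detect_salt_bridges(m2)} == ref_bridges
            assert ia.clash_score(m2, l2).count == ref_clash


class TestClashScore:
    def test_distant_ligand_accepted(self, bundle):
        b = bundle("murine")
        far = b.ligand.transformed(np.eye(3), np.array([100.0, 0, 0]))
        rep = ia.clash_score(b.model, far)
        assert rep.count == 0 and rep.accepted

    def test_forced_overlap_rejected(self):
        m = _model([_res("GLY", 1, "a", "CA", [0, 0, 0])])
        lig, _ = sd.make_toy_ligand(4)
        # drop a ligand atom onto the protein atom: 1.0 < 0.7*(1.7+1.7)
        shift = np.array([0, 0, 1.0]) - lig.atoms[0].coords
        near = lig.transformed(np.eye(3), shift)
        rep = ia.clash_score(m, near)
        assert rep.count >= 1 and rep.verdict == "rejected"

    def test_flip_into_obstruction_rejected_flip_back_accepted(self):
        m, _ = sd.make_toy_complex("human", obstruct_flipped_site=True)
        lig = st.extract_ligand(m, ["LIG"])
        assert ia.clash_score(m, lig).accepted
        mf, _ = sd.make_toy_complex("human", pose="flipped",
                                    obstruct_flipped_site=True)
        ligf = st.extract_ligand(mf, ["LIG"])
        assert ia.clash_score(mf, ligf).verdict == "rejected"

    def test_monotone_in_overlap_factor(self, bundle):
        b = bundle("murine")
        counts = [ia.clash_score(b.model, b.ligand, overlap_factor=f).count
                  for f in (0.5, 0.7, 0.9, 1.1)]
        assert counts == sorted(counts)


class TestBurialDepth:
    def test_self_delta_zero(self, bundle):
        b = bundle("murine")
        d = ia.burial_depth_delta((b.model, b.ligand), (b.model, b.ligand))
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_axis_displacement_recovered_exactly(self, bundle):
        b = bundle("murine")
        _, axis = ia.pocket_axis(b.model, b.ligand)
        moved = b.ligand.transformed(np.eye(3), 2.0 * axis)
        d = ia.burial_depth_delta((b.model, b.ligand), (b.model, moved))
        assert d == pytest.approx(2.0, abs=1e-6)

    def test_antisymmetry(self, bundle):
        b = bundle("murine")
        _, axis = ia.pocket_axis(b.model, b.ligand)
        moved = b.ligand.transformed(np.eye(3), 1.3 * axis)
        d_ab = ia.burial_depth_delta((b.model, b.ligand), (b.model, moved))
        d_ba = ia.burial_depth_delta((b.model, moved), (b.model, b.ligand))
        assert d_ab == pytest.approx(-d_ba, abs=1e-6)

    def test_alt_frame_independence(self, bundle):
        # the alt complex may arrive in any frame; superposition removes it
        b = bundle("murine")
        _, axis = ia.pocket_axis(b.model, b.ligand)
        moved = b.ligand.transformed(np.eye(3), 2.0 * axis)
        rng = np.random.default_rng(7)
        R, t = random_rigid_transform(rng)
        d = ia.burial_depth_delta(
            (b.model, b.ligand),
            (b.model.transformed(R, t), moved.transformed(R, t)),
        )
        assert d == pytest.approx(2.0, abs=1e-6)


class TestTfeEstimate:
    def test_butane_has_one_rotatable_bond(self):
        g = nx.path_graph(4)
        n, tfe = ia.tfe_estimate(g, weight=0.2983)
        assert n == 1
        assert tfe == pytest.approx(0.2983)

    def test_ring_only_graph_zero(self):
        n, tfe = ia.tfe_estimate(nx.cycle_graph(6))
        assert n == 0 and tfe == 0

    def test_matches_enumeration_on_toy_ligand(self):
        lig, g = sd.make_toy_ligand(4)
        n, _ = ia.tfe_estimate(g)
        # independent enumeration straight from the definition
        cyc = set()
        for cycle in nx.cycle_basis(g):
            for i, u in enumerate(cycle):
                cyc.add(frozenset((u, cycle[(i + 1) % len(cycle)])))
        expected = sum(
            1 for u, v in g.edges
            if frozenset((u, v)) not in cyc
            and g.degree(u) >= 2 and g.degree(v) >= 2
        )
        assert n == expected

    def test_longer_chains_strictly_increase(self):
        _, g1 = sd.make_toy_ligand(4, (8, 8, 8, 8))
        _, g2 = sd.make_toy_ligand(4, (16, 16, 16, 16))
        assert ia.tfe_estimate(g2)[0] > ia.tfe_estimate(g1)[0]

    def test_disconnected_graph_rejected(self):
        g = nx.Graph([(0, 1), (2, 3)])
        with pytest.raises(ia.InteractionError):
            ia.tfe_estimate(g)
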