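"""PDB I/O, chain roles, ligand extraction and rigid superposition."""

import numpy as np
import pytest

from wedgemap import structio as st
from wedgemap import synthetic_data as sd
from wedgemap.structio import Atom, Residue, StructureModel, StructureError


def _toy_two_chain():
    def res(name, num, chain, pos):
        return Residue(name=name, number=num, chain=chain,
                       atoms=[Atom("CA", "C", np.array(pos, float))])
    return StructureModel(chains={
        "A": [res("GLY", i, "A", [i * 3.8, 0, 0]) for i in range(1, 4)],
        "B": [res("ALA", i, "B", [i * 3.8, 5, 0]) for i in range(1, 3)],
    })


class TestPdbRoundTrip:
    def test_write_read_preserves_atoms_and_coords(self, tmp_path):
        m0, _ = sd.make_toy_complex("human")
        p = tmp_path / "toy.pdb"
        st.write_pdb(m0, p)
        m1 = st.read_pdb(p)
        assert sorted(m1.chains) == sorted(m0.chains)
        for cid in m0.chains:
            r0s, r1s = m0.chains[cid], m1.chains[cid]
            assert [r.number for r in r0s] == [r.number for r in r1s]
            for r0, r1 in zip(r0s, r1s):
                assert r0.name == r1.name
                for a0, a1 in zip(r0.atoms, r1.atoms):
                    assert np.allclose(a0.coords, a1.coords, atol=1.5e-3)

    def test_two_chain_toy(self, tmp_path):
        p = tmp_path / "two.pdb"
        st.write_pdb(_toy_two_chain(), p)
        m = st.read_pdb(p)
        assert len(m.chains) == 2

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(
            "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.40  0.00"
            "           C\n"
            "ATOM      2  CA BGLY A   1       1.000   0.000   0.000  0.60  0.00"
            "           C\n"
            "ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00"
            "           C\nEND\n"
        )
        m = st.read_pdb(p)
        # one atom kept per (chain, resnum, atom name) triple
        keys = [(r.chain, r.number, a.name) for r, a in m.atoms()]
        assert len(keys) == len(set(keys)) == 2
        kept = m.chains["A"][0].atom("CA")
        assert kept.coords[0] == pytest.approx(1.0)  # occupancy 0.60 wins


class TestChainRoles:
    def test_explicit_config(self):
        m = _toy_two_chain()
        out = st.assign_chain_roles(m, {"A": "a", "B": "c"})
        assert out.roles == {"a": "A", "c": "B"}

    def test_auto_dimer_partition_by_length(self):
        def chain(cid, n, offset):
            return [Residue("GLY", i, cid,
                            [Atom("CA", "C", np.array([i * 0.05, offset, 0.0]))])
                    for i in range(1, n + 1)]
        m = StructureModel(chains={
            "A": chain("A", 600, 0.0), "B": chain("B", 600, 40.0),
            "C": chain("C", 160, 1.0), "D": chain("D", 160, 41.0),
        })
        out = st.assign_chain_roles(m, "auto")
        # independent length partition: two 600-residue TLR4s, two MD-2s
        assert {out.roles["a"], out.roles["b"]} == {"A", "B"}
        assert {out.roles["c"], out.roles["c*"]} == {"C", "D"}
        # MD-2 pairs with the TLR4 it actually touches
        assert (out.roles["a"], out.roles["c"]) in [("A", "C"), ("B", "D")]

    def test_auto_monomer_leaves_role_b_absent(self):
        def chain(cid, n, offset):
            return [Residue("GLY", i, cid,
                            [Atom("CA", "C", np.array([i * 0.05, offset, 0.0]))])
                    for i in range(1, n + 1)]
        m = StructureModel(chains={"A": chain("A", 600, 0.0),
                                   "C": chain("C", 160, 1.0)})
        out = st.assign_chain_roles(m, "auto")
        assert "b" not in out.roles
        assert out.roles["a"] == "A" and out.roles["c"] == "C"


class TestExtractLigand:
    def test_p1_on_glycosidic_ring(self):
        # the generator's own bond list is the connectivity oracle
        lig, g = sd.make_toy_ligand(4)
        inferred = st.infer_bonds(lig.atoms)
        assert set(map(frozenset, inferred.edges)) == set(map(frozenset, g.edges))
        m, _ = sd.make_toy_complex("murine")
        ext = st.extract_ligand(m, ["LIG"])
        # P1 is bonded through an O to an anomeric carbon of its ring
        p1 = ext.p1[0]
        ester_os = [o for o in ext.bonds.neighbors(p1)
                    if any(ext.atoms[c].element == "C"
                           for c in ext.bonds.neighbors(o) if c != p1)]
        carbons = [c for o in ester_os for c in ext.bonds.neighbors(o)
                   if ext.atoms[c].element == "C"]
        ring_o = next(i for i in ext.glcn1 if ext.atoms[i].element == "O")
        assert any(c in ext.bonds.neighbors(ring_o) for c in carbons)
        assert ext.atoms[p1].element == "P"

    def test_four_chain_plan_recovered(self):
        m, _ = sd.make_toy_complex("murine")
        ext = st.extract_ligand(m, ["LIG"])
        assert sorted(ext.acyl_chains) == [("A", 14), ("B", 14), ("C", 14),
                                           ("D", 14)]

    def test_six_chain_plan_recovered(self):
        lig, _ = sd.make_toy_ligand(6, (14, 14, 14, 14, 12, 14))
        counts = dict(lig.acyl_chains)
        assert counts["C'"] == 12 and counts["D'"] == 14
        # and via the distance-based extractor on a full model
        spec = sd.ToySpec(acyl_plan=(14, 14, 14, 14, 12, 14))
        m, _ = sd.make_toy_complex("murine", spec)
        ext = st.extract_ligand(m, ["LIG"])
        assert sorted(c for _, c in ext.acyl_chains) == [12, 14, 14, 14, 14, 14]

    def test_single_phosphate_rejected(self):
        m, _ = sd.make_toy_complex("murine")
        lig_res = m.chains["L"][0]
        # strip the P2 group
        p2_names = {"P2"}
        lig_res.atoms = [a for a in lig_res.atoms
                         if not (a.name in p2_names and a.element == "P")]
        with pytest.raises(StructureError, match="phosphorus"):
            st.extract_ligand(m, ["LIG"])

    def test_record_order_invariance(self):
        m, _ = sd.make_toy_complex("equine")
        ext1 = st.extract_ligand(m, ["LIG"])
        lig_res = m.chains["L"][0]
        lig_res.atoms = list(reversed(lig_res.atoms))
        ext2 = st.extract_ligand(m, ["LIG"])
        assert ext1.acyl_chains == ext2.acyl_chains
        assert np.allclose(ext1.p_coord("P1"), ext2.p_coord("P1"))


class TestSuperpose:
    def test_identical_gives_zero_rmsd(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        _, _, rmsd = st.superpose_points(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3)) * 5
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = (R @ pts.T).T + np.array([10.0, -3.0, 7.0])
        _, _, rmsd = st.superpose_points(pts, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_four_point_displacement_matches_closed_form(self):
        # square in a plane; one corner lifted by 2 Å. By symmetry the
        # best fit splits the displacement: rmsd = sqrt(sum d_i^2 / 4)
        # computed here with an independent dense grid refinement.
        ref = np.array([[1, 1, 0], [-1, 1, 0], [-1, -1, 0], [1, -1, 0]], float)
        mov = ref.copy()
        mov[0, 2] += 2.0
        _, _, rmsd = st.superpose_points(ref, mov)

        # independent oracle: brute-force over rotations (scipy-free, coarse
        # grid + local refinement around the optimum)
        def rmsd_at(angles):
            ax, ay, az = angles
            Rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)],
                           [0, np.sin(ax), np.cos(ax)]])
            Ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0],
                           [-np.sin(ay), 0, np.cos(ay)]])
            Rz = np.array([[np.cos(az), -np.sin(az), 0],
                           [np.sin(az), np.cos(az), 0], [0, 0, 1]])
            R = Rz @ Ry @ Rx
            a = mov - mov.mean(axis=0)
            b = ref - ref.mean(axis=0)
            d = (R @ a.T).T - b
            return np.sqrt((d ** 2).sum() / 4)

        best = min(
            rmsd_at((ax, ay, az))
            for ax in np.linspace(-0.5, 0.5, 41)
            for ay in np.linspace(-0.5, 0.5, 41)
            for az in np.linspace(-0.5, 0.5, 11)
        )
        assert rmsd == pytest.approx(best, abs=5e-3)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(StructureError):
            st.superpose_points(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_selection_syntax(self):
        m, _ = sd.make_toy_complex("murine")
        pts = st.select_atoms(m, ["b:367@NZ"])
        assert pts.shape == (1, 3)
        with pytest.raises(StructureError):
            st.parse_selection("nonsense")
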