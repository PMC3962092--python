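"""Numbering translation, alignment-structure mapping, species models."""

import numpy as np
import pytest

from wedgemap import mapping as mp
from wedgemap import seqalign as sa
from wedgemap import synthetic_data as sd
from wedgemap.mapping import (
    MappingError,
    NumberingRangeError,
    UnalignedPosition,
    default_numbering_rule,
    translate_numbering,
)
from wedgemap.seqalign import MSA, Sequence


@pytest.fixture(scope="module")
def rule():
    return default_numbering_rule()


class TestNumberingRule:
    @pytest.mark.parametrize("frm,to,pos,expected", [
        ("equine", "murine", 389, 386),   # eLys389b <-> mSer386b
        ("human", "equine", 388, 389),    # hLys388b <-> eLys389b
        ("equine", "human", 100, 100),    # segment 1: e = h
        ("equine", "canine", 100, 100),   # segment 1: e = c
        ("equine", "murine", 100, 99),    # segment 1: e = m + 1
        ("murine", "equine", 367, 370),   # mLys367b labeled 370b
        ("murine", "equine", 434, 437),   # mArg434b labeled 437b
        ("murine", "equine", 386, 389),   # mSer386b labeled 389b
        ("murine", "human", 341, 343),    # mLys341a / hGly343a
        ("human", "canine", 388, 388),    # canine tracks human numbering
    ])
    def test_published_residue_pairs(self, rule, frm, to, pos, expected):
        assert translate_numbering(rule, frm, to, pos) == expected

    def test_round_trip_identity_over_printed_range(self, rule):
        for sp in ("human", "murine", "canine"):
            for e in range(1, rule.valid_range + 1):
                try:
                    p = rule.from_equine(sp, e)
                except UnalignedPosition:
                    continue
                assert rule.to_equine(sp, p) == e

    def test_monotone_within_species(self, rule):
        for sp in ("human", "murine", "canine"):
            mapped = []
            for e in range(1, rule.valid_range + 1):
                try:
                    mapped.append(rule.from_equine(sp, e))
                except UnalignedPosition:
                    continue
            assert mapped == sorted(mapped)
            assert len(mapped) == len(set(mapped))

    def test_beyond_rule_signals_alignment_fallback(self, rule):
        with pytest.raises(NumberingRangeError, match="alignment"):
            translate_numbering(rule, "equine", "murine", 561)

    def test_gap_positions_signal_not_guess(self, rule):
        # murine lacks equivalents for the two equine positions consumed
        # by its inter-segment deletion
        with pytest.raises(UnalignedPosition):
            rule.from_equine("murine", 297)
        with pytest.raises(UnalignedPosition):
            rule.from_equine("murine", 298)

    def test_unknown_species_rejected(self, rule):
        with pytest.raises(MappingError):
            translate_numbering(rule, "feline", "human", 100)


class TestMapAlignmentToStructure:
    def _msa(self, row_a, row_b):
        return MSA(ids=["tmpl", "other"], rows=[row_a, row_b],
                   species={"tmpl": "human", "other": "murine"})

    def test_full_coverage_on_exact_chain(self):
        seq = "ALKSVEDLKRAMGELA"
        helix = sd.make_toy_helix(seq)
        rmap = mp.map_alignment_to_structure(
            self._msa(seq, seq), helix, "A", "human")
        assert rmap.coverage == pytest.approx(1.0)
        assert [p for p, _, _ in rmap.pairs] == list(range(1, len(seq) + 1))

    def test_truncated_chain_reduces_coverage(self):
        seq = "ALKSVEDLKRAMGELA"
        helix = sd.make_toy_helix(seq[5:], start_number=6)
        rmap = mp.map_alignment_to_structure(
            self._msa(seq, seq), helix, "A", "human")
        assert len(rmap.pairs) == len(seq) - 5
        assert rmap.coverage == pytest.approx((len(seq) - 5) / len(seq))
        assert rmap.pairs[0][0] == 6  # first five columns unmapped

    def test_md2_position_122_maps_to_chain_c_residue_122(self):
        # an MD-2-sized toy chain numbered 1..160: column 122 of the species
        # row must pair with chain-c residue number 122
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list(sa.AMINO_ACIDS), 160))
        helix = sd.make_toy_helix(seq, chain="c")
        rmap = mp.map_alignment_to_structure(
            self._msa(seq, seq), helix, "c", "human")
        assert rmap.residue_for_position(122) == 122

    def test_wrong_chain_raises_identity_error(self):
        helix = sd.make_toy_helix("ALKSVEDLKRAMGELA")
        rng = np.random.default_rng(3)
        other = "".join(rng.choice(list(sa.AMINO_ACIDS), 16))
        with pytest.raises(MappingError, match="identity"):
            mp.map_alignment_to_structure(
                self._msa(other, other), helix, "A", "human")


class TestBuildSpeciesModel:
    def _rmap(self, helix, seq):
        msa = MSA(ids=["t", "q"], rows=[seq, seq],
                  species={"t": "human", "q": "murine"})
        return mp.map_alignment_to_structure(msa, helix, "A", "human")

    def test_identical_target_keeps_all_coordinates(self):
        seq = "ALKSVEDLKRAMGELA"
        helix = sd.make_toy_helix(seq)
        model = mp.build_species_model(
            helix, Sequence(id="m", residues=seq), self._rmap(helix, seq))
        for r0, r1 in zip(helix.chains["A"], model.chains["A"]):
            for a0, a1 in zip(r0.atoms, r1.atoms):
                assert np.allclose(a0.coords, a1.coords)

    def test_single_substitution_changes_one_side_chain(self):
        seq = "ALKSVEDLKRAMGELA"
        target = seq[:2] + "E" + seq[3:]  # K3E
        helix = sd.make_toy_helix(seq)
        model = mp.build_species_model(
            helix, Sequence(id="m", residues=target), self._rmap(helix, seq))
        changed = []
        for r0, r1 in zip(helix.chains["A"], model.chains["A"]):
            same = (len(r0.atoms) == len(r1.atoms) and all(
                a.name == b.name and np.allclose(a.coords, b.coords)
                for a, b in zip(r0.atoms, r1.atoms)))
            if not same:
                changed.append(r1)
        assert len(changed) == 1
        assert changed[0].name == "GLU"
        assert changed[0].atom("OE1") is not None

    def test_backbone_never_moves(self):
        seq = "ALKSVEDLKRAMGELA"
        target = "GREYHEKWANMQTVIC"
        helix = sd.make_toy_helix(seq)
        model = mp.build_species_model(
            helix, Sequence(id="m", residues=target), self._rmap(helix, seq))
        for r0, r1 in zip(helix.chains["A"], model.chains["A"]):
            for name in ("N", "CA", "C", "O"):
                assert np.allclose(r0.atom(name).coords, r1.atom(name).coords)

    def test_md2_122_substitution_threads_glutamate(self):
        rng = np.random.default_rng(12)
        seq = list(rng.choice(list(sa.AMINO_ACIDS), 160))
        seq[121] = "K"   # human lysine at 122
        seq = "".join(seq)
        target = seq[:121] + "E" + seq[122:]   # murine glutamate
        helix = sd.make_toy_helix(seq, chain="c")
        msa = MSA(ids=["t", "q"], rows=[seq, seq],
                  species={"t": "human", "q": "murine"})
        rmap = mp.map_alignment_to_structure(msa, helix, "c", "human")
        model = mp.build_species_model(
            helix, Sequence(id="mMD2", residues=target), rmap)
        res = model.residue("c", 122)
        assert res.name == "GLU"

    def test_low_coverage_refused(self):
        seq = "ALKSVEDLKRAMGELA"
        helix = sd.make_toy_helix(seq[8:], start_number=9)
        msa = MSA(ids=["t", "q"], rows=[seq, seq],
                  species={"t": "human", "q": "murine"})
        rmap = mp.map_alignment_to_structure(msa, helix, "A", "human")
        with pytest.raises(MappingError, match="coverage"):
            mp.build_species_model(helix, Sequence(id="m", residues=seq), rmap)


@pytest.fixture(scope="module")
def md2_msa():
    # three MD-2-like sequences realizing the published differential
    # positions on a shared random background
    rng = np.random.default_rng(5)
    bg = list(rng.choice(list(sa.AMINO_ACIDS), 160))

    def seq(subs):
        x = bg.copy()
        for pos, aa in subs.items():
            x[pos - 1] = aa
        return "".join(x)

    table6 = {
        "hMD2": {58: "K", 90: "R", 101: "D", 122: "K"},
        "mMD2": {58: "N", 90: "R", 101: "D", 122: "E"},
        "eMD2": {58: "R", 90: "R", 101: "D", 122: "R"},
    }
    species = {"hMD2": "human", "mMD2": "murine", "eMD2": "equine"}
    seqs = [Sequence(id=k, residues=seq(v), species=species[k],
                     protein="MD2") for k, v in table6.items()]
    return sa.progressive_msa(seqs)


class TestDifferentialResidues:

    def test_position_90_identical_cationic(self, md2_msa):
        row = mp.differential_residues(md2_msa, [90]).rows[0]
        assert set(row["residues"].values()) == {"R"}
        assert row["class"] == "identical"
        assert set(row["charges"].values()) == {"+"}

    def test_position_101_identical_anionic(self, md2_msa):
        row = mp.differential_residues(md2_msa, [101]).rows[0]
        assert set(row["residues"].values()) == {"D"}
        assert row["class"] == "identical"
        assert set(row["charges"].values()) == {"-"}

    def test_position_122_nonconserved_with_charge_reversal(self, md2_msa):
        row = mp.differential_residues(md2_msa, [122]).rows[0]
        assert row["residues"] == {"hMD2": "K", "mMD2": "E", "eMD2": "R"}
        assert row["class"] == "nonconserved"
        assert row["charges"] == {"hMD2": "+", "mMD2": "-", "eMD2": "+"}

    def test_position_58_follows_documented_default(self, md2_msa):
        # the sources disagree on the equine residue at 58 (Arg vs Glu);
        # the documented default is Arg
        row = mp.differential_residues(md2_msa, [58]).rows[0]
        assert row["residues"]["eMD2"] == "R"
        assert row["residues"]["mMD2"] == "N"

    def test_unknown_position_rejected(self, md2_msa):
        with pytest.raises(MappingError):
            mp.differential_residues(md2_msa, [500])

    def test_tsv_export(self, md2_msa, tmp_path):
        table = mp.differential_residues(md2_msa, [58, 90, 101, 122])
        out = tmp_path / "diff.tsv"
        table.to_tsv(out)
        assert len(out.read_text().strip().splitlines()) == 5
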