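#!/usr/bin/env python
"""Differential MD-2 residues and cross-species TLR4 numbering.

Builds an MD-2-like three-species alignment carrying the published
differential positions (58, 90, 101, 122 on chain c), writes the
differential table, and tabulates the piecewise numbering translation for
the mechanistically relevant chain-b/chain-a residues so each residue can
be quoted in any species' numbering.
"""

from pathlib import Path

import numpy as np

from wedgemap import mapping, seqalign
from wedgemap.seqalign import Sequence

OUT = Path(__file__).resolve().parents[1] / "results"

TABLE6 = {
    "hMD2": {58: "K", 90: "R", 101: "D", 122: "K"},
    "mMD2": {58: "N", 90: "R", 101: "D", 122: "E"},
    "eMD2": {58: "R", 90: "R", 101: "D", 122: "R"},
}
SPECIES = {"hMD2": "human", "mMD2": "murine", "eMD2": "equine"}


def main() -> None:
    rng = np.random.default_rng(5)
    bg = list(rng.choice(list(seqalign.AMINO_ACIDS), 160))
    seqs = []
    for sid, subs in TABLE6.items():
        x = bg.copy()
        for pos, aa in subs.items():
            x[pos - 1] = aa
        seqs.append(Sequence(id=sid, residues="".join(x),
                             species=SPECIES[sid], protein="MD2"))
    msa = seqalign.progressive_msa(seqs)
    table = mapping.differential_residues(msa, [58, 90, 101, 122])
    table.to_tsv(OUT / "differential_md2.tsv")
    table.to_json(OUT / "differential_md2.json")
    for row in table.rows:
        print(f"MD-2 {row['position']:>3}c: "
              + "  ".join(f"{s}={r}" for s, r in row["residues"].items())
              + f"  [{row['class']}]")

    rule = mapping.default_numbering_rule()
    pairs = [
        ("equine", 389, "the equine chain-b lysine locked by Glu344a"),
        ("equine", 370, "the chain-b position that is murine Lys367"),
        ("equine", 437, "the chain-b position that is murine Arg434"),
        ("human", 388, "the human chain-b lysine neutralized by Glu369b"),
    ]
    with open(OUT / "numbering_pairs.tsv", "w") as fh:
        fh.write("anchor_species\tanchor_pos\thuman\tmurine\tequine\tcanine\tnote\n")
        for sp, pos, note in pairs:
            row = [sp, str(pos)]
            for target in ("human", "murine", "equine", "canine"):
                try:
                    row.append(str(mapping.translate_numbering(rule, sp, target, pos)))
                except mapping.MappingError:
                    row.append("NA")
            fh.write("\t".join(row + [note]) + "\n")
            print(f"{sp} {pos} -> h{row[2]} m{row[3]} e{row[4]} c{row[5]}  ({note})")
    print("wrote differential_md2.tsv and numbering_pairs.tsv")


if __name__ == "__main__":
    main()
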