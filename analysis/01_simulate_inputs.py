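#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes, under results/: one wedge complex per species (PDB, normal pose),
the flipped human complex, and a toy MD-2-like sequence family (FASTA).
These are the desk-scale stand-ins for the crystal complexes and the
species sequence panel; every later analysis step reads them back through
the package's ordinary parsers.
"""

from pathlib import Path

from wedgemap import seqalign, synthetic_data as sd
from wedgemap.structio import write_pdb

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    for species in ("murine", "human", "equine", "canine"):
        model, _ = sd.make_toy_complex(species)
        path = OUT / f"toy_{species}.pdb"
        write_pdb(model, path,
                  remarks=[f"synthetic {species} TLR4/TLR4*/MD-2 wedge toy"])
        print(f"wrote {path.name}: "
              f"{sum(len(r) for r in model.chains.values())} residues, "
              f"roles {sorted(model.roles)}")

    model, _ = sd.make_toy_complex("human", pose="flipped")
    write_pdb(model, OUT / "toy_human_flipped.pdb",
              remarks=["synthetic human wedge toy, backbone-flipped ligand"])
    print("wrote toy_human_flipped.pdb")

    seqs = sd.make_toy_sequences(4, 160, 0.8, seed=42)
    seqalign.write_fasta(seqs, OUT / "toy_family.fasta")
    print(f"wrote toy_family.fasta: {len(seqs)} sequences of length 160, "
          "per-site divergence 0.2 from a common ancestor")


if __name__ == "__main__":
    main()
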