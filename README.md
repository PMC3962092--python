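# wedgemap

Cross-species structural analysis of the lipopolysaccharide (LPS) receptor
complex TLR4/MD-2.

## The problem

Lipid IVA — a tetra-acylated precursor of the endotoxic lipid A — activates
the mouse TLR4/MD-2 receptor, weakly activates the horse receptor, and
*blocks* the human one. The same molecule, three different outcomes. The
structural explanation lives in a small triangular interface (the "wedge")
formed by TLR4 (chain a), the second TLR4 copy recruited upon activation
(counter-TLR4*, chain b) and MD-2 (chain c), where the two phosphate groups
of the ligand's diglucosamine backbone bind:

* **Pag** — the uppermost corner, exposed toward counter-TLR4*. A phosphate
  held here bridges the two receptor units and enables the dimerization
  that triggers signaling.
* **Pag-Pan** — the rightmost corner, a conserved phosphate grip common to
  agonist- and antagonist-bound structures.
* **Pan** — the leftmost corner at the MD-2 pocket lip, occupied by
  antagonists whose backbone sits rotated ~180° ("flipped").

Whether the Pag corner can hold a phosphate is decided by a handful of
species-differential charged side chains, and by whether each of them is
*free* or *neutralized* — locked in an intra-complex salt bridge. Mouse
uniquely offers two free chain-b cations (Lys367b, Arg434b) plus Lys341a;
in horse the equivalent chain-b lysine (Lys389b) is neutralized by Glu344a
and only chain-a cations remain; in human the corner holds anions instead
(Glu369b reinforced by Asp371b) and the would-be cation Lys388b is itself
neutralized.

`wedgemap` turns that narrative into a reproducible pipeline:

1. **seqalign** — FASTA input, affine-gap global alignment (BLOSUM62,
   gap open 10 / extend 0.5), integer percent-identity matrices,
   progressive MSA with a Clustal-style conservation line;
2. **structio** — PDB parsing/writing (gemmi), a/b/c chain-role
   assignment, ligand extraction with P1/P2 identification from
   distance-inferred connectivity, Kabsch superposition;
3. **mapping** — alignment↔structure residue maps, the piecewise
   cross-species TLR4 numbering translator (e = h = c = m+1 up to equine
   297; e = m+3 = h+1 = c+1 from 297 to 560), simplified template-based
   species models, differential-residue tables;
4. **interactions** — salt bridges (4.0 Å), neutralization status,
   phosphate charge environments (6.0 Å shell), van der Waals pose
   acceptance (0.7 × Bondi radii), pocket burial depth, a static
   rotatable-bond torsion estimate;
5. **wedge** — the triangular frame from anchor-residue centroids,
   nearest-corner phosphate assignment, normal/flipped orientation calls,
   backbone flips, and the 36-entry docking start-pose matrix;
6. **classify** — per-species agonist / partial-agonist / antagonist calls
   with a machine-readable rationale;
7. **synthetic_data** — deterministic desk-scale toys (sequence families,
   wedge complexes realizing each species' charge profile, 4- and 6-chain
   ligands) so the full pipeline runs and is tested without downloads.

## Worked example

```bash
python analysis/01_simulate_inputs.py
python analysis/04_wedge_interactions.py
python analysis/05_classify_species.py
```

prints (abridged):

```
 murine: P1 net +3 (chain-b free cations 2), P2 net +1; pose normal, accepted (0 bad contacts)
  human: P1 net +0 (chain-b free cations 0), P2 net -2; pose normal, accepted (0 bad contacts)
 equine: P1 net +2 (chain-b free cations 0), P2 net +1; pose normal, accepted (0 bad contacts)

 murine: agonist  [free cations near the Pag phosphate: b=2 a=1 c=0]
  human: antagonist  [free cations near the Pag phosphate: b=0 a=0 c=0]
 equine: partial_agonist  [free cations near the Pag phosphate: b=0 a=2 c=0]
 canine: antagonist (extrapolated)  [free cations near the Pag phosphate: b=0 a=0 c=0]

perturbations:
  murine without Lys367b -> partial_agonist (the bridging cluster loses its chain-b anchor)
  equine without Glu344a -> agonist (Lys389b is freed and completes the cluster)

start poses: 36 total, per column (1, 8, 9, 1, 8, 9)
```

Reading: the murine Pag phosphate sees net +3 free cationic attraction with
two contributions from counter-TLR4*, so the ligand can bridge the dimer —
an agonist call. The human corner is neutral-to-repulsive with free chain-b
anions repelling the second phosphate — antagonist. The equine corner
attracts only from the TLR4 side — partial agonist. Ablating single
residues moves the calls exactly the way the neutralization logic predicts.

A `wedgemap` command-line tool wraps the same steps
(`wedgemap align`, `translate`, `poses`, `simulate`, `panel`).

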