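# Methods

## Model

The package treats receptor-ligand species specificity as a geometry and
bookkeeping problem, not an energetics one. The central object is the
triangular "wedge" interface between TLR4 (chain a), counter-TLR4*
(chain b) and MD-2 (chain c), with three phosphate-binding corners (Pag,
Pag-Pan, Pan). The working assumptions are:

* the ligand's two phosphates carry formal charge −1 each; no partial
  charges are computed (each phosphate is treated as a monoanion);
* a charged side chain influences a phosphate only if one of its
  charged-group heavy atoms (NZ; NE/NH1/NH2; OD1/OD2; OE1/OE2) lies inside
  a distance shell around the phosphorus atom;
* a side chain engaged in any protein-protein salt bridge is *neutralized*
  and contributes neither attraction nor repulsion; ligand contacts never
  neutralize;
* activity is decided by counting free cations/anions around the phosphate
  occupying the Pag corner, not by scoring binding affinity.

Histidine is counted neutral by default (configurable) because the species
comparison rests entirely on Lys/Arg versus Asp/Glu.

## Activity rules

Let P\* be the phosphate nearest the Pag corner, and count free charged
residues with charged-group atoms inside the shell of P\*:

* **R1 (agonist)** — at least one free chain-b cation *and* at least three
  free cations in total. Rationale: bridging the dimer needs both a
  counter-TLR4* contact and a full cationic grip; the murine system is the
  only one offering three free cations (Lys341a + Lys367b + Arg434b) with
  two on chain b. The total-count requirement (default 3, configurable) is
  what makes the rule engine respond monotonically to single-residue
  changes: removing murine Lys367b leaves a free chain-b arginine but an
  incomplete cluster (demotion to partial agonist), while deleting the
  equine Glu344a frees Lys389b and completes the equine cluster
  (promotion to agonist). A pure "any free chain-b cation" rule cannot
  reproduce both behaviors at once.
* **R2 (partial agonist)** — some free cationic attraction near P\*
  remains, on any chain, but the bridging cluster is incomplete; the
  phosphate is held from the TLR4 side (the equine configuration:
  Arg385a and Lys366a free, Lys389b neutralized).
* **R3 (antagonist)** — no free cation near P\* (net score ≤ 0) and at
  least one free chain-b anion inside the shell of the *other* phosphate
  (the human configuration: Lys388b neutralized, Asp371b and Glu439b
  repelling P2). Dimerization is not enabled.
* **R4** — indeterminate.

A glutamate at the MD-2 lip (chain-c position 122) is recorded as evidence
for the upward phosphate shift but never gates the verdict, and the
protrusion of the amide-bound fatty acid FA1 toward the Pag hemisphere is
a boolean evidence field only — both are supporting observations in the
underlying mechanism, not load-bearing criteria.

## Geometry parameters

| parameter | default | unit | why |
|---|---|---|---|
| salt-bridge cutoff | 4.0 | Å | community-standard N-O distance for a charged contact |
| H-bond cutoff | 3.5 | Å | distinguishes the Ser386b-type polar contact from salt bridges |
| phosphate shell | 6.0 | Å | large enough to capture second-shell attraction, small enough to keep the three corners disjoint |
| vdW radii | Bondi set | Å | standard |
| clash overlap factor | 0.7 | — | a pair closer than 70 % of summed radii is a bad contact; tolerance 0 contacts |
| torsion weight | 0.2983 | energy/bond | the classic static per-torsion penalty; reported, never used in classification |

None of these values is printed in the source analysis, which describes
contacts qualitatively; they are stated here so every detector is exactly
reproducible, and all live in `InteractionConfig`.

## Cross-species numbering

The two printed offset segments (e = h = c = m+1 up to equine 297;
e = m+3 = h+1 = c+1 from 297 to 560) are non-injective if applied naively
at the boundary: equine 295 and 297 would both map to murine 294. The
translator therefore treats the equine positions consumed by each species'
inter-segment deletion (297 for human/canine; 297-298 for murine) as
*unaligned* and raises a dedicated signal there, rather than guessing.
This makes the mapping monotone and exactly self-inverse everywhere it is
defined, which is the property the round-trip checks verify. Beyond equine
560 no rule is printed and the translator instructs the caller to fall
back to alignment-based mapping.

## Alignment stage

Pairwise global alignment is Biopython's `PairwiseAligner` under BLOSUM62
with gap open 10 and extension 0.5 (a Clustal W-like parameterization; the
original analysis names the program but no parameters). A gap of length L
costs open + (L−1)·extend; determinism comes from taking the aligner's
first optimal alignment in its fixed enumeration order. Percent identity
is 100 × identical columns / gapless columns, rounded half-up — the
denominator choice closest to the published integer table, which is why
cross-checks against that table carry a ±2-point tolerance. The
progressive MSA builds a UPGMA guide tree on (100 − identity) distances
and merges profiles leaf-to-root with sum-of-pairs affine DP. Conservation
lines use Clustal's published strong and weak residue groups (stored as
data); the differential-residue table deliberately counts only *strong*
groups as "similar", because weak groups admit charge reversals
(Lys/Glu), which is precisely what the analysis must flag as
nonconserved.

## Species models

Template-based species models keep the template backbone (N, CA, C, O, CB)
untouched; identical residues keep template side chains, substitutions get
a simplified ideal side chain grown along the CA→CB vector and relieved of
steric overlap by a coarse chi1/chi2 grid search (30° steps, clash count
as the objective). This replaces rotamer-library repacking: the analysis
only needs charged-group positions to ~1-2 Å, not rotamer-exact packing.
Backbone insertions/deletions are not modeled (gap columns are left
unmodeled and logged).

## Burial depth

The MD-2 pocket axis runs from the mouth centroid (configured lip
residues, default positions 58 and 122 on chain c) to the centroid of the
deepest 10 pocket-lining residues (chain-c residues within 6 Å of any
ligand atom, ranked by distance from the mouth). Burial depth is the
projection of the diglucosamine centroid on this axis; comparisons between
complexes first superpose the MD-2 chains on shared CA atoms, which makes
the delta independent of the incoming frame and antisymmetric under
argument exchange.

## What the synthetic toys are — and are not

`make_toy_complex` realizes each species column of the differential-residue
tables as literal geometry: three short pseudo-chains arranged as the
wedge triangle (corner span ~13 Å, pocket depth 11 Å), each
mechanistically named residue placed as a four-atom backbone plus one
charged-group pseudo-atom at a curated site, salt-bridge partners within
~2.8-2.9 Å, the ligand in the normal pose with P1 ~4 Å from the Pag
anchors. The toy ligand has exact-bond-length connectivity (so the
distance-based bond inference recovers the generator's bond list
atom-for-atom) but schematic conformation: acyl chains descend into the
pocket and level off, rather than coiling realistically. The 180° flip
about the pocket axis reproduces the antagonist corner pattern
(P1 → Pag-Pan, P2 → Pan) by construction of the toy geometry.

Passing tests on these toys therefore demonstrate that the *detectors and
rules* are correct and stable (they survive rigid motions, 0.2 Å
coordinate noise, and residue ablations with the predicted monotone
response). They do not demonstrate anything about real side-chain
conformations, pocket plasticity, water, or binding free energies — the
real-structure checks exist separately and require the published records.

Determinism: a fixed `ToySpec` seed gives bit-identical coordinates,
sequences and ligands; σ = 0 toys are identical across seeds.

## Known limitations

* No energetics anywhere: counts of formal charges stand in for
  electrostatics, and pose acceptance is purely steric.
* The canine branch is an extrapolation (theoretical MD-2 record, no
  published residue column); its calls are labeled `extrapolated`.
* The numbering rule covers equine 1-560 only; the C-terminal half of the
  ectodomain must be mapped through the MSA.
* The published identity table's exact denominator convention is unknown;
  integer identities are only guaranteed to ±2 points of it.
* Two source-table inconsistencies are resolved by documented defaults:
  equine MD-2 position 58 is Arg (consistent with the attraction argument),
  and equine Arg385 is placed on chain a.
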