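"""Sequence handling, pairwise global alignment and progressive MSA.

Covers the sequence stage of the pipeline: read species-labeled TLR4 / MD-2
protein sequences from FASTA, align them globally under an affine-gap
substitution-matrix score (BLOSUM62, gap open 10, gap extend 0.5 by default,
a Clustal W-like parameterization), derive an integer percent-identity matrix
and a progressive multiple alignment with a Clustal-style conservation line
(``*`` identity, ``:`` strong group, ``.`` weak group).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

SPECIES_CODES = {"h": "human", "m": "murine", "e": "equine", "c": "canine"}

#: Clustal's published residue groups, stored as data.
STRONG_GROUPS = [
    "STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW",
]
WEAK_GROUPS = [
    "CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SNDEQK", "NDEQHK",
    "NEQHRK", "FVLIM", "HFY",
]

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


class SeqAlignError(ValueError):
    """Raised for malformed sequence input or invalid alignment requests."""


@dataclass(frozen=True)
class Sequence:
    """A species-labeled protein sequence.

    ``id`` is a short tag such as ``hTLR4`` or ``mMD2``; ``species`` and
    ``protein`` are parsed from it when the naming convention matches.
    """

    id: str
    residues: str
    species: str | None = None
    protein: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise SeqAlignError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise SeqAlignError(
                f"sequence {self.id!r} contains non amino-acid symbol(s): "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped rows of equal length plus the affine-gap score."""

    ids: tuple[str, str]
    rows: tuple[str, str]
    score: float
    matrix: str = DEFAULT_MATRIX
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND

    def __post_init__(self) -> None:
        a, b = self.rows
        if len(a) != len(b):
            raise SeqAlignError("alignment rows differ in length")
        if any(x == "-" and y == "-" for x, y in zip(a, b)):
            raise SeqAlignError("alignment contains a gap/gap column")


@dataclass
class MSA:
    """A multiple alignment: equal-length gapped rows keyed by sequence id."""

    ids: list[str]
    rows: list[str]
    conservation: str = ""
    protein: str | None = None
    species: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise SeqAlignError("MSA rows differ in length")
        if not self.conservation and self.rows:
            self.conservation = conservation_line(self.rows)
        if self.rows and len(self.conservation) != len(self.rows[0]):
            raise SeqAlignError("conservation line length mismatch")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace("-", "")


def _parse_header(header: str) -> tuple[str, str | None, str | None]:
    """Parse ``hTLR4`` / ``mMD2`` / ``mMD-2`` style ids; fall back to raw."""
    token = header.split()[0]
    species = SPECIES_CODES.get(token[:1])
    rest = token[1:].upper().replace("-", "")
    protein = rest if rest in {"TLR4", "MD2"} else None
    if species is not None and protein is not None:
        return token, species, protein
    return token, None, None


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a FASTA file into :class:`Sequence` records.

    Headers following the ``<species letter><protein>`` convention (e.g.
    ``>hMD2``) are parsed into species/protein tags; other headers are kept
    verbatim as ids. Duplicate ids and empty files are errors.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SeqAlignError(f"{path}: no FASTA records found")
    seqs: list[Sequence] = []
    seen: set[str] = set()
    for rec in records:
        seq_id, species, protein = _parse_header(rec.description or rec.id)
        if seq_id in seen:
            raise SeqAlignError(f"{path}: duplicate sequence id {seq_id!r}")
        seen.add(seq_id)
        seqs.append(
            Sequence(
                id=seq_id,
                residues=str(rec.seq).upper(),
                species=species,
                protein=protein,
            )
        )
    return seqs


def write_fasta(seqs: Iterable[Sequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def _aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.substitution_matrix = substitution_matrices.load(matrix)
    aln.open_gap_score = -float(gap_open)
    aln.extend_gap_score = -float(gap_extend)
    aln.mode = "global"
    return aln


def global_align(
    a: Sequence,
    b: Sequence,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal global alignment of two sequences under affine-gap scoring.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``. The first
    optimal alignment in the aligner's deterministic enumeration order is
    returned, which fixes tie-breaking.
    """
    mat = substitution_matrices.load(matrix)
    for seq in (a, b):
        bad = set(seq.residues) - set(str(x) for x in mat.alphabet)
        if bad:
            raise SeqAlignError(
                f"sequence {seq.id!r} has symbol(s) unknown to {matrix}: {sorted(bad)}"
            )
    aligner = _aligner(matrix, gap_open, gap_extend)
    result = aligner.align(a.residues, b.residues)
    best = result[0]
    row_a, row_b = str(best[0]), str(best[1])
    return PairwiseAlignment(
        ids=(a.id, b.id),
        rows=(row_a, row_b),
        score=float(best.score),
        matrix=matrix,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


def percent_identity(aln: PairwiseAlignment | tuple[str, str]) -> int:
    """100 x identical columns / gapless columns, rounded half-up."""
    rows = aln.rows if isinstance(aln, PairwiseAlignment) else aln
    a, b = rows
    gapless = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
    if gapless == 0:
        raise SeqAlignError("alignment has no gapless columns")
    same = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return int(math.floor(100.0 * same / gapless + 0.5))


def conservation_line(rows: TypingSequence[str]) -> str:
    """Clustal-style conservation annotation for a set of aligned rows."""
    out = []
    for col in zip(*rows):
        symbols = set(col)
        if "-" in symbols:
            out.append(" ")
        elif len(symbols) == 1:
            out.append("*")
        elif any(symbols <= set(g) for g in STRONG_GROUPS):
            out.append(":")
        elif any(symbols <= set(g) for g in WEAK_GROUPS):
            out.append(".")
        else:
            out.append(" ")
    return "".join(out)


def identity_matrix(
    seqs: TypingSequence[Sequence],
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> "IdentityMatrix":
    """All pairwise percent identities from global alignments."""
    if len(seqs) < 2:
        raise SeqAlignError("identity matrix needs at least 2 sequences")
    entries: dict[tuple[str, str], int] = {}
    for s in seqs:
        entries[(s.id, s.id)] = 100
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            pid = percent_identity(
                global_align(seqs[i], seqs[j], matrix, gap_open, gap_extend)
            )
            entries[(seqs[i].id, seqs[j].id)] = pid
            entries[(seqs[j].id, seqs[i].id)] = pid
    return IdentityMatrix(ids=[s.id for s in seqs], entries=entries)


@dataclass
class IdentityMatrix:
    """Symmetric integer percent-identity matrix with a 100 diagonal."""

    ids: list[str]
    entries: dict[tuple[str, str], int]

    def __getitem__(self, pair: tuple[str, str]) -> int:
        return self.entries[pair]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for a in self.ids:
                fh.write(a)
                for b in self.ids:
                    fh.write(f"\t{self.entries[(a, b)]}")
                fh.write("\n")


# ---------------------------------------------------------------------------
# Progressive MSA: UPGMA guide tree over identity distances, then leaf-to-root
# profile-profile merging with sum-of-pairs scoring.
# ---------------------------------------------------------------------------

_ALPHA_IDX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _profile(rows: list[str]) -> np.ndarray:
    """Column frequency profile over the 20 residues (gaps excluded)."""
    ncol = len(rows[0])
    prof = np.zeros((ncol, len(AMINO_ACIDS)))
    for row in rows:
        for i, ch in enumerate(row):
            if ch != "-":
                prof[i, _ALPHA_IDX[ch]] += 1
    totals = prof.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return prof / totals


def _profile_align(
    rows_a: list[str],
    rows_b: list[str],
    score_mat: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment (Gotoh affine DP, sum-of-pairs)."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    n, m = pa.shape[0], pb.shape[0]
    # sum-of-pairs expected substitution score between columns
    col_scores = pa @ score_mat @ pb.T

    neg = -np.inf
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = col_scores[i - 1, j - 1]
            opts = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(opts))
            M[i, j] = opts[k] + s
            ptr_m[i, j] = k
            ox = (M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            kx = int(np.argmax(ox))
            X[i, j] = ox[kx]
            ptr_x[i, j] = kx
            oy = (M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
            ky = int(np.argmax(oy))
            Y[i, j] = oy[ky]
            ptr_y[i, j] = ky

    # traceback from the best terminal state (preference M > X > Y)
    i, j = n, m
    state = int(np.argmax((M[n, m], X[n, m], Y[n, m])))
    path: list[int] = []
    while i > 0 or j > 0:
        path.append(state)
        if state == 0:
            state = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            state = 0 if ptr_x[i, j] == 0 else 1
            i -= 1
        else:
            state = 0 if ptr_y[i, j] == 0 else 2
            j -= 1
    path.reverse()

    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for st in path:
        if st in (0, 1):
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
        if st in (0, 2):
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += "-"
    return out_a, out_b


def progressive_msa(
    seqs: TypingSequence[Sequence],
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> MSA:
    """Progressive multiple alignment.

    Guide tree: UPGMA over (100 - percent identity) pairwise distances.
    Profiles are merged leaf-to-root by affine-gap sum-of-pairs DP.
    Mixing TLR4 and MD-2 sequences is an error.
    """
    if len(seqs) < 2:
        raise SeqAlignError("MSA needs at least 2 sequences")
    proteins = {s.protein for s in seqs if s.protein is not None}
    if len(proteins) > 1:
        raise SeqAlignError(
            f"refusing to align mixed proteins in one MSA: {sorted(proteins)}"
        )
    if len(seqs) == 2:
        pw = global_align(seqs[0], seqs[1], matrix, gap_open, gap_extend)
        return MSA(
            ids=[s.id for s in seqs],
            rows=list(pw.rows),
            protein=next(iter(proteins), None),
            species={s.id: s.species for s in seqs},
        )

    mat = substitution_matrices.load(matrix)
    alpha = [str(x) for x in mat.alphabet]
    idx = [alpha.index(aa) for aa in AMINO_ACIDS]
    score_mat = np.asarray(mat)[np.ix_(idx, idx)]

    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(
                global_align(seqs[i], seqs[j], matrix, gap_open, gap_extend)
            )
            dist[i, j] = dist[j, i] = 100 - pid
    tree = linkage(squareform(dist, checks=False), method="average")

    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([seqs[i].id], [seqs[i].residues]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(tree):
        ids_a, rows_a = clusters.pop(int(a))
        ids_b, rows_b = clusters.pop(int(b))
        new_a, new_b = _profile_align(rows_a, rows_b, score_mat, gap_open, gap_extend)
        clusters[n + step] = (ids_a + ids_b, new_a + new_b)

    ids, rows = clusters.popitem()[1]
    order = {s.id: k for k, s in enumerate(seqs)}
    paired = sorted(zip(ids, rows), key=lambda t: order[t[0]])
    ids = [p[0] for p in paired]
    rows = [p[1] for p in paired]
    return MSA(
        ids=ids,
        rows=rows,
        protein=next(iter(proteins), None),
        species={s.id: s.species for s in seqs},
    )


def write_msa(msa: MSA, path: str | Path, fmt: str = "clustal", width: int = 60) -> None:
    """Write an MSA in CLUSTAL or (gapped) FASTA dialect."""
    with open(path, "w") as fh:
        if fmt == "fasta":
            for sid, row in zip(msa.ids, msa.rows):
                fh.write(f">{sid}\n")
                for i in range(0, len(row), width):
                    fh.write(row[i : i + width] + "\n")
            return
        if fmt != "clustal":
            raise SeqAlignError(f"unknown MSA format {fmt!r}")
        fh.write("CLUSTAL format alignment (wedgemap)\n\n")
        name_w = max(len(s) for s in msa.ids) + 2
        for start in range(0, msa.length, width):
            for sid, row in zip(msa.ids, msa.rows):
                fh.write(sid.ljust(name_w) + row[start : start + width] + "\n")
            fh.write(" " * name_w + msa.conservation[start : start + width] + "\n\n")
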