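"""Alignment-to-structure mapping, cross-species numbering, species models.

Residue numbering differs slightly between the four TLR4 orthologs because
of non-identical deletions; the published piecewise rule (relative to the
gap-free equine numbering) is:

* up to equine position 297:  e = h = c = m + 1
* equine 297 to 560:          e = m + 3 = h + 1 = c + 1

The rule is realized here as exact piecewise offsets with the positions
consumed by the inter-segment gap treated as unaligned, which makes the
translator monotone and exactly self-inverse everywhere it is defined.
Beyond position 560 no printed rule exists and the translator signals that
alignment-based mapping must be used instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from wedgemap import seqalign
from wedgemap.seqalign import MSA, Sequence
from wedgemap.structio import (
    Atom,
    Residue,
    StructureModel,
    StructureError,
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

CATIONIC_1 = set("KR")
ANIONIC_1 = set("DE")


class MappingError(ValueError):
    pass


class UnalignedPosition(MappingError):
    """The position has no equivalent in the target numbering (it falls in
    an inter-segment gap); use alignment-based mapping instead."""


class NumberingRangeError(MappingError):
    """The position lies beyond the printed rule; use alignment-based
    mapping instead."""


# ---------------------------------------------------------------------------
# Cross-species numbering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NumberingRule:
    """Piecewise offsets of each species' TLR4 numbering relative to equine.

    ``segments`` holds (equine_lo, equine_hi, {species: offset}) with
    ``species_position = equine_position + offset``; segments must be sorted
    and non-overlapping.
    """

    segments: tuple[tuple[int, int, dict[str, int]], ...]

    def __post_init__(self) -> None:
        prev_hi = 0
        for lo, hi, _ in self.segments:
            if lo <= prev_hi or hi < lo:
                raise MappingError("segments must be sorted and non-overlapping")
            prev_hi = hi

    @property
    def valid_range(self) -> int:
        return self.segments[-1][1]

    @property
    def species(self) -> set[str]:
        out: set[str] = {"equine"}
        for _, _, off in self.segments:
            out |= set(off)
        return out

    # -- helpers -----------------------------------------------------------
    def _gap_before(self, seg_index: int, species: str) -> int:
        """Residues of ``species`` deleted at the start of segment seg_index."""
        if seg_index == 0:
            return 0
        prev_off = self.segments[seg_index - 1][2].get(species, 0)
        this_off = self.segments[seg_index][2].get(species, 0)
        return prev_off - this_off

    def from_equine(self, species: str, e: int) -> int:
        if not 1 <= e <= self.valid_range:
            raise NumberingRangeError(
                f"equine position {e} is outside the printed rule "
                f"(1..{self.valid_range}); use alignment-based mapping"
            )
        if species == "equine":
            return e
        for k, (lo, hi, off) in enumerate(self.segments):
            if lo <= e <= hi:
                if k > 0 and e < lo + self._gap_before(k, species):
                    raise UnalignedPosition(
                        f"equine position {e} falls in the {species} "
                        "inter-segment gap; use alignment-based mapping"
                    )
                return e + off.get(species, 0)
        raise NumberingRangeError(f"equine position {e} not covered")

    def to_equine(self, species: str, pos: int) -> int:
        if species == "equine":
            if not 1 <= pos <= self.valid_range:
                raise NumberingRangeError(
                    f"equine position {pos} is outside 1..{self.valid_range}; "
                    "use alignment-based mapping"
                )
            return pos
        for k, (lo, hi, off) in enumerate(self.segments):
            o = off.get(species, 0)
            e = pos - o
            if lo <= e <= hi and (k == 0 or e >= lo + self._gap_before(k, species)):
                return e
        raise NumberingRangeError(
            f"{species} position {pos} is outside the printed rule; "
            "use alignment-based mapping"
        )


def default_numbering_rule() -> NumberingRule:
    """The published two-segment TLR4 rule (equine positions 1..560)."""
    return NumberingRule(
        segments=(
            (1, 296, {"human": 0, "canine": 0, "murine": -1}),
            (297, 560, {"human": -1, "canine": -1, "murine": -3}),
        )
    )


def translate_numbering(
    rule: NumberingRule, from_species: str, to_species: str, position: int
) -> int:
    """Translate a TLR4 residue number between species numbering schemes."""
    for sp in (from_species, to_species):
        if sp not in rule.species:
            raise MappingError(f"unknown species {sp!r}")
    e = rule.to_equine(from_species, int(position))
    return rule.from_equine(to_species, e)


# ---------------------------------------------------------------------------
# Alignment <-> structure mapping
# ---------------------------------------------------------------------------

@dataclass
class ResidueMap:
    """Pairs (sequence position, structure residue number, MSA column)."""

    species: str
    chain_id: str
    pairs: list[tuple[int, int, int]] = field(default_factory=list)
    mismatches: list[tuple[int, str, str]] = field(default_factory=list)
    coverage: float = 0.0

    def column_for_position(self, pos: int) -> int | None:
        for p, _, col in self.pairs:
            if p == pos:
                return col
        return None

    def residue_for_position(self, pos: int) -> int | None:
        for p, num, _ in self.pairs:
            if p == pos:
                return num
        return None


def _chain_sequence(residues: list[Residue]) -> tuple[str, list[int]]:
    letters, numbers = [], []
    for r in residues:
        if r.het:
            continue
        one = THREE_TO_ONE.get(r.name)
        if one is not None:
            letters.append(one)
            numbers.append(r.number)
    return "".join(letters), numbers


def map_alignment_to_structure(
    msa: MSA,
    m: StructureModel,
    chain_role: str,
    species: str,
    min_identity: float = 0.95,
) -> ResidueMap:
    """Pair MSA columns of one species row with the residues of a chain.

    The degapped row is globally aligned to the chain sequence; matched
    positions become (sequence position, residue number, column) triples.
    Identity below ``min_identity`` over the mapped region raises, which
    usually means the wrong chain or species was requested.
    """
    row_id = None
    for sid in msa.ids:
        if msa.species.get(sid) == species or sid == species:
            row_id = sid
            break
    if row_id is None:
        raise MappingError(f"species {species!r} not present in MSA")
    row = msa.row(row_id)
    seq = row.replace("-", "")
    cid = m.roles.get(chain_role, chain_role)
    residues = m.chains.get(cid)
    if residues is None:
        raise MappingError(f"chain/role {chain_role!r} absent from model")
    chain_seq, chain_nums = _chain_sequence(residues)
    if not chain_seq:
        raise MappingError(f"chain {cid!r} has no standard residues")

    pw = seqalign.global_align(
        Sequence(id="msa_row", residues=seq),
        Sequence(id="chain", residues=chain_seq),
    )
    # column index of each non-gap position in the species row
    col_of_pos = [i for i, ch in enumerate(row) if ch != "-"]

    pairs: list[tuple[int, int, int]] = []
    mismatches: list[tuple[int, str, str]] = []
    ip = ic = 0
    for x, y in zip(*pw.rows):
        if x != "-" and y != "-":
            pos = ip + 1
            pairs.append((pos, chain_nums[ic], col_of_pos[ip]))
            if x != y:
                mismatches.append((pos, x, y))
        if x != "-":
            ip += 1
        if y != "-":
            ic += 1
    if not pairs:
        raise MappingError("no residues could be mapped")
    identity = 1.0 - len(mismatches) / len(pairs)
    if identity < min_identity:
        raise MappingError(
            f"mapped identity {identity:.2f} below {min_identity:.2f}; "
            f"wrong chain or species? ({len(mismatches)} mismatches)"
        )
    return ResidueMap(
        species=species,
        chain_id=cid,
        pairs=pairs,
        mismatches=mismatches,
        coverage=len(pairs) / len(seq),
    )


# ---------------------------------------------------------------------------
# Differential residue tables
# ---------------------------------------------------------------------------

@dataclass
class DifferentialTable:
    """Per-position species residues with conservation and charge classes."""

    positions: list[int]
    species_order: list[str]
    rows: list[dict]  # position, residues per species, classes

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.rows, indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\t" + "\t".join(self.species_order)
                     + "\tconservation\tcharges\n")
            for row in self.rows:
                residues = "\t".join(row["residues"][s] for s in self.species_order)
                charges = ",".join(row["charges"][s] for s in self.species_order)
                fh.write(f"{row['position']}\t{residues}\t{row['class']}\t{charges}\n")


def _charge_of(letter: str) -> str:
    if letter in CATIONIC_1:
        return "+"
    if letter in ANIONIC_1:
        return "-"
    return "0"


def differential_residues(
    msa: MSA,
    positions: Iterable[int],
    charge_annotate: bool = True,
    ref_id: str | None = None,
) -> DifferentialTable:
    """Report the residue of every species at the given reference positions.

    ``positions`` are residue numbers of the reference row (default: the
    first MSA row); each is located as the Nth non-gap column of that row.
    Conservation class: identical / similar (a Clustal strong or weak group)
    / nonconserved.
    """
    ref_id = ref_id or msa.ids[0]
    ref_row = msa.row(ref_id)
    col_of_pos = [i for i, ch in enumerate(ref_row) if ch != "-"]
    rows = []
    for pos in positions:
        if not 1 <= pos <= len(col_of_pos):
            raise MappingError(
                f"position {pos} outside reference row 1..{len(col_of_pos)}"
            )
        col = col_of_pos[pos - 1]
        residues = {sid: msa.rows[k][col] for k, sid in enumerate(msa.ids)}
        letters = set(residues.values())
        if "-" in letters:
            cls = "nonconserved"
        elif len(letters) == 1:
            cls = "identical"
        elif any(letters <= set(g) for g in seqalign.STRONG_GROUPS):
            # weak groups are deliberately not "similar" here: they admit
            # charge reversals (e.g. Lys/Glu), which is exactly what the
            # differential analysis must flag
            cls = "similar"
        else:
            cls = "nonconserved"
        row = {
            "position": pos,
            "column": col,
            "residues": residues,
            "class": cls,
        }
        if charge_annotate:
            row["charges"] = {sid: _charge_of(ch) for sid, ch in residues.items()}
        rows.append(row)
    return DifferentialTable(
        positions=list(positions), species_order=list(msa.ids), rows=rows
    )


# ---------------------------------------------------------------------------
# Simplified species homology models
# ---------------------------------------------------------------------------

#: Simplified ideal side-chain topologies: linear heavy atoms beyond CB, with
#: an optional terminal fork. Geometry is coarse (1.3 Å steps with zig-zag);
#: the analysis only needs charged-group positions to ~1-2 Å.
SIDECHAIN_TEMPLATES: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "ALA": ((), ()),
    "SER": (("OG",), ()),
    "CYS": (("SG",), ()),
    "THR": (("OG1",), ("CG2",)),
    "VAL": ((), ("CG1", "CG2")),
    "LEU": (("CG",), ("CD1", "CD2")),
    "ILE": (("CG1", "CD1"), ("CG2",)),
    "MET": (("CG", "SD", "CE"), ()),
    "PRO": (("CG", "CD"), ()),
    "PHE": (("CG", "CD1", "CE1", "CZ"), ("CD2", "CE2")),
    "TYR": (("CG", "CD1", "CE1", "CZ", "OH"), ("CD2", "CE2")),
    "TRP": (("CG", "CD1", "NE1", "CE2", "CZ2", "CH2"), ("CD2",)),
    "ASN": (("CG",), ("OD1", "ND2")),
    "GLN": (("CG", "CD"), ("OE1", "NE2")),
    "ASP": (("CG",), ("OD1", "OD2")),
    "GLU": (("CG", "CD"), ("OE1", "OE2")),
    "LYS": (("CG", "CD", "CE", "NZ"), ()),
    "ARG": (("CG", "CD", "NE", "CZ"), ("NH1", "NH2")),
    "HIS": (("CG", "ND1", "CE1"), ("CD2", "NE2")),
    "GLY": ((), ()),
}

_VDW = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch
    return "C"


def _build_sidechain(
    n: np.ndarray, ca: np.ndarray, cb: np.ndarray, restype: str,
    chi1: float = 0.0, chi2: float = 0.0,
) -> list[Atom]:
    """Place a simplified ideal side chain along CA->CB, then apply chi
    rotations about CA-CB (chi1) and CB-CG (chi2)."""
    linear, fork = SIDECHAIN_TEMPLATES.get(restype, ((), ()))
    u = cb - ca
    u = u / np.linalg.norm(u)
    ref = n - ca
    w = ref - np.dot(ref, u) * u
    nw = np.linalg.norm(w)
    w = w / nw if nw > 1e-6 else np.array([0.0, 0.0, 1.0])

    atoms: list[Atom] = []
    positions: list[np.ndarray] = []
    pos = cb
    for k, name in enumerate(linear):
        pos = pos + 1.3 * u + (0.5 if k % 2 == 0 else -0.5) * w
        positions.append(pos.copy())
        atoms.append(Atom(name, _element_of(name), pos.copy()))
    tip = positions[-1] if positions else cb
    side = np.cross(u, w)
    for k, name in enumerate(fork):
        d = (side if k == 0 else -side)
        p = tip + 1.1 * u + 1.1 * d
        atoms.append(Atom(name, _element_of(name), p))

    def rotate(atoms_sub: list[Atom], origin: np.ndarray, axis: np.ndarray,
               angle: float) -> None:
        if abs(angle) < 1e-9:
            return
        axis = axis / np.linalg.norm(axis)
        c, s = np.cos(angle), np.sin(angle)
        K = np.array([
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ])
        R = np.eye(3) + s * K + (1 - c) * (K @ K)
        for a in atoms_sub:
            a.coords = origin + R @ (a.coords - origin)

    rotate(atoms, ca, cb - ca, chi1)
    if atoms:
        cg = atoms[0].coords
        rotate(atoms[1:], cb, cg - cb, chi2)
    return atoms


def build_species_model(
    template: StructureModel,
    target_seq: Sequence,
    rmap: ResidueMap,
    clash_factor: float = 0.7,
    grid_step_deg: float = 30.0,
) -> StructureModel:
    """Thread a target sequence onto a template chain.

    The template backbone (N, CA, C, O, CB) is always kept; identical
    residues keep their template side chains, substituted residues get a
    simplified ideal side chain placed along the template CA->CB vector and
    relieved of steric overlap by a coarse chi1/chi2 grid search.
    """
    if rmap.coverage < 0.9:
        raise MappingError(
            f"residue map coverage {rmap.coverage:.2f} below 0.9; refusing to model"
        )
    out = template.transformed(np.eye(3), np.zeros(3))
    out.provenance = f"model:{target_seq.id}-on-{template.provenance}"
    chain = out.chains[rmap.chain_id]
    by_number = {r.number: r for r in chain if not r.het}

    # environment atoms for the clash search
    env_coords = [a.coords for r in chain for a in r.atoms]
    env = np.vstack(env_coords)
    env_names = [a.name for r in chain for a in r.atoms]
    env_res = [id(r) for r in chain for _ in r.atoms]

    log: list[str] = []
    for pos, resnum, _col in rmap.pairs:
        target_letter = target_seq.residues[pos - 1] if pos <= len(target_seq.residues) else None
        res = by_number.get(resnum)
        if res is None or target_letter is None:
            continue
        current = THREE_TO_ONE.get(res.name)
        if current == target_letter:
            continue
        new_name = ONE_TO_THREE.get(target_letter)
        if new_name is None:
            continue
        n_at, ca_at, cb_at = res.atom("N"), res.atom("CA"), res.atom("CB")
        backbone = [a for a in res.atoms if a.name in ("N", "CA", "C", "O", "CB")]
        if ca_at is None or n_at is None:
            log.append(f"{res.label}: missing backbone, left unmodeled")
            continue
        if cb_at is None:
            # rebuild an approximate CB from backbone geometry
            c_at = res.atom("C")
            if c_at is None:
                log.append(f"{res.label}: no C atom, left unmodeled")
                continue
            bisector = 2 * ca_at.coords - n_at.coords - c_at.coords
            nb = np.linalg.norm(bisector)
            bisector = bisector / nb if nb > 1e-6 else np.array([0, 0, 1.0])
            cb_at = Atom("CB", "C", ca_at.coords + 1.53 * bisector)
            backbone = backbone + [cb_at]
            log.append(f"{res.label}: CB rebuilt from backbone geometry")
        if new_name in ("GLY",):
            res.name = new_name
            res.atoms = [a for a in backbone if a.name != "CB"]
            continue

        own = {id(res)}
        mask = np.array([er not in own for er in env_res])
        other = env[mask]
        other_names = [nm for nm, keep in zip(env_names, mask) if keep]
        other_radii = np.array([_VDW.get(_element_of(nm), 1.7) for nm in other_names])

        best: tuple[int, float, float, list[Atom]] | None = None
        step = np.radians(grid_step_deg)
        n_steps = int(round(2 * np.pi / step))
        for i in range(n_steps):
            for j in range(n_steps):
                side = _build_sidechain(
                    n_at.coords, ca_at.coords, cb_at.coords, new_name,
                    chi1=i * step, chi2=j * step,
                )
                if not side:
                    break
                pts = np.vstack([a.coords for a in side])
                radii = np.array([_VDW.get(a.element, 1.7) for a in side])
                d = np.linalg.norm(pts[:, None, :] - other[None, :, :], axis=2)
                thresh = clash_factor * (radii[:, None] + other_radii[None, :])
                clashes = int((d < thresh).sum())
                key = (clashes, i * step, j * step)
                if best is None or key < (best[0], best[1], best[2]):
                    best = (clashes, i * step, j * step, side)
            if not SIDECHAIN_TEMPLATES.get(new_name, ((), ()))[0] and best:
                break
        res.name = new_name
        res.atoms = backbone + (best[3] if best else [])
        if best and best[0] > 0:
            log.append(f"{res.label}->{new_name}: {best[0]} residual overlap(s)")
    out.provenance += f" ({len(log)} notes)" if log else ""
    return out
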