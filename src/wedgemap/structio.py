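"""Minimal structure I/O and rigid geometry.

Parses and writes PDB files (via gemmi), assigns the a/b/c chain-role
convention of the agonist-bound TLR4 dimer crystal (a: TLR4, b: counter
TLR4*, c: MD-2, c*: counter MD-2), extracts diglucosamine-bisphosphate
ligand poses with P1/P2 phosphate identification from distance-inferred
connectivity, and performs least-squares rigid superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

CATIONIC = {"LYS", "ARG"}
CATIONIC_WITH_HIS = {"LYS", "ARG", "HIS"}
ANIONIC = {"ASP", "GLU"}

#: Side-chain atoms carrying the formal charge, per residue type.
CHARGED_GROUP_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Covalent bond-inference cutoffs (Å); CONECT records are not trusted.
BOND_CUTOFF = 1.9
BOND_CUTOFF_P = 2.0


class StructureError(ValueError):
    """Raised for unparseable or structurally inconsistent input."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: non-finite coordinates")
        if not self.element:
            raise StructureError(f"atom {self.name}: empty element")


@dataclass
class Residue:
    name: str
    number: int
    chain: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""
    het: bool = False

    @property
    def charge_class(self) -> str:
        if self.name in CATIONIC:
            return "cationic"
        if self.name in ANIONIC:
            return "anionic"
        return "neutral"

    def charge_sign(self, his_cationic: bool = False) -> int:
        cats = CATIONIC_WITH_HIS if his_cationic else CATIONIC
        if self.name in cats:
            return +1
        if self.name in ANIONIC:
            return -1
        return 0

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def charged_group_coords(self) -> np.ndarray:
        """Coordinates of the charged-group atoms (fallback: side chain,
        then all atoms) as an (n, 3) array."""
        names = CHARGED_GROUP_ATOMS.get(self.name, ())
        pts = [a.coords for a in self.atoms if a.name in names]
        if not pts:
            pts = [a.coords for a in self.atoms if a.name not in BACKBONE_ATOMS]
        if not pts:
            pts = [a.coords for a in self.atoms]
        return np.vstack(pts)

    @property
    def label(self) -> str:
        return f"{self.name.capitalize()}{self.number}{self.chain}"


@dataclass
class StructureModel:
    """Chains of residues plus the a/b/c role map."""

    chains: dict[str, list[Residue]] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)  # role -> chain id
    provenance: str = "model"

    def __post_init__(self) -> None:
        for role, cid in self.roles.items():
            if cid not in self.chains:
                raise StructureError(f"role {role!r} points to missing chain {cid!r}")
        for cid, residues in self.chains.items():
            keys = [(r.number, r.icode) for r in residues]
            if len(keys) != len(set(keys)):
                raise StructureError(f"chain {cid!r}: duplicate residue numbers")

    # -- accessors ---------------------------------------------------------
    def chain_for_role(self, role: str) -> list[Residue] | None:
        cid = self.roles.get(role)
        return self.chains.get(cid) if cid is not None else None

    def residue(self, chain_or_role: str, number: int) -> Residue | None:
        cid = self.roles.get(chain_or_role, chain_or_role)
        for r in self.chains.get(cid, []):
            if r.number == number:
                return r
        return None

    def role_of_chain(self, cid: str) -> str | None:
        for role, chain in self.roles.items():
            if chain == cid:
                return role
        return None

    def residues(self, het: bool | None = None) -> Iterator[Residue]:
        for residues in self.chains.values():
            for r in residues:
                if het is None or r.het == het:
                    yield r

    def atoms(self, het: bool | None = None) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues(het=het):
            for a in r.atoms:
                yield r, a

    def coords(self, het: bool | None = None) -> np.ndarray:
        pts = [a.coords for _, a in self.atoms(het=het)]
        return np.vstack(pts) if pts else np.empty((0, 3))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """A copy with every atom rigidly moved: x -> R x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        chains = {
            cid: [
                Residue(
                    r.name, r.number, r.chain,
                    [Atom(a.name, a.element, R @ a.coords + t) for a in r.atoms],
                    r.icode, r.het,
                )
                for r in residues
            ]
            for cid, residues in self.chains.items()
        }
        return StructureModel(chains=chains, roles=dict(self.roles),
                              provenance=self.provenance)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> StructureModel:
    """Parse ATOM/HETATM records; altlocs resolved to highest occupancy."""
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"{path}: cannot parse PDB ({exc})") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models in file")
    st.remove_empty_chains()
    model = st[0]
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            # keep one atom per name: highest occupancy wins
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name or "X",
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                )
                for a in best.values()
            ]
            residues.append(
                Residue(
                    name=res.name,
                    number=res.seqid.num,
                    chain=chain.name,
                    atoms=atoms,
                    icode=(res.seqid.icode or "").strip(),
                    het=res.het_flag == "H",
                )
            )
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise StructureError(f"{path}: no atoms parsed")
    return StructureModel(chains=chains, provenance=path.stem)


def write_pdb(m: StructureModel, path: str | Path, remarks: Iterable[str] = ()) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for i, text in enumerate(remarks, start=1):
            fh.write(f"REMARK   3 {text}\n"[:80].rstrip() + "\n")
        serial = 1
        for cid in m.chains:
            for r in m.chains[cid]:
                rec = "HETATM" if r.het else "ATOM  "
                for a in r.atoms:
                    x, y, z = a.coords
                    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                    fh.write(
                        f"{rec}{serial:5d} {name:<4s}{'':1s}{r.name:>3s} "
                        f"{cid[:1]}{r.number:4d}{r.icode[:1] or '':1s}   "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                        f"          {a.element:>2s}\n"
                    )
                    serial += 1
            fh.write("TER\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Chain roles
# ---------------------------------------------------------------------------

def _protein_chains(m: StructureModel) -> dict[str, list[Residue]]:
    return {
        cid: [r for r in residues if not r.het]
        for cid, residues in m.chains.items()
        if any(not r.het for r in residues)
    }


def assign_chain_roles(
    m: StructureModel, config: dict[str, str] | str = "auto"
) -> StructureModel:
    """Assign roles a / b / c (and c* for dimers).

    ``config`` maps chain id -> role explicitly, or ``"auto"``: the longest
    chains become the TLR4 copies, ~160-residue chains the MD-2 copies, and
    each MD-2 is paired with the TLR4 it contacts most.
    """
    prot = _protein_chains(m)
    if len(prot) < 2:
        raise StructureError("role assignment needs at least 2 protein chains")
    if isinstance(config, dict):
        roles = {role: cid for cid, role in config.items()}
        missing = set(roles.values()) - set(m.chains)
        if missing:
            raise StructureError(f"role config names missing chain(s) {sorted(missing)}")
        return StructureModel(chains=m.chains, roles=roles, provenance=m.provenance)
    if config != "auto":
        raise StructureError(f"unknown role config {config!r}")

    sizes = {cid: len(res) for cid, res in prot.items()}
    ordered = sorted(sizes, key=lambda c: -sizes[c])
    big = [c for c in ordered if sizes[c] >= 400]
    small = [c for c in ordered if 100 <= sizes[c] < 400]
    if not big or not small:
        raise StructureError(
            f"auto role assignment is ambiguous; chain sizes: {sizes}"
        )
    if len(big) > 2 or len(small) > 2:
        raise StructureError(
            f"auto role assignment found too many candidates; sizes: {sizes}"
        )

    def contacts(c1: str, c2: str) -> int:
        a = np.vstack([at.coords for r in prot[c1] for at in r.atoms])
        b = np.vstack([at.coords for r in prot[c2] for at in r.atoms])
        tree = cKDTree(b)
        return int(sum(len(x) for x in tree.query_ball_point(a, 4.5)))

    roles = {"a": big[0]}
    if len(big) == 2:
        roles["b"] = big[1]
    # pair each MD-2 with the TLR4 it touches most; "c" is the one on chain a
    md2_for_a = max(small, key=lambda c: contacts(c, roles["a"]))
    roles["c"] = md2_for_a
    rest = [c for c in small if c != md2_for_a]
    if rest:
        roles["c*"] = rest[0]
    return StructureModel(chains=m.chains, roles=roles, provenance=m.provenance)


# ---------------------------------------------------------------------------
# Ligand extraction
# ---------------------------------------------------------------------------

@dataclass
class LigandPose:
    """A diglucosamine-bisphosphate ligand with identified phosphates.

    ``p1`` is the glycosidic phosphate on GlcN1 (axial), ``p2`` the
    ester-bound phosphate on GlcN2 (equatorial). Atom indices refer to
    ``atoms``. Each phosphate carries formal charge -1.
    """

    atoms: list[Atom]
    bonds: nx.Graph
    glcn1: tuple[int, ...]
    glcn2: tuple[int, ...]
    p1: tuple[int, ...]  # P atom first
    p2: tuple[int, ...]
    acyl_chains: list[tuple[str, int]]  # (label, carbon count)
    acyl_atoms: dict[str, tuple[int, ...]] = field(default_factory=dict)
    orientation: str = "indeterminate"
    formal_charges: dict[str, int] = field(default_factory=lambda: {"P1": -1, "P2": -1})

    def __post_init__(self) -> None:
        if len(self.acyl_chains) not in (4, 6):
            raise StructureError(
                f"ligand must carry 4 or 6 acyl chains, got {len(self.acyl_chains)}"
            )
        labels = [l for l, _ in self.acyl_chains]
        if len(labels) != len(set(labels)):
            raise StructureError("duplicate acyl chain labels")

    @property
    def coords(self) -> np.ndarray:
        return np.vstack([a.coords for a in self.atoms])

    def p_coord(self, which: str) -> np.ndarray:
        idx = self.p1[0] if which.upper() == "P1" else self.p2[0]
        return self.atoms[idx].coords

    def backbone_centroid(self) -> np.ndarray:
        """Centroid of the two glucosamine rings."""
        idx = list(self.glcn1) + list(self.glcn2)
        return np.mean([self.atoms[i].coords for i in idx], axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LigandPose":
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        atoms = [Atom(a.name, a.element, R @ a.coords + t) for a in self.atoms]
        return replace(self, atoms=atoms)


def infer_bonds(atoms: list[Atom]) -> nx.Graph:
    """Distance-based covalent bond inference over heavy atoms."""
    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    coords = np.vstack([a.coords for a in atoms])
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(BOND_CUTOFF_P):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        cutoff = (
            BOND_CUTOFF_P
            if "P" in (atoms[i].element, atoms[j].element)
            else BOND_CUTOFF
        )
        if d <= cutoff:
            g.add_edge(i, j, length=d)
    return g


def extract_ligand(
    m: StructureModel, het_names: Iterable[str]
) -> LigandPose:
    """Extract the ligand and identify P1/GlcN1 vs P2/GlcN2 from connectivity.

    The phosphorus bonded through an oxygen to an anomeric ring carbon (the
    carbon adjacent to the ring oxygen) is P1; the other is P2. Acyl chains
    are traced as maximal carbon paths from ester/amide attachment points.
    """
    wanted = set(het_names)
    atoms: list[Atom] = []
    for r in m.residues(het=True):
        if r.name in wanted:
            atoms.extend(r.atoms)
    if not atoms:
        raise StructureError(f"no HETATM residues named {sorted(wanted)}")
    # deterministic order regardless of record order in the file
    order = sorted(
        range(len(atoms)),
        key=lambda i: (atoms[i].element, atoms[i].name, *np.round(atoms[i].coords, 3)),
    )
    atoms = [atoms[i] for i in order]
    g = infer_bonds(atoms)

    p_idx = [i for i, a in enumerate(atoms) if a.element == "P"]
    if len(p_idx) != 2:
        raise StructureError(f"expected 2 phosphorus atoms, found {len(p_idx)}")

    # six-membered rings containing exactly one oxygen = the pyranose rings
    rings = [
        tuple(sorted(cyc))
        for cyc in nx.cycle_basis(g)
        if len(cyc) == 6
        and sum(1 for i in cyc if atoms[i].element == "O") == 1
    ]
    if len(rings) != 2:
        raise StructureError(f"expected 2 pyranose rings, found {len(rings)}")

    def ring_oxygen(ring: tuple[int, ...]) -> int:
        return next(i for i in ring if atoms[i].element == "O")

    def anomeric_carbons(ring: tuple[int, ...]) -> set[int]:
        ro = ring_oxygen(ring)
        return {i for i in g.neighbors(ro) if i in ring and atoms[i].element == "C"}

    # classify each phosphate by the carbon its ester oxygen is attached to
    assignments: dict[int, tuple[int, tuple[int, ...]]] = {}
    for p in p_idx:
        olinks = [
            o for o in g.neighbors(p)
            if atoms[o].element == "O" and any(
                atoms[c].element == "C" for c in g.neighbors(o) if c != p
            )
        ]
        for o in olinks:
            carbons = [c for c in g.neighbors(o) if atoms[c].element == "C"]
            for c in carbons:
                for ring in rings:
                    if c in ring:
                        assignments[p] = (c, ring)
    if len(assignments) != 2:
        raise StructureError("could not trace both phosphates to ring carbons")

    p1 = p2 = None
    glcn1 = glcn2 = None
    for p, (c, ring) in assignments.items():
        if c in anomeric_carbons(ring):
            p1, glcn1 = p, ring
        else:
            p2, glcn2 = p, ring
    if p1 is None or p2 is None or glcn1 == glcn2:
        raise StructureError(
            "phosphate identification failed: need one glycosidic (anomeric) "
            "and one ester-bound phosphate on distinct rings"
        )

    def phosphate_group(p: int) -> tuple[int, ...]:
        os = tuple(o for o in g.neighbors(p) if atoms[o].element == "O")
        return (p, *os)

    ring_atoms = set(glcn1) | set(glcn2)
    phosphate_atoms = set(phosphate_group(p1)) | set(phosphate_group(p2))

    # Acyl chains are the connected components of the carbon-only subgraph
    # outside the rings: ester/amide N/O attachment atoms split a secondary
    # (branch) acyl from its primary chain, so 4- and 6-chain ligands come
    # apart into exactly 4 or 6 carbon components.
    chain_carbons = [
        i for i, a in enumerate(atoms)
        if a.element == "C" and i not in ring_atoms
    ]
    carbon_sub = g.subgraph(chain_carbons)
    components = [sorted(c) for c in nx.connected_components(carbon_sub)]
    # keep only components tethered to the rest through an N/O heteroatom
    acyl_comps: list[tuple[int, list[int]]] = []
    for comp in components:
        attach: int | None = None
        for x in comp:
            for h in g.neighbors(x):
                if h not in comp and atoms[h].element in ("N", "O") \
                        and h not in phosphate_atoms:
                    attach = h if attach is None else min(attach, h)
        if attach is not None:
            acyl_comps.append((attach, comp))
    if len(acyl_comps) not in (4, 6):
        raise StructureError(
            f"expected 4 or 6 acyl chains, traced {len(acyl_comps)}"
        )
    # primary chains (attached to a ring carbon via the heteroatom) labeled
    # A/B on GlcN1 and C/D on GlcN2; secondary branches labeled C'/D'
    primary: list[tuple[tuple[int, int], list[int]]] = []
    secondary: list[tuple[int, list[int]]] = []
    for attach, comp in acyl_comps:
        ring_link = [c for c in g.neighbors(attach) if c in ring_atoms]
        if ring_link:
            ring_rank = 0 if ring_link[0] in glcn1 else 1
            primary.append(((ring_rank, attach), comp))
        else:
            secondary.append((attach, comp))
    primary.sort(key=lambda t: t[0])
    secondary.sort(key=lambda t: t[0])
    labels = ["A", "B", "C", "D"][: len(primary)]
    chains = [
        (lab, len(comp)) for lab, (_, comp) in zip(labels, primary)
    ]
    chains += [
        (lab, len(comp))
        for lab, (_, comp) in zip(["C'", "D'"], secondary)
    ]
    acyl_atom_map = {
        lab: tuple(comp) for lab, (_, comp) in zip(labels, primary)
    }
    acyl_atom_map.update(
        {lab: tuple(comp) for lab, (_, comp) in zip(["C'", "D'"], secondary)}
    )

    return LigandPose(
        atoms=atoms,
        bonds=g,
        glcn1=tuple(sorted(glcn1)),
        glcn2=tuple(sorted(glcn2)),
        p1=phosphate_group(p1),
        p2=phosphate_group(p2),
        acyl_chains=chains,
        acyl_atoms=acyl_atom_map,
    )


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def superpose_points(
    ref: np.ndarray, mov: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of ``mov`` onto ``ref`` (Kabsch).

    Returns (rotation, translation, rmsd) with the convention
    ``moved = R @ x + t``.
    """
    ref = np.asarray(ref, float)
    mov = np.asarray(mov, float)
    if ref.shape != mov.shape or ref.shape[0] < 3:
        raise StructureError("superposition needs >=3 paired atoms")
    cr, cm = ref.mean(axis=0), mov.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref - cr, mov - cm)
    R = rot.as_matrix()
    t = cr - R @ cm
    moved = (R @ mov.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return R, t, rmsd


def parse_selection(sel: str) -> tuple[str, int, int | None, str | None]:
    """Parse ``chain:resnum[-resnum][@atomname]`` selection syntax."""
    if "@" in sel:
        sel, atom = sel.split("@", 1)
    else:
        atom = None
    chain, _, rng = sel.partition(":")
    if not chain or not rng:
        raise StructureError(f"bad selection {sel!r}; expected chain:resnum[-resnum]")
    if "-" in rng:
        lo, hi = rng.split("-", 1)
        return chain, int(lo), int(hi), atom
    return chain, int(rng), None, atom


def select_atoms(m: StructureModel, selections: Iterable[str]) -> np.ndarray:
    """Coordinates matching a list of selection strings, in order."""
    pts: list[np.ndarray] = []
    for sel in selections:
        chain, lo, hi, atom = parse_selection(sel)
        cid = m.roles.get(chain, chain)
        hi = hi if hi is not None else lo
        for r in m.chains.get(cid, []):
            if lo <= r.number <= hi:
                for a in r.atoms:
                    if atom is None or a.name == atom:
                        pts.append(a.coords)
    if not pts:
        raise StructureError("selection matched no atoms")
    return np.vstack(pts)


def superpose(
    ref: StructureModel,
    mov: StructureModel,
    selection: Iterable[str] | tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Superpose ``mov`` onto ``ref`` over paired atom selections.

    ``selection`` is either a list of selection strings applied to both
    models, or an explicit (ref_coords, mov_coords) pair.
    """
    if isinstance(selection, tuple) and len(selection) == 2 and not isinstance(
        selection[0], str
    ):
        ref_pts, mov_pts = selection
    else:
        sels = list(selection)  # type: ignore[arg-type]
        ref_pts = select_atoms(ref, sels)
        mov_pts = select_atoms(mov, sels)
    if np.shape(ref_pts) != np.shape(mov_pts):
        raise StructureError(
            f"paired selections differ in size: {np.shape(ref_pts)} vs {np.shape(mov_pts)}"
        )
    return superpose_points(ref_pts, mov_pts)
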