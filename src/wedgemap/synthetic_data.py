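"""Synthetic fixtures: toy sequence families, toy wedge complexes, toy ligands.

Everything the pipeline consumes can be generated here at desk scale, with a
fixed seed giving bit-identical output:

* :func:`make_toy_sequences` - a small protein family mutated away from a
  common ancestor at a controlled per-site rate;
* :func:`make_toy_complex` - a three-chain (TLR4 "a", counter-TLR4* "b",
  MD-2 "c") pseudo-complex arranged as the triangular wedge, with
  charged-group pseudo-atoms realizing a species charge profile
  (which side chains sit near which phosphate, and which are locked in
  protein-protein salt bridges);
* :func:`make_toy_ligand` - a diglucosamine-bisphosphate ligand with 4 or 6
  acyl chains and a flippable backbone;
* :func:`perturb` - i.i.d. Gaussian coordinate noise for robustness tests.

Placed residues reuse the published residue labels (367b, 122c, ...) verbatim
so reports are directly comparable to the species tables. Pseudo-residues
carry a four-atom backbone plus a single charged-group atom; that is all the
interaction detectors read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from wedgemap.structio import (
    Atom,
    LigandPose,
    Residue,
    StructureModel,
    StructureError,
    infer_bonds,
)
from wedgemap.seqalign import AMINO_ACIDS, Sequence

# ---------------------------------------------------------------------------
# Canonical wedge geometry (Å). The triangle lies in the z=0 plane with the
# MD-2 pocket extending toward -z; corners: Pag uppermost (agonist site on
# counter-TLR4*), Pan leftmost (MD-2 lip, antagonist site), Pag-Pan rightmost
# (conserved site).
# ---------------------------------------------------------------------------

PAG = np.array([0.0, 9.0, -1.0])
PAN = np.array([-6.5, -5.0, 0.5])
PAGPAN = np.array([6.5, -5.0, -0.4])

#: Phosphate positions of the "normal" (agonist-like) pose.
P1_POS = np.array([0.0, 5.0, 0.0])
P2_POS = np.array([4.2, -2.6, 0.0])

#: Glucosamine ring centers of the normal pose (rings hang toward the pocket).
RING1_CENTER = np.array([0.66, 0.9, -1.5])
RING2_CENTER = np.array([1.44, -4.7, -2.87])

POCKET_CENTER_XY = np.array([1.0, -2.0])
POCKET_BOTTOM_Z = -11.0
POCKET_BOTTOM_RADIUS = 5.5

_CHARGED_ATOM = {
    "LYS": "NZ", "ARG": "NH1", "GLU": "OE1", "ASP": "OD1",
    "SER": "OG", "GLN": "NE2", "ASN": "ND2", "HIS": "NE2",
}

#: Named pseudo-atom sites in the canonical wedge frame.
SITES: dict[str, tuple[float, float, float]] = {
    # around the Pag corner / P1
    "pag_w": (-1.5, 9.0, -1.0),
    "pag_e": (1.5, 9.0, -1.0),
    "pag_w_up": (-1.5, 9.0, 1.8),      # partner 2.8 Å above pag_w
    "pag_mid": (0.0, 9.0, 1.5),
    "p1_near_b": (1.8, 7.0, -3.0),
    "p1_partner_a": (1.8, 9.3, -4.8),  # 2.9 Å from p1_near_b
    "p1_near_a": (0.0, 7.8, -2.2),
    "p1_flank_e": (2.2, 6.6, -1.6),
    "p1_flank_w": (-2.6, 4.6, -3.0),
    # around the Pan corner (MD-2 lip)
    "lip_w": (-7.6, -5.6, 0.5),
    "lip_e": (-5.4, -4.4, 0.5),
    "pan_lo": (-6.0, -6.5, -1.0),
    "pan_lo_up": (-6.0, -6.5, 1.8),
    "pan_extra": (-7.0, -4.0, -1.0),
    # around the Pag-Pan corner / P2
    "pagpan_c": (6.5, -5.0, -0.4),
    "pagpan_e": (8.3, -5.9, 0.8),
    "pagpan_w": (5.9, -5.9, 0.8),      # 2.4 Å from pagpan_e
    "p2_near_b": (2.4, -0.6, 3.0),
    "p2_near_b2": (6.4, -1.0, -3.2),
}


@dataclass(frozen=True)
class Placement:
    """One charged (or polar) pseudo-residue of a species profile."""

    role: str          # chain role a / b / c
    number: int        # published residue number
    restype: str       # three-letter code
    site: str          # key into SITES
    partner: tuple[str, int] | None = None  # salt-bridge partner (role, number)


@dataclass(frozen=True)
class SpeciesProfile:
    """Charge placements realizing one species column of the residue tables."""

    name: str
    placements: tuple[Placement, ...]
    lip_residue: str = "LYS"   # residue type at the MD-2 lip position 122c
    extrapolated: bool = False

    def __post_init__(self) -> None:
        keys = [(p.role, p.number) for p in self.placements]
        if len(keys) != len(set(keys)):
            raise ValueError(f"profile {self.name}: duplicate placement")
        by_key = {(p.role, p.number): p for p in self.placements}
        for p in self.placements:
            if p.partner is not None:
                other = by_key.get(p.partner)
                if other is None or other.partner != (p.role, p.number):
                    raise ValueError(
                        f"profile {self.name}: partner of {p.role}{p.number} "
                        "is not reciprocal"
                    )


def _p(role, number, restype, site, partner=None) -> Placement:
    return Placement(role, number, restype, site, partner)


MURINE = SpeciesProfile(
    name="murine",
    lip_residue="GLU",
    placements=(
        _p("b", 367, "LYS", "pag_w"),
        _p("b", 434, "ARG", "pag_e"),
        _p("b", 386, "SER", "pag_mid"),
        _p("a", 341, "LYS", "p1_near_a"),
        _p("a", 319, "LYS", "pagpan_c"),
        _p("c", 58, "ASN", "lip_w"),
        _p("c", 122, "GLU", "lip_e"),
    ),
)

HUMAN = SpeciesProfile(
    name="human",
    lip_residue="LYS",
    placements=(
        _p("b", 369, "GLU", "pag_w", partner=("b", 388)),
        _p("b", 388, "LYS", "pag_w_up", partner=("b", 369)),
        _p("b", 436, "GLN", "pag_e"),
        _p("b", 371, "ASP", "p2_near_b"),
        _p("b", 439, "GLU", "p2_near_b2"),
        _p("a", 321, "GLU", "pagpan_e", partner=("a", 322)),
        _p("a", 322, "ARG", "pagpan_w", partner=("a", 321)),
        _p("c", 58, "LYS", "lip_w"),
        _p("c", 122, "LYS", "lip_e"),
        _p("c", 89, "LYS", "pan_extra"),
        _p("c", 90, "ARG", "pan_lo"),
    ),
)

EQUINE = SpeciesProfile(
    name="equine",
    lip_residue="ARG",
    placements=(
        _p("b", 370, "GLU", "pag_w", partner=("b", 372)),
        _p("b", 372, "LYS", "pag_w_up", partner=("b", 370)),
        _p("b", 437, "GLN", "pag_e"),
        _p("b", 389, "LYS", "p1_near_b", partner=("a", 344)),
        _p("a", 344, "GLU", "p1_partner_a", partner=("b", 389)),
        _p("a", 385, "ARG", "p1_flank_e"),
        _p("a", 366, "LYS", "p1_flank_w"),
        _p("a", 342, "ARG", "pagpan_c"),
        _p("c", 58, "ARG", "lip_w"),
        _p("c", 122, "ARG", "lip_e"),
        _p("c", 90, "ARG", "pan_lo", partner=("b", 440)),
        _p("b", 440, "ASP", "pan_lo_up", partner=("c", 90)),
    ),
)

# The canine MD-2 record exists only as a theoretical prediction and the
# species has no column in the residue tables; this profile is a human-like
# extrapolation (canine TLR4 numbering equals human throughout the mapped
# range) and any activity call built on it is labeled as extrapolated.
CANINE = SpeciesProfile(
    name="canine",
    lip_residue="LYS",
    extrapolated=True,
    placements=(
        _p("b", 369, "GLU", "pag_w", partner=("b", 388)),
        _p("b", 388, "LYS", "pag_w_up", partner=("b", 369)),
        _p("b", 436, "GLN", "pag_e"),
        _p("b", 371, "ASP", "p2_near_b"),
        _p("b", 439, "GLU", "p2_near_b2"),
        _p("a", 321, "GLU", "pagpan_e", partner=("a", 322)),
        _p("a", 322, "ARG", "pagpan_w", partner=("a", 321)),
        _p("c", 58, "LYS", "lip_w"),
        _p("c", 122, "LYS", "lip_e"),
    ),
)

PROFILES: dict[str, SpeciesProfile] = {
    "murine": MURINE,
    "human": HUMAN,
    "equine": EQUINE,
    "canine": CANINE,
}

#: Per-species wedge corner anchors (role, residue number) for define_wedge.
DEFAULT_ANCHORS: dict[str, dict[str, list[tuple[str, int]]]] = {
    "murine": {
        "Pag": [("b", 367), ("b", 434)],
        "Pan": [("c", 58), ("c", 122)],
        "PagPan": [("a", 319)],
    },
    "human": {
        "Pag": [("b", 369), ("b", 436)],
        "Pan": [("c", 58), ("c", 122)],
        "PagPan": [("a", 321), ("a", 322)],
    },
    "equine": {
        "Pag": [("b", 370), ("b", 437)],
        "Pan": [("c", 58), ("c", 122)],
        "PagPan": [("a", 342)],
    },
    "canine": {
        "Pag": [("b", 369), ("b", 436)],
        "Pan": [("c", 58), ("c", 122)],
        "PagPan": [("a", 321), ("a", 322)],
    },
}


def anchors_for(
    species: str, omit: tuple[tuple[str, int], ...] = ()
) -> dict[str, list[tuple[str, int]]]:
    """Wedge anchor selections for a species toy, minus ablated residues.

    A corner whose anchors were all ablated keeps the full list so the
    downstream error names the missing residue instead of silently moving
    the corner.
    """
    out = {}
    for corner, anchors in DEFAULT_ANCHORS[species].items():
        kept = [a for a in anchors if a not in omit]
        out[corner] = kept if kept else list(anchors)
    return out


@dataclass(frozen=True)
class ToySpec:
    """Geometry and randomness knobs of the toy complex generator."""

    edge_length: float = 13.0       # Pan to Pag-Pan corner distance (Å)
    pocket_depth: float = 11.0      # z-depth of the pocket bottom ring (Å)
    noise_sigma: float = 0.0        # Gaussian jitter on protein atoms (Å)
    seed: int = 0
    acyl_plan: tuple[int, ...] = (14, 14, 14, 14)

    def __post_init__(self) -> None:
        if self.edge_length <= 0 or self.pocket_depth <= 0:
            raise ValueError("toy dimensions must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def make_toy_sequences(
    n: int,
    length: int,
    target_identity: float,
    seed: int = 0,
    protein: str = "MD2",
) -> list[Sequence]:
    """A star family: one uniform ancestor, ``n`` descendants mutated i.i.d.
    per site at rate ``1 - target_identity`` (substitutions uniform over the
    other 19 letters). The first returned sequence is the ancestor.
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    ancestor = rng.integers(0, 20, size=length)
    seqs = [Sequence(id="toy0", residues="".join(letters[ancestor]), protein=protein)]
    mu = 1.0 - target_identity
    for k in range(1, n):
        child = ancestor.copy()
        hit = rng.random(length) < mu
        shifts = rng.integers(1, 20, size=length)
        child[hit] = (child[hit] + shifts[hit]) % 20
        seqs.append(
            Sequence(id=f"toy{k}", residues="".join(letters[child]), protein=protein)
        )
    return seqs


def expected_pairwise_identity(target_identity: float, ancestor: bool = True) -> float:
    """Expected identity under the generator's own mutation model."""
    mu = 1.0 - target_identity
    if ancestor:
        return 1.0 - mu
    # two independent descendants agree if neither mutated, or both mutated
    # to the same of the 19 alternatives
    return (1.0 - mu) ** 2 + mu * mu / 19.0


# ---------------------------------------------------------------------------
# Ligand
# ---------------------------------------------------------------------------

_RING_RADIUS = 1.5


def _hexagon(center: np.ndarray, toward: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Six ring vertices in the plane spanned by ``toward`` and ``ref``,
    with vertex 0 pointing along ``toward``."""
    u = toward / np.linalg.norm(toward)
    v = ref - np.dot(ref, u) * u
    v = v / np.linalg.norm(v)
    pts = []
    for k in range(6):
        ang = math.radians(60.0 * k)
        pts.append(center + _RING_RADIUS * (math.cos(ang) * u + math.sin(ang) * v))
    return np.vstack(pts)


_CHAIN_Z_FLOOR = -6.5


def _acyl_ray(start: np.ndarray, direction: np.ndarray, n_carbons: int,
              wobble: np.ndarray, z_floor: float | None = _CHAIN_Z_FLOOR) -> list[np.ndarray]:
    """A zig-zag chain of carbons marching along ``direction``.

    Descending chains level off at ``z_floor`` and continue horizontally
    away from the pocket axis (lipid tails coil inside the cavity rather
    than spearing its floor)."""
    d = direction / np.linalg.norm(direction)
    w = wobble - np.dot(wobble, d) * d
    w = w / np.linalg.norm(w)
    pts = []
    pos = start
    for k in range(n_carbons):
        if z_floor is not None and d[2] < -0.05 and pos[2] <= z_floor:
            # level off gradually (gentle turns keep 1-3 neighbor
            # distances above the bond-inference cutoff)
            out = np.array([pos[0] - POCKET_CENTER_XY[0],
                            pos[1] - POCKET_CENTER_XY[1], 0.0])
            n = np.linalg.norm(out)
            out = out / n if n > 1e-6 else np.array([1.0, 0.0, 0.0])
            d = d + 1.2 * out
            d /= np.linalg.norm(d)
            w = w - np.dot(w, d) * d
            nw = np.linalg.norm(w)
            w = w / nw if nw > 1e-3 else np.array([0.0, 0.0, 1.0])
        pos = pos + 1.25 * d + (0.45 if k % 2 == 0 else -0.45) * w
        pts.append(pos.copy())
    return pts


def flip_transform(centroid_xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """180° rotation about the vertical pocket axis through ``centroid_xy``.

    Returns (R, t) with x -> R x + t; z is preserved, x/y are negated about
    the axis.
    """
    R = np.diag([-1.0, -1.0, 1.0])
    cx, cy = float(centroid_xy[0]), float(centroid_xy[1])
    t = np.array([2.0 * cx, 2.0 * cy, 0.0])
    return R, t


def make_toy_ligand(
    n_chains: int = 4,
    chain_plan: tuple[int, ...] | None = None,
    orientation: str = "normal",
) -> tuple[LigandPose, nx.Graph]:
    """Build the toy diglucosamine-bisphosphate ligand in the wedge frame.

    Two fused pyranose-like rings; P1 sits glycosidically on the anomeric
    carbon of GlcN1, P2 ester-bound on a non-anomeric carbon of GlcN2. Acyl
    chains (4 or 6 per ``chain_plan``) are carbon zig-zags descending into
    the pocket; a 6-chain plan attaches two secondary chains as ester
    branches on the third carbon of chains C and D. Returns the pose plus
    the generator's own bond graph (ground truth for connectivity checks).
    """
    if n_chains not in (4, 6):
        raise StructureError("ligand must have 4 or 6 acyl chains")
    if chain_plan is None:
        chain_plan = (14,) * n_chains
    chain_plan = tuple(int(c) for c in chain_plan)
    if len(chain_plan) != n_chains:
        raise StructureError("chain plan length must equal n_chains")
    if orientation not in ("normal", "flipped"):
        raise StructureError(f"unknown orientation {orientation!r}")

    atoms: list[tuple[str, str, np.ndarray]] = []  # (name, element, xyz)
    bonds: list[tuple[int, int]] = []

    def add(name: str, element: str, pos: np.ndarray) -> int:
        atoms.append((name, element, np.asarray(pos, float)))
        return len(atoms) - 1

    down = np.array([0.0, 0.0, -1.0])

    def build_ring(tag: str, center: np.ndarray, p_target: np.ndarray,
                   other_center: np.ndarray, anomeric_bridge: bool) -> dict:
        """One pyranose-like hexagon.

        Vertex 0 points at the phosphate target; the ring oxygen and the
        bridge carbon are placed so that the phosphate-bearing carbon is
        anomeric (adjacent to the ring O) on ring 1 and non-anomeric on
        ring 2, where instead the bridge carbon is anomeric.
        """
        u = p_target - center
        pts = _hexagon(center, u, other_center - center)
        # nearest vertex to the other ring hosts the glycosidic bridge
        dists = [np.linalg.norm(p - other_center) for p in pts]
        bridge_v = int(np.argmin([
            d if k != 0 else np.inf for k, d in enumerate(dists)
        ]))
        if anomeric_bridge:
            # ring O adjacent to the bridge carbon, not to vertex 0
            cand = [v for v in ((bridge_v + 1) % 6, (bridge_v - 1) % 6)
                    if v not in (0, 1, 5)]
            ring_o_v = cand[0]
        else:
            # ring O adjacent to vertex 0 (the phosphate carbon is anomeric)
            cand = [v for v in (1, 5) if v != bridge_v]
            ring_o_v = cand[0]
        idxs = []
        for v in range(6):
            if v == ring_o_v:
                idxs.append(add(f"O5{tag}", "O", pts[v]))
            else:
                idxs.append(add(f"C{v + 1}{tag}", "C", pts[v]))
        for v in range(6):
            bonds.append((idxs[v], idxs[(v + 1) % 6]))
        free = [v for v in range(6) if v not in (0, ring_o_v, bridge_v)]
        return {"pts": pts, "idx": idxs, "bridge_v": bridge_v,
                "ring_o_v": ring_o_v, "free": free, "u": u / np.linalg.norm(u)}

    # ring 2's bridge carbon must be its anomeric carbon; ring 1's
    # phosphate carbon (vertex 0) is anomeric
    ring1 = build_ring("A", RING1_CENTER, P1_POS, RING2_CENTER, False)
    ring2 = build_ring("B", RING2_CENTER, P2_POS, RING1_CENTER, True)

    def add_phosphate(tag: str, ring: dict, p_pos: np.ndarray) -> tuple[int, int]:
        c_idx = ring["idx"][0]
        c_pos = ring["pts"][0]
        u = ring["u"]
        o_est = add(f"O{tag}E", "O", c_pos + 1.43 * u)
        p = add(f"P{tag[-1]}", "P", p_pos)
        bonds.extend([(c_idx, o_est), (o_est, p)])
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 0.3:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        perp2 = np.cross(u, perp)
        for k, d in enumerate((perp, -perp, 0.8 * u + 0.6 * perp2)):
            o = add(f"O{tag}{'PQR'[k]}", "O", p_pos + 1.5 * d / np.linalg.norm(d))
            bonds.append((p, o))
        return p, o_est

    p1, o1 = add_phosphate("1", ring1, P1_POS)
    p2, o4 = add_phosphate("2", ring2, P2_POS)

    # glycosidic bridge oxygen midway between the two bridge carbons
    b1 = ring1["pts"][ring1["bridge_v"]]
    b2 = ring2["pts"][ring2["bridge_v"]]
    o6 = add("O6A", "O", 0.5 * (b1 + b2))
    bonds += [(ring1["idx"][ring1["bridge_v"]], o6),
              (ring2["idx"][ring2["bridge_v"]], o6)]

    # --- acyl chains: each gets its own radial azimuth so rays diverge
    acyl_atoms: dict[str, list[int]] = {}
    branch_hosts: dict[str, int] = {}
    branch_wobble: dict[str, np.ndarray] = {}
    # the amide-bound FA1 (chain A) gets the GlcN1 vertex facing the Pag
    # corner so it can protrude toward counter-TLR4* without crossing its ring
    free1 = sorted(
        ring1["free"],
        key=lambda v: -(ring1["pts"][v] - ring1["pts"].mean(axis=0))[1],
    )
    specs = [
        ("A", ring1, free1[0], "N"),   # amide-bound FA1 on GlcN1
        ("B", ring1, free1[1], "O"),
        ("C", ring2, ring2["free"][0], "N"),
        ("D", ring2, ring2["free"][1], "O"),
    ]
    for (label, ring, v, het), n_c in zip(specs, chain_plan[:4]):
        vpos = ring["pts"][v]
        center = ring["pts"].mean(axis=0)
        radial = vpos - center
        radial[2] = 0.0
        nr = np.linalg.norm(radial)
        radial = radial / nr if nr > 1e-6 else np.array([1.0, 0.0, 0.0])
        if label == "A":
            # FA1 runs north toward the Pag corner through the gap between
            # the chain-a flank cations, descending below their side chains
            direction = np.array([0.0, 0.72, -0.60])
            wobble = np.array([1.0, 0.0, 0.0])
        else:
            direction = 0.55 * radial + 0.85 * down
            wobble = np.cross(direction, down)
        direction /= np.linalg.norm(direction)
        hpos = vpos + 1.43 * direction
        h = add(f"{het}{label}", het, hpos)
        bonds.append((ring["idx"][v], h))
        if np.linalg.norm(wobble) < 0.3:
            wobble = np.array([1.0, 0.0, 0.0])
        wobble /= np.linalg.norm(wobble)
        pts = _acyl_ray(hpos, direction, n_c, wobble)
        prev = h
        idxs = []
        for k, ppos in enumerate(pts):
            c = add(f"C{label}{k + 1}", "C", ppos)
            bonds.append((prev, c))
            prev = c
            idxs.append(c)
        acyl_atoms[label] = idxs
        branch_hosts[label] = idxs[2] if len(idxs) > 2 else idxs[-1]
        branch_wobble[label] = wobble

    if n_chains == 6:
        for label, host_label, n_c in (
            ("C'", "C", chain_plan[4]),
            ("D'", "D", chain_plan[5]),
        ):
            host = branch_hosts[host_label]
            hpos = atoms[host][2]
            # scan candidate azimuths for the clearest branch direction
            existing = np.vstack([pos for k, (_, _, pos) in enumerate(atoms)
                                  if k != host])
            best = None
            for kphi in range(12):
                phi = 2.0 * math.pi * kphi / 12.0
                az = np.array([math.cos(phi), math.sin(phi), 0.0])
                direction = 0.8 * az + 0.62 * down
                direction /= np.linalg.norm(direction)
                opos = hpos + 1.43 * direction
                probe = np.vstack([opos + s * 1.25 * direction
                                   for s in range(0, 4)])
                dmin = float(np.linalg.norm(
                    existing[None, :, :] - probe[:, None, :], axis=2
                ).min())
                if best is None or dmin > best[0]:
                    best = (dmin, direction, opos)
            _, direction, opos = best
            o = add(f"O{label[0]}S", "O", opos)
            bonds.append((host, o))
            wobble = np.cross(direction, down)
            if np.linalg.norm(wobble) < 0.3:
                wobble = np.array([0.0, 1.0, 0.0])
            pts = _acyl_ray(opos, direction, n_c, wobble)
            prev = o
            idxs = []
            for k, ppos in enumerate(pts):
                c = add(f"C{label[0]}S{k + 1}", "C", ppos)
                bonds.append((prev, c))
                prev = c
                idxs.append(c)
            acyl_atoms[label] = idxs

    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    g.add_edges_from(bonds)

    atom_objs = [Atom(name, el, pos) for name, el, pos in atoms]
    ring1_idx = tuple(sorted(ring1["idx"]))
    ring2_idx = tuple(sorted(ring2["idx"]))
    pose = LigandPose(
        atoms=atom_objs,
        bonds=g,
        glcn1=ring1_idx,
        glcn2=ring2_idx,
        p1=(p1, o1, *[i for i in g.neighbors(p1) if i != o1]),
        p2=(p2, o4, *[i for i in g.neighbors(p2) if i != o4]),
        acyl_chains=[(lab, len(v)) for lab, v in acyl_atoms.items()],
        acyl_atoms={lab: tuple(v) for lab, v in acyl_atoms.items()},
        orientation="normal",
    )
    if orientation == "flipped":
        R, t = flip_transform(pose.backbone_centroid()[:2])
        pose = pose.transformed(R, t)
        pose = replace(pose, orientation="flipped")
    return pose, g


# ---------------------------------------------------------------------------
# Complex
# ---------------------------------------------------------------------------

_WEDGE_CENTER = np.array([0.0, 0.0, 0.0])


#: Backbone directions overriding the default radial-outward placement
#: (sites whose radial direction would cross the FA1 corridor).
_SITE_BACKBONE_DIR = {
    "p1_partner_a": np.array([0.9, 0.3, -0.3]),
}


def _pseudo_residue(
    name: str, number: int, chain: str, site_pos: np.ndarray,
    backbone_dir: np.ndarray | None = None,
) -> Residue:
    """Backbone + one charged-group atom, backbone pushed radially outward."""
    out = backbone_dir if backbone_dir is not None else site_pos - _WEDGE_CENTER
    n = np.linalg.norm(out)
    out = out / n if n > 1e-6 else np.array([0.0, 0.0, 1.0])
    ca = site_pos + 2.0 * out
    atoms = [
        Atom("N", "N", ca + np.array([0.0, 0.0, 1.3])),
        Atom("CA", "C", ca),
        Atom("C", "C", ca + np.array([1.3, 0.0, 0.0])),
        Atom("O", "O", ca + np.array([1.3, 1.1, 0.0])),
    ]
    if name != "GLY":
        atoms.append(Atom(_CHARGED_ATOM.get(name, "CB"),
                          "N" if _CHARGED_ATOM.get(name, "").startswith("N") else "O",
                          site_pos))
    return Residue(name=name, number=number, chain=chain, atoms=atoms)


def _gly_filler(number: int, chain: str, pos: np.ndarray,
                away: np.ndarray) -> Residue:
    """A glycine whose backbone extends along ``away`` from the wedge."""
    away = np.asarray(away, float)
    away = away / np.linalg.norm(away)
    perp = np.cross(away, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 0.3:
        perp = np.cross(away, [1.0, 0.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    atoms = [
        Atom("CA", "C", pos),
        Atom("N", "N", pos + 1.3 * away + 0.4 * perp),
        Atom("C", "C", pos + 2.5 * away),
        Atom("O", "O", pos + 2.5 * away + 1.2 * perp),
    ]
    return Residue(name="GLY", number=number, chain=chain, atoms=atoms)


def _edge_fillers(chain: str, start_num: int, a: np.ndarray, b: np.ndarray,
                  offset: np.ndarray, n: int = 8) -> list[Residue]:
    res = []
    for k in range(n):
        t = 0.12 + 0.76 * k / max(n - 1, 1)
        pos = a + t * (b - a) + offset
        res.append(_gly_filler(start_num + k, chain, pos, offset))
    return res


def make_toy_complex(
    profile: SpeciesProfile | str,
    spec: ToySpec | None = None,
    pose: str = "normal",
    omit: tuple[tuple[str, int], ...] = (),
    monomer: bool = False,
    obstruct_flipped_site: bool = False,
) -> tuple[StructureModel, LigandPose]:
    """Assemble a species toy complex plus its ligand pose.

    ``omit`` drops placements (ablation experiments, e.g. removing the
    murine chain-b lysine); ``monomer`` drops chain b entirely;
    ``obstruct_flipped_site`` parks a bulky phenylalanine pseudo side chain
    where the flipped ligand's P1 group would land, so the flipped pose
    clashes while the normal pose stays clean.
    """
    if isinstance(profile, str):
        profile = PROFILES[profile]
    spec = spec or ToySpec()
    scale = spec.edge_length / 13.0

    site_xyz = {k: np.array(v) * np.array([scale, scale, 1.0]) for k, v in SITES.items()}

    chains: dict[str, list[Residue]] = {"a": [], "b": [], "c": []}

    for p in profile.placements:
        if (p.role, p.number) in omit:
            continue
        if monomer and p.role == "b":
            continue
        chains[p.role].append(
            _pseudo_residue(p.restype, p.number, p.role, site_xyz[p.site],
                            _SITE_BACKBONE_DIR.get(p.site))
        )

    # filler backbones along the triangle edges, pushed outward and up
    pag, pan, pagpan = (PAG * scale, PAN * scale, PAGPAN * scale)
    pag = np.array([pag[0], pag[1], PAG[2]])
    pan = np.array([pan[0], pan[1], PAN[2]])
    pagpan = np.array([pagpan[0], pagpan[1], PAGPAN[2]])
    chains["a"] += _edge_fillers("a", 700, pag, pagpan, np.array([2.8, 1.3, 2.5]))
    if not monomer:
        chains["b"] += _edge_fillers("b", 700, pag, pan, np.array([-2.8, 1.3, 2.5]))
    chains["c"] += _edge_fillers("c", 140, pan, pagpan, np.array([0.0, -6.5, 2.0]))

    # pocket bottom ring (chain c lining, 10 residues, extending downward)
    for k in range(10):
        ang = 2.0 * math.pi * k / 10.0
        pos = np.array([
            POCKET_CENTER_XY[0] + POCKET_BOTTOM_RADIUS * math.cos(ang),
            POCKET_CENTER_XY[1] + POCKET_BOTTOM_RADIUS * math.sin(ang),
            -spec.pocket_depth,
        ])
        chains["c"].append(_gly_filler(125 + k, "c", pos, np.array([0.0, 0.0, -1.0])))

    if obstruct_flipped_site:
        # the flipped image of P1 about the ligand backbone centroid
        lig0, _ = make_toy_ligand(len(spec.acyl_plan), spec.acyl_plan, "normal")
        R, t = flip_transform(lig0.backbone_centroid()[:2])
        spot = R @ lig0.p_coord("P1") + t
        atoms = [
            Atom("CA", "C", spot + np.array([0.0, 0.0, 2.0])),
            Atom("CG", "C", spot),
            Atom("CD1", "C", spot + np.array([0.8, 0.0, 0.3])),
            Atom("CD2", "C", spot + np.array([-0.8, 0.0, 0.3])),
        ]
        chains["c"].append(Residue(name="PHE", number=150, chain="c", atoms=atoms))

    # ligand
    lig, _ = make_toy_ligand(len(spec.acyl_plan), spec.acyl_plan, pose)
    lig_res = Residue(
        name="LIG", number=1, chain="L",
        atoms=[Atom(a.name, a.element, a.coords.copy()) for a in lig.atoms],
        het=True,
    )

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        for cid in ("a", "b", "c"):
            for r in chains[cid]:
                for a in r.atoms:
                    a.coords = a.coords + rng.normal(0.0, spec.noise_sigma, 3)

    model_chains = {cid: res for cid, res in chains.items() if res}
    model_chains["L"] = [lig_res]
    roles = {"a": "a", "c": "c"}
    if not monomer:
        roles["b"] = "b"
    model = StructureModel(
        chains=model_chains, roles=roles, provenance=f"toy-{profile.name}"
    )
    return model, lig


def make_toy_helix(sequence: str, chain: str = "A",
                   start_number: int = 1) -> StructureModel:
    """An ideal-geometry alpha helix (N, CA, C, O, CB) for threading tests."""
    from wedgemap.mapping import ONE_TO_THREE

    rise, turn, radius = 1.5, math.radians(100.0), 2.3
    residues = []
    for i, one in enumerate(sequence):
        name = ONE_TO_THREE.get(one)
        if name is None:
            raise ValueError(f"unknown residue letter {one!r}")
        ang = i * turn
        ca = np.array([radius * math.cos(ang), radius * math.sin(ang), rise * i])
        axis_out = np.array([math.cos(ang), math.sin(ang), 0.0])
        tangent = np.array([-math.sin(ang), math.cos(ang), 0.0])
        atoms = [
            Atom("N", "N", ca - 0.9 * tangent + np.array([0, 0, -0.8])),
            Atom("CA", "C", ca),
            Atom("C", "C", ca + 0.9 * tangent + np.array([0, 0, 0.7])),
            Atom("O", "O", ca + 1.4 * tangent + np.array([0.9, 0, 0.9]) * 0),
        ]
        if name != "GLY":
            atoms.append(Atom("CB", "C", ca + 1.53 * axis_out))
        residues.append(Residue(name=name, number=start_number + i,
                                chain=chain, atoms=atoms))
    return StructureModel(chains={chain: residues}, provenance="toy-helix")


def perturb(m: StructureModel, sigma: float, seed: int = 0) -> StructureModel:
    """I.i.d. Gaussian displacement of every atom; sigma = 0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return m.transformed(np.eye(3), np.zeros(3))
    rng = np.random.default_rng(seed)
    out = m.transformed(np.eye(3), np.zeros(3))
    for _, a in out.atoms():
        a.coords = a.coords + rng.normal(0.0, sigma, 3)
    return out
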