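"""Charged-contact detectors around the ligand phosphates.

The species comparison rests on a small set of geometric detectors:

* salt bridges - cation (Lys/Arg, optionally His) to anion (Asp/Glu)
  charged-group heavy-atom pairs within a cutoff (default 4.0 Å);
* neutralization - a charged side chain engaged in at least one
  protein-protein salt bridge no longer attracts or repels a ligand
  phosphate (ligand contacts never neutralize);
* phosphate environment - every charged residue with a charged-group atom
  inside a shell (default 6.0 Å) around a phosphate P atom is classified
  attractive (free cation), repulsive (free anion) or neutralized;
* clash score - ligand/protein heavy-atom pairs closer than
  ``overlap_factor x (rvdW_i + rvdW_j)`` (Bondi radii, factor 0.7) reject
  a pose;
* burial depth - ligand backbone depth along the MD-2 pocket axis
  (mouth centroid to deep-lining centroid), compared between two complexes
  after superposing their MD-2 chains;
* torsional free energy - Autodock-style static estimate
  ``n_rotatable x weight`` from the ligand's 2D connectivity graph. The
  estimate is reported for completeness but never used for classification:
  for lipid-like ligands with coalescing acyl chains it is only a crude
  upper bound on torsional entropy.

All cutoffs live in :class:`InteractionConfig`; none are printed in the
source material, so community-standard values are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from wedgemap.structio import (
    ANIONIC,
    CATIONIC,
    CATIONIC_WITH_HIS,
    LigandPose,
    Residue,
    StructureModel,
    StructureError,
    superpose_points,
)

#: Bondi van der Waals radii (Å).
VDW_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "P": 1.8, "S": 1.8}


@dataclass(frozen=True)
class InteractionConfig:
    salt_bridge_cutoff: float = 4.0     # Å, charged-group N-O distance
    hbond_cutoff: float = 3.5           # Å, donor-acceptor distance
    phosphate_shell: float = 6.0        # Å around each phosphate P atom
    overlap_factor: float = 0.7         # fraction of summed vdW radii
    clash_tolerance: int = 0            # bad contacts allowed before reject
    his_cationic: bool = False
    tfe_weight: float = 0.2983          # energy units per rotatable bond
    lining_cutoff: float = 6.0          # Å, residue-to-ligand for pocket lining
    n_bottom: int = 10                  # deepest lining residues for the axis
    mouth_lip_positions: tuple[int, ...] = (58, 122)  # MD-2 lip residues


DEFAULT_CONFIG = InteractionConfig()


class InteractionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Salt bridges / neutralization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SaltBridge:
    cation: tuple[str, int, str]  # (chain, resnum, resname)
    anion: tuple[str, int, str]
    distance: float

    def involves(self, chain: str, number: int) -> bool:
        return (chain, number) in ((self.cation[0], self.cation[1]),
                                   (self.anion[0], self.anion[1]))


def _charged_residues(m: StructureModel, his_cationic: bool) -> list[Residue]:
    cats = CATIONIC_WITH_HIS if his_cationic else CATIONIC
    return [
        r for r in m.residues(het=False)
        if r.name in cats or r.name in ANIONIC
    ]


def detect_salt_bridges(
    m: StructureModel,
    cutoff: float | None = None,
    config: InteractionConfig = DEFAULT_CONFIG,
) -> list[SaltBridge]:
    """All protein cation/anion pairs with charged-group atoms within cutoff."""
    cutoff = cutoff if cutoff is not None else config.salt_bridge_cutoff
    cats = CATIONIC_WITH_HIS if config.his_cationic else CATIONIC
    charged = _charged_residues(m, config.his_cationic)
    cations = [r for r in charged if r.name in cats]
    anions = [r for r in charged if r.name in ANIONIC]
    bridges: list[SaltBridge] = []
    for c in cations:
        cpts = c.charged_group_coords()
        for a in anions:
            apts = a.charged_group_coords()
            d = float(np.min(np.linalg.norm(
                cpts[:, None, :] - apts[None, :, :], axis=2)))
            if d <= cutoff:
                bridges.append(SaltBridge(
                    cation=(c.chain, c.number, c.name),
                    anion=(a.chain, a.number, a.name),
                    distance=round(d, 3),
                ))
    return bridges


def neutralization_status(
    m: StructureModel,
    residue: Residue | tuple[str, int],
    cutoff: float | None = None,
    config: InteractionConfig = DEFAULT_CONFIG,
    bridges: list[SaltBridge] | None = None,
) -> str:
    """``"neutralized"`` if the residue sits in >=1 protein-protein salt
    bridge, else ``"free"``. Ligand contacts never neutralize."""
    if isinstance(residue, tuple):
        res = m.residue(*residue)
        if res is None:
            raise InteractionError(f"residue {residue} not found")
        residue = res
    if residue.charge_class == "neutral" and not (
        config.his_cationic and residue.name == "HIS"
    ):
        raise InteractionError(f"{residue.label} is not a charged residue")
    if bridges is None:
        bridges = detect_salt_bridges(m, cutoff, config)
    for b in bridges:
        if b.involves(residue.chain, residue.number):
            return "neutralized"
    return "free"


def detect_hydrogen_bonds(
    m: StructureModel,
    cutoff: float | None = None,
    config: InteractionConfig = DEFAULT_CONFIG,
) -> list[tuple[tuple[str, int, str], tuple[str, int, str], float]]:
    """Polar side-chain N/O pairs from different residues within the H-bond
    cutoff (reported as evidence; geometry-only, no angle term)."""
    cutoff = cutoff if cutoff is not None else config.hbond_cutoff
    polar: list[tuple[Residue, np.ndarray]] = []
    for r in m.residues(het=False):
        pts = [a.coords for a in r.atoms
               if a.element in ("N", "O") and a.name not in ("N", "O")]
        if pts:
            polar.append((r, np.vstack(pts)))
    out = []
    for i in range(len(polar)):
        for j in range(i + 1, len(polar)):
            ri, pi = polar[i]
            rj, pj = polar[j]
            d = float(np.min(np.linalg.norm(pi[:, None, :] - pj[None, :, :], axis=2)))
            if d <= cutoff:
                out.append(((ri.chain, ri.number, ri.name),
                            (rj.chain, rj.number, rj.name), round(d, 3)))
    return out


# ---------------------------------------------------------------------------
# Phosphate environment
# ---------------------------------------------------------------------------

@dataclass
class ResidueContact:
    chain_role: str
    chain: str
    number: int
    name: str
    distance: float     # min charged-group atom to P distance
    status: str         # attractive / repulsive / neutralized


@dataclass
class PhosphateReport:
    """Charge environment of P1 and P2 inside the shell."""

    shell: float
    phosphates: dict[str, list[ResidueContact]] = field(default_factory=dict)

    def contacts(self, which: str, status: str | None = None,
                 chain_role: str | None = None) -> list[ResidueContact]:
        out = self.phosphates.get(which, [])
        if status is not None:
            out = [c for c in out if c.status == status]
        if chain_role is not None:
            out = [c for c in out if c.chain_role == chain_role]
        return out

    def net_score(self, which: str) -> int:
        return (len(self.contacts(which, "attractive"))
                - len(self.contacts(which, "repulsive")))

    def chain_breakdown(self, which: str) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for c in self.phosphates.get(which, []):
            d = out.setdefault(c.chain_role, {"attractive": 0, "repulsive": 0,
                                              "neutralized": 0})
            d[c.status] += 1
        return out

    def to_rows(self) -> list[dict]:
        rows = []
        for which, contacts in self.phosphates.items():
            for c in contacts:
                rows.append({
                    "phosphate": which, "chain": c.chain_role,
                    "residue": f"{c.name.capitalize()}{c.number}{c.chain_role}",
                    "distance": c.distance, "status": c.status,
                })
        return rows


def phosphate_environment(
    m: StructureModel,
    lig: LigandPose,
    shell: float | None = None,
    config: InteractionConfig = DEFAULT_CONFIG,
) -> PhosphateReport:
    """Classify every charged residue inside the shell of either phosphate.

    A residue engaged in a protein-protein salt bridge is neutralized;
    otherwise a cation is attractive and an anion repulsive toward the
    monoanionic phosphate. Each residue lands in exactly one class per
    phosphate.
    """
    shell = shell if shell is not None else config.phosphate_shell
    if lig.p1 is None or lig.p2 is None:
        raise InteractionError("ligand lacks an identified phosphate")
    bridges = detect_salt_bridges(m, config=config)
    cats = CATIONIC_WITH_HIS if config.his_cationic else CATIONIC
    report = PhosphateReport(shell=shell)
    for which in ("P1", "P2"):
        p = lig.p_coord(which)
        contacts: list[ResidueContact] = []
        for r in m.residues(het=False):
            sign = r.charge_sign(config.his_cationic)
            if sign == 0:
                continue
            d = float(np.min(np.linalg.norm(r.charged_group_coords() - p, axis=1)))
            if d > shell:
                continue
            bridged = any(b.involves(r.chain, r.number) for b in bridges)
            if bridged:
                status = "neutralized"
            elif r.name in cats:
                status = "attractive"
            else:
                status = "repulsive"
            contacts.append(ResidueContact(
                chain_role=m.role_of_chain(r.chain) or r.chain,
                chain=r.chain, number=r.number, name=r.name,
                distance=round(d, 3), status=status,
            ))
        contacts.sort(key=lambda c: c.distance)
        report.phosphates[which] = contacts
    return report


# ---------------------------------------------------------------------------
# Clash score
# ---------------------------------------------------------------------------

@dataclass
class ClashReport:
    pairs: list[tuple[str, str, float]]
    count: int
    verdict: str  # accepted / rejected

    @property
    def accepted(self) -> bool:
        return self.verdict == "accepted"


def clash_score(
    m: StructureModel,
    lig: LigandPose,
    overlap_factor: float | None = None,
    config: InteractionConfig = DEFAULT_CONFIG,
) -> ClashReport:
    """Bad van der Waals contacts between ligand and protein heavy atoms."""
    factor = overlap_factor if overlap_factor is not None else config.overlap_factor
    prot = [(r, a) for r, a in m.atoms(het=False)]
    if not prot:
        raise InteractionError("model has no protein atoms")
    pcoords = np.vstack([a.coords for _, a in prot])
    pradii = np.array([VDW_RADII.get(a.element, 1.7) for _, a in prot])
    lcoords = lig.coords
    lradii = np.array([VDW_RADII.get(a.element, 1.7) for a in lig.atoms])
    tree = cKDTree(pcoords)
    max_thresh = factor * (lradii.max() + pradii.max())
    pairs: list[tuple[str, str, float]] = []
    for i, (lpos, lr) in enumerate(zip(lcoords, lradii)):
        for j in tree.query_ball_point(lpos, max_thresh):
            d = float(np.linalg.norm(lpos - pcoords[j]))
            if d < factor * (lr + pradii[j]):
                res, at = prot[j]
                pairs.append((lig.atoms[i].name, f"{res.label}@{at.name}", round(d, 3)))
    verdict = "rejected" if len(pairs) > config.clash_tolerance else "accepted"
    return ClashReport(pairs=pairs, count=len(pairs), verdict=verdict)


# ---------------------------------------------------------------------------
# Burial depth
# ---------------------------------------------------------------------------

def pocket_axis(
    m: StructureModel,
    lig: LigandPose,
    config: InteractionConfig = DEFAULT_CONFIG,
) -> tuple[np.ndarray, np.ndarray]:
    """(mouth centroid, unit axis into the pocket) for the MD-2 chain.

    Mouth = centroid of the configured lip residues; bottom = centroid of
    the deepest ``n_bottom`` pocket-lining residues (chain-c residues within
    ``lining_cutoff`` of any ligand atom), ranked by distance from the mouth.
    """
    md2 = m.chain_for_role("c")
    if md2 is None:
        raise InteractionError("model lacks an MD-2 (role c) chain")
    lip = [r for r in md2 if r.number in config.mouth_lip_positions]
    if not lip:
        raise InteractionError(
            f"no lip residues {config.mouth_lip_positions} on the MD-2 chain"
        )
    mouth = np.mean([a.coords for r in lip for a in r.atoms], axis=0)
    lpts = lig.coords
    lining = []
    for r in md2:
        pts = np.vstack([a.coords for a in r.atoms])
        d = float(np.min(np.linalg.norm(pts[:, None, :] - lpts[None, :, :], axis=2)))
        if d <= config.lining_cutoff:
            centroid = pts.mean(axis=0)
            lining.append((float(np.linalg.norm(centroid - mouth)), centroid))
    if len(lining) < 3:
        raise InteractionError("too few pocket-lining residues to define an axis")
    lining.sort(key=lambda t: -t[0])
    bottom = np.mean([c for _, c in lining[: config.n_bottom]], axis=0)
    axis = bottom - mouth
    norm = np.linalg.norm(axis)
    if norm < 1e-6:
        raise InteractionError("degenerate pocket axis")
    return mouth, axis / norm


def burial_depth(
    m: StructureModel,
    lig: LigandPose,
    config: InteractionConfig = DEFAULT_CONFIG,
) -> float:
    """Projection of the diglucosamine centroid onto the pocket axis (Å)."""
    mouth, axis = pocket_axis(m, lig, config)
    return float(np.dot(lig.backbone_centroid() - mouth, axis))


def burial_depth_delta(
    ref: tuple[StructureModel, LigandPose],
    alt: tuple[StructureModel, LigandPose],
    config: InteractionConfig = DEFAULT_CONFIG,
) -> float:
    """depth(alt) - depth(ref) after superposing alt's MD-2 onto ref's.

    Positive means the alternative ligand backbone sits deeper in the MD-2
    cavity than the reference.
    """
    ref_m, ref_l = ref
    alt_m, alt_l = alt
    ref_md2 = ref_m.chain_for_role("c")
    alt_md2 = alt_m.chain_for_role("c")
    if ref_md2 is None or alt_md2 is None:
        raise InteractionError("both complexes need an MD-2 (role c) chain")
    ref_ca = {r.number: r.atom("CA") for r in ref_md2 if r.atom("CA")}
    alt_ca = {r.number: r.atom("CA") for r in alt_md2 if r.atom("CA")}
    shared = sorted(set(ref_ca) & set(alt_ca))
    if len(shared) < 3:
        raise InteractionError("fewer than 3 shared MD-2 CA atoms")
    R, t, _ = superpose_points(
        np.vstack([ref_ca[n].coords for n in shared]),
        np.vstack([alt_ca[n].coords for n in shared]),
    )
    alt_m2 = alt_m.transformed(R, t)
    alt_l2 = alt_l.transformed(R, t)
    d_ref = burial_depth(ref_m, ref_l, config)
    d_alt = burial_depth(alt_m2, alt_l2, config)
    return float(d_alt - d_ref)


# ---------------------------------------------------------------------------
# Torsional free energy estimate
# ---------------------------------------------------------------------------

def tfe_estimate(
    lig_graph: nx.Graph,
    weight: float | None = None,
    config: InteractionConfig = DEFAULT_CONFIG,
) -> tuple[int, float]:
    """Static torsion count from the 2D connectivity graph.

    A bond is rotatable when it is acyclic (a bridge) and both endpoints
    have at least one further heavy neighbor. Returns
    (n_rotatable, n_rotatable * weight).
    """
    weight = weight if weight is not None else config.tfe_weight
    if lig_graph.number_of_nodes() == 0:
        raise InteractionError("empty ligand graph")
    if not nx.is_connected(lig_graph):
        raise InteractionError("ligand graph is disconnected")
    bridges = set(nx.bridges(lig_graph))
    n_rot = 0
    for u, v in bridges:
        if lig_graph.degree(u) >= 2 and lig_graph.degree(v) >= 2:
            n_rot += 1
    return n_rot, n_rot * weight
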