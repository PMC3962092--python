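"""The triangular wedge frame and the docking start-pose bookkeeping.

The ligand phosphates bind at three clustered sites on the TLR4 / counter
TLR4* / MD-2 interface, treated here as the corners of a triangle:

* ``Pag``    - uppermost corner, exposed toward counter-TLR4*; occupied by
  the glycosidic phosphate P1 in agonist-bound structures;
* ``PagPan`` - rightmost corner, the conserved site gripped regardless of
  activity;
* ``Pan``    - leftmost corner at the MD-2 lip, occupied by the ester
  phosphate P2 in antagonist-bound (backbone-flipped) structures.

Corners are defined as centroids of configurable anchor residue sets (never
hard-coded coordinates) so the same frame works on crystal structures,
homology models and synthetic toys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from wedgemap.structio import LigandPose, StructureModel, StructureError

CORNERS = ("Pag", "PagPan", "Pan")  # order fixes tie-breaking


class WedgeError(ValueError):
    pass


@dataclass(frozen=True)
class WedgeFrame:
    corners: dict[str, np.ndarray]       # corner -> centroid
    normal: np.ndarray                   # unit plane normal (pocket axis)
    anchors: dict[str, list[str]]        # provenance: residue labels

    def corner(self, name: str) -> np.ndarray:
        return self.corners[name]


def define_wedge(
    m: StructureModel,
    anchors: Mapping[str, Iterable[tuple[str, int]]],
) -> WedgeFrame:
    """Build the frame from per-corner anchor residue selections.

    ``anchors`` maps each corner name to (chain role or id, residue number)
    pairs; the corner is the centroid of the anchors' side-chain
    charged-group atoms (falling back to side-chain atoms for neutral
    anchors). Missing anchors and collinear corners are errors; a monomeric
    complex lacking role b cannot provide chain-b anchors and fails with an
    explicit message.
    """
    missing_corners = set(CORNERS) - set(anchors)
    if missing_corners:
        raise WedgeError(f"anchor config lacks corner(s) {sorted(missing_corners)}")
    corners: dict[str, np.ndarray] = {}
    provenance: dict[str, list[str]] = {}
    for corner in CORNERS:
        pts = []
        labels = []
        for chain, number in anchors[corner]:
            if chain == "b" and "b" not in m.roles and chain not in m.chains:
                raise WedgeError(
                    f"corner {corner}: anchor {chain}:{number} needs the "
                    "counter-TLR4* chain (role b), absent from this model; "
                    "use monomer-mode anchors"
                )
            res = m.residue(chain, number)
            if res is None:
                raise WedgeError(f"corner {corner}: anchor residue "
                                 f"{chain}:{number} not found")
            pts.append(res.charged_group_coords().mean(axis=0))
            labels.append(res.label)
        corners[corner] = np.mean(pts, axis=0)
        provenance[corner] = labels
    v1 = corners["PagPan"] - corners["Pag"]
    v2 = corners["Pan"] - corners["Pag"]
    n = np.cross(v1, v2)
    area2 = np.linalg.norm(n)
    if area2 < 1e-6 * max(np.linalg.norm(v1), np.linalg.norm(v2), 1.0):
        raise WedgeError("wedge corners are collinear")
    return WedgeFrame(corners=corners, normal=n / area2, anchors=provenance)


def assign_phosphate_corner(
    w: WedgeFrame, p: np.ndarray
) -> tuple[str, float]:
    """Nearest corner to a phosphate position; ties break in the fixed
    order Pag > PagPan > Pan. Returns (corner, distance)."""
    p = np.asarray(p, float)
    best: tuple[str, float] | None = None
    for corner in CORNERS:
        d = float(np.linalg.norm(w.corners[corner] - p))
        if best is None or d < best[1]:
            best = (corner, d)
    return best


def classify_orientation(w: WedgeFrame, lig: LigandPose) -> str:
    """``normal`` when P1 occupies Pag (agonist pattern); ``flipped`` when
    P1 sits at the conserved corner and P2 at the lip corner (antagonist
    pattern); otherwise ``indeterminate``."""
    c1, _ = assign_phosphate_corner(w, lig.p_coord("P1"))
    c2, _ = assign_phosphate_corner(w, lig.p_coord("P2"))
    if c1 == "Pag":
        return "normal"
    if c1 == "PagPan" and c2 == "Pan":
        return "flipped"
    return "indeterminate"


def flip_backbone(lig: LigandPose, w: WedgeFrame) -> LigandPose:
    """180° rotation of the ligand about the pocket axis (the wedge plane
    normal) through the diglucosamine centroid; the orientation label is
    recomputed afterwards. Applying the flip twice restores the input."""
    n = w.normal / np.linalg.norm(w.normal)
    c = lig.backbone_centroid()
    R = 2.0 * np.outer(n, n) - np.eye(3)
    t = c - R @ c
    out = lig.transformed(R, t)
    return replace(out, orientation=classify_orientation(w, out))


def wedge_to_json(w: WedgeFrame, path: str | Path) -> None:
    data = {
        "corners": {k: list(map(float, v)) for k, v in w.corners.items()},
        "normal": list(map(float, w.normal)),
        "anchors": w.anchors,
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Docking start-pose matrix
# ---------------------------------------------------------------------------

SPECIES_ROWS = ("human", "murine", "equine")
LIGANDS = ("lipidA", "lipidIVA", "eritoran")
POSE_COLUMNS = (
    "3FXI_observed",
    "3FXI_copied",
    "3FXI_flipped",
    "2E59_observed",
    "2E59_copied",
    "2E59_flipped",
)


@dataclass(frozen=True)
class StartPose:
    species: str
    ligand: str
    source: str      # 3FXI-derived / 2E59-derived
    flipped: bool
    mode: str        # observed / copied / flipped-copy

    @property
    def key(self) -> tuple[str, str, str, bool]:
        return (self.species, self.ligand, self.source, self.flipped)


def default_pose_config() -> dict[str, list[tuple[str, str]]]:
    """The published start-pose grid: 3 species x 3 ligands against six
    columns. Observed poses exist only where a crystal provides them
    (agonist-bound for the hexa-acyl ligand, antagonist-bound for the
    tetra-acyl precursor, both in the human system); copied columns cover
    every other cell; flipped-backbone variants cover all cells."""
    config: dict[str, list[tuple[str, str]]] = {col: [] for col in POSE_COLUMNS}
    for species in SPECIES_ROWS:
        for ligand in LIGANDS:
            cell = (species, ligand)
            if cell == ("human", "lipidA"):
                config["3FXI_observed"].append(cell)
            else:
                config["3FXI_copied"].append(cell)
            if cell == ("human", "lipidIVA"):
                config["2E59_observed"].append(cell)
            else:
                config["2E59_copied"].append(cell)
            config["3FXI_flipped"].append(cell)
            config["2E59_flipped"].append(cell)
    return config


def generate_pose_matrix(
    config: Mapping[str, list[tuple[str, str]]] | None = None,
) -> list[StartPose]:
    """One StartPose per non-empty cell of the start-position grid."""
    config = config if config is not None else default_pose_config()
    poses: list[StartPose] = []
    seen: set[tuple[str, str, str, bool]] = set()
    for column, cells in config.items():
        source, kind = column.split("_", 1)
        flipped = kind == "flipped"
        mode = "flipped-copy" if flipped else kind
        for species, ligand in cells:
            pose = StartPose(species=species, ligand=ligand,
                             source=f"{source}-derived", flipped=flipped,
                             mode=mode)
            if pose.key in seen:
                raise WedgeError(f"duplicate start pose {pose.key}")
            seen.add(pose.key)
            poses.append(pose)
    return poses


def pose_column_counts(
    poses: Iterable[StartPose],
    config: Mapping[str, list[tuple[str, str]]] | None = None,
) -> tuple[int, ...]:
    """Pose counts per column, in the published column order."""
    counts = dict.fromkeys(POSE_COLUMNS, 0)
    for p in poses:
        source = p.source.split("-")[0]
        if p.flipped:
            col = f"{source}_flipped"
        else:
            col = f"{source}_{p.mode}"
        counts[col] += 1
    return tuple(counts[c] for c in POSE_COLUMNS)


def pose_matrix_tsv(poses: Iterable[StartPose], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tligand\tsource\tmode\tflipped\n")
        for p in poses:
            fh.write(f"{p.species}\t{p.ligand}\t{p.source}\t{p.mode}\t"
                     f"{int(p.flipped)}\n")
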