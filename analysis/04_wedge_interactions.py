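#!/usr/bin/env python
"""Phosphate charge environments, pose acceptance, burial and torsions.

Reads the species toys from step 01 back through the PDB parser, builds
each wedge frame, classifies every charged residue around the two ligand
phosphates, scores normal and flipped poses for van der Waals clashes,
and reports the torsion count of the ligand connectivity graph. A
schematic of the wedge (corners, phosphates, charged residues) is saved
as a figure.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from wedgemap import interactions, structio, synthetic_data as sd, wedge

OUT = Path(__file__).resolve().parents[1] / "results"
SPECIES = ("murine", "human", "equine", "canine")


def main() -> None:
    rows = []
    for sp in SPECIES:
        model = structio.read_pdb(OUT / f"toy_{sp}.pdb")
        model = structio.assign_chain_roles(model, {c: c for c in "abc"})
        lig = structio.extract_ligand(model, ["LIG"])
        frame = wedge.define_wedge(model, sd.DEFAULT_ANCHORS[sp])
        rep = interactions.phosphate_environment(model, lig)
        clash = interactions.clash_score(model, lig)
        orient = wedge.classify_orientation(frame, lig)
        print(f"{sp:>7}: P1 net {rep.net_score('P1'):+d} "
              f"(chain-b free cations "
              f"{len(rep.contacts('P1', 'attractive', chain_role='b'))}), "
              f"P2 net {rep.net_score('P2'):+d}; pose {orient}, "
              f"{clash.verdict} ({clash.count} bad contacts)")
        rows += [dict(species=sp, **r) for r in rep.to_rows()]

    with open(OUT / "phosphate_environment.tsv", "w") as fh:
        fh.write("species\tphosphate\tchain\tresidue\tdistance\tstatus\n")
        for r in rows:
            fh.write(f"{r['species']}\t{r['phosphate']}\t{r['chain']}\t"
                     f"{r['residue']}\t{r['distance']}\t{r['status']}\n")

    # pose acceptance: the flipped human pose against an occupied pocket
    m_obst, _ = sd.make_toy_complex("human", obstruct_flipped_site=True)
    lig_n = structio.extract_ligand(m_obst, ["LIG"])
    m_obst_f, _ = sd.make_toy_complex("human", pose="flipped",
                                      obstruct_flipped_site=True)
    lig_f = structio.extract_ligand(m_obst_f, ["LIG"])
    v_n = interactions.clash_score(m_obst, lig_n).verdict
    v_f = interactions.clash_score(m_obst_f, lig_f).verdict
    print(f"occupied-pocket test: normal pose {v_n}, flipped pose {v_f} "
          "(the flip collides with the parked side chain)")

    lig4, g4 = sd.make_toy_ligand(4)
    lig6, g6 = sd.make_toy_ligand(6, (14, 14, 14, 14, 12, 14))
    n4, tfe4 = interactions.tfe_estimate(g4)
    n6, tfe6 = interactions.tfe_estimate(g6)
    print(f"torsion estimate: tetra-acyl {n4} rotatable bonds (TFE {tfe4:.2f}), "
          f"hexa-acyl {n6} (TFE {tfe6:.2f}) - reported only, never used "
          "for classification")

    # burial: displacement along the pocket axis is recovered exactly
    model = structio.read_pdb(OUT / "toy_murine.pdb")
    model = structio.assign_chain_roles(model, {c: c for c in "abc"})
    lig = structio.extract_ligand(model, ["LIG"])
    _, axis = interactions.pocket_axis(model, lig)
    deeper = lig.transformed(__import__("numpy").eye(3), 4.5 * axis)
    delta = interactions.burial_depth_delta((model, lig), (model, deeper))
    print(f"burial check: a ligand pushed 4.5 Å down the pocket axis reads "
          f"as {delta:.2f} Å deeper")

    _plot_wedge(OUT / "wedge_schematic.png")
    print("wrote phosphate_environment.tsv and wedge_schematic.png")


def _plot_wedge(path: Path) -> None:
    model, _ = sd.make_toy_complex("murine")
    lig = structio.extract_ligand(model, ["LIG"])
    frame = wedge.define_wedge(model, sd.DEFAULT_ANCHORS["murine"])
    fig, ax = plt.subplots(figsize=(5, 5))
    corners = frame.corners
    tri = [corners[c][:2] for c in ("Pag", "PagPan", "Pan")]
    tri.append(tri[0])
    xs, ys = zip(*tri)
    ax.plot(xs, ys, "k--", lw=1)
    for name, c in corners.items():
        ax.annotate(name, c[:2], fontsize=11, fontweight="bold")
    for which, color in (("P1", "tab:red"), ("P2", "tab:orange")):
        p = lig.p_coord(which)
        ax.scatter(*p[:2], c=color, s=80, zorder=3)
        ax.annotate(which, p[:2] + 0.3, color=color)
    for r in model.residues(het=False):
        sign = r.charge_sign()
        if sign:
            pt = r.charged_group_coords().mean(axis=0)
            ax.scatter(*pt[:2], c="tab:blue" if sign > 0 else "tab:green",
                       s=25, zorder=2)
    ax.set_aspect("equal")
    ax.set_xlabel("x (Å)")
    ax.set_ylabel("y (Å)")
    ax.set_title("murine wedge: corners, phosphates, charged residues")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


if __name__ == "__main__":
    main()
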