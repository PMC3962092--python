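"""Per-species activity calls from the wedge-resolved phosphate environment.

The verdict encodes, as counts of FREE (non-neutralized) charged side
chains near the phosphate occupying the agonist corner Pag, the narrative
logic of the species comparison:

* agonist - the Pag phosphate is gripped by a full cationic cluster
  (>= ``agonist_min_total`` free cations, default 3) including at least
  ``agonist_min_b`` (default 1) on counter-TLR4* (chain b): the ligand can
  bridge TLR4/MD-2 to the counter unit and dimerization proceeds. Only the
  murine system, with its unique pair of free chain-b cations plus a free
  chain-a lysine, satisfies this;
* partial agonist - some free cationic attraction remains near Pag, but
  not the full bridging cluster: the phosphate leans toward the TLR4 side
  (the equine situation, where the chain-b lysine is locked in a salt
  bridge and only chain-a arginine/lysine attract);
* antagonist - no free cation near Pag (net score <= 0) while free
  chain-b anions repel the other phosphate: the counter unit is pushed
  away and dimerization is not enabled (the human situation);
* indeterminate - none of the above.

A glutamate at the MD-2 lip (position-122 homolog on chain c) is recorded
as supporting evidence for the upward phosphate shift but never changes
the verdict on its own, and the amide-bound fatty-acid (FA1) protrusion
toward Pag is a speculative evidence flag only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from wedgemap.interactions import (
    DEFAULT_CONFIG,
    InteractionConfig,
    PhosphateReport,
    phosphate_environment,
)
from wedgemap.structio import LigandPose, StructureModel
from wedgemap.wedge import WedgeFrame, assign_phosphate_corner, classify_orientation

VERDICTS = ("agonist", "partial_agonist", "antagonist", "indeterminate")

#: Ranking for monotonicity checks (higher = stronger activation).
VERDICT_RANK = {"antagonist": 0, "indeterminate": 1, "partial_agonist": 2,
                "agonist": 3}


class ClassifyError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifyConfig:
    agonist_min_b: int = 1        # free chain-b cations near the Pag phosphate
    agonist_min_total: int = 3    # free cations (any chain) near it
    lip_position: int = 122       # MD-2 lip residue checked for Glu


DEFAULT_RULES = ClassifyConfig()


@dataclass
class ActivityCall:
    species: str
    ligand: str
    verdict: str
    evidence: dict = field(default_factory=dict)
    rationale: list[str] = field(default_factory=list)
    extrapolated: bool = False

    def to_dict(self) -> dict:
        return {
            "species": self.species, "ligand": self.ligand,
            "verdict": self.verdict, "extrapolated": self.extrapolated,
            "evidence": self.evidence, "rationale": self.rationale,
        }


def _fa1_toward_pag(lig: LigandPose, w: WedgeFrame) -> bool | None:
    idx = lig.acyl_atoms.get("A")
    if not idx:
        return None
    tip = lig.atoms[idx[-1]].coords
    centroid = lig.backbone_centroid()
    to_pag = w.corners["Pag"] - centroid
    return bool(np.dot(tip - centroid, to_pag) > 0)


def call_activity(
    report: PhosphateReport,
    w: WedgeFrame,
    lig: LigandPose,
    m: StructureModel | None = None,
    species: str = "unknown",
    ligand_name: str = "lipidIVA",
    rules: ClassifyConfig = DEFAULT_RULES,
    extrapolated: bool = False,
) -> ActivityCall:
    """Apply the rule ladder to a wedge-framed phosphate report."""
    corner1, d1 = assign_phosphate_corner(w, lig.p_coord("P1"))
    corner2, d2 = assign_phosphate_corner(w, lig.p_coord("P2"))
    if corner1 is None or corner2 is None:
        raise ClassifyError("report lacks corner assignments")
    # the phosphate nearest the agonist corner is judged
    if float(np.linalg.norm(lig.p_coord("P1") - w.corners["Pag"])) <= float(
        np.linalg.norm(lig.p_coord("P2") - w.corners["Pag"])
    ):
        p_star, p_other = "P1", "P2"
    else:
        p_star, p_other = "P2", "P1"

    free_b = len(report.contacts(p_star, "attractive", chain_role="b"))
    free_a = len(report.contacts(p_star, "attractive", chain_role="a"))
    free_c = len(report.contacts(p_star, "attractive", chain_role="c"))
    free_total = free_b + free_a + free_c
    net_star = report.net_score(p_star)
    anions_b_other = len(report.contacts(p_other, "repulsive", chain_role="b"))

    lip_anion = False
    if m is not None:
        lip_res = m.residue("c", rules.lip_position)
        lip_anion = lip_res is not None and lip_res.name == "GLU"

    orientation = classify_orientation(w, lig)
    rationale: list[str] = [
        f"{p_star} occupies the Pag side (corners: P1->{corner1} @{d1:.1f} Å, "
        f"P2->{corner2} @{d2:.1f} Å)",
        f"free cations near {p_star}: chain b={free_b}, a={free_a}, c={free_c}; "
        f"net score {net_star:+d}",
    ]
    if free_b >= rules.agonist_min_b and free_total >= rules.agonist_min_total:
        verdict = "agonist"
        rationale.append(
            f"R1: {p_star} is held by a full cationic cluster including "
            "counter-TLR4*; the phosphate can mediate the TLR4*/MD-2 contact "
            "and dimerization is established"
        )
    elif free_total >= 1:
        verdict = "partial_agonist"
        rationale.append(
            f"R2: free cationic attraction near {p_star} persists but the "
            "bridging cluster is incomplete; the phosphate is more attached "
            "to the TLR4 side than to TLR4*"
        )
    elif net_star <= 0 and anions_b_other >= 1:
        verdict = "antagonist"
        rationale.append(
            f"R3: no free cation holds {p_star} (net {net_star:+d}) and "
            f"{anions_b_other} free chain-b anion(s) repel {p_other}; "
            "dimerization is not enabled"
        )
    else:
        verdict = "indeterminate"
        rationale.append("R4: no rule matched")
    if lip_anion:
        rationale.append(
            "MD-2 lip glutamate (position-122 homolog) supports the upward "
            "phosphate shift (evidence only)"
        )
    evidence = {
        "p_star": p_star,
        "pag_net_score": net_star,
        "free_b_cations": free_b,
        "free_a_cations": free_a,
        "free_c_cations": free_c,
        "free_b_anions_other": anions_b_other,
        "pan_lip_anion": lip_anion,
        "orientation": orientation,
        "fa1_toward_pag": _fa1_toward_pag(lig, w),
        "corner_P1": corner1,
        "corner_P2": corner2,
    }
    return ActivityCall(
        species=species, ligand=ligand_name, verdict=verdict,
        evidence=evidence, rationale=rationale, extrapolated=extrapolated,
    )


def species_panel(
    models: Mapping[str, tuple[StructureModel, LigandPose]]
    | Iterable[tuple[str, StructureModel, LigandPose]],
    anchors: Mapping[str, Mapping[str, list[tuple[str, int]]]] | None = None,
    ligand_name: str = "lipidIVA",
    rules: ClassifyConfig = DEFAULT_RULES,
    config: InteractionConfig = DEFAULT_CONFIG,
) -> list[ActivityCall]:
    """One activity call per species model.

    ``anchors`` supplies per-species wedge anchor selections (defaults to
    the built-in per-species anchor table). Canine calls are labeled
    extrapolated: that species rests on a theoretical MD-2 record and has
    no column in the residue tables.
    """
    from wedgemap.synthetic_data import DEFAULT_ANCHORS
    from wedgemap.wedge import define_wedge

    if isinstance(models, Mapping):
        items = list(models.items())
        entries = [(sp, m, l) for sp, (m, l) in items]
    else:
        entries = list(models)
    seen = set()
    for sp, _, _ in entries:
        if sp in seen:
            raise ClassifyError(f"duplicate species key {sp!r}")
        seen.add(sp)
    anchors = anchors or DEFAULT_ANCHORS
    calls = []
    for sp, m, lig in entries:
        anchor = anchors.get(sp)
        if anchor is None:
            raise ClassifyError(f"no wedge anchors known for species {sp!r}")
        w = define_wedge(m, anchor)
        report = phosphate_environment(m, lig, config=config)
        calls.append(call_activity(
            report, w, lig, m=m, species=sp, ligand_name=ligand_name,
            rules=rules, extrapolated=(sp == "canine"),
        ))
    return calls


def panel_to_tsv(calls: Iterable[ActivityCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tligand\tverdict\textrapolated\tfree_b\tfree_a\t"
                 "free_c\tnet\tlip_anion\torientation\n")
        for c in calls:
            e = c.evidence
            fh.write(
                f"{c.species}\t{c.ligand}\t{c.verdict}\t{int(c.extrapolated)}\t"
                f"{e.get('free_b_cations')}\t{e.get('free_a_cations')}\t"
                f"{e.get('free_c_cations')}\t{e.get('pag_net_score')}\t"
                f"{int(bool(e.get('pan_lip_anion')))}\t{e.get('orientation')}\n"
            )


def panel_to_json(calls: Iterable[ActivityCall], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([c.to_dict() for c in calls], indent=2) + "\n"
    )
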