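"""Substrate-specificity rules read off the core alignment.

Two rules are applied to template-annotated motif positions (never to
regex scans of the raw sequence):

* The DFG+1 rule for aminoglycoside kinases: an acidic residue (Asp, the
  observed case, or Glu by charge-class extrapolation) immediately after
  the magnesium-binding DFG motif marks an APH2-type enzyme, whose
  substrates present hydroxyl/amine groups in the order OH-NH2-OH from
  the phosphorylatable hydroxyl; a basic residue (Arg observed, Lys by
  extrapolation) marks APH3 with the OH-OH-NH2 order.  Anything else is
  unassigned.  Calls made through the E/K extrapolation are flagged.

* Catalytic-loop basic-residue scanning: protein-substrate kinases keep a
  Lys/Arg in the catalytic loop; a His there (as in the UbiB group) is a
  weaker hint of peptide phosphorylation capability; small-molecule
  kinases generally have neither.
"""
from __future__ import annotations

from dataclasses import dataclass

from .alphabet import GAP
from .core import CoreAlignment
from .hieralign import TemplateAlignment

APH2_MOTIF = "OH-NH2-OH"
APH3_MOTIF = "OH-OH-NH2"

# Motif names expected in the template annotation.
MOTIF_NAMES = (
    "g_rich_loop",
    "beta3_lysine",
    "c_helix_glutamate",
    "catalytic_loop",
    "dfg_region",
)


@dataclass
class MotifHit:
    """Residues of one annotated motif in one core-aligned sequence."""

    name: str
    span: tuple[int, int]  # 0-based inclusive core columns
    residues: str  # verbatim, with '-' at gapped columns
    seq_id: str
    complete: bool


@dataclass
class APHCall:
    seq_id: str
    dfg_region: str
    dfg_plus1: str
    label: str  # APH2 | APH3 | unassigned
    substrate_motif: str  # OH-NH2-OH | OH-OH-NH2 | none
    extrapolated: bool = False


def locate_motifs(
    row: str, seq_id: str, template: TemplateAlignment
) -> list[MotifHit]:
    """Extract annotated motif residues from a core-aligned row."""
    if not template.motifs:
        raise ValueError("template carries no motif annotations")
    hits = []
    for name, (start, end) in template.motifs.items():
        if not (0 <= start <= end < len(row)):
            raise ValueError(f"motif {name!r} span outside core columns")
        residues = row[start : end + 1]
        hits.append(
            MotifHit(
                name=name,
                span=(start, end),
                residues=residues,
                seq_id=seq_id,
                complete=GAP not in residues,
            )
        )
    return hits


def classify_aph(dfg_region: str) -> APHCall:
    """Classify by the DFG+1 residue of a 4-residue DFG-region motif.

    DFG+1 in {D, E} → APH2 / OH-NH2-OH; in {R, K} → APH3 / OH-OH-NH2;
    otherwise unassigned.  The E and K calls extrapolate the observed
    D/R conservation to charge classes and are flagged as such.
    """
    if len(dfg_region) != 4:
        raise ValueError("DFG-region motif must be exactly 4 residues")
    plus1 = dfg_region[3]
    if plus1 in "DE":
        label, motif = "APH2", APH2_MOTIF
    elif plus1 in "RK":
        label, motif = "APH3", APH3_MOTIF
    else:
        label, motif = "unassigned", "none"
    return APHCall(
        seq_id="",
        dfg_region=dfg_region,
        dfg_plus1=plus1,
        label=label,
        substrate_motif=motif,
        extrapolated=plus1 in "EK",
    )


def catalytic_loop_basic(hit: MotifHit) -> str:
    """Basic-residue flag for a catalytic-loop hit.

    Lys or Arg anywhere in the loop → ``basic-KR``; else His →
    ``basic-H``; else ``none``.  An incomplete hit is an error.
    """
    if hit.name != "catalytic_loop":
        raise ValueError("expected a catalytic-loop hit")
    if not hit.complete:
        raise ValueError("catalytic-loop hit is incomplete (gapped)")
    if any(r in "KR" for r in hit.residues):
        return "basic-KR"
    if "H" in hit.residues:
        return "basic-H"
    return "none"


def annotate_superfamily(
    master: CoreAlignment,
    assignments: dict[str, str] | None,
    template: TemplateAlignment,
) -> list[dict]:
    """Per-sequence annotation table: group, APH call, catalytic-loop flag.

    Motif annotations are independent of the partitioning stage: a
    sequence without a group assignment still receives them.
    """
    assignments = assignments or {}
    rows = []
    for i, sid in enumerate(master.ids):
        row = master.rows[i]
        hits = {h.name: h for h in locate_motifs(row, sid, template)}
        dfg = hits.get("dfg_region")
        if dfg is not None and dfg.complete:
            call = classify_aph(dfg.residues)
            call.seq_id = sid
        else:
            call = APHCall(
                sid,
                dfg.residues if dfg else "",
                "-",
                "unassigned",
                "none",
            )
        loop = hits.get("catalytic_loop")
        loop_flag = (
            catalytic_loop_basic(loop)
            if loop is not None and loop.complete
            else "incomplete"
        )
        rows.append(
            {
                "seq_id": sid,
                "group": assignments.get(sid, "-"),
                "dfg_region": call.dfg_region or "-",
                "dfg_plus1": call.dfg_plus1,
                "aph_class": call.label,
                "substrate_motif": call.substrate_motif,
                "cat_loop_flag": loop_flag,
                "extrapolated_flag": int(call.extrapolated),
            }
        )
    return rows


def write_annotation_table(rows: list[dict], path) -> None:
    cols = [
        "seq_id",
        "group",
        "dfg_region",
        "dfg_plus1",
        "aph_class",
        "substrate_motif",
        "cat_loop_flag",
        "extrapolated_flag",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")
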