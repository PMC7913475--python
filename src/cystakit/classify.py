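"""Rule-based assignment of annotated cystatins to subfamily subtypes.

The decision procedure codifies the structural definitions of the
subfamilies: type 2 cystatins are secreted (signal peptide), disulfide
bonded, carry a cystatin-class second-hairpin pair and lack the stefin
D-x-L-x-Y-F carboxy terminus; classical stefins are intracellular
(no signal peptide, no bridges) with a stefin-class pair and the C-terminal
motif; atypical stefins are the chimeric subtype — stefin-class pair,
missing C-terminal motif — without (type 1) or with (type 2) a signal
peptide. Sequences with contradictory features are reported unclassified
with the failing criteria in the rule trace rather than forced to a guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core_io import CHARACTERS, InputError, PresenceMatrix
from .features import StructuralFeatures
from .motifs import classify_pair

LABELS = (
    "classical_stefin",
    "atypical_stefin_type1",
    "atypical_stefin_type2",
    "type2_cystatin",
    "unclassified",
)

#: Subtype label -> repertoire character family.
LABEL_FAMILY = {
    "classical_stefin": "stefin",
    "atypical_stefin_type1": "atypical_stefin",
    "atypical_stefin_type2": "atypical_stefin",
    "type2_cystatin": "type2_cystatin",
}


@dataclass
class SubtypeCall:
    """Classifier verdict with the ordered fired-rule trace."""

    record_id: str
    label: str
    rule_trace: list[str]
    notes: str = ""

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label != "unclassified" and not self.rule_trace:
            raise ValueError("non-unclassified call requires a rule trace")


def classify(f: StructuralFeatures) -> SubtypeCall:
    """Pure function from a feature vector to a subtype call.

    Decision order: (1) type 2 cystatin, (2) classical stefin, (3) type 1
    atypical stefin, (4) type 2 atypical stefin, (5) unclassified. The four
    positive rules are mutually exclusive by construction: (1) requires a
    cystatin-class pair while (2)-(4) require a stefin-class pair, (2)
    differs from (3)/(4) on the C-terminal motif, and (3)/(4) differ on the
    signal peptide.
    """
    pair = f.motif("hairpin2_pair")
    cterm = f.motif("DxLxYF_cterm")
    pair_class = "absent"
    pair_status = None
    if pair.status != "absent":
        pair_class, pair_status = classify_pair(pair.matched)
    dxlxyf_present = cterm.status != "absent"
    y_present = dxlxyf_present and len(cterm.matched) == 6 and cterm.matched[4] == "Y"
    sp = f.has_signal_peptide
    bridges = f.n_bridges

    trace = [
        f"pair={pair.matched or '-'}({pair_class})",
        f"dxlxyf={'present' if dxlxyf_present else 'absent'}",
        f"signal_peptide={'present' if sp else 'absent'}",
        f"bridges={bridges}",
    ]
    notes_bits = []
    if pair_status == "substituted":
        notes_bits.append(f"hairpin pair substituted ({pair.matched})")
    if dxlxyf_present and cterm.status == "substituted":
        notes_bits.append(
            "C-terminal motif substituted "
            + ("(Y retained)" if y_present else "(Y lost)")
        )
    notes = "; ".join(notes_bits)

    if pair_class == "cystatin_class" and sp and bridges >= 1 and not dxlxyf_present:
        trace.append("rule=type2_cystatin")
        return SubtypeCall(f.record_id, "type2_cystatin", trace, notes)
    if pair_class == "stefin_class" and dxlxyf_present and not sp and bridges == 0:
        trace.append("rule=classical_stefin")
        return SubtypeCall(f.record_id, "classical_stefin", trace, notes)
    if pair_class == "stefin_class" and not dxlxyf_present and not sp and bridges == 0:
        trace.append("rule=atypical_stefin_type1")
        return SubtypeCall(f.record_id, "atypical_stefin_type1", trace, notes)
    if pair_class == "stefin_class" and not dxlxyf_present and sp and bridges == 0:
        trace.append("rule=atypical_stefin_type2")
        return SubtypeCall(f.record_id, "atypical_stefin_type2", trace, notes)

    failing = []
    if pair_class in ("absent", "unassigned"):
        failing.append("hairpin pair unassignable")
    elif pair_class == "cystatin_class":
        if not sp:
            failing.append("cystatin-class pair without signal peptide")
        if bridges == 0:
            failing.append("cystatin-class pair without disulfide bridge")
        if dxlxyf_present:
            failing.append("cystatin-class pair with stefin C-terminal motif")
    else:
        if bridges > 0:
            failing.append("stefin-class pair with disulfide bridge(s)")
    trace.append("rule=unclassified[" + "; ".join(failing) + "]")
    return SubtypeCall(f.record_id, "unclassified", trace, notes)


def repertoire_summary(
    calls: Sequence[SubtypeCall], lineages: Mapping[str, str]
) -> PresenceMatrix:
    """Collapse per-sequence calls into a lineage x gene-type presence matrix.

    Presence is 1 iff at least one call of the label family occurs in the
    lineage (the two atypical subtypes collapse into ``atypical_stefin``).
    Row order follows first appearance in the *lineages* mapping.
    """
    ordered = list(dict.fromkeys(lineages.values()))
    df = pd.DataFrame(0, index=ordered, columns=list(CHARACTERS), dtype=int)
    for call in calls:
        if call.record_id not in lineages:
            raise InputError(f"call {call.record_id!r} carries no lineage tag")
        family = LABEL_FAMILY.get(call.label)
        if family is not None:
            df.loc[lineages[call.record_id], family] = 1
    df.index.name = "lineage"
    return PresenceMatrix(values=df)


def calls_table(calls: Sequence[SubtypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": c.record_id,
                "label": c.label,
                "rule_trace": " | ".join(c.rule_trace),
                "notes": c.notes,
            }
            for c in calls
        ],
        columns=["id", "label", "rule_trace", "notes"],
    )
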