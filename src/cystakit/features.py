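"""Lightweight signal-peptide and disulfide-bridge calls.

The signal-peptide call is a rule-based von Heijne-style heuristic over the
classic tripartite architecture (charged n-region, hydrophobic h-region,
small-residue c-region cleavage site); the disulfide call pairs cysteines
sequentially along the chain, matching the non-crossing bridge topology of
the type 2 cystatin fold. Both are desk-scale approximations: externally
produced annotations can be supplied as a TSV and override the heuristics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core_io import InputError, SequenceRecord, tsv_header
from .motifs import DEFAULT_WINDOWS, MotifHit, MotifWindows, detect_motifs

#: Residues accepted in the hydrophobic h-region core.
HYDROPHOBIC = frozenset("AILMFVWC")
#: Small residues accepted at the -3/-1 cleavage-site positions.
SMALL = frozenset("AGS")

N_REGION_END = 6          # K/R required somewhere in positions [0, 6)
H_REGION_STARTS = range(2, 13)   # hydrophobic run of >=6 starting here
H_RUN = 6
CLEAVAGE_RANGE = range(14, 36)   # candidate cleavage positions (site end)
SEARCH_LIMIT = 40                # nothing beyond the first 40 residues counts
MAX_CLEAVAGE = 60


@dataclass
class StructuralFeatures:
    """Full per-sequence feature vector consumed by the classifier."""

    record_id: str
    has_signal_peptide: bool
    cleavage_pos: int | None
    disulfide_pairs: list[tuple[int, int]]
    motif_hits: list[MotifHit]
    intron_count: int = 0
    source: str = "heuristic"  # heuristic | external

    def __post_init__(self) -> None:
        if self.has_signal_peptide and self.cleavage_pos is None:
            raise InputError(f"{self.record_id}: signal peptide without cleavage position")
        if self.cleavage_pos is not None and self.cleavage_pos > MAX_CLEAVAGE:
            raise InputError(f"{self.record_id}: cleavage position beyond {MAX_CLEAVAGE}")
        if self.intron_count < 0:
            raise InputError(f"{self.record_id}: negative intron count")
        flat = [i for p in self.disulfide_pairs for i in p]
        if len(flat) != len(set(flat)):
            raise InputError(f"{self.record_id}: disulfide pairs reuse a cysteine")

    def motif(self, name: str) -> MotifHit:
        for h in self.motif_hits:
            if h.motif == name:
                return h
        raise KeyError(name)

    @property
    def n_bridges(self) -> int:
        return len(self.disulfide_pairs)


def predict_signal_peptide(seq: SequenceRecord | str) -> tuple[bool, int | None]:
    """Rule-based signal-peptide call.

    Positive iff, within the first 40 residues, all three hold:
    (n) at least one K/R in positions 0-5, (h) a run of >=6 consecutive
    hydrophobic residues starting in positions 2-12, and (c) a small residue
    (A/G/S) at the -3 and -1 positions of some cleavage site in positions
    14-35. The reported cleavage position is the first valid site; sequences
    shorter than 20 residues are negative by construction.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    head = residues[:SEARCH_LIMIT]
    if len(residues) < 20:
        return False, None
    if not any(c in "KR" for c in head[:N_REGION_END]):
        return False, None
    if not any(
        h + H_RUN <= len(head) and all(c in HYDROPHOBIC for c in head[h : h + H_RUN])
        for h in H_REGION_STARTS
    ):
        return False, None
    for c in CLEAVAGE_RANGE:
        if c <= len(head) and head[c - 3] in SMALL and head[c - 1] in SMALL:
            return True, c
    return False, None


def infer_disulfides(
    seq: SequenceRecord | str, qxvxg_end: int
) -> list[tuple[int, int]]:
    """Pair cysteines downstream of the Q-x-V-x-G motif sequentially.

    Pairing is 1st-2nd, 3rd-4th, ... (non-crossing, as in the type 2
    cystatin fold); an odd trailing cysteine is left unpaired with a warning.
    Coordinates are on the sequence as given (use the mature sequence for
    consistency with motif coordinates).
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    cys = [i for i, ch in enumerate(residues) if ch == "C" and i >= qxvxg_end]
    if len(cys) % 2:
        warnings.warn(
            f"odd cysteine count downstream of QxVxG; position {cys[-1]} left unpaired",
            stacklevel=2,
        )
    return [(cys[i], cys[i + 1]) for i in range(0, len(cys) - 1, 2)]


def read_annotations(path: str | Path) -> dict[str, dict]:
    """External annotation overrides (e.g., real SignalP/DISULFIND output).

    TSV columns: id, has_signal_peptide (0/1), cleavage_pos (int or empty),
    disulfide_pairs (semicolon list of ``i-j``).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    out: dict[str, dict] = {}
    for _, row in df.iterrows():
        pairs = []
        for token in str(row.get("disulfide_pairs", "")).split(";"):
            token = token.strip()
            if token:
                i, j = token.split("-")
                pairs.append((int(i), int(j)))
        out[row["id"]] = {
            "has_signal_peptide": row["has_signal_peptide"] in ("1", "true", "True"),
            "cleavage_pos": int(row["cleavage_pos"]) if str(row.get("cleavage_pos", "")).strip() else None,
            "disulfide_pairs": pairs,
        }
    return out


def build_features(
    record: SequenceRecord,
    intron_count: int = 0,
    overrides: Mapping[str, dict] | None = None,
    windows: MotifWindows = DEFAULT_WINDOWS,
) -> StructuralFeatures:
    """Assemble the full feature vector for one protein record.

    The signal-peptide call fixes ``mature_start``; motifs and disulfides are
    then reported on the mature sequence. Entries in *overrides* replace the
    heuristic signal-peptide and disulfide calls for matching record ids.
    """
    if record.moltype != "protein":
        raise InputError(f"record {record.id!r}: feature annotation needs protein input")
    source = "heuristic"
    if overrides and record.id in overrides:
        ov = overrides[record.id]
        has_sp = ov["has_signal_peptide"]
        cleavage = ov["cleavage_pos"]
        pairs = list(ov["disulfide_pairs"])
        source = "external"
    else:
        has_sp, cleavage = predict_signal_peptide(record)
        pairs = None
    mature_start = cleavage if has_sp and cleavage is not None else 0
    hits = detect_motifs(record, mature_start=mature_start, windows=windows)
    if pairs is None:
        qx = next(h for h in hits if h.motif == "QxVxG")
        qx_end = qx.end if h_present(qx) else 0
        mature = record.residues[mature_start:]
        pairs = infer_disulfides(mature, qx_end)
    for i, j in pairs:
        mature = record.residues[mature_start:]
        if not (0 <= i < len(mature) and 0 <= j < len(mature)) or mature[i] != "C" or mature[j] != "C":
            raise InputError(f"{record.id}: disulfide index ({i},{j}) does not point at C")
    return StructuralFeatures(
        record_id=record.id,
        has_signal_peptide=has_sp,
        cleavage_pos=cleavage if has_sp else None,
        disulfide_pairs=pairs,
        motif_hits=hits,
        intron_count=intron_count,
        source=source,
    )


def h_present(hit: MotifHit) -> bool:
    return hit.status != "absent"


def features_table(features: Sequence[StructuralFeatures]) -> pd.DataFrame:
    rows = []
    for f in features:
        pair = f.motif("hairpin2_pair")
        cterm = f.motif("DxLxYF_cterm")
        rows.append(
            {
                "id": f.record_id,
                "has_signal_peptide": int(f.has_signal_peptide),
                "cleavage_pos": "" if f.cleavage_pos is None else f.cleavage_pos,
                "disulfide_pairs": ";".join(f"{i}-{j}" for i, j in f.disulfide_pairs),
                "hairpin2_pair": pair.matched,
                "hairpin2_status": pair.status,
                "dxlxyf_status": cterm.status,
                "intron_count": f.intron_count,
                "source": f.source,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id", "has_signal_peptide", "cleavage_pos", "disulfide_pairs",
            "hairpin2_pair", "hairpin2_status", "dxlxyf_status", "intron_count", "source",
        ],
    )
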