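"""Detection and grading of the conserved cystatin-domain regions.

The cystatin fold presents four regions that contact the target papain-like
protease: a glycine in the N-terminal "trunk", the Q-x-V-x-G consensus of the
first hairpin loop, a two-residue pair in the second hairpin loop (LP in
stefins, PW in type 2 cystatins), and the D-x-L-x-Y-F carboxy terminus that
is specific to classical stefins. Two further conserved residues flank these
landmarks in stefins: a histidine exactly seven residues N-terminal of the
hairpin pair and a lysine exactly eight residues N-terminal of the conserved
C-terminal tyrosine. Both offsets are measured on the ungapped mature
sequence (alignment-free operation).

All coordinates reported here are 0-based half-open on the *mature* protein
(the sequence downstream of ``mature_start``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Align import substitution_matrices

from .core_io import InputError, SequenceRecord

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

MOTIF_NAMES = (
    "G_trunk",
    "QxVxG",
    "hairpin2_pair",
    "DxLxYF_cterm",
    "H_minus7",
    "K_minus8",
)

#: Second-hairpin pair catalogue. Canonical pairs define the two subfamilies;
#: the substituted sets collect the lineage-specific replacements observed in
#: early-emerging metazoans (sponges, ctenophores, cnidarians, myxozoans).
STEFIN_CANONICAL = frozenset({"LP"})
CYSTATIN_CANONICAL = frozenset({"PW"})
STEFIN_SUBSTITUTED = frozenset({"LD", "LS", "LY", "LR", "FK", "SA", "FD", "FS", "FA", "LK"})
CYSTATIN_SUBSTITUTED = frozenset({"AW", "RW", "SW", "KF", "GW", "PF", "PL"})

CANONICAL_PAIRS = STEFIN_CANONICAL | CYSTATIN_CANONICAL
CATALOGUE_PAIRS = CANONICAL_PAIRS | STEFIN_SUBSTITUTED | CYSTATIN_SUBSTITUTED

MIN_MATURE_LENGTH = 30


@dataclass(frozen=True)
class MotifWindows:
    """Search windows (decisions, config-exposed; positions on the mature seq).

    trunk_len: the N-terminal stretch scanned for the trunk glycine.
    hairpin_min/max: offset range of the second-hairpin pair start downstream
    of the Q-x-V-x-G glycine. cterm_len: C-terminal stretch scanned for the
    D-x-L-x-Y-F motif.
    """

    trunk_len: int = 10
    hairpin_min: int = 15
    hairpin_max: int = 30
    cterm_len: int = 12


DEFAULT_WINDOWS = MotifWindows()


@dataclass
class MotifHit:
    """One located conserved-region match (or its recorded absence)."""

    motif: str
    start: int | None
    end: int | None
    matched: str
    status: str  # canonical | substituted | absent

    def __post_init__(self) -> None:
        if self.status not in ("canonical", "substituted", "absent"):
            raise ValueError(f"bad motif status {self.status!r}")
        if self.status != "absent" and (self.start is None or self.end is None):
            raise ValueError(f"{self.motif}: non-absent hit requires coordinates")

    @property
    def present(self) -> bool:
        return self.status != "absent"


def classify_pair(matched: str) -> tuple[str, str | None]:
    """Assign a second-hairpin pair to a subfamily class.

    Returns ``(class, status)`` where class is ``stefin_class``,
    ``cystatin_class`` or ``unassigned`` and status is ``canonical``,
    ``substituted`` or None for unassigned pairs.
    """
    if len(matched) != 2:
        raise InputError(f"hairpin pair must be exactly two residues, got {matched!r}")
    if matched in STEFIN_CANONICAL:
        return "stefin_class", "canonical"
    if matched in CYSTATIN_CANONICAL:
        return "cystatin_class", "canonical"
    if matched in STEFIN_SUBSTITUTED:
        return "stefin_class", "substituted"
    if matched in CYSTATIN_SUBSTITUTED:
        return "cystatin_class", "substituted"
    return "unassigned", None


def has_qxvxg(residues: str) -> bool:
    """Quick grammar check used by the combined-search pre-filter."""
    return any(
        residues[i] == "Q" and residues[i + 2] == "V" and residues[i + 4] == "G"
        for i in range(len(residues) - 4)
    )


def _pair_similarity(pair: str) -> float:
    """BLOSUM62 similarity of a pair to the nearest canonical pair."""
    return max(
        float(_BLOSUM62[pair[0], ref[0]] + _BLOSUM62[pair[1], ref[1]])
        for ref in CANONICAL_PAIRS
    )


def _absent(motif: str) -> MotifHit:
    return MotifHit(motif=motif, start=None, end=None, matched="", status="absent")


def detect_motifs(
    seq: SequenceRecord | str,
    mature_start: int = 0,
    windows: MotifWindows = DEFAULT_WINDOWS,
) -> list[MotifHit]:
    """Locate the six conserved cystatin regions on one protein sequence.

    ``mature_start`` is 0 for sequences without a signal peptide, otherwise
    the cleavage position; reported coordinates are relative to the mature
    sequence, which makes them invariant to prepending a signal peptide.
    Returns exactly one hit per motif name (absent motifs included with
    ``status='absent'``).
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if mature_start >= len(residues):
        raise InputError("mature_start beyond sequence end")
    mature = residues[mature_start:]
    n = len(mature)
    if n < MIN_MATURE_LENGTH:
        raise InputError(
            f"mature sequence of length {n} is shorter than {MIN_MATURE_LENGTH}; "
            "cystatin domain cannot be annotated"
        )
    hits: dict[str, MotifHit] = {}

    # (i) glycine in the N-terminal trunk
    g_pos = mature.find("G", 0, windows.trunk_len)
    if g_pos >= 0:
        hits["G_trunk"] = MotifHit("G_trunk", g_pos, g_pos + 1, "G", "canonical")
    else:
        hits["G_trunk"] = _absent("G_trunk")

    # (ii) first-hairpin Q-x-V-x-G, first match downstream of the trunk
    search_from = g_pos + 1 if g_pos >= 0 else 0
    qx = None
    for i in range(search_from, n - 4):
        if mature[i] == "Q" and mature[i + 2] == "V" and mature[i + 4] == "G":
            qx = i
            break
    if qx is not None:
        hits["QxVxG"] = MotifHit("QxVxG", qx, qx + 5, mature[qx : qx + 5], "canonical")
    else:
        hits["QxVxG"] = _absent("QxVxG")

    # (iii) second-hairpin pair, 15-30 residues downstream of the QxVxG glycine
    pair_hit = _absent("hairpin2_pair")
    if qx is not None:
        g_anchor = qx + 4
        lo = g_anchor + windows.hairpin_min
        hi = min(g_anchor + windows.hairpin_max, n - 2)
        canonical_at = None
        candidates: list[tuple[int, float]] = []  # (start, similarity score)
        for s in range(lo, hi + 1):
            pair = mature[s : s + 2]
            if pair in CANONICAL_PAIRS and canonical_at is None:
                canonical_at = s
            if pair in CATALOGUE_PAIRS:
                candidates.append((s, _pair_similarity(pair)))
        if canonical_at is not None:
            chosen = canonical_at
        elif candidates:
            # leftmost substituted candidate wins; a cluster of mutually
            # overlapping candidates (one spurious pair sharing a residue
            # with the real one) is arbitrated by BLOSUM62 similarity to a
            # canonical pair, ties to the leftmost
            cluster = [candidates[0]]
            for s, score in candidates[1:]:
                if s <= cluster[-1][0] + 1:
                    cluster.append((s, score))
                else:
                    break
            chosen = max(cluster, key=lambda c: (c[1], -c[0]))[0]
        else:
            chosen = None
        if chosen is not None:
            pair = mature[chosen : chosen + 2]
            status = "canonical" if pair in CANONICAL_PAIRS else "substituted"
            pair_hit = MotifHit("hairpin2_pair", chosen, chosen + 2, pair, status)
    hits["hairpin2_pair"] = pair_hit

    # conserved histidine exactly 7 residues before the hairpin pair
    if pair_hit.present and pair_hit.start - 7 >= 0:
        p = pair_hit.start - 7
        hits["H_minus7"] = MotifHit(
            "H_minus7", p, p + 1, mature[p],
            "canonical" if mature[p] == "H" else "substituted",
        )
    else:
        hits["H_minus7"] = _absent("H_minus7")

    # (iv) D-x-L-x-Y-F carboxy terminus within the final residues
    cterm = _absent("DxLxYF_cterm")
    best: tuple[int, int] | None = None  # (-matches, start)
    lo = max(0, n - windows.cterm_len)
    for s in range(lo, n - 5):
        window = mature[s : s + 6]
        d_ok = window[0] == "D"
        l_ok = window[2] == "L"
        y_ok = window[4] == "Y"
        f_ok = window[5] == "F"
        matches = d_ok + l_ok + y_ok + f_ok
        if best is None or -matches < best[0]:
            best = (-matches, s)
    if best is not None:
        s = best[1]
        window = mature[s : s + 6]
        d_ok, l_ok, y_ok, f_ok = (
            window[0] == "D", window[2] == "L", window[4] == "Y", window[5] == "F",
        )
        if d_ok and l_ok and y_ok and f_ok:
            cterm = MotifHit("DxLxYF_cterm", s, s + 6, window, "canonical")
        elif y_ok or (d_ok and l_ok):
            # partial match: present-but-substituted when the tyrosine is in
            # place, or when the D/L anchors hold with a varied tyrosine
            cterm = MotifHit("DxLxYF_cterm", s, s + 6, window, "substituted")
    hits["DxLxYF_cterm"] = cterm

    # conserved lysine exactly 8 residues before the C-terminal tyrosine
    if cterm.present and cterm.start + 4 - 8 >= 0:
        p = cterm.start + 4 - 8
        hits["K_minus8"] = MotifHit(
            "K_minus8", p, p + 1, mature[p],
            "canonical" if mature[p] == "K" else "substituted",
        )
    else:
        hits["K_minus8"] = _absent("K_minus8")

    return [hits[name] for name in MOTIF_NAMES]


def detect_motifs_on_alignment(
    aln_row: str,
    mature_start: int = 0,
    windows: MotifWindows = DEFAULT_WINDOWS,
) -> list[MotifHit]:
    """Alignment-anchored mode: annotate an ungapped row, then report hit
    coordinates as alignment columns."""
    ungapped = aln_row.replace("-", "")
    hits = detect_motifs(ungapped, mature_start=mature_start, windows=windows)
    # map ungapped mature index -> alignment column
    cols = [j for j, ch in enumerate(aln_row) if ch != "-"]
    mapped = []
    for h in hits:
        if not h.present:
            mapped.append(h)
            continue
        start = cols[mature_start + h.start]
        end = cols[mature_start + h.end - 1] + 1
        mapped.append(replace(h, start=start, end=end))
    return mapped


def substitution_table(
    annotated: Sequence[tuple[SequenceRecord, Sequence[MotifHit]]],
    group_by: str = "lineage",
) -> pd.DataFrame:
    """Tabulate observed motif variants per taxon group.

    Rows are (group, motif, variant, count), ordered lexicographically;
    absent motifs are counted under the variant ``<absent>``.
    """
    counts: dict[tuple[str, str, str], int] = {}
    for record, hits in annotated:
        if not hits:
            raise InputError(f"record {record.id!r} lacks motif annotation")
        group = getattr(record, group_by) or ""
        for h in hits:
            variant = h.matched if h.present else "<absent>"
            key = (group, h.motif, variant)
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {"group": g, "motif": m, "variant": v, "count": c}
        for (g, m, v), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["group", "motif", "variant", "count"])


def motifs_table(annotated: Sequence[tuple[SequenceRecord, Sequence[MotifHit]]]) -> pd.DataFrame:
    """Flat per-sequence motif TSV: id, motif, start, end, matched, status."""
    rows = []
    for record, hits in annotated:
        for h in hits:
            rows.append(
                {
                    "id": record.id,
                    "motif": h.motif,
                    "start": "" if h.start is None else h.start,
                    "end": "" if h.end is None else h.end,
                    "matched": h.matched,
                    "status": h.status,
                }
            )
    return pd.DataFrame(rows, columns=["id", "motif", "start", "end", "matched", "status"])
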