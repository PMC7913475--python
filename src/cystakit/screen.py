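"""Translated homology screen: a small stand-in for a tBLASTn-style mining loop.

Nucleotide subjects are translated in all six reading frames and scanned
against protein queries with a Smith-Waterman local alignment (BLOSUM62,
affine gaps). Hits are filtered either by an approximate Karlin-Altschul
E-value or by a raw-score cutoff, and accepted subject regions can be fed
back as additional queries until a fixpoint is reached (iterative query
expansion).

The E-value uses the ungapped BLOSUM62 constants (lambda=0.267, K=0.041) and
is a filter, not a statistical claim: the classic 1e-5 cutoff is
database-size dependent, so a raw-score threshold is offered as an
alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .core_io import InputError, SequenceRecord

BLOSUM62 = substitution_matrices.load("BLOSUM62")

#: Ungapped Karlin-Altschul constants for BLOSUM62.
KA_LAMBDA = 0.267
KA_K = 0.041

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_EVALUE = 1e-5

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass
class ScreenHit:
    """One retained query/subject local-alignment hit.

    Coordinates are 0-based half-open on the translated subject frame (or the
    protein subject itself when ``frame`` is None).
    """

    query_id: str
    subject_id: str
    frame: int | None
    raw_score: int
    bit_score: float
    approx_evalue: float
    subject_start: int
    subject_end: int


def translate_six_frames(dna: SequenceRecord) -> list[SequenceRecord]:
    """Translate a nucleotide record in all six frames (standard code).

    Stop codons are rendered as ``*``; trailing partial codons are dropped;
    reverse frames read the reverse complement.
    """
    if dna.moltype != "dna":
        raise InputError(f"record {dna.id!r}: six-frame translation needs dna input")
    if len(dna.residues) < 3:
        raise InputError(f"record {dna.id!r}: sequence shorter than one codon")
    fwd = Seq(dna.residues)
    rev = fwd.reverse_complement()
    out = []
    for frame in FRAMES:
        src = fwd if frame > 0 else rev
        off = abs(frame) - 1
        trimmed = src[off : off + (len(src) - off) // 3 * 3]
        aa = str(trimmed.translate())
        if not aa:
            continue
        out.append(
            SequenceRecord(
                id=f"{dna.id}|frame{frame:+d}",
                residues=aa,
                moltype="protein",
                description=f"frame {frame:+d} of {dna.id}",
                taxon=dna.taxon,
                lineage=dna.lineage,
            )
        )
    return out


def _pair_score(a: str, b: str) -> float:
    try:
        return BLOSUM62[a, b]
    except (KeyError, IndexError) as exc:
        raise InputError(f"illegal residue in alignment input: {a!r}/{b!r}") from exc


def local_align(
    a: str,
    b: str,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> tuple[int, tuple[int, int], tuple[int, int]]:
    """Smith-Waterman optimum with affine gaps (Gotoh recurrences).

    A gap of length L costs ``gap_open + L * gap_extend``. Returns
    ``(raw_score, a_span, b_span)`` with 0-based half-open spans attaining
    the score. Ties among equal-scoring optima are broken toward the smallest
    subject (``b``) start, then the shortest subject span, then the smallest
    query start. A score of 0 yields empty spans.
    """
    if not a or not b:
        raise InputError("local_align requires two non-empty sequences")
    m, n = len(a), len(b)
    neg = float("-inf")
    open_cost = gap_open + gap_extend
    # H: best local alignment ending at (i, j); E: ending with gap in a
    # (consuming b); F: ending with gap in b (consuming a).
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[neg] * (n + 1) for _ in range(m + 1)]
    F = [[neg] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    ends: list[tuple[int, int]] = []
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + _pair_score(ai, b[j - 1])
            h = max(0.0, diag, E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best = h
                ends = [(i, j)]
            elif h == best and h > 0:
                ends.append((i, j))
    if best <= 0:
        return 0, (0, 0), (0, 0)

    def trace(i: int, j: int) -> tuple[int, int]:
        """Walk one optimal path back to its origin (deterministic choices)."""
        state = "H"
        while True:
            if state == "H":
                h = H[i][j]
                if h == 0:
                    return i, j
                diag = H[i - 1][j - 1] + _pair_score(a[i - 1], b[j - 1])
                if h == diag:
                    i, j = i - 1, j - 1
                elif h == F[i][j]:
                    state = "F"
                else:
                    state = "E"
            elif state == "F":
                if F[i][j] == H[i - 1][j] - open_cost:
                    i, state = i - 1, "H"
                else:
                    i = i - 1
            else:
                if E[i][j] == H[i][j - 1] - open_cost:
                    j, state = j - 1, "H"
                else:
                    j = j - 1

    candidates = []
    for i_end, j_end in ends:
        i0, j0 = trace(i_end, j_end)
        candidates.append((j0, j_end - j0, i0, (i0, i_end), (j0, j_end)))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    _, _, _, a_span, b_span = candidates[0]
    return int(best), a_span, b_span


def bit_score(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2)


def approx_evalue(raw_score: float, m: int, n: int) -> float:
    """Karlin-Altschul E = K*m*n*exp(-lambda*S) with fixed ungapped constants."""
    return KA_K * m * n * math.exp(-KA_LAMBDA * raw_score)


def _subject_frames(subject: SequenceRecord) -> list[SequenceRecord]:
    if subject.moltype == "dna":
        return translate_six_frames(subject)
    return [subject]


def _best_hit(query: SequenceRecord, subject: SequenceRecord) -> ScreenHit | None:
    """Best-scoring frame for one query/subject pair (no thresholding)."""
    best: ScreenHit | None = None
    for frame_rec in _subject_frames(subject):
        frame = None
        if "|frame" in frame_rec.id:
            frame = int(frame_rec.id.rsplit("|frame", 1)[1])
        score, _, b_span = local_align(query.residues, frame_rec.residues)
        hit = ScreenHit(
            query_id=query.id,
            subject_id=subject.id,
            frame=frame,
            raw_score=score,
            bit_score=bit_score(score),
            approx_evalue=approx_evalue(score, len(query.residues), len(frame_rec.residues)),
            subject_start=b_span[0],
            subject_end=b_span[1],
        )
        if best is None or hit.raw_score > best.raw_score:
            best = hit
    return best


def _region_record(subject: SequenceRecord, hit: ScreenHit) -> SequenceRecord:
    """Accepted subject region, translated, for query expansion."""
    frames = {f.id: f for f in _subject_frames(subject)}
    key = subject.id if hit.frame is None else f"{subject.id}|frame{hit.frame:+d}"
    src = frames[key]
    region = src.residues[hit.subject_start : hit.subject_end]
    return SequenceRecord(
        id=f"{subject.id}|region{hit.subject_start}-{hit.subject_end}",
        residues=region,
        moltype="protein",
        description=f"hit region of {subject.id}",
    )


def screen(
    queries: Sequence[SequenceRecord],
    subjects: Sequence[SequenceRecord],
    evalue_cutoff: float = DEFAULT_EVALUE,
    iterate: bool = True,
    score_cutoff: int | None = None,
) -> list[ScreenHit]:
    """Screen subjects against protein queries; optionally expand queries.

    A hit is retained when its raw score is positive and it passes the
    E-value cutoff (or ``score_cutoff`` when given). With ``iterate`` the
    accepted subject regions are appended to the query set and screening
    repeats until no new subject gains a hit; the fixpoint is reached in at
    most ``len(subjects)`` rounds.
    """
    if not queries:
        raise InputError("screen requires at least one query")
    if not subjects:
        raise InputError("screen requires a non-empty subject set")
    for q in queries:
        if q.moltype != "protein":
            raise InputError(f"query {q.id!r} must be protein")

    def accepted(hit: ScreenHit) -> bool:
        if hit.raw_score <= 0:
            return False
        if score_cutoff is not None:
            return hit.raw_score >= score_cutoff
        return hit.approx_evalue <= evalue_cutoff

    hits: dict[tuple[str, str], ScreenHit] = {}
    active_queries = list(queries)
    expanded: set[str] = set()
    subjects_by_id = {s.id: s for s in subjects}
    for _round in range(len(subjects) + 1):
        new_subject_hit = False
        for q in active_queries:
            for s in subjects:
                key = (q.id, s.id)
                if key in hits:
                    continue
                hit = _best_hit(q, s)
                if hit is not None and accepted(hit):
                    if not any(sid == s.id for _, sid in hits):
                        new_subject_hit = True
                    hits[key] = hit
        if not iterate:
            break
        grew = False
        for (_qid, sid), hit in sorted(hits.items()):
            if sid not in expanded:
                expanded.add(sid)
                active_queries.append(_region_record(subjects_by_id[sid], hit))
                grew = True
        if not grew and not new_subject_hit:
            break
    return sorted(hits.values(), key=lambda h: (h.subject_id, h.query_id, -h.raw_score))


def combined_candidates(
    queries: Sequence[SequenceRecord],
    subjects: Sequence[SequenceRecord],
    **screen_kwargs,
) -> set[str]:
    """Union of similarity-based hits and motif-grammar pre-filter matches.

    A subject passes the motif pre-filter when some reading frame carries the
    cystatin first-hairpin Q-x-V-x-G consensus; union semantics mirror a
    combined motif + similarity search strategy.
    """
    from .motifs import has_qxvxg  # local import: motifs does not import screen

    by_similarity = {h.subject_id for h in screen(queries, subjects, **screen_kwargs)}
    by_motif = {
        s.id
        for s in subjects
        if any(has_qxvxg(f.residues) for f in _subject_frames(s))
    }
    return by_similarity | by_motif


def hits_table(hits: Iterable[ScreenHit]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "query_id": h.query_id,
                "subject_id": h.subject_id,
                "frame": "" if h.frame is None else f"{h.frame:+d}",
                "raw_score": h.raw_score,
                "bit_score": round(h.bit_score, 3),
                "approx_evalue": f"{h.approx_evalue:.3e}",
                "subject_start": h.subject_start,
                "subject_end": h.subject_end,
            }
            for h in hits
        ],
        columns=[
            "query_id", "subject_id", "frame", "raw_score", "bit_score",
            "approx_evalue", "subject_start", "subject_end",
        ],
    )
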