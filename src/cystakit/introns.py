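"""Reconcile genomic DNA with cDNA to locate spliceosomal introns.

The cDNA must be reconstructable from the genomic sequence by excising
internal blocks (introns). The mapper finds the splicing with the minimal
number of introns; when repeated nucleotides make an exon/intron boundary
ambiguous (the junction can slide), the placement maximizing canonical
GT...AG junctions is preferred, then the leftmost. Non-canonical junctions
are flagged, not rejected. Exactness is the default (mismatches between
exon and cDNA abort with a diagnostic); a mismatch budget is available for
real data with sequencing noise.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import pandas as pd

from .core_io import Alignment, InputError, SequenceRecord

#: Smallest accepted intron (room for the GT and AG dinucleotides).
MIN_INTRON_LENGTH = 4


@dataclass
class Intron:
    genomic_start: int
    genomic_end: int
    donor: str
    acceptor: str
    cdna_insertion_point: int
    phase: int
    canonical: bool


@dataclass
class IntronMap:
    """Exon/intron coordinates reconciling one genomic sequence with its cDNA."""

    gene_id: str
    introns: list[Intron]
    exons: list[tuple[int, int]]

    @property
    def intron_count(self) -> int:
        return len(self.introns)

    def splice(self, genomic: str) -> str:
        """Concatenate the exon blocks (must reproduce the cDNA exactly)."""
        return "".join(genomic[s:e] for s, e in self.exons)


def map_introns(
    genomic: SequenceRecord,
    cdna: SequenceRecord,
    min_intron: int = MIN_INTRON_LENGTH,
    max_mismatch: int = 0,
    cds_offset: int = 0,
) -> IntronMap:
    """Locate the minimal set of introns turning *genomic* into *cdna*.

    Phase is the position of the insertion point within its codon
    (``(insertion - cds_offset) % 3``). Raises with a longest-matching-prefix
    diagnostic when the cDNA cannot be reconstructed.
    """
    if genomic.moltype != "dna" or cdna.moltype != "dna":
        raise InputError("map_introns requires dna records")
    g, c = genomic.residues, cdna.residues
    if len(g) < len(c):
        raise InputError(
            f"{genomic.id}: genomic sequence shorter than cDNA ({len(g)} < {len(c)})"
        )
    D = len(g) - len(c)
    n_c = len(c)
    best_progress = 0

    def extension(j: int, d: int, mm_budget: int) -> list[tuple[int, int]]:
        """(t, mismatches) checkpoints walking c[j:] against g[j+d:]."""
        out = [(0, 0)]
        mm = 0
        t = 0
        while j + t < n_c:
            if c[j + t] != g[j + d + t]:
                mm += 1
                if mm > mm_budget:
                    break
            t += 1
            out.append((t, mm))
        return out

    sys.setrecursionlimit(10000)

    @lru_cache(maxsize=None)
    def solve(j: int, d: int, mm_used: int):
        """Best completion from cdna position j with cumulative intron length d.

        Returns (n_introns, -n_canonical, starts_tuple, introns_tuple) or None.
        """
        nonlocal best_progress
        best = None
        for t, mm in extension(j, d, max_mismatch - mm_used):
            best_progress = max(best_progress, j + t)
            if j + t == n_c and d == D:
                cand = (0, 0, (), ())
                if best is None or cand < best:
                    best = cand
                continue
            pos = j + t
            if pos == 0 or pos >= n_c:
                continue  # introns are internal
            gs = pos + d
            nxt = c[pos]
            for glen in range(min_intron, D - d + 1):
                ge = gs + glen
                # prune: after a zero-mismatch continuation the next exon base
                # must match; with a mismatch budget, allow it to mismatch
                if max_mismatch - (mm_used + mm) == 0 and g[ge] != nxt:
                    continue
                sub = solve(pos, d + glen, mm_used + mm)
                if sub is None:
                    continue
                canonical = g[gs : gs + 2] == "GT" and g[ge - 2 : ge] == "AG"
                cand = (
                    sub[0] + 1,
                    sub[1] - (1 if canonical else 0),
                    (gs,) + sub[2],
                    ((gs, ge, pos),) + sub[3],
                )
                if best is None or cand < best:
                    best = cand
        return best

    result = solve(0, 0, 0)
    solve.cache_clear()
    if result is None:
        raise InputError(
            f"{genomic.id}: cDNA not reconstructable from genomic sequence; "
            f"longest reconcilable cDNA prefix is {best_progress} nt"
        )
    introns = []
    for gs, ge, pos in result[3]:
        introns.append(
            Intron(
                genomic_start=gs,
                genomic_end=ge,
                donor=g[gs : gs + 2],
                acceptor=g[ge - 2 : ge],
                cdna_insertion_point=pos,
                phase=(pos - cds_offset) % 3,
                canonical=g[gs : gs + 2] == "GT" and g[ge - 2 : ge] == "AG",
            )
        )
    if any(not i.canonical for i in introns):
        import warnings

        bad = [f"({i.genomic_start},{i.genomic_end})" for i in introns if not i.canonical]
        warnings.warn(f"{genomic.id}: non-canonical junction(s) at {', '.join(bad)}", stacklevel=2)
    exons = []
    prev = 0
    for i in introns:
        exons.append((prev, i.genomic_start))
        prev = i.genomic_end
    exons.append((prev, len(g)))
    return IntronMap(gene_id=genomic.id, introns=introns, exons=exons)


def intron_positions_on_alignment(
    maps: Sequence[IntronMap],
    aln: Alignment,
    cds_offsets: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Project intron insertion points onto protein alignment columns.

    Each insertion point is converted codon -> residue (using the gene's CDS
    offset, default 0) -> alignment column of that residue in the gene's row.
    Introns falling inside a codon keep their phase and are never dropped.
    Output columns: gene, intron ordinal, alignment column, phase; sorted by
    column then gene.
    """
    cds_offsets = cds_offsets or {}
    rows = []
    for imap in maps:
        try:
            gapped = aln.row(imap.gene_id)
        except KeyError:
            raise InputError(f"gene {imap.gene_id!r} absent from alignment") from None
        cols = [j for j, ch in enumerate(gapped) if ch != "-"]
        offset = cds_offsets.get(imap.gene_id, 0)
        for ordinal, intron in enumerate(imap.introns):
            rel = intron.cdna_insertion_point - offset
            residue = rel // 3
            phase = rel % 3
            if residue < 0 or residue >= len(cols):
                raise InputError(
                    f"gene {imap.gene_id!r}: intron insertion at CDS nt {rel} maps "
                    f"outside the aligned protein ({len(cols)} residues)"
                )
            rows.append(
                {
                    "gene": imap.gene_id,
                    "intron_ordinal": ordinal,
                    "alignment_column": cols[residue],
                    "phase": phase,
                }
            )
    df = pd.DataFrame(rows, columns=["gene", "intron_ordinal", "alignment_column", "phase"])
    return df.sort_values(["alignment_column", "gene"], kind="stable").reset_index(drop=True)


def introns_table(maps: Sequence[IntronMap]) -> pd.DataFrame:
    rows = []
    for imap in maps:
        for ordinal, i in enumerate(imap.introns):
            rows.append(
                {
                    "gene": imap.gene_id,
                    "intron_ordinal": ordinal,
                    "genomic_start": i.genomic_start,
                    "genomic_end": i.genomic_end,
                    "donor": i.donor,
                    "acceptor": i.acceptor,
                    "cdna_insertion_point": i.cdna_insertion_point,
                    "phase": i.phase,
                    "canonical": int(i.canonical),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "intron_ordinal", "genomic_start", "genomic_end", "donor",
            "acceptor", "cdna_insertion_point", "phase", "canonical",
        ],
    )


def write_gff3(maps: Sequence[IntronMap], path) -> None:
    """Exon/intron features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for imap in maps:
            for k, (s, e) in enumerate(imap.exons):
                fh.write(
                    f"{imap.gene_id}\tcystakit\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"ID=exon-{imap.gene_id}-{k}\n"
                )
            for k, i in enumerate(imap.introns):
                fh.write(
                    f"{imap.gene_id}\tcystakit\tintron\t{i.genomic_start + 1}\t"
                    f"{i.genomic_end}\t.\t+\t.\tID=intron-{imap.gene_id}-{k}\n"
                )
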