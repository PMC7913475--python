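"""Domain types and file IO: FASTA (plain and gapped), newick trees, TSV matrices.

Conventions used throughout the package:

* All coordinates are 0-based, half-open ``[start, end)``.
* Protein alphabet is the 20 standard amino acids plus ``X``; nucleotide
  alphabet is ``ACGT`` plus ``N``.
* TSV outputs are UTF-8 and carry a single commented header line naming the
  tool version and the run seed.
* Lineage tags are free tokens matched case-insensitively against tree tips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord
from skbio import TreeNode

__version__ = "0.1.0"

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGTN")
GAP = "-"

#: Presence/absence characters tracked in repertoire matrices.
CHARACTERS = ("stefin", "type2_cystatin", "atypical_stefin", "multidomain")

Moltype = Literal["protein", "dna"]


class InputError(ValueError):
    """Raised for malformed or inconsistent input files."""


def tsv_header(seed: int | None = None) -> str:
    """Commented header line written at the top of every TSV output."""
    tag = f"# cystakit {__version__}"
    if seed is not None:
        tag += f" seed={seed}"
    return tag


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """One protein or nucleotide sequence with identity and lineage tags."""

    id: str
    residues: str
    moltype: Moltype = "protein"
    description: str = ""
    taxon: str = ""
    lineage: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence record requires a non-empty id")
        if not self.residues:
            raise InputError(f"record {self.id!r}: empty sequence")
        # in-memory protein records may carry '*' (frame-translation stops);
        # file readers strip stops so loaded records never contain them
        alphabet = PROTEIN_ALPHABET | {"*"} if self.moltype == "protein" else DNA_ALPHABET
        for pos, ch in enumerate(self.residues):
            if ch not in alphabet:
                raise InputError(
                    f"record {self.id!r}: illegal {self.moltype} character "
                    f"{ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """A gapped multiple alignment; rows are (record id, gapped string)."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise InputError("alignment requires at least 2 rows")
        n = len(self.rows[0][1])
        for rid, gapped in self.rows:
            if len(gapped) != n:
                raise InputError(
                    f"alignment row {rid!r} has length {len(gapped)}, expected {n}"
                )
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise InputError("alignment contains duplicate row ids")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        for r, gapped in self.rows:
            if r == rid:
                return gapped
        raise KeyError(rid)

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(gapped[j] for _, gapped in self.rows)


@dataclass
class SpeciesTree:
    """A rooted species tree whose tips host repertoire lineages.

    Thin wrapper around :class:`skbio.TreeNode`; tip labels are matched
    case-insensitively against lineage tokens.
    """

    root: TreeNode

    def __post_init__(self) -> None:
        names = [t.name for t in self.root.tips()]
        if any(n is None for n in names):
            raise InputError("species tree has unlabeled tips")
        lowered = [n.lower() for n in names]
        if len(set(lowered)) != len(lowered):
            raise InputError("species tree tip labels are not unique")
        for node in self.root.traverse():
            if node.length is not None and node.length < 0:
                raise InputError(f"negative branch length on {node.name!r}")

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.root.tips()]

    def match_tip(self, lineage: str) -> str:
        """Resolve a lineage token to the unique tip label (case-insensitive)."""
        hits = [n for n in self.tip_names if n.lower() == lineage.lower()]
        if len(hits) != 1:
            raise InputError(
                f"lineage {lineage!r} maps to {len(hits)} tree tips, expected 1"
            )
        return hits[0]

    def sheared(self, lineages: Sequence[str]) -> "SpeciesTree":
        """Restrict the tree to the given lineages (tips matched loosely)."""
        keep = [self.match_tip(l) for l in lineages]
        return SpeciesTree(self.root.copy().shear(keep))


@dataclass
class PresenceMatrix:
    """Lineage x gene-type presence/absence table (values strictly 0/1)."""

    values: pd.DataFrame  # index: lineages, columns: characters, dtype int

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise InputError("presence matrix has duplicate lineage labels")
        unknown = [c for c in self.values.columns if c not in CHARACTERS]
        if unknown:
            raise InputError(f"unknown character name(s): {unknown}")
        arr = self.values.to_numpy()
        if not ((arr == 0) | (arr == 1)).all():
            raise InputError("presence matrix cells must all be 0 or 1")
        self.values = self.values.astype(int)

    @property
    def lineages(self) -> list[str]:
        return list(self.values.index)

    @property
    def characters(self) -> list[str]:
        return list(self.values.columns)

    def tip_states(self, character: str) -> dict[str, int]:
        """Mapping lineage -> 0/1 for one character column."""
        if character not in self.values.columns:
            raise InputError(f"unknown character {character!r}")
        return {l: int(v) for l, v in self.values[character].items()}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _infer_moltype(residue_pool: str) -> Moltype:
    """dna iff >=90% of characters fall in ACGTN (deterministic, order-free)."""
    if not residue_pool:
        raise InputError("cannot infer moltype from empty input")
    n_dna = sum(1 for c in residue_pool if c in DNA_ALPHABET)
    return "dna" if n_dna / len(residue_pool) >= 0.9 else "protein"


def read_fasta(path: str | Path, moltype: Moltype | None = None) -> list[SequenceRecord]:
    """Read a plain (ungapped) FASTA file into :class:`SequenceRecord` objects.

    Headers are parsed as ``id description``. ``*`` stop characters are
    stripped with a warning; gap characters are rejected. When *moltype* is
    None it is inferred from the pooled residue content of the whole file.
    """
    path = Path(path)
    raw = list(SeqIO.parse(str(path), "fasta"))
    if not raw:
        raise InputError(f"{path}: empty or non-FASTA file")
    seqs = [str(r.seq).upper() for r in raw]
    if any("*" in s for s in seqs):
        warnings.warn(f"{path}: '*' stop characters stripped", stacklevel=2)
        seqs = [s.replace("*", "") for s in seqs]
    for r, s in zip(raw, seqs):
        if GAP in s or "." in s:
            raise InputError(
                f"{path}: record {r.id!r} contains gap characters; "
                "use read_alignment for gapped FASTA"
            )
    if moltype is None:
        moltype = _infer_moltype("".join(seqs))
    records = []
    seen: set[str] = set()
    for r, s in zip(raw, seqs):
        if r.id in seen:
            raise InputError(f"{path}: duplicate record id {r.id!r}")
        seen.add(r.id)
        desc = r.description[len(r.id):].strip() if r.description.startswith(r.id) else r.description
        records.append(SequenceRecord(id=r.id, residues=s, moltype=moltype, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA, wrapping at *wrap* columns."""
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bio)


def read_alignment(path: str | Path) -> Alignment:
    """Read a gapped FASTA alignment; row lengths are verified equal."""
    path = Path(path)
    raw = list(SeqIO.parse(str(path), "fasta"))
    if not raw:
        raise InputError(f"{path}: empty or non-FASTA file")
    rows = [(r.id, str(r.seq).upper()) for r in raw]
    return Alignment(rows=rows)


def write_alignment(aln: Alignment, path: str | Path, wrap: int = 60) -> None:
    bio = [_BioRecord(Seq(g), id=rid, description="") for rid, g in aln.rows]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Newick and TSV
# ---------------------------------------------------------------------------

def read_species_tree(path: str | Path) -> SpeciesTree:
    return SpeciesTree(TreeNode.read(str(path), convert_underscores=False))


def parse_species_tree(newick: str) -> SpeciesTree:
    return SpeciesTree(TreeNode.read(StringIO(newick), convert_underscores=False))


def read_presence_matrix(path: str | Path) -> PresenceMatrix:
    """Read a lineage x character TSV; cells must be exactly 0 or 1."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    try:
        numeric = df.astype(int)
    except ValueError as exc:
        raise InputError(f"{path}: non-integer presence cell ({exc})") from exc
    return PresenceMatrix(values=numeric)


def write_presence_matrix(matrix: PresenceMatrix, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tsv_header(seed) + "\n")
        fh.write("lineage\t" + "\t".join(matrix.characters) + "\n")
        for lineage in matrix.lineages:
            vals = "\t".join(str(int(matrix.values.loc[lineage, c])) for c in matrix.characters)
            fh.write(f"{lineage}\t{vals}\n")


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write a pandas table as TSV with the standard commented header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tsv_header(seed) + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def load_basal_repertoire() -> PresenceMatrix:
    """The packaged early-metazoan cystatin repertoire presence matrix."""
    return read_presence_matrix(_data_path("basal_repertoire.tsv"))


def load_basal_tree() -> SpeciesTree:
    """The packaged basal-metazoan species tree (editable; deep branching is contested)."""
    return read_species_tree(_data_path("basal_metazoa.nwk"))
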