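"""Ground-truth generator for cystatin gene families.

Emits protein families built on domain scaffolds that carry the conserved
cystatin landmarks (trunk glycine, Q-x-V-x-G, second-hairpin pair, the
stefin H(-7)/K(-8) residues and D-x-L-x-Y-F terminus), with lineage-specific
pair substitutions, optional signal peptides, matching coding DNA with
planted GT/AG-bounded introns, and presence/absence matrices evolved under a
named gain/loss scenario. Every emitted record carries a byte-consistent
ground-truth entry, which downstream modules use as their oracle.

Point mutations are substitutions only (no indels: the H(-7)/K(-8) landmarks
are sequence-positional) and never touch protected motif positions. Proposed
substitutions that would fabricate a competing landmark — a catalogue pair
inside the second-hairpin search window, a D/L/Y/F anchor inside a
C-terminal window that must stay motif-free, a spurious Q-x-V-x-G or trunk
glycine upstream of the planted one, a cysteine, or a hydrophobic h-region
run in a sequence without a signal peptide — are redrawn, so the planted
architecture remains the decision surface at any mutation rate.

Reverse translation is deterministic (first codon per residue in a fixed
table) so DNA output is reproducible across platforms; randomized codon
usage is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import CHARACTERS, InputError, PresenceMatrix, SequenceRecord, SpeciesTree
from .features import HYDROPHOBIC, H_REGION_STARTS, H_RUN
from .motifs import CATALOGUE_PAIRS

SUBTYPES = (
    "classical_stefin",
    "atypical_stefin_type1",
    "atypical_stefin_type2",
    "type2_cystatin",
)

#: Classical stefin scaffold (50 aa): trunk G at 3, QxVxG at 14-19, H at 29,
#: hairpin pair LP at 36-38, K at 40, DxLxYF at 44-50.
TOY_STEFIN_50 = "MASGKTEEAQNAAEQTVAGNLDAIKSEAIHQTMEASLPGEKSENDALKYF"
#: Atypical stefin scaffold: same domain with the C-terminal motif region
#: replaced by a motif-free tail.
TOY_ATYP_50 = TOY_STEFIN_50[:44] + "GSTNSG"
#: Type 2 cystatin mature scaffold (45 aa): QxVxG at 4-9, PW pair at 27-29,
#: four cysteines (9, 20, 35, 41) forming two sequential bridges, no DxLxYF.
TOY_TYPE2_MATURE = "GAPRQTVAGCNLDAIKSEAICQTMEASPWGEKSENCAASNECGGF"
#: Rule-satisfying signal peptide (15 aa): charged n-region, hydrophobic
#: h-region, A-x-A cleavage site.
TOY_SIGNAL_PEPTIDE = "MKLLVLLALLALAQA"

#: Scaffold hairpin-pair spans on the mature sequence.
_PAIR_SPAN = {"stefin": (36, 38), "type2": (27, 29)}

#: Default lineage -> admissible second-hairpin pairs (stefin scaffolds).
STEFIN_PAIRS_BY_LINEAGE: Mapping[str, tuple[str, ...]] = {
    "Porifera": ("LD",),
    "Ctenophora": ("LP",),
    "Anthozoa": ("LP", "FD", "FS"),
    "Staurozoa": ("LP",),
    "Cubozoa": ("LP",),
    "Scyphozoa": ("LP", "FA", "LK"),
    "Hydrozoa": ("LP", "FA", "LK"),
    "Malacosporea": ("LP",),
    "Myxosporea": ("LP", "LS", "LY", "LR", "FK", "SA"),
}

#: Default lineage -> admissible pairs (type 2 cystatin scaffolds).
CYSTATIN_PAIRS_BY_LINEAGE: Mapping[str, tuple[str, ...]] = {
    "Ctenophora": ("PW", "AW"),
    "Anthozoa": ("PW", "SW", "GW"),
    "Cubozoa": ("PW", "SW", "KF"),
    "Scyphozoa": ("PW", "AW", "RW", "SW"),
    "Hydrozoa": ("PW", "AW", "RW", "SW", "PF", "PL"),
    "Polypodiozoa": ("PW",),
}

#: Which lineages each subtype is drawn from by default: classical stefins
#: and type 2 cystatins from free-living groups, atypical stefins from the
#: parasitic myxozoan subgroups.
DEFAULT_SUBTYPE_LINEAGES: Mapping[str, tuple[str, ...]] = {
    "classical_stefin": ("Porifera", "Ctenophora", "Anthozoa", "Cubozoa", "Scyphozoa", "Hydrozoa"),
    "atypical_stefin_type1": ("Myxosporea", "Malacosporea"),
    "atypical_stefin_type2": ("Myxosporea",),
    "type2_cystatin": ("Ctenophora", "Anthozoa", "Cubozoa", "Scyphozoa", "Hydrozoa"),
}

#: Deterministic reverse-translation table: alphabetically first codon per
#: residue of the standard genetic code.
PREFERRED_CODON = {
    "A": "GCA", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC", "G": "GGA",
    "H": "CAC", "I": "ATA", "K": "AAA", "L": "CTA", "M": "ATG", "N": "AAC",
    "P": "CCA", "Q": "CAA", "R": "AGA", "S": "AGC", "T": "ACA", "V": "GTA",
    "W": "TGG", "Y": "TAC",
}
CODON_CHOICES = {
    "A": ("GCA", "GCC", "GCG", "GCT"), "C": ("TGC", "TGT"), "D": ("GAC", "GAT"),
    "E": ("GAA", "GAG"), "F": ("TTC", "TTT"), "G": ("GGA", "GGC", "GGG", "GGT"),
    "H": ("CAC", "CAT"), "I": ("ATA", "ATC", "ATT"), "K": ("AAA", "AAG"),
    "L": ("CTA", "CTC", "CTG", "CTT", "TTA", "TTG"), "M": ("ATG",),
    "N": ("AAC", "AAT"), "P": ("CCA", "CCC", "CCG", "CCT"),
    "Q": ("CAA", "CAG"), "R": ("AGA", "AGG", "CGA", "CGC", "CGG", "CGT"),
    "S": ("AGC", "AGT", "TCA", "TCC", "TCG", "TCT"),
    "T": ("ACA", "ACC", "ACG", "ACT"), "V": ("GTA", "GTC", "GTG", "GTT"),
    "W": ("TGG",), "Y": ("TAC", "TAT"),
}
STOP_CODON = "TAA"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FamilyConfig:
    """Study conditions for one simulated family.

    Defaults encode the conditions the package is exercised under: 50
    sequences per subtype, no point mutations, stefin genes with two introns
    at conserved coding positions, type 2 genes with 0-2 introns at variable
    positions, intron lengths 8-200 nt.
    """

    n_classical: int = 50
    n_atypical_type1: int = 50
    n_atypical_type2: int = 50
    n_type2: int = 50
    mutation_rate: float = 0.0
    #: cDNA insertion points (nt, mature-CDS coordinates) of the two
    #: conserved stefin introns; both fall on codon boundaries (phase 0).
    stefin_intron_points: tuple[int, ...] = (30, 93)
    type2_intron_range: tuple[int, int] = (0, 2)
    intron_length_range: tuple[int, int] = (8, 200)
    subtype_lineages: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_LINEAGES)
    )
    stefin_pairs: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(STEFIN_PAIRS_BY_LINEAGE)
    )
    cystatin_pairs: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(CYSTATIN_PAIRS_BY_LINEAGE)
    )
    randomized_codons: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate < 1:
            raise InputError("mutation_rate must be in [0, 1)")
        lo, hi = self.type2_intron_range
        if not 0 <= lo <= hi <= 2:
            raise InputError("type 2 intron count range must sit within [0, 2]")
        if len(self.stefin_intron_points) > 2:
            raise InputError("at most 2 conserved stefin introns")
        if self.intron_length_range[0] < 8:
            raise InputError("intron length must be at least 8")


@dataclass
class GroundTruth:
    """Planted truth for one simulated record (byte-consistent with output)."""

    record_id: str
    label: str
    lineage: str
    pair: str
    signal_peptide: tuple[int, int] | None  # (start, end) on the protein
    motif_positions: dict[str, tuple[int, int]]  # mature coordinates
    introns: list[tuple[int, int, int]]  # (genomic_start, genomic_end, cdna_point)
    protein: str
    cdna: str
    genomic: str


@dataclass
class SimulatedFamily:
    proteins: list[SequenceRecord]
    genomic: list[SequenceRecord]
    cdna: list[SequenceRecord]
    truth: list[GroundTruth]

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": t.record_id,
                    "label": t.label,
                    "lineage": t.lineage,
                    "pair": t.pair,
                    "signal_peptide": (
                        "" if t.signal_peptide is None
                        else f"{t.signal_peptide[0]}-{t.signal_peptide[1]}"
                    ),
                    "introns": ";".join(f"{s}-{e}@{p}" for s, e, p in t.introns),
                }
                for t in self.truth
            ],
            columns=["id", "label", "lineage", "pair", "signal_peptide", "introns"],
        )


# ---------------------------------------------------------------------------
# protein construction
# ---------------------------------------------------------------------------

def _scaffold(subtype: str, pair: str) -> tuple[str, bool]:
    """(mature sequence with the pair spliced in, has signal peptide)."""
    if subtype == "classical_stefin":
        base, span, sp = TOY_STEFIN_50, _PAIR_SPAN["stefin"], False
    elif subtype == "atypical_stefin_type1":
        base, span, sp = TOY_ATYP_50, _PAIR_SPAN["stefin"], False
    elif subtype == "atypical_stefin_type2":
        base, span, sp = TOY_ATYP_50, _PAIR_SPAN["stefin"], True
    elif subtype == "type2_cystatin":
        base, span, sp = TOY_TYPE2_MATURE, _PAIR_SPAN["type2"], True
    else:
        raise InputError(f"unknown subtype {subtype!r}")
    s, e = span
    return base[:s] + pair + base[e:], sp


def _protected_positions(subtype: str, mature: str, sp_len: int) -> set[int]:
    """Full-protein indices that mutations must never touch."""
    protected = set(range(sp_len))  # whole signal peptide when present
    off = sp_len

    def mark(span: tuple[int, int]) -> None:
        protected.update(range(off + span[0], off + span[1]))

    if subtype == "type2_cystatin":
        mark((0, 1))            # trunk glycine
        mark((4, 9))            # QxVxG
        mark(_PAIR_SPAN["type2"])
        for i, ch in enumerate(mature):
            if ch == "C":
                protected.add(off + i)
    else:
        mark((3, 4))            # trunk glycine
        mark((14, 19))          # QxVxG
        mark((29, 30))          # H(-7)
        mark(_PAIR_SPAN["stefin"])
        if subtype == "classical_stefin":
            mark((40, 41))      # K(-8)
            mark((44, 50))      # DxLxYF
    return protected


def _mature_windows(subtype: str, mature: str) -> dict:
    """Regions the mutation-rejection rules need, in mature coordinates."""
    if subtype == "type2_cystatin":
        qx_g = 8
        pair_start = _PAIR_SPAN["type2"][0]
        trunk_g = 0
    else:
        qx_g = 18
        pair_start = _PAIR_SPAN["stefin"][0]
        trunk_g = 3
    return {
        "hairpin_lo": qx_g + 15,
        "hairpin_hi": min(qx_g + 30, len(mature) - 2),
        "pair_start": pair_start,
        "trunk_g": trunk_g,
        "qxvxg_start": 14 if subtype != "type2_cystatin" else 4,
        "cterm_lo": max(0, len(mature) - 12),
        "cterm_free": subtype != "classical_stefin",  # window must stay motif-free
    }


def _mutation_allowed(
    protein: list[str], pos: int, new: str, sp_len: int, win: dict, has_sp: bool
) -> bool:
    """Reject substitutions that would plant a competing landmark."""
    if new == "C":
        return False
    old = protein[pos]
    protein[pos] = new
    try:
        mature = protein[sp_len:]
        m = pos - sp_len
        # no catalogue/canonical pair may appear in the hairpin search window
        # anywhere except the planted pair position
        for s in range(win["hairpin_lo"], win["hairpin_hi"] + 1):
            if s == win["pair_start"]:
                continue
            if "".join(mature[s : s + 2]) in CATALOGUE_PAIRS:
                return False
        # no trunk glycine upstream of the planted one
        if 0 <= m < win["trunk_g"] and new == "G":
            return False
        # no QxVxG completion upstream of the planted motif
        for i in range(win["trunk_g"] + 1, win["qxvxg_start"]):
            if i + 4 < len(mature) and mature[i] == "Q" and mature[i + 2] == "V" and mature[i + 4] == "G":
                return False
        # scaffolds without the C-terminal motif must keep the window free of
        # its anchors
        if win["cterm_free"] and m >= win["cterm_lo"] and new in "DLYF":
            return False
        # sequences without a signal peptide must not acquire an h-region
        if not has_sp:
            head = protein[:40]
            for h in H_REGION_STARTS:
                if h + H_RUN <= len(head) and all(c in HYDROPHOBIC for c in head[h : h + H_RUN]):
                    return False
        return True
    finally:
        protein[pos] = old


def _mutate(
    protein: str, subtype: str, sp_len: int, rate: float, rng: np.random.Generator
) -> str:
    if rate == 0:
        return protein
    mature = protein[sp_len:]
    protected = _protected_positions(subtype, mature, sp_len)
    win = _mature_windows(subtype, mature)
    out = list(protein)
    for pos in range(len(out)):
        if pos in protected or rng.random() >= rate:
            continue
        choices = [a for a in AMINO_ACIDS if a != out[pos]]
        order = rng.permutation(len(choices))
        for k in order:
            cand = choices[int(k)]
            if _mutation_allowed(out, pos, cand, sp_len, win, sp_len > 0):
                out[pos] = cand
                break
        # no admissible substitution: site left unchanged
    return "".join(out)


# ---------------------------------------------------------------------------
# DNA construction
# ---------------------------------------------------------------------------

def reverse_translate(protein: str, rng: np.random.Generator | None = None) -> str:
    """Coding sequence for a protein; deterministic unless *rng* is given."""
    if rng is None:
        return "".join(PREFERRED_CODON[a] for a in protein) + STOP_CODON
    return (
        "".join(
            CODON_CHOICES[a][int(rng.integers(len(CODON_CHOICES[a])))] for a in protein
        )
        + STOP_CODON
    )


def _slide_ambiguous(cdna: str, point: int, intron: str) -> bool:
    """True if the planted intron admits an alternative canonical placement
    reachable by sliding the junction over repeated nucleotides."""
    L = len(intron)
    for s in range(1, 7):
        if s <= point and cdna[point - s : point] == intron[L - s :]:
            slid = cdna[point - s : point] + intron[: L - s]
            if slid[:2] == "GT" and slid[-2:] == "AG":
                return True
        if point + s <= len(cdna) and intron[:s] == cdna[point : point + s]:
            slid = intron[s:] + cdna[point : point + s]
            if slid[:2] == "GT" and slid[-2:] == "AG":
                return True
    return False


def _make_intron(length: int, cdna: str, point: int, rng: np.random.Generator) -> str:
    bases = "ACGT"
    for _ in range(50):
        interior = "".join(bases[int(b)] for b in rng.integers(0, 4, size=length - 4))
        intron = "GT" + interior + "AG"
        if not _slide_ambiguous(cdna, point, intron):
            return intron
    raise RuntimeError("could not draw an unambiguous intron")  # pragma: no cover


def _plant_introns(
    cdna: str, points: Sequence[int], rng: np.random.Generator, length_range: tuple[int, int]
) -> tuple[str, list[tuple[int, int, int]]]:
    """Insert GT/AG introns at the given cDNA points; returns (genomic, truth)."""
    for p in points:
        if not 0 < p < len(cdna):
            raise InputError(f"intron position {p} outside the CDS")
    genomic_parts = []
    truth = []
    prev = 0
    shift = 0
    for p in sorted(points):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        intron = _make_intron(length, cdna, p, rng)
        genomic_parts.append(cdna[prev:p])
        gstart = p + shift
        truth.append((gstart, gstart + length, p))
        genomic_parts.append(intron)
        shift += length
        prev = p
    genomic_parts.append(cdna[prev:])
    return "".join(genomic_parts), truth


# ---------------------------------------------------------------------------
# family generation
# ---------------------------------------------------------------------------

def make_family(config: FamilyConfig | None = None) -> SimulatedFamily:
    """Generate one labeled cystatin family under the configured conditions."""
    config = config or FamilyConfig()
    rng = np.random.default_rng(config.seed)
    counts = {
        "classical_stefin": config.n_classical,
        "atypical_stefin_type1": config.n_atypical_type1,
        "atypical_stefin_type2": config.n_atypical_type2,
        "type2_cystatin": config.n_type2,
    }
    proteins: list[SequenceRecord] = []
    genomic_recs: list[SequenceRecord] = []
    cdna_recs: list[SequenceRecord] = []
    truths: list[GroundTruth] = []
    serial = 0
    for subtype in SUBTYPES:
        lineage_pool = tuple(config.subtype_lineages.get(subtype, ()))
        if counts[subtype] and not lineage_pool:
            raise InputError(f"no lineages configured for subtype {subtype}")
        for _ in range(counts[subtype]):
            serial += 1
            rec_id = f"sim{serial:04d}_{subtype}"
            lineage = lineage_pool[int(rng.integers(len(lineage_pool)))]
            pair_pool = (
                config.cystatin_pairs if subtype == "type2_cystatin" else config.stefin_pairs
            ).get(lineage)
            if not pair_pool:
                raise InputError(f"no pair catalogue for lineage {lineage!r}")
            pair = pair_pool[int(rng.integers(len(pair_pool)))]
            mature, has_sp = _scaffold(subtype, pair)
            sp_len = len(TOY_SIGNAL_PEPTIDE) if has_sp else 0
            protein = (TOY_SIGNAL_PEPTIDE if has_sp else "") + mature
            protein = _mutate(protein, subtype, sp_len, config.mutation_rate, rng)
            mature = protein[sp_len:]

            cdna = reverse_translate(protein, rng if config.randomized_codons else None)
            if subtype == "type2_cystatin":
                lo, hi = config.type2_intron_range
                n_introns = int(rng.integers(lo, hi + 1))
                codon_slots = np.arange(1, len(protein))  # codon boundaries, internal
                chosen = rng.choice(codon_slots, size=n_introns, replace=False)
                points = sorted(int(p) * 3 for p in chosen)
            else:
                points = [p + 3 * sp_len for p in config.stefin_intron_points]
            genomic, intron_truth = _plant_introns(
                cdna, points, rng, config.intron_length_range
            )

            motif_positions = _truth_motifs(subtype, mature)
            proteins.append(
                SequenceRecord(
                    id=rec_id, residues=protein, moltype="protein",
                    description=f"lineage={lineage} label={subtype}", lineage=lineage,
                )
            )
            cdna_recs.append(
                SequenceRecord(id=rec_id, residues=cdna, moltype="dna",
                               description=f"lineage={lineage}", lineage=lineage)
            )
            genomic_recs.append(
                SequenceRecord(id=rec_id, residues=genomic, moltype="dna",
                               description=f"lineage={lineage}", lineage=lineage)
            )
            truths.append(
                GroundTruth(
                    record_id=rec_id,
                    label=subtype,
                    lineage=lineage,
                    pair=pair,
                    signal_peptide=(0, sp_len) if has_sp else None,
                    motif_positions=motif_positions,
                    introns=intron_truth,
                    protein=protein,
                    cdna=cdna,
                    genomic=genomic,
                )
            )
    return SimulatedFamily(proteins=proteins, genomic=genomic_recs, cdna=cdna_recs, truth=truths)


def _truth_motifs(subtype: str, mature: str) -> dict[str, tuple[int, int]]:
    if subtype == "type2_cystatin":
        out = {"G_trunk": (0, 1), "QxVxG": (4, 9), "hairpin2_pair": (27, 29)}
    else:
        out = {
            "G_trunk": (3, 4), "QxVxG": (14, 19), "hairpin2_pair": (36, 38),
            "H_minus7": (29, 30),
        }
        if subtype == "classical_stefin":
            out["DxLxYF_cterm"] = (44, 50)
            out["K_minus8"] = (40, 41)
    return out


# ---------------------------------------------------------------------------
# presence/absence scenario simulation
# ---------------------------------------------------------------------------

#: Named gain/loss scenarios for the type 2 cystatin character, expressed as
#: lineage sets (gains at the MRCA of each set, losses on pendant branches).
SCENARIO_EVENTS = {
    # retained from the metazoan ancestor; lost independently four times
    "A": {
        "gains": [("__all__",)],
        "losses": ["Porifera", "Placozoa", "Staurozoa", "Myxozoa"],
    },
    # lost early, regained in the eumetazoan ancestor, lost again thrice
    "B": {
        "gains": [("Ctenophora", "Anthozoa", "Hydrozoa")],
        "losses": ["Placozoa", "Staurozoa", "Myxozoa"],
    },
    # regained twice: in ctenophores and in the cnidarian+bilaterian ancestor
    "C": {
        "gains": [("Ctenophora",), ("Anthozoa", "Hydrozoa", "Bilateria")],
        "losses": ["Staurozoa", "Myxozoa"],
    },
}


def simulate_gain_loss(
    tree: SpeciesTree,
    gains: Sequence[Sequence[str]],
    losses: Sequence[str],
    character: str = "type2_cystatin",
) -> PresenceMatrix:
    """Tip presence states after applying gains (at MRCA nodes) and losses
    (on pendant branches), walking each root-to-tip path in order."""
    root = tree.root
    gain_nodes = set()
    for group in gains:
        if tuple(group) == ("__all__",):
            gain_nodes.add(id(root))
            continue
        tips = [tree.match_tip(l) for l in group if _tip_exists(tree, l)]
        if not tips:
            continue
        node = root.lca(tips) if len(tips) > 1 else root.find(tips[0])
        gain_nodes.add(id(node))
    loss_tips = {tree.match_tip(l) for l in losses if _tip_exists(tree, l)}
    states = {}
    for tip in root.tips():
        state = 0
        path = list(tip.ancestors())[::-1] + [tip]
        for node in path:
            if id(node) in gain_nodes:
                state = 1
            if node is tip and node.name in loss_tips:
                state = 0
        states[tip.name] = state
    df = pd.DataFrame({character: pd.Series(states)}).astype(int)
    df = df.loc[[t.name for t in root.tips()]]
    df.index.name = "lineage"
    return PresenceMatrix(values=df)


def _tip_exists(tree: SpeciesTree, lineage: str) -> bool:
    return any(n.lower() == lineage.lower() for n in tree.tip_names)


def make_presence_scenario(
    tree: SpeciesTree,
    scenario: str,
    character: str = "type2_cystatin",
    seed: int = 0,
) -> PresenceMatrix:
    """Tip presence matrix evolved under a named gain/loss scenario (A/B/C).

    The simulation is event-deterministic; *seed* is accepted for interface
    symmetry with the sequence generator and recorded by the pipeline.
    """
    if scenario not in SCENARIO_EVENTS:
        raise InputError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIO_EVENTS)}")
    spec = SCENARIO_EVENTS[scenario]
    return simulate_gain_loss(tree, spec["gains"], spec["losses"], character=character)
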