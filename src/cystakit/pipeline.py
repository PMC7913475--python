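"""Run orchestration: screen -> annotate -> features -> classify -> introns
-> profile -> evolve as one reproducible run.

Each stage writes one TSV; a JSON manifest records the tool version, the
seed, the configuration, and SHA-256 digests of every input and output, so a
rerun with the same configuration and seed is byte-identical (no timestamps
are ever written).
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import core_io, evolution, features, introns, motifs, profile
from .classify import calls_table, classify as classify_features, repertoire_summary
from .core_io import InputError, SequenceRecord
from .screen import hits_table, screen as run_screen

STAGES = ("screen", "annotate", "features", "classify", "introns", "profile", "evolve")


@dataclass
class RunConfig:
    """Inputs, thresholds, and bookkeeping for one pipeline run.

    Unset input paths simply skip their stage. Threshold defaults mirror the
    per-module defaults; all of them are package decisions exposed here.
    """

    outdir: str = "cystakit_run"
    seed: int = 0
    proteins: str | None = None
    queries: str | None = None
    subjects: str | None = None
    genomic: str | None = None
    cdna: str | None = None
    alignment: str | None = None
    tree: str | None = None
    matrix: str | None = None
    annotations: str | None = None
    character: str = "type2_cystatin"
    evalue: float = 1e-5
    iterate: bool = True
    min_occupancy: float = 0.5
    gain_penalty: float = 2.0
    max_gains: int = 3

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise InputError("evalue cutoff must be positive")
        if not 0 < self.min_occupancy <= 1:
            raise InputError("min_occupancy must be in (0, 1]")
        if self.gain_penalty <= 0:
            raise InputError("gain_penalty must be positive")
        if self.max_gains < 1:
            raise InputError("max_gains must be at least 1")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(path: str | None, stage: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise InputError(f"stage {stage!r}: input file {p} not found")
    return p


def _parse_lineage(rec: SequenceRecord) -> str:
    for token in rec.description.split():
        if token.startswith("lineage="):
            return token.split("=", 1)[1]
    return rec.lineage or "unassigned"


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages in order; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    inputs: dict[str, str] = {}
    outputs: dict[str, str] = {}

    def register_input(name: str, path: Path) -> None:
        inputs[name] = _sha256(path)

    def emit(name: str, df) -> None:
        path = outdir / name
        core_io.write_table(df, path, seed=seed)
        outputs[name] = _sha256(path)

    # --- screen ---------------------------------------------------------
    if config.queries and config.subjects:
        qp = _require(config.queries, "screen")
        sp = _require(config.subjects, "screen")
        register_input("queries", qp)
        register_input("subjects", sp)
        queries = core_io.read_fasta(qp, moltype="protein")
        subjects = core_io.read_fasta(sp)
        hits = run_screen(
            queries, subjects, evalue_cutoff=config.evalue, iterate=config.iterate
        )
        emit("screen.tsv", hits_table(hits))

    # --- introns (computed early so feature vectors can carry counts) ---
    intron_maps: dict[str, introns.IntronMap] = {}
    if config.genomic and config.cdna:
        gp = _require(config.genomic, "introns")
        cp = _require(config.cdna, "introns")
        register_input("genomic", gp)
        register_input("cdna", cp)
        genomic_recs = {r.id: r for r in core_io.read_fasta(gp, moltype="dna")}
        cdna_recs = {r.id: r for r in core_io.read_fasta(cp, moltype="dna")}
        shared = sorted(set(genomic_recs) & set(cdna_recs))
        for rid in shared:
            try:
                intron_maps[rid] = introns.map_introns(genomic_recs[rid], cdna_recs[rid])
            except InputError as exc:
                raise InputError(f"stage 'introns': record {rid!r}: {exc}") from exc

    # --- annotate / features / classify ---------------------------------
    if config.proteins:
        pp = _require(config.proteins, "annotate")
        register_input("proteins", pp)
        records = core_io.read_fasta(pp, moltype="protein")
        overrides = None
        if config.annotations:
            ap = _require(config.annotations, "features")
            register_input("annotations", ap)
            overrides = features.read_annotations(ap)
        feats = []
        annotated = []
        for rec in records:
            try:
                f = features.build_features(
                    rec,
                    intron_count=intron_maps[rec.id].intron_count if rec.id in intron_maps else 0,
                    overrides=overrides,
                )
            except InputError as exc:
                raise InputError(f"stage 'annotate': record {rec.id!r}: {exc}") from exc
            feats.append(f)
            annotated.append((rec, f.motif_hits))
        emit("motifs.tsv", motifs.motifs_table(annotated))
        emit("substitutions.tsv", motifs.substitution_table(
            [(r, f.motif_hits) for r, f in zip(records, feats)]
        ))
        emit("features.tsv", features.features_table(feats))
        calls = [classify_features(f) for f in feats]
        emit("calls.tsv", calls_table(calls))
        lineages = {r.id: _parse_lineage(r) for r in records}
        summary = repertoire_summary(calls, lineages)
        rep_path = outdir / "repertoire.tsv"
        core_io.write_presence_matrix(summary, rep_path, seed=seed)
        outputs["repertoire.tsv"] = _sha256(rep_path)

    if intron_maps:
        emit("introns.tsv", introns.introns_table(list(intron_maps.values())))

    # --- profile ---------------------------------------------------------
    if config.alignment:
        ap = _require(config.alignment, "profile")
        register_input("alignment", ap)
        aln = core_io.read_alignment(ap)
        trimmed = profile.trim_alignment(aln, min_occupancy=config.min_occupancy)
        prof = profile.column_information(trimmed)
        emit("profile.tsv", profile.profile_table(prof))

    # --- evolve ----------------------------------------------------------
    if config.tree and config.matrix:
        tp = _require(config.tree, "evolve")
        mp = _require(config.matrix, "evolve")
        register_input("tree", tp)
        register_input("matrix", mp)
        tree = core_io.read_species_tree(tp)
        matrix = core_io.read_presence_matrix(mp)
        pruned = tree.sheared(matrix.lineages)
        states = matrix.tip_states(config.character)
        scenarios = evolution.enumerate_scenarios(
            pruned, states,
            max_gains=config.max_gains,
            gain_penalty=config.gain_penalty,
            character=config.character,
        )
        emit("scenarios.tsv", evolution.scenarios_table(scenarios))
        dollo = evolution.dollo_reconstruction(pruned, states, character=config.character)
        nwk_path = outdir / "dollo.nwk"
        nwk_path.write_text(evolution.annotated_newick(pruned, dollo) + "\n", encoding="utf-8")
        outputs["dollo.nwk"] = _sha256(nwk_path)

    manifest = {
        "tool": "cystakit",
        "version": core_io.__version__,
        "seed": seed,
        "config": asdict(config),
        "inputs": inputs,
        "outputs": outputs,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
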