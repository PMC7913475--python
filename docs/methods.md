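# Methods

`cystakit` implements a desk-scale pipeline for surveying cystatin
(cysteine-protease-inhibitor, MEROPS family I25) gene repertoires: motif
annotation of the cystatin domain, rule-based subtype classification, intron
mapping from genomic/cDNA comparison, conservation profiling, a small
distance/NJ toolkit, and parsimony reconstruction of gene gain and loss on a
species tree. This note records the models, the knobs that matter, and the
design decisions taken where the problem was genuinely open.

## The motif grammar

The cystatin fold presents four protease-contact regions, annotated on the
*mature* protein (0-based, half-open coordinates; `mature_start` is the
signal-peptide cleavage position or 0):

1. **Trunk glycine** — the first `G` within the first 10 mature residues.
2. **Q-x-V-x-G** — the first-hairpin consensus; the first match downstream of
   the trunk glycine is taken, matching the single-copy expectation in
   single-domain cystatins.
3. **Second-hairpin pair** — `LP` in stefins, `PW` in type 2 cystatins, with
   a catalogue of observed lineage-specific substitutions
   (`LD LS LY LR FK SA FD FS FA LK` stefin-like;
   `AW RW SW KF GW PF PL` cystatin-like). The pair is searched 15–30
   residues downstream of the Q-x-V-x-G glycine. A canonical pair wins
   (leftmost); otherwise the leftmost catalogue pair wins, except that a
   cluster of *overlapping* candidates (a spurious pair sharing a residue
   with the real one, e.g. `SA` inside `...AS|AW...`) is arbitrated by
   BLOSUM62 similarity to a canonical pair.
4. **D-x-L-x-Y-F carboxy terminus** — stefin-specific; searched in the final
   12 residues. The candidate with the most matching anchors (D, L, Y, F)
   wins; all four ⇒ canonical; a retained tyrosine, or retained D and L
   anchors with a varied tyrosine, ⇒ substituted; otherwise absent. The
   tyrosine flag is carried in the classifier notes because of its role in
   stabilizing the inhibitor–protease complex.

Two flanking conserved residues are checked at **exact sequence offsets**: a
histidine 7 residues N-terminal of the pair's first residue, and a lysine 8
residues N-terminal of the C-terminal tyrosine. Offsets are measured on the
ungapped sequence (alignment-free operation); an alignment-anchored mode
(`detect_motifs_on_alignment`) reports the same hits as alignment columns
when an alignment is available. Both residues are reported absent whenever
their anchor motif is absent — no dangling offsets.

The search windows (trunk = 10, hairpin = 15–30 downstream, C-terminus = 12)
are package decisions exposed in `MotifWindows`; no published window values
exist for them. Sequences with fewer than 30 mature residues are rejected as
unannotatable.

## Feature heuristics

**Signal peptide** (`predict_signal_peptide`) is a rule-based von
Heijne-style test over the classic tripartite architecture, evaluated on the
first 40 residues: ≥1 K/R in positions 0–5 (n-region), a run of ≥6
consecutive residues from `AILMFVWC` starting in positions 2–12 (h-region),
and a small residue (A/G/S) at the −3 and −1 positions of a cleavage site in
positions 14–35 (c-region); the first valid site is reported. This is a
documented stand-in for a neural predictor, adequate for desk-scale,
scaffold-based data; real SignalP/DISULFIND output can be supplied as a TSV
override (`--annotations`) and replaces the heuristics per record.

**Disulfides** (`infer_disulfides`): cysteines downstream of the Q-x-V-x-G
motif are paired sequentially (1st–2nd, 3rd–4th), because the two bridges of
the type 2 cystatin fold are non-crossing; an odd trailing cysteine is left
unpaired with a warning. Crossing topologies are out of scope.

## The classifier

A pure function of the feature vector, with an ordered rule list and a
fired-rule trace:

1. **type 2 cystatin** — cystatin-class pair ∧ signal peptide ∧ ≥1 bridge ∧
   D-x-L-x-Y-F absent. One bridge suffices (ctenophore-type homologues carry
   a single bridge).
2. **classical stefin** — stefin-class pair ∧ D-x-L-x-Y-F present (canonical
   or substituted) ∧ no signal peptide ∧ 0 bridges.
3. **atypical stefin, type 1** — stefin-class pair ∧ D-x-L-x-Y-F absent ∧ no
   signal peptide ∧ 0 bridges.
4. **atypical stefin, type 2** — as (3) with a signal peptide.
5. otherwise **unclassified**, with the failing criteria in the trace.

Rules 1–4 are mutually exclusive by construction (cystatin vs stefin pair;
C-terminal motif; signal peptide). Contradictory feature combinations (e.g.
a stefin pair with bridges) are deliberately not forced into a subtype.
`repertoire_summary` collapses calls into a lineage × gene-type
presence/absence matrix (the two atypical subtypes collapse into one
character).

## Homology screen

A simplified translated-search loop: nucleotide subjects are translated in
all six frames (standard code, stops as `*`, trailing partial codons
dropped) and scanned with a hand-written Gotoh Smith–Waterman (BLOSUM62,
gap of length L costs 11 + L). Among equal-scoring optima the smallest
subject start, then the shortest subject span, is reported. Hits are
filtered by an approximate Karlin–Altschul E-value `E = K·m·n·exp(−λS)`
with fixed ungapped BLOSUM62 constants (λ = 0.267, K = 0.041) and a default
cutoff of 1e−5; this is a *filter*, not a statistical claim — the cutoff is
database-size dependent, so a raw-score threshold is available instead.
With iteration enabled, accepted subject regions are appended to the query
set and the screen repeats to a fixpoint (≤ |subjects| rounds), emulating
iterative query expansion; the iterated hit set is always a superset of the
single pass. `combined_candidates` unions the similarity hits with a
motif-grammar pre-filter (any frame carrying Q-x-V-x-G), the "combined
motif + similarity" strategy.

## Intron mapping

Given a genomic sequence and its cDNA, the mapper finds the splicing with
the **minimal number of introns** whose exons concatenate to the cDNA
exactly, by memoized search over exon-boundary states (cDNA position ×
cumulative intron length), with a mismatch budget of 0 by default
(`max_mismatch` exists for real, noisy data). Among minimal splicings the
placement maximizing canonical `GT...AG` junctions is chosen, then the
leftmost (sliding-junction ambiguity); non-canonical junctions are flagged
with a warning, never rejected. Minimum intron length is 4 nt (room for
GT + AG), config-exposed; synthetic introns are 8–200 nt. Intron phase is
the insertion point modulo 3 relative to the CDS offset.
`intron_positions_on_alignment` projects insertion points codon → residue →
alignment column, so conserved intron positions across genes appear as
shared columns; mid-codon introns keep their phase and are never dropped.

## Conservation and trees

Per-column information content follows the protein sequence-logo
convention, `IC = log2(20) − H` with `H` the Shannon entropy of non-gap
residue frequencies; all-gap columns are flagged. No small-sample
correction is applied by default so analytic test values are exact
(constant column = log2 20 ≈ 4.3219 bits; 4-way uniform = 2.3219 bits); the
logo-style correction `19/(2·ln2·n)` is a flag. Alignment trimming removes
leading/trailing columns below an occupancy threshold (default 0.5) — the
signal-peptide/ragged-end cleanup — and is idempotent.

Distances are raw p-distances (mismatches over mutually non-gap positions;
divergence figures in this domain are quoted uncorrected); pairs with no
comparable positions are flagged missing. Neighbor joining is delegated to
scikit-bio behind the module surface, with symmetry/negativity validation
and negative-branch clamping; on additive matrices NJ recovers topology and
branch lengths exactly, which the tests verify on random additive trees.
`long_branch_score` is the mean pendant branch length inside a tip subset
over the mean outside — a simple detector for fast-evolving (e.g.,
myxozoan-like) lineages.

Maximum-likelihood and Bayesian inference, bootstraps, and model selection
are out of scope; the NJ toolkit exists to support clade/long-branch
property checks on synthetic data, not to reproduce published phylogenies.

## Gain/loss reconstruction

Characters are binary presence/absence per lineage on a rooted species
tree; polytomies are resolved deterministically (left-to-right nesting)
before counting. Three reconstructions are offered:

* **Fitch** — standard two-pass small parsimony; counts changes on tree
  branches only (no stem), so an all-present character costs 0.
* **Dollo** — a single gain on the branch above the MRCA of all present
  tips, then the minimum number of losses (one per maximal absent subtree
  below the MRCA).
* **Scenario enumeration** — exhaustive over internal labelings, with the
  character assumed absent on the stem: a root-present history includes one
  origin gain on the stem branch. For each gain count ≤ `max_gains` the
  minimal-loss histories are kept, ranked by `k·gains + losses` (default
  gain penalty k = 2: gains are rarer events than losses; config-exposed),
  ties broken by fewer events then branch order. Alternative verbal
  scenarios (single origin with repeated loss vs multiple regains) are then
  distinguishable as `(n_gains, n_losses)` signatures.

Because enumeration counts the stem origin while Fitch does not, the
cheapest unit-penalty history equals the Fitch count exactly when some
Fitch-optimal labeling leaves the root absent, and exceeds it by one when
every optimum places the character at the root. `enumerate_scenarios` with
`max_gains=1` reproduces the Dollo solution exactly (tested).

The packaged basal-metazoan tree places Ctenophora as sister to the
remaining Metazoa, with Porifera and Placozoa branching successively, and
Polypodiozoa+Myxozoa (Endocnidozoa) inside Medusozoa next to Hydrozoa. Deep
metazoan branching is contested; the tree is an editable fixture and an
explicit input — scenario costs depend on it. On this tree and the packaged
repertoire matrix, the Dollo reconstruction of the type 2 cystatin
character places one gain at the root and losses exactly on the Porifera,
Placozoa, Staurozoa, and Myxozoa branches (event count confirmed by brute
force in the tests). The named scenarios A/B/C in the generator are
operationalized as gain events at MRCAs of named lineage sets plus pendant
losses; scenario C (two regains) presupposes that Ctenophora is not sister
to Cnidaria+Bilateria.

## The synthetic-data generator

The generator is first-class, tested code and the ground-truth oracle for
every other module. It emulates:

* **Domain scaffolds** — a 50-residue classical stefin carrying all six
  landmarks; an atypical stefin equal to it with the C-terminal motif
  region replaced by a motif-free tail; a 45-residue type 2 cystatin mature
  domain with a PW pair, four cysteines (two sequential bridges), and no
  C-terminal motif; a 15-residue signal peptide satisfying the heuristic
  exactly (planted on type 2 cystatins and type 2 atypical stefins, never
  elsewhere).
* **Lineage-specific substitutions** — each sequence draws its lineage and
  its hairpin pair from per-lineage catalogues (sponges `LD`; myxosporeans
  `LP/LS/LY/LR/FK/SA`; ctenophore-type cystatins `PW/AW`; etc.).
* **Gene structure** — deterministic reverse translation (first codon per
  residue; randomized codon usage behind a flag), a stop codon, and planted
  `GT...AG` introns: stefin genes carry two introns at fixed coding
  positions (conserved positions across the family), type 2 genes 0–2
  introns at random codon boundaries; lengths 8–200 nt. Drawn introns that
  would admit an alternative canonical placement by junction sliding are
  redrawn, so planted coordinates are the unique optimum.
* **Point mutations** — substitutions only (no indels, because the −7/−8
  landmarks are sequence-positional), at a configurable per-site rate,
  never at protected positions (motif spans, the flanking H/K, cysteines,
  the signal peptide). A proposed substitution is redrawn if it would
  fabricate a competing landmark: a catalogue pair in the hairpin window, a
  D/L/Y/F anchor in a C-terminal window that must stay motif-free, a
  Q-x-V-x-G or trunk glycine upstream of the planted one, a cysteine
  anywhere, or a hydrophobic h-region run in a sequence without a signal
  peptide. The planted architecture therefore remains the decision surface,
  and label recovery stays exact under mutation (tested to rate 0.1).

Defaults are the package's study conditions: 50 sequences per subtype (200
per family), mutation rate 0. What the generator does **not** emulate:
indels and alignment uncertainty, phylogenetically realistic substitution
processes (no WAG-style model), sequencing error, contamination, and
fragmentary assemblies. Passing tests therefore demonstrate correctness of
the decision procedures on clean, well-formed domains — not robustness to
the full noise spectrum of real mining data, where the external-annotation
override and the mismatch budget are the intended escape hatches.

## Numerical and determinism choices

All randomness flows through `numpy.random.default_rng` seeded from the
user-supplied seed; reruns are byte-identical and the pipeline manifest
records the seed and SHA-256 digests of every input and output (no
timestamps are written anywhere). TSV outputs carry one commented header
line naming the tool version and seed. Problem sizes in the tests and the
acceptance script — 200-sequence families, 1000 alignment-oracle pairs, 100
additive trees, 50 parsimony trees — were chosen as the smallest sizes that
exercise every code path and tie-break while keeping a full run in the
low minutes on one CPU.

## Known limitations

* The signal-peptide rule is far weaker than a neural predictor on real
  sequences; it is exact only on rule-conformant peptides.
* The E-value approximation uses ungapped constants for a gapped search;
  rankings are sensible, absolute values are not calibrated.
* The intron mapper assumes exactness; with `max_mismatch > 0` it prefers
  fewer introns over fewer mismatches at equal intron counts.
* Scenario enumeration is exponential in internal nodes — intended for
  lineage-level trees (tens of tips), not species-level trees.
* Multi-domain (type 3/kininogen) cystatins are out of scope throughout.
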