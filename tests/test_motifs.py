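"""Conserved-region detection, pair grading, and the substitution table."""

import pytest

from cystakit import InputError, SequenceRecord, classify_pair, detect_motifs, substitution_table
from cystakit.motifs import CATALOGUE_PAIRS, detect_motifs_on_alignment
from cystakit.simulate import TOY_SIGNAL_PEPTIDE, TOY_STEFIN_50, make_family, FamilyConfig


def hit(hits, name):
    return next(h for h in hits if h.motif == name)


class TestDetectMotifs:
    def test_toy_stefin_all_six_landmarks(self):
        hits = {h.motif: h for h in detect_motifs(TOY_STEFIN_50)}
        assert (hits["G_trunk"].start, hits["G_trunk"].end) == (3, 4)
        assert (hits["QxVxG"].start, hits["QxVxG"].end) == (14, 19)
        assert hits["QxVxG"].matched == "QTVAG"
        assert (hits["hairpin2_pair"].start, hits["hairpin2_pair"].end) == (36, 38)
        assert hits["hairpin2_pair"].matched == "LP"
        assert hits["hairpin2_pair"].status == "canonical"
        assert (hits["H_minus7"].start, hits["H_minus7"].matched) == (29, "H")
        assert hits["H_minus7"].status == "canonical"
        assert (hits["DxLxYF_cterm"].start, hits["DxLxYF_cterm"].end) == (44, 50)
        assert hits["DxLxYF_cterm"].matched == "DALKYF"
        assert hits["DxLxYF_cterm"].status == "canonical"
        assert (hits["K_minus8"].start, hits["K_minus8"].matched) == (40, "K")

    def test_lp_to_ld_substitution_leaves_other_hits(self):
        variant = TOY_STEFIN_50[:36] + "LD" + TOY_STEFIN_50[38:]
        base = {h.motif: h for h in detect_motifs(TOY_STEFIN_50)}
        hits = {h.motif: h for h in detect_motifs(variant)}
        assert hits["hairpin2_pair"].status == "substituted"
        assert hits["hairpin2_pair"].matched == "LD"
        for name in ("G_trunk", "QxVxG", "DxLxYF_cterm", "H_minus7", "K_minus8"):
            assert (hits[name].start, hits[name].status) == (base[name].start, base[name].status)

    def test_truncation_loses_cterm_motif(self):
        truncated = TOY_STEFIN_50[:44]
        hits = {h.motif: h for h in detect_motifs(truncated)}
        assert hits["DxLxYF_cterm"].status == "absent"
        assert hits["K_minus8"].status == "absent"

    def test_cterm_substituted_when_tyrosine_retained(self):
        # vary the D and F anchors but keep the Y: present-but-substituted
        variant = TOY_STEFIN_50[:44] + "NALKYA"
        hits = {h.motif: h for h in detect_motifs(variant)}
        assert hits["DxLxYF_cterm"].status == "substituted"
        assert hits["DxLxYF_cterm"].matched[4] == "Y"

    def test_signal_peptide_offsets_mature_coordinates(self):
        plain = detect_motifs(TOY_STEFIN_50, mature_start=0)
        prefixed = detect_motifs(TOY_SIGNAL_PEPTIDE + TOY_STEFIN_50, mature_start=15)
        assert [(h.motif, h.start, h.end) for h in plain] == [
            (h.motif, h.start, h.end) for h in prefixed
        ]

    def test_short_sequence_rejected(self):
        with pytest.raises(InputError, match="shorter"):
            detect_motifs("MASGKTEEAQNAAEQTVAG")

    def test_minus_offsets_absent_without_anchor(self):
        # no QxVxG -> no hairpin pair -> no H(-7); no DxLxYF -> no K(-8)
        seq = "MASGKTEEANNAAEATAANLDAIKSEAIAATMEASAAGEKSENAAAAAA"
        hits = {h.motif: h for h in detect_motifs(seq)}
        assert hits["QxVxG"].status == "absent"
        assert hits["hairpin2_pair"].status == "absent"
        assert hits["H_minus7"].status == "absent"
        assert hits["DxLxYF_cterm"].status == "absent"
        assert hits["K_minus8"].status == "absent"

    @pytest.mark.parametrize("seed", range(0, 100, 7))
    def test_generator_noise_free_output_is_canonical(self, seed):
        fam = make_family(FamilyConfig(
            n_classical=1, n_atypical_type1=0, n_atypical_type2=0, n_type2=0, seed=seed
        ))
        rec = fam.proteins[0]
        truth = fam.truth[0]
        hits = {h.motif: h for h in detect_motifs(rec.residues)}
        for name, span in truth.motif_positions.items():
            assert (hits[name].start, hits[name].end) == span
            if truth.pair == "LP" or name != "hairpin2_pair":
                assert hits[name].status == "canonical"

    def test_alignment_anchored_mode_reports_columns(self):
        gapped = TOY_STEFIN_50[:14] + "---" + TOY_STEFIN_50[14:]
        hits = {h.motif: h for h in detect_motifs_on_alignment(gapped)}
        assert (hits["QxVxG"].start, hits["QxVxG"].end) == (17, 22)
        assert (hits["G_trunk"].start) == 3


class TestClassifyPair:
    @pytest.mark.parametrize(
        "pair,expected",
        [
            ("LP", ("stefin_class", "canonical")),
            ("PW", ("cystatin_class", "canonical")),
            ("LD", ("stefin_class", "substituted")),
            ("LS", ("stefin_class", "substituted")),
            ("LY", ("stefin_class", "substituted")),
            ("LR", ("stefin_class", "substituted")),
            ("FK", ("stefin_class", "substituted")),
            ("SA", ("stefin_class", "substituted")),
            ("FD", ("stefin_class", "substituted")),
            ("FS", ("stefin_class", "substituted")),
            ("FA", ("stefin_class", "substituted")),
            ("LK", ("stefin_class", "substituted")),
            ("AW", ("cystatin_class", "substituted")),
            ("RW", ("cystatin_class", "substituted")),
            ("SW", ("cystatin_class", "substituted")),
            ("KF", ("cystatin_class", "substituted")),
            ("GW", ("cystatin_class", "substituted")),
            ("PF", ("cystatin_class", "substituted")),
            ("PL", ("cystatin_class", "substituted")),
            ("QQ", ("unassigned", None)),
        ],
    )
    def test_catalogue(self, pair, expected):
        assert classify_pair(pair) == expected

    def test_wrong_length_rejected(self):
        with pytest.raises(InputError):
            classify_pair("LPW")

    def test_catalogue_is_closed(self):
        for pair in CATALOGUE_PAIRS:
            cls, _ = classify_pair(pair)
            assert cls in ("stefin_class", "cystatin_class")


class TestSubstitutionTable:
    def _annotate(self, entries):
        out = []
        for rid, lineage, seq in entries:
            rec = SequenceRecord(id=rid, residues=seq, lineage=lineage)
            out.append((rec, detect_motifs(seq)))
        return out

    def test_porifera_ld_counted(self):
        variant = TOY_STEFIN_50[:36] + "LD" + TOY_STEFIN_50[38:]
        table = substitution_table(
            self._annotate([("a", "Porifera", variant), ("b", "Porifera", variant)])
        )
        row = table[(table.group == "Porifera") & (table.motif == "hairpin2_pair")]
        assert list(row.variant) == ["LD"]
        assert list(row["count"]) == [2]

    def test_empty_input_gives_empty_table(self):
        assert substitution_table([]).empty

    def test_mixed_variants_counted_separately(self):
        lp = TOY_STEFIN_50
        ls = TOY_STEFIN_50[:36] + "LS" + TOY_STEFIN_50[38:]
        table = substitution_table(
            self._annotate(
                [("a", "Myxosporea", lp), ("b", "Myxosporea", ls), ("c", "Myxosporea", ls)]
            )
        )
        rows = table[(table.group == "Myxosporea") & (table.motif == "hairpin2_pair")]
        assert dict(zip(rows.variant, rows["count"])) == {"LP": 1, "LS": 2}

    def test_missing_annotation_rejected(self):
        rec = SequenceRecord(id="a", residues=TOY_STEFIN_50)
        with pytest.raises(InputError):
            substitution_table([(rec, [])])
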