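import pytest

from prequant.constructs import (
    AmbiguousJunctionError,
    JunctionNotFoundError,
    PrimerError,
    apply_quikchange_deletion,
    default_enzyme_catalog,
    diff_construct_motifs,
    in_silico_pcr,
    read_primer_table,
    split_primer,
    validate_quikchange_pair,
)
from prequant.motifs import compile_motif
from prequant.seqio import SequenceRecord, reverse_complement
from prequant.synthetic import (
    build_fig5a_fixture,
    get_primer,
    load_packaged_primers,
    load_pre_region_template,
)

GAGA = compile_motif("GAF/PSQ", "GAGAG")
GT = compile_motif("GTGT", "GTGTG")

MUTAGENESIS = [
    "vgDGAGA", "vgD1stGT", "vgD1st2ndGT", "vgD1st3rdGT", "vgD1st4thGT",
]


@pytest.fixture(scope="module")
def primers():
    return load_packaged_primers()


@pytest.fixture(scope="module")
def template():
    return load_pre_region_template()


class TestSplitPrimer:
    @pytest.mark.parametrize(
        "seq,tail,annealing,enzyme",
        [
            (
                "TAAAGCGGCCGCAAGTCTCCGCCCAATAAT",
                "TAAAGCGGCCGC", "AAGTCTCCGCCCAATAAT", "NotI",
            ),
            (
                "GCGCTTTCTAGAGAGCATATAGAAGTGGTCGAA",
                "GCGCTTTCTAGA", "GAGCATATAGAAGTGGTCGAA", "XbaI",
            ),
            (
                "GGCGCTTACTAGTGCACAGAGAGTGCAGAAAG",
                "GGCGCTTACTAGT", "GCACAGAGAGTGCAGAAAG", "SpeI",
            ),
        ],
    )
    def test_cloning_primer_tails(self, seq, tail, annealing, enzyme):
        p = split_primer(seq)
        assert (p.tail, p.annealing, p.enzyme) == (tail, annealing, enzyme)

    def test_no_catalog_site_gives_empty_tail(self):
        p = split_primer("AAGAGGTTGAACCCCTTGAGGAAACCGGTTTATTTC")
        assert p.tail == "" and p.annealing == p.full_seq

    def test_site_beyond_search_window_ignored(self):
        # NotI site starting at position 12 ends past the 16 bp window
        seq = "A" * 12 + "GCGGCCGC" + "ACGTACGTAC"
        p = split_primer(seq)
        assert p.tail == ""

    def test_short_annealing_rejected(self):
        with pytest.raises(PrimerError, match="annealing"):
            split_primer("TAAAGCGGCCGCAAGTC")

    def test_catalog_from_library(self):
        sites = {s.enzyme: s.recognition for s in default_enzyme_catalog()}
        assert sites == {
            "NotI": "GCGGCCGC", "XbaI": "TCTAGA", "SpeI": "ACTAGT",
        }


class TestQuikChangeValidation:
    @pytest.mark.parametrize("name", MUTAGENESIS)
    def test_all_mutagenesis_pairs_validate(self, primers, name):
        fwd = get_primer(primers, name, "forward")
        rev = get_primer(primers, name, "reverse")
        assert validate_quikchange_pair(fwd, rev)
        assert fwd.tail == "" and rev.tail == ""

    def test_mismatched_pair_rejected(self, primers):
        fwd = get_primer(primers, "vgDGAGA", "forward")
        rev = get_primer(primers, "vgD1stGT", "reverse")
        assert not validate_quikchange_pair(fwd, rev)

    def test_empty_primer_error(self, primers):
        from prequant.constructs import PrimerRecord

        fwd = get_primer(primers, "vgDGAGA", "forward")
        empty = PrimerRecord("empty", "reverse", "", "", "")
        with pytest.raises(PrimerError, match="empty"):
            validate_quikchange_pair(fwd, empty)


class TestInSilicoPCR:
    def _primer(self, seq, direction, tail=""):
        from prequant.constructs import PrimerRecord

        return PrimerRecord(
            name=f"toy_{direction}", direction=direction,
            full_seq=tail + seq, tail=tail, annealing=seq,
        )

    def test_identity_amplicon(self, random_dna_factory):
        seq = random_dna_factory(60)
        tmpl = SequenceRecord("t", seq)
        fwd = self._primer(seq[:15], "forward")
        rev = self._primer(reverse_complement(seq[-15:]), "reverse")
        assert in_silico_pcr(tmpl, fwd, rev).seq == seq

    def test_internal_segment_with_tails(self, random_dna_factory):
        seq = random_dna_factory(200)
        tmpl = SequenceRecord("t", seq)
        fwd = self._primer(seq[40:58], "forward", tail="TAAAGCGGCCGC")
        rev = self._primer(
            reverse_complement(seq[120:140]), "reverse", tail="GCGCTTTCTAGA"
        )
        product = in_silico_pcr(tmpl, fwd, rev)
        # independent substring construction of the expected product
        assert product.seq == (
            "TAAAGCGGCCGC" + seq[40:140] + reverse_complement("GCGCTTTCTAGA")
        )
        assert len(product) == (140 - 40) + 12 + 12

    def test_multiple_annealing_sites_rejected(self):
        tmpl = SequenceRecord("t", "ACGTACGTACGTACGTTTTTTTTTTGGGGGGGGGGG")
        fwd = self._primer("ACGTACGTACGT", "forward")
        rev = self._primer(reverse_complement("GGGGGGGGGG"), "reverse")
        with pytest.raises(PrimerError, match="annealing sites"):
            in_silico_pcr(tmpl, fwd, rev)

    def test_orientation_error(self, random_dna_factory):
        seq = random_dna_factory(120)
        tmpl = SequenceRecord("t", seq)
        fwd = self._primer(seq[80:95], "forward")
        rev = self._primer(reverse_complement(seq[10:25]), "reverse")
        with pytest.raises(PrimerError, match="upstream"):
            in_silico_pcr(tmpl, fwd, rev)

    def test_region_template_amplicon(self, primers, template):
        """The packaged deletion-series primers amplify the surrogate tail."""
        fwd = get_primer(primers, "vgD100", "forward")
        rev = get_primer(primers, "vg_all", "reverse")
        product = in_silico_pcr(template, fwd, rev)
        assert product.seq.startswith(fwd.tail)
        assert product.seq.endswith(reverse_complement(rev.tail))
        genomic = len(template) - 106
        assert len(product) == genomic + len(fwd.tail) + len(rev.tail)


class TestQuikChangeDeletion:
    def _toy_pair(self, left, right):
        from prequant.constructs import PrimerRecord

        fwd_seq = left + right
        fwd = PrimerRecord("toy", "forward", fwd_seq, "", fwd_seq)
        rc = reverse_complement(fwd_seq)
        rev = PrimerRecord("toy_r", "reverse", rc, "", rc)
        return fwd, rev

    def test_removes_exactly_planted_segment(self):
        # boundary characters chosen distinct so the junction cannot slide
        left = "ATCCTGAACTGGATCAAGCT"
        deleted = "GCAAAAGGAATGAAATCAGTTCAGCCTTGA"
        right = "CAGGATCCATTGACCTGATC"
        tmpl = SequenceRecord("t", left + deleted + right)
        fwd, rev = self._toy_pair(left[-12:], right[:12])
        spec = apply_quikchange_deletion(tmpl, fwd, rev)
        assert spec.product.seq == left + right
        assert spec.deleted_seq == deleted
        assert (spec.deletion_start, spec.deletion_end) == (20, 50)
        assert len(spec.product) == len(tmpl) - len(deleted)
        assert fwd.full_seq in spec.product.seq

    def test_invalid_pair_rejected_before_search(self, primers):
        fwd = get_primer(primers, "vgDGAGA", "forward")
        rev = get_primer(primers, "vgD1stGT", "reverse")
        tmpl = load_pre_region_template()
        with pytest.raises(PrimerError, match="reverse-complementary"):
            apply_quikchange_deletion(tmpl, fwd, rev)

    def test_junction_not_found(self, random_dna_factory):
        tmpl = SequenceRecord("t", random_dna_factory(80))
        fwd, rev = self._toy_pair("GGGGGGCCCCCC", "TTTTTTAAAAAA")
        with pytest.raises(JunctionNotFoundError):
            apply_quikchange_deletion(tmpl, fwd, rev)

    def test_ambiguous_junction_listed(self):
        # right half occurs at two distant positions -> two products
        left = "ACGTACGTACGTA"
        right = "GGATCCGGATCA"
        tmpl = SequenceRecord(
            "t", left + "TTTTT" + right + "CCCCCAAAAAGGGGG" + right
        )
        fwd, rev = self._toy_pair(left, right)
        with pytest.raises(AmbiguousJunctionError) as err:
            apply_quikchange_deletion(tmpl, fwd, rev)
        assert len(err.value.candidates) >= 2

    def test_idempotent_second_application(self, random_dna_factory):
        left = random_dna_factory(25)
        right = random_dna_factory(25)
        tmpl = SequenceRecord("t", left + "GAGAGGAGAG" + right)
        fwd, rev = self._toy_pair(left[-13:], right[:13])
        first = apply_quikchange_deletion(tmpl, fwd, rev)
        assert not first.is_noop
        second = apply_quikchange_deletion(first.product, fwd, rev)
        assert second.is_noop
        assert second.product.seq == first.product.seq

    @pytest.mark.parametrize(
        "name,expect_lost_gt,expect_lost_gaga",
        [
            ("vgDGAGA", 0, 1),
            ("vgD1stGT", 1, 0),
            ("vgD1st2ndGT", 2, 0),
            ("vgD1st3rdGT", 3, 0),
        ],
    )
    def test_printed_primer_series_on_surrogate(
        self, primers, template, name, expect_lost_gt, expect_lost_gaga
    ):
        """Each deletion removes the annotated motif blocks and nothing else."""
        fwd = get_primer(primers, name, "forward")
        rev = get_primer(primers, name, "reverse")
        spec = apply_quikchange_deletion(template, fwd, rev)
        assert len(spec.product) == len(template) - len(spec.deleted_seq)
        assert fwd.full_seq in spec.product.seq
        lost, gained = diff_construct_motifs(template, spec.product, [GAGA, GT])
        lost_by = {"GTGT": 0, "GAF/PSQ": 0}
        for b in lost:
            lost_by[b.motif_name] += 1
        assert lost_by["GTGT"] == expect_lost_gt
        assert lost_by["GAF/PSQ"] == expect_lost_gaga
        assert gained == []

    def test_fourth_gt_deletion_applies_to_triple_deletion_product(
        self, primers, template
    ):
        """The 1st-4th repeat deletion primer presupposes the 1st-3rd product."""
        f3 = get_primer(primers, "vgD1st3rdGT", "forward")
        r3 = get_primer(primers, "vgD1st3rdGT", "reverse")
        triple = apply_quikchange_deletion(template, f3, r3)
        f4 = get_primer(primers, "vgD1st4thGT", "forward")
        r4 = get_primer(primers, "vgD1st4thGT", "reverse")
        quad = apply_quikchange_deletion(triple.product, f4, r4)
        lost, gained = diff_construct_motifs(
            triple.product, quad.product, [GAGA, GT]
        )
        assert [b.motif_name for b in lost] == ["GTGT"]
        assert gained == []
        # on the untouched template the junction does not exist
        with pytest.raises(JunctionNotFoundError):
            apply_quikchange_deletion(template, f4, r4)


class TestDiffMotifs:
    def test_identical_sequences_no_diff(self, random_dna_factory):
        a = SequenceRecord("a", random_dna_factory(300))
        b = SequenceRecord("b", a.seq)
        assert diff_construct_motifs(a, b, [GAGA, GT]) == ([], [])

    def test_single_planted_deletion_detected(self):
        # G-free flanks cannot form or join into a spurious GAGAG
        left = ("ACT" * 34)[:100]
        right = ("TCA" * 34)[:100]
        before = SequenceRecord("before", left + "GAGAG" + right)
        after = SequenceRecord("after", left + right)
        lost, gained = diff_construct_motifs(before, after, [GAGA])
        lost_spans = [
            (b.interval.start, b.interval.end)
            for b in lost if b.motif_name == "GAF/PSQ"
        ]
        assert (100, 105) in lost_spans

    def test_fixture_gt_blocks_all_lost_when_deleted(self):
        fix = build_fig5a_fixture()
        from prequant.motifs import merge_hits_to_blocks, scan_motifs

        blocks = merge_hits_to_blocks(scan_motifs(fix, [GT]))
        assert len(blocks) == 4
        # remove all four GT blocks (right to left to keep coordinates valid)
        seq = fix.seq
        for b in sorted(blocks, key=lambda b: -b.interval.start):
            seq = seq[: b.interval.start] + seq[b.interval.end:]
        after = SequenceRecord("gutted", seq)
        lost, _ = diff_construct_motifs(fix, after, [GT])
        assert len([b for b in lost if b.motif_name == "GTGT"]) == 4


class TestPrimerTable:
    def test_packaged_table_loads(self, primers):
        assert len(primers) == 16
        directions = {p.direction for p in primers}
        assert directions == {"forward", "reverse"}

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("name\tsequence\nx\tACGTACGTACGTACGT\n")
        with pytest.raises(PrimerError, match="direction"):
            read_primer_table(p)
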