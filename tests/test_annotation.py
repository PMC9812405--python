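from __future__ import annotations

import numpy as np
import pytest

from isotriage.annotation import (
    GenomicInterval,
    GtfParseError,
    PrematureStopError,
    TranscriptModel,
    cds_overlaps,
    extract_cds_sequence,
    find_orf,
    group_distinct_proteins,
    read_gtf,
    translate,
    _revcomp,
)

from oracles import translate_oracle, find_orf_oracle, _CODON_TABLE


def _gtf(lines):
    return "\n".join(lines) + "\n"


def _line(feature, start, end, gene, tx, strand="+"):
    return (
        f"chr1\ttest\t{feature}\t{start}\t{end}\t.\t{strand}\t."
        f'\tgene_id "{gene}"; transcript_id "{tx}";'
    )


class TestReadGtf:
    def test_one_gene_two_transcripts(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            _gtf(
                [
                    _line("exon", 1, 100, "g1", "t1"),
                    _line("CDS", 10, 90, "g1", "t1"),
                    _line("exon", 1, 80, "g1", "t2"),
                    _line("CDS", 10, 60, "g1", "t2"),
                ]
            )
        )
        loci, unanchored = read_gtf(p, {"t1"})
        assert len(loci) == 1 and not unanchored
        assert loci[0].canonical.transcript_id == "t1"
        assert [t.transcript_id for t in loci[0].alternates] == ["t2"]
        # GTF 1-based inclusive -> 0-based half-open
        assert loci[0].canonical.exons[0].start == 0
        assert loci[0].canonical.exons[0].end == 100

    def test_canonical_only_locus(self, tmp_path):
        p = tmp_path / "b.gtf"
        p.write_text(_gtf([_line("exon", 1, 50, "g1", "t1")]))
        loci, _ = read_gtf(p, {"t1"})
        assert loci[0].alternates == []

    def test_locus_without_canonical_is_unanchored(self, tmp_path):
        p = tmp_path / "c.gtf"
        p.write_text(_gtf([_line("exon", 1, 50, "g1", "t1")]))
        with pytest.warns(UserWarning, match="absent"):
            loci, unanchored = read_gtf(p, {"missing"})
        assert not loci
        assert [t.transcript_id for t in unanchored] == ["t1"]

    def test_benchmark_grouping_matches_truth(self, benchmark_inputs):
        inputs, truth = benchmark_inputs
        assert {l.locus_id for l in inputs.loci} == {lt.locus_id for lt in truth.loci}
        by_id = {l.locus_id: l for l in inputs.loci}
        for lt in truth.loci:
            locus = by_id[lt.locus_id]
            assert locus.canonical.transcript_id == lt.canonical_id
            assert {t.transcript_id for t in locus.alternates} == {
                a.transcript_id for a in lt.alternates
            }


class TestCdsExtraction:
    def test_plus_strand_single_exon(self):
        t = TranscriptModel(
            "t", "g", "+",
            exons=[GenomicInterval("c", 0, 9, "+")],
            cds=[GenomicInterval("c", 0, 9, "+")],
        )
        assert extract_cds_sequence(t, {"c": "ATGAAATAG"}) == "ATGAAATAG"

    def test_minus_strand_reverse_complement(self):
        genome = {"c": _revcomp("ATGAAATAG")}
        t = TranscriptModel(
            "t", "g", "-",
            exons=[GenomicInterval("c", 0, 9, "-")],
            cds=[GenomicInterval("c", 0, 9, "-")],
        )
        assert extract_cds_sequence(t, genome) == "ATGAAATAG"

    def test_spliced_cds_concatenates_in_transcription_order(self):
        genome = {"c": "ATG" + "gtxxag" + "AAATAG"}
        t = TranscriptModel(
            "t", "g", "+",
            exons=[GenomicInterval("c", 0, 3, "+"), GenomicInterval("c", 9, 15, "+")],
            cds=[GenomicInterval("c", 0, 3, "+"), GenomicInterval("c", 9, 15, "+")],
        )
        assert extract_cds_sequence(t, genome) == "ATGAAATAG"

    def test_strand_symmetry_random_cds(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, size=60)])
        plus = TranscriptModel(
            "p", "g", "+",
            exons=[GenomicInterval("c", 10, 40, "+")],
            cds=[GenomicInterval("c", 10, 40, "+")],
        )
        L = 60
        minus = TranscriptModel(
            "m", "g", "-",
            exons=[GenomicInterval("c", L - 40, L - 10, "-")],
            cds=[GenomicInterval("c", L - 40, L - 10, "-")],
        )
        assert extract_cds_sequence(plus, {"c": seq}) == extract_cds_sequence(
            minus, {"c": _revcomp(seq)}
        )

    def test_non_multiple_of_three_truncates_with_warning(self):
        t = TranscriptModel(
            "t", "g", "+",
            exons=[GenomicInterval("c", 0, 8, "+")],
            cds=[GenomicInterval("c", 0, 8, "+")],
        )
        with pytest.warns(UserWarning, match="truncating"):
            out = extract_cds_sequence(t, {"c": "ATGAAATA"})
        assert out == "ATGAAA"


class TestTranslate:
    @pytest.mark.parametrize("cds,protein", [("ATGAAATAG", "MK"), ("ATGTAG", "M")])
    def test_simple(self, cds, protein):
        assert translate(cds) == protein

    def test_internal_stop_names_codon(self):
        with pytest.raises(PrematureStopError) as err:
            translate("ATGTAAAAA")
        assert err.value.codon_index == 1

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="codon"):
            translate("ATGNNNTAG")

    def test_matches_table_oracle_on_random_orfs(self):
        rng = np.random.default_rng(11)
        codons = [c for c in _CODON_TABLE if _CODON_TABLE[c] != "*"]
        for _ in range(50):
            body = "".join(rng.choice(codons) for _ in range(30))
            cds = "ATG" + body + "TAA"
            assert translate(cds) == translate_oracle(cds)


class TestFindOrf:
    def test_whole_sequence_orf(self):
        assert find_orf("ATGAAATAG") == (0, "ATGAAATAG")

    def test_no_atg_gives_none(self):
        assert find_orf("CCCTTTCCC") is None

    def test_no_stop_gives_none(self):
        assert find_orf("ATGAAAAAA") is None

    def test_longest_orf_wins(self):
        short = "ATG" + "AAA" * 9 + "TAA"  # 30nt + stop region
        long = "ATG" + "GGG" * 20 + "TAA"
        mrna = "CC" + short + "T" + long
        start, cds = find_orf(mrna)
        assert cds == long

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        bases = np.array(list("ACGT"))
        for _ in range(100):
            mrna = "".join(bases[rng.integers(0, 4, size=120)])
            assert find_orf(mrna) == find_orf_oracle(mrna)


class TestGrouping:
    def _tx(self, tid, protein):
        return TranscriptModel(
            tid, "g", "+", exons=[GenomicInterval("c", 0, 10, "+")], protein=protein
        )

    def test_identical_proteins_share_group(self):
        groups = group_distinct_proteins([self._tx("a", "MK"), self._tx("b", "MK")])
        assert groups == {"MK": ["a", "b"]}

    def test_distinct_proteins_distinct_groups(self):
        groups = group_distinct_proteins(
            [self._tx("a", "MK"), self._tx("b", "MR"), self._tx("c", "MV")]
        )
        assert len(groups) == 3

    def test_partition_property(self):
        rng = np.random.default_rng(6)
        txs = [
            self._tx(f"t{i}", rng.choice(["MA", "MC", "MD", "ME"]))
            for i in range(30)
        ]
        groups = group_distinct_proteins(txs)
        assert sum(len(v) for v in groups.values()) == 30

    def test_missing_protein_warns_and_excluded(self):
        with pytest.warns(UserWarning, match="no protein"):
            groups = group_distinct_proteins(
                [self._tx("a", "MK"), self._tx("b", None)]
            )
        assert groups == {"MK": ["a"]}


class TestCdsOverlap:
    def _tx(self, tid, cds_ivs, strand="+"):
        return TranscriptModel(
            tid, "g", strand,
            exons=[GenomicInterval("c", s, e, strand) for s, e in cds_ivs],
            cds=[GenomicInterval("c", s, e, strand) for s, e in cds_ivs],
        )

    def test_identical_cds_overlap(self):
        a = self._tx("a", [(0, 30)])
        assert cds_overlaps(a, self._tx("b", [(0, 30)]))

    def test_pseudogene_inside_intron_no_overlap(self):
        canonical = self._tx("c", [(0, 30), (100, 130)])
        pseudo = self._tx("p", [(50, 80)])
        assert not cds_overlaps(pseudo, canonical)

    def test_one_bp_overlap_counts(self):
        a = self._tx("a", [(0, 30)])
        b = self._tx("b", [(29, 60)])
        assert cds_overlaps(a, b)
        assert not cds_overlaps(self._tx("b2", [(30, 60)]), a)

    def test_antisense_does_not_count(self):
        a = self._tx("a", [(0, 30)], "+")
        b = self._tx("b", [(0, 30)], "-")
        assert not cds_overlaps(a, b)

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            s1, s2 = rng.integers(0, 50, size=2)
            a = self._tx("a", [(int(s1), int(s1) + 20)])
            b = self._tx("b", [(int(s2), int(s2) + 20)])
            assert cds_overlaps(a, b) == cds_overlaps(b, a)

    def test_missing_cds_raises(self):
        a = self._tx("a", [(0, 30)])
        b = TranscriptModel(
            "b", "g", "+", exons=[GenomicInterval("c", 0, 30, "+")]
        )
        with pytest.raises(ValueError):
            cds_overlaps(a, b)
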