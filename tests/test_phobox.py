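"""Promoter extraction and Pho box scanning against naive oracles."""

import numpy as np
import pytest

from phostress import formats, phobox, simulate
from phostress.exceptions import FormatError, UnknownGeneError


def naive_scan(sequence: str, model: phobox.MotifModel) -> list[tuple[int, int]]:
    """Position-by-position set-membership recount (the oracle)."""
    L = model.length
    out = []
    for i in range(len(sequence) - L + 1):
        mm = sum(
            b not in allowed
            for b, allowed in zip(sequence[i : i + L].upper(), model.half_site)
        )
        if mm <= model.max_mismatch:
            out.append((i, mm))
    return out


class TestCompileMotif:
    def test_default_consensus_structure(self):
        model = phobox.compile_motif()
        assert model.length == 8
        expected = [
            {"C", "T"},
            {"T"},
            {"T"},
            {"A"},
            {"A"},
            {"C", "T"},
            {"C", "T"},
            {"T", "A"},
        ]
        assert [set(s) for s in model.half_site] == expected

    def test_literal_consensus(self):
        model = phobox.compile_motif("ACGT", max_mismatch=0, architecture="single")
        assert [set(s) for s in model.half_site] == [{"A"}, {"C"}, {"G"}, {"T"}]

    @pytest.mark.parametrize("bad", ["PyX", "T/Z", "QQQQ"])
    def test_unknown_codes_rejected(self, bad):
        with pytest.raises(FormatError):
            phobox.compile_motif(bad)


class TestExtractPromoter:
    def test_plus_strand_window_arithmetic(self):
        seq = "A" * 2000
        ann = formats.read_genome_table(
            f">c\n{seq}\n", "id\tstart\tstop\tstrand\ng\t1255\t1560\t+\n"
        )
        region = phobox.extract_promoter(ann, "g", 200)
        assert region.genome_span == (1055, 1254, "+")
        assert len(region) == 200
        assert region.offset_of_first_base == -200

    def test_minus_strand_window_reverse_complemented(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=15_000))
        ann = formats.read_genome_table(
            f">c\n{seq}\n", "id\tstart\tstop\tstrand\ng\t14226\t14432\t-\n"
        )
        region = phobox.extract_promoter(ann, "g", 200)
        assert region.genome_span == (14433, 14632, "-")
        assert region.sequence == formats.reverse_complement(seq[14432:14632])

    def test_gene_at_contig_start_gives_empty_region(self):
        ann = formats.read_genome_table(
            ">c\nACGTACGTAA\n", "id\tstart\tstop\tstrand\ng\t1\t6\t+\n"
        )
        region = phobox.extract_promoter(ann, "g", 50)
        assert region.sequence == ""
        assert phobox.scan_sequence(region, phobox.compile_motif()) == []

    def test_window_truncated_at_contig_edge(self):
        ann = formats.read_genome_table(
            ">c\nACGTACGTAA\n", "id\tstart\tstop\tstrand\ng\t5\t9\t+\n"
        )
        region = phobox.extract_promoter(ann, "g", 50)
        assert region.sequence == "ACGT"
        assert region.offset_of_first_base == -4

    def test_unknown_gene(self, toy_annotation):
        with pytest.raises(UnknownGeneError):
            phobox.extract_promoter(toy_annotation, "nope")


def _region(seq: str) -> phobox.PromoterRegion:
    return phobox.PromoterRegion("g", seq, (1, len(seq), "+"), -len(seq))


class TestScan:
    def test_consensus_instance_hits_with_zero_mismatches(self):
        model = phobox.compile_motif(max_mismatch=0)
        hits = phobox.scan_sequence(_region("TTTAACTT"), model)
        assert len(hits) == 1 and hits[0].mismatches == 0
        assert hits[0].position == -8

    def test_single_mismatch_half_site(self):
        # the final G falls outside the T/A set: exactly one mismatch
        model = phobox.compile_motif(max_mismatch=1)
        hits = phobox.scan_sequence(_region("TTTAACTG"), model)
        assert len(hits) == 1 and hits[0].mismatches == 1

    def test_far_word_not_hit(self):
        model = phobox.compile_motif(max_mismatch=2)
        assert phobox.scan_sequence(_region("AAAAAAAA"), model) == []
        assert model.mismatches("AAAAAAAA") == 5

    def test_scanner_equals_naive_oracle_on_random_sequences(self):
        rng = np.random.default_rng(123)
        model_cache = {
            mm: phobox.compile_motif(max_mismatch=mm) for mm in range(4)
        }
        for _ in range(1000):
            n = int(rng.integers(1, 31))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            mm = int(rng.integers(0, 4))
            model = model_cache[mm]
            hits = phobox.scan_sequence(_region(seq), model)
            assert [
                (h.position + len(seq), h.mismatches) for h in hits
            ] == naive_scan(seq, model)

    def test_n_bases_count_as_mismatches(self):
        model = phobox.compile_motif(max_mismatch=0)
        assert phobox.scan_sequence(_region("TTTAACTTNNN"), model)[0].position == -11
        assert phobox.scan_sequence(_region("NTTAACTT"), model) == []


class TestTandemAssembly:
    def test_planted_tandem_pair_reported_as_one_box(self):
        model = phobox.compile_motif(max_mismatch=0)
        seq = "GGGG" + "TTTAACTT" + "ACG" + "CTTAACTA" + "GGGG"
        region = _region(seq)
        halves = phobox.scan_sequence(region, model)
        boxes = phobox.assemble_tandem_boxes(region, model, halves)
        assert len(boxes) == 1
        box = boxes[0]
        assert box.half_site_count == 2
        assert box.matched_sequence == "TTTAACTT" + "acg" + "CTTAACTA"
        assert box.position == -len(seq) + 4

    def test_triple_half_site_run_is_one_box(self):
        model = phobox.compile_motif(max_mismatch=0)
        seq = "TTTAACTT" + "AAA" + "TTTAACTT" + "CCC" + "TTTAACTT"
        region = _region(seq)
        boxes = phobox.assemble_tandem_boxes(
            region, model, phobox.scan_sequence(region, model)
        )
        assert len(boxes) == 1 and boxes[0].half_site_count == 3

    def test_disallowed_spacer_yields_no_tandem_box(self):
        model = phobox.compile_motif(max_mismatch=0)  # spacers {3}
        seq = "TTTAACTT" + "AAAAA" + "TTTAACTT"
        region = _region(seq)
        boxes = phobox.assemble_tandem_boxes(
            region, model, phobox.scan_sequence(region, model)
        )
        assert boxes == []


class TestFindPhoBoxes:
    def test_full_recovery_of_planted_boxes(self):
        cfg = simulate.GenomeSimConfig(
            seed=31, length=60_000, n_genes=12, planted_fraction=1.0
        )
        ann, truth = simulate.simulate_genome(cfg)
        hits = phobox.find_pho_boxes(ann, phobox.compile_motif(max_mismatch=0))
        for gene, info in truth["planted_boxes"].items():
            sub = hits[(hits["gene_id"] == gene) & (hits["position"] == info["offset"])]
            assert len(sub) >= 1, f"planted box missed for {gene}"
            assert sub.iloc[0]["box"].upper() == info["box"].upper()

    def test_strand_symmetric_offsets(self):
        # same planted offset recovered on + and − strand genes
        cfg = simulate.GenomeSimConfig(
            seed=32,
            length=60_000,
            n_genes=12,
            planted_fraction=1.0,
            alternate_strands=True,
        )
        ann, truth = simulate.simulate_genome(cfg)
        hits = phobox.find_pho_boxes(ann, phobox.compile_motif(max_mismatch=0))
        strands = {ann.feature(g).strand for g in truth["planted_boxes"]}
        assert strands == {"+", "-"}
        for gene, info in truth["planted_boxes"].items():
            assert (
                (hits["gene_id"] == gene) & (hits["position"] == info["offset"])
            ).any()

    def test_fixture_box_mismatch_counts_match_oracle(self, pho_table):
        # every recorded 8-mer half-site's distance equals a naive recount
        model = phobox.compile_motif()
        for box in pho_table["box"].dropna():
            halves, _ = formats.decompose_box(box)
            for h in halves:
                if len(h) != model.length:
                    continue
                naive = sum(
                    b not in allowed for b, allowed in zip(h, model.half_site)
                )
                assert model.mismatches(h) == naive

    def test_bed_output_round_trip_plus_strand(self, toy_annotation):
        model = phobox.compile_motif(max_mismatch=3, architecture="single")
        hits = phobox.find_pho_boxes(toy_annotation, model, window=50)
        bed = phobox.hits_to_bed(toy_annotation, hits)
        for line, row in zip(bed.splitlines(), hits.itertuples(index=False)):
            _, lo0, hi0, name, _, strand = line.split("\t")
            assert int(hi0) - int(lo0) == len(row.box)
            f = toy_annotation.feature(row.gene_id)
            genomic = toy_annotation.sequence[int(lo0) : int(hi0)]
            if f.strand == "+":
                assert genomic == row.box.upper()
            else:
                assert formats.reverse_complement(genomic) == row.box.upper()
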