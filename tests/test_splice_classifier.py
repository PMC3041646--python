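"""Split-alignment taxonomy, multi-read filtering and intervening exons."""

import itertools

import numpy as np
import pytest

from ticfinder.genome_model import GeneModel, Transcript, catalog_splice_sites
from ticfinder.splice_classifier import (
    CATEGORIES,
    GeneLocator,
    Segment,
    SplitAlignmentRecord,
    annotate_known_sites,
    classify_records,
    classify_split,
    detect_ticie,
    filter_multiread,
    read_split_records_tsv,
)
from table2_rows import TABLE2_ROWS, encode_row

from conftest import two_plus_genes, random_seq


def record(chrA, sA, a0, a1, chrB, sB, b0, b1, read="r1", sample="S1"):
    return SplitAlignmentRecord(
        read_id=read,
        sample_id=sample,
        segment_a=Segment(chrA, sA, a0, a1),
        segment_b=Segment(chrB, sB, b0, b1),
    )


class TestClassifySplit:
    @pytest.mark.parametrize(
        "rec,expected",
        [
            # different chromosomes
            (record("chr20", "+", 100, 120, "chr17", "+", 500, 520), "translocation"),
            # opposite strands, one chromosome
            (record("chr13", "+", 100, 120, "chr13", "-", 400, 420), "inversion"),
            # acceptor upstream of donor, plus strand
            (record("chr17", "+", 100_000, 100_020, "chr17", "+", 25_000, 25_020), "scrambled"),
            # acceptor "upstream" on minus strand = larger coordinate
            (record("chr12", "-", 50_000, 50_020, "chr12", "-", 120_000, 120_020), "scrambled"),
            # same strand, downstream, > 200 kb
            (record("chr3", "+", 100, 120, "chr3", "+", 501_800, 501_820), "long_range"),
            (record("chr21", "-", 4_000_000, 4_000_020, "chr21", "-", 930_000, 930_020), "long_range"),
            # same strand, downstream, <= 200 kb, unannotated genes
            (record("chr1", "+", 100, 120, "chr1", "+", 5_000, 5_020), "readthrough"),
        ],
    )
    def test_geometry_categories(self, rec, expected):
        assert classify_split(rec).category == expected

    def test_gene_annotation_separates_intragenic(self, toy_model):
        locator = GeneLocator(toy_model)
        t = toy_model.transcripts[0]
        # splice across gene A's own intron: intragenic
        rec = record("chr1", "+", t.exons[0][0], t.exons[0][1], "chr1", "+", *t.exons[1])
        call = classify_split(rec, locator)
        assert call.category == "intragenic" and call.donor_gene == "GA"
        # splice from gene A into gene B: readthrough within the window
        t2 = toy_model.transcripts[1]
        rec2 = record("chr1", "+", t.exons[1][0], t.exons[1][1], "chr1", "+", *t2.exons[1])
        call2 = classify_split(rec2, locator)
        assert call2.category == "readthrough"
        assert (call2.donor_gene, call2.acceptor_gene) == ("GA", "GB")
        assert call2.distance is not None and call2.distance <= 200_000

    def test_categories_exclusive_and_exhaustive_on_random_geometry(self):
        rng = np.random.default_rng(13)
        chroms = ["chr1", "chr2"]
        for _ in range(500):
            ca, cb = rng.choice(chroms, 2)
            sa, sb = rng.choice(["+", "-"], 2)
            a0 = int(rng.integers(0, 1_000_000))
            b0 = int(rng.integers(0, 1_000_000))
            rec = record(ca, sa, a0, a0 + 20, cb, sb, b0, b0 + 20)
            call = classify_split(rec)
            assert call.category in CATEGORIES
            assert (call.distance is None) == (call.category == "translocation")

    def test_printed_multiread_table_sections(self):
        for row in TABLE2_ROWS:
            section, samples, name = row[0], row[1], row[2]
            rec = encode_row(*row)[0]
            assert classify_split(rec).category == section, name


class TestMultireadFilter:
    def test_distant_single_read_dropped_multi_kept(self):
        records = [
            record("chr1", "+", 0, 20, "chr2", "+", 0, 20, read="r1"),
            record("chr1", "+", 100, 120, "chr3", "+", 0, 20, read="r2"),
            record("chr1", "+", 100, 120, "chr3", "+", 0, 20, read="r3"),
        ]
        calls = filter_multiread(classify_records(records), min_reads=2)
        assert len(calls) == 1 and calls[0].n_reads == 2

    def test_readthrough_untouched_by_multiread_filter(self):
        records = [record("chr1", "+", 0, 20, "chr1", "+", 5_000, 5_020)]
        calls = classify_records(records)
        assert calls[0].category == "readthrough"
        assert filter_multiread(calls, min_reads=2) == calls

    def test_table2_rows_survive_multiread_filter(self):
        records = []
        for row in TABLE2_ROWS:
            records.extend(encode_row(*row))
        calls = classify_records(records)
        distant = [c for c in calls if c.category != "readthrough"]
        assert len(filter_multiread(distant, 2)) == len(TABLE2_ROWS)


# ---------------------------------------------------------------------------
# Intervening exons


@pytest.fixture(scope="module")
def ticie_model():
    return two_plus_genes(gap=3_000)


def ticie_records(model: GeneModel, exon_start: int, exon_len: int,
                  sample="S1", same_read=False):
    """A known-donor->novel-acceptor splice plus a novel-donor->known-acceptor
    splice delimiting an intervening interval on the plus strand."""
    tA, tB = model.transcripts
    donor_pos = tA.exons[-2][1]  # (n-1) donor of gene A
    acceptor_pos = tB.exons[1][0]  # +2 acceptor of gene B
    up = record(
        "chr1", "+", donor_pos - 20, donor_pos,
        "chr1", "+", exon_start, exon_start + 20,
        read="ru", sample=sample,
    )
    down = record(
        "chr1", "+", exon_start + exon_len - 20, exon_start + exon_len,
        "chr1", "+", acceptor_pos, acceptor_pos + 20,
        read="ru" if same_read else "rd", sample=sample,
    )
    return [up, down]


def annotate(model, records):
    donors, acceptors = catalog_splice_sites(model.transcripts)
    annotate_known_sites(records, donors, acceptors)
    return records


class TestDetectTicie:
    def test_planted_intergenic_exon_recovered(self, ticie_model):
        gap_start = ticie_model.transcripts[0].exons[-1][1]
        records = annotate(ticie_model, ticie_records(ticie_model, gap_start + 800, 120))
        cands = detect_ticie(records, ticie_model)
        assert len(cands) == 1
        c = cands[0]
        assert (c.gene5, c.gene3) == ("GA", "GB")
        assert c.exon_length == 120
        assert c.location_class == "intergenic"
        assert c.n_reads == 2 and not c.same_read_support

    @pytest.mark.parametrize("exon_len,called", [(300, True), (301, False), (450, False)])
    def test_exon_length_threshold(self, ticie_model, exon_len, called):
        gap_start = ticie_model.transcripts[0].exons[-1][1]
        records = annotate(
            ticie_model, ticie_records(ticie_model, gap_start + 400, exon_len)
        )
        cands = detect_ticie(records, ticie_model)
        assert bool(cands) is called

    def test_location_classes_from_overlap(self, ticie_model):
        tA, tB = ticie_model.transcripts
        # interval overlapping the last exon of the 5' gene
        over5 = ticie_records(ticie_model, tA.exons[-1][1] - 30, 100)
        c5 = detect_ticie(annotate(ticie_model, over5), ticie_model)
        assert c5 and c5[0].location_class == "overlaps_5p_last_exon"
        # interval overlapping the first exon of the 3' gene
        over3 = ticie_records(ticie_model, tB.exons[0][0] - 70, 100)
        c3 = detect_ticie(annotate(ticie_model, over3), ticie_model)
        assert c3 and c3[0].location_class == "overlaps_3p_first_exon"

    def test_same_read_support_flagged(self, ticie_model):
        gap_start = ticie_model.transcripts[0].exons[-1][1]
        records = annotate(
            ticie_model,
            ticie_records(ticie_model, gap_start + 800, 120, same_read=True),
        )
        cands = detect_ticie(records, ticie_model)
        assert cands and cands[0].same_read_support and cands[0].n_reads == 1

    def test_pairs_only_within_sample(self, ticie_model):
        gap_start = ticie_model.transcripts[0].exons[-1][1]
        up = ticie_records(ticie_model, gap_start + 800, 120, sample="S1")[0]
        down = ticie_records(ticie_model, gap_start + 800, 120, sample="S2")[1]
        cands = detect_ticie(annotate(ticie_model, [up, down]), ticie_model)
        assert cands == []

    def test_matches_brute_force_pairing(self, ticie_model):
        """Candidate set equals the brute-force pairing of all qualifying
        upstream/downstream splice records."""
        rng = np.random.default_rng(3)
        gap_start = ticie_model.transcripts[0].exons[-1][1]
        records = []
        for i, (off, ln) in enumerate(
            [(700, 120), (700, 160), (1200, 90), (1500, 400)]
        ):
            recs = ticie_records(ticie_model, gap_start + off, ln, sample="S1")
            for r in recs:
                r.read_id += f"_{i}"
            records.extend(recs)
        records = annotate(ticie_model, records)
        cands = detect_ticie(records, ticie_model, apply_homology=False)
        ups = [r for r in records if r.site_a_known and not r.site_b_known]
        downs = [r for r in records if r.site_b_known and not r.site_a_known]
        expected = set()
        for u, d in itertools.product(ups, downs):
            lo, hi = sorted((u.acceptor_pos, d.donor_pos))
            if 0 < hi - lo <= 300 and d.donor_pos > u.acceptor_pos:
                expected.add((u.acceptor_pos, d.donor_pos))
        assert {(c.intervening_exon[2], c.intervening_exon[3]) for c in cands} == expected


class TestIO:
    def test_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "records.tsv"
        p.write_text(
            "read_id\tsample_id\tchromA\tstrandA\tstartA\tendA\tchromB\tstrandB\tstartB\tendB\n"
            "r1\tS1\tchr1\t+\t10\t30\tchr2\t-\t50\t70\n"
        )
        (rec,) = read_split_records_tsv(str(p))
        assert rec.segment_a.chrom == "chr1" and rec.segment_b.strand == "-"
        assert classify_split(rec).category == "translocation"
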