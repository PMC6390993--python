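"""I/O, coverage and locus-catalog behaviour."""

import numpy as np
import pandas as pd
import pytest

import snreadthrough as srt
from snreadthrough.genome_io import (
    AnnotationError, BED12_COLUMNS, catalog_to_frame, iter_read_blocks,
)

GFF_MINI = """##gff-version 3
chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=gA
chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=gA.t1;Parent=gA
chr1\tsrc\texon\t101\t200\t.\t+\t.\tID=gA.t1.e1;Parent=gA.t1
chr1\tsrc\tCDS\t111\t200\t.\t+\t.\tID=gA.t1.c1;Parent=gA.t1
chr1\tsrc\tsnRNA\t11\t90\t.\t+\t.\tID=sn1;sn_class=U2-like
"""


def make_reads(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                     "block_count", "block_sizes",
                                     "block_starts"])
    df["name"] = [f"r{i}" for i in range(len(df))]
    df["score"] = 0
    df["thick_start"] = df["start"]
    df["thick_end"] = df["end"]
    df["item_rgb"] = 0
    return df[BED12_COLUMNS]


class TestAnnotation:
    def test_gff3_coordinates_become_zero_based_half_open(self):
        genes, sn = srt.parse_annotation(GFF_MINI)
        g = genes["gA"]
        assert (g.start, g.end) == (100, 200)
        assert g.exons == ((100, 200),)
        assert g.cds_start == 110
        assert sn[0].start == 10 and sn[0].end == 90
        assert sn[0].sn_class == "U2-like"

    def test_single_exon_gene_has_no_introns(self):
        genes, _ = srt.parse_annotation(GFF_MINI)
        assert genes["gA"].introns == ()

    def test_round_trip_is_identity(self):
        genes, sn = srt.parse_annotation(GFF_MINI)
        text = srt.write_annotation(genes.values(), sn)
        genes2, sn2 = srt.parse_annotation(text)
        assert genes == genes2
        assert sn == sn2

    def test_malformed_gff_raises(self):
        with pytest.raises(AnnotationError):
            srt.parse_annotation("##gff-version 3\nchr1\tonly\tthree\n")

    def test_gene_model_validation(self):
        with pytest.raises(AnnotationError, match="overlap"):
            srt.GeneModel(gene_id="g", chrom="c", strand="+", start=0, end=100,
                          exons=((0, 60), (50, 100)), cds_start=0)
        with pytest.raises(AnnotationError, match="cds_start"):
            srt.GeneModel(gene_id="g", chrom="c", strand="+", start=0, end=100,
                          exons=((0, 40), (60, 100)), cds_start=50)


class TestCoverage:
    sizes = {"chr1": 200}

    def test_single_read_depth(self):
        reads = make_reads([("chr1", 10, 60, "+", 1, "50", "0")])
        cov = srt.load_alignments(reads, self.sizes)["chr1"]
        assert (cov.depth["+"][10:60] == 1).all()
        assert cov.depth["+"].sum() == 50
        assert cov.depth["-"].sum() == 0

    def test_split_read_records_one_junction(self):
        reads = make_reads([("chr1", 10, 70, "+", 2, "20,20", "0,40")])
        cov = srt.load_alignments(reads, self.sizes)["chr1"]
        assert cov.junctions["+"] == {(30, 50): 1}
        assert cov.depth["+"][30:50].sum() == 0
        assert (cov.depth["+"][10:30] == 1).all()

    def test_reverse_protocol_flips_strand(self):
        reads = make_reads([("chr1", 10, 60, "+", 1, "50", "0")])
        cov = srt.load_alignments(reads, self.sizes, protocol="reverse")["chr1"]
        assert cov.depth["+"].sum() == 0
        assert cov.depth["-"].sum() == 50

    def test_unsorted_input_rejected(self):
        reads = make_reads([("chr1", 60, 80, "+", 1, "20", "0"),
                            ("chr1", 10, 30, "+", 1, "20", "0")])
        with pytest.raises(ValueError, match="sorted"):
            srt.load_alignments(reads, self.sizes)

    def test_unknown_chromosome_rejected(self):
        reads = make_reads([("chrX", 10, 30, "+", 1, "20", "0")])
        with pytest.raises(ValueError, match="unknown chromosome"):
            srt.load_alignments(reads, self.sizes)

    def test_coverage_conserves_block_length(self, knockdown_run):
        reads = knockdown_run["reads"]
        total_depth = sum(cov.depth[s].sum()
                          for cov in knockdown_run["coverage"].values()
                          for s in "+-")
        block_len = sum(
            sum(e - s for s, e in iter_read_blocks(row))
            for row in reads.itertuples())
        assert total_depth == block_len

    def test_one_read_hits_exactly_one_strand(self, knockdown_run):
        reads = knockdown_run["reads"]
        cov = knockdown_run["coverage"]
        per_strand_blocks = reads.groupby("strand")["block_count"].count()
        for s in "+-":
            n_starts = sum(c.starts[s].sum() for c in cov.values())
            n_blocks = int(reads.loc[reads["strand"] == s, "block_count"].sum())
            assert n_starts == n_blocks
        assert per_strand_blocks.sum() == len(reads)

    def test_bed12_round_trip(self, knockdown_run, tmp_path):
        path = tmp_path / "reads.bed"
        srt.write_bed12(knockdown_run["reads"], path)
        back = srt.read_bed12(path)
        assert len(back) == len(knockdown_run["reads"])
        assert (back["start"].to_numpy()
                == knockdown_run["reads"]["start"].to_numpy()).all()


class TestCountRegion:
    def test_mean_depth_examples(self):
        cov = srt.StrandedCoverage(chrom="c", length=10)
        cov.depth["+"][:] = 10
        assert srt.count_region(cov, (2, 8), "+")[0] == 10.0
        cov.depth["+"][:] = 0
        assert srt.count_region(cov, (2, 8), "+")[0] == 0.0
        cov.depth["+"][0], cov.depth["+"][1] = 0, 10
        assert srt.count_region(cov, (0, 2), "+")[0] == 5.0

    def test_empty_interval_rejected(self):
        cov = srt.StrandedCoverage(chrom="c", length=10)
        with pytest.raises(ValueError):
            srt.count_region(cov, (5, 5), "+")

    def test_block_count_is_exact(self):
        reads = make_reads([("chr1", 0, 30, "+", 1, "30", "0"),
                            ("chr1", 20, 50, "+", 1, "30", "0"),
                            ("chr1", 60, 90, "+", 1, "30", "0")])
        cov = srt.load_alignments(reads, {"chr1": 100})["chr1"]
        assert srt.count_region(cov, (25, 45), "+")[1] == 2
        assert srt.count_region(cov, (0, 100), "+")[1] == 3
        assert srt.count_region(cov, (50, 60), "+")[1] == 0


class TestLocusCatalog:
    def feature(self, start, end, strand="+", locus_id="sn1"):
        return srt.SnFeature(locus_id=locus_id, sn_class="U2-like",
                             chrom="chr1", start=start, end=end, strand=strand)

    def gene(self, gid, start, end, strand="+"):
        return srt.GeneModel(gene_id=gid, chrom="chr1", strand=strand,
                             start=start, end=end, exons=((start, end),),
                             cds_start=start if strand == "+" else end - 1)

    def test_sense_pairing_and_distance(self):
        genes = {"gA": self.gene("gA", 1300, 1600)}
        [e] = srt.build_locus_catalog([self.feature(900, 1000)], genes)
        assert e.downstream_gene_id == "gA"
        assert e.orientation == "sense"
        assert e.distance_to_gene == 300

    def test_antisense_pairing(self):
        genes = {"gA": self.gene("gA", 1300, 1600, strand="-")}
        [e] = srt.build_locus_catalog([self.feature(900, 1000)], genes)
        assert e.orientation == "antisense"
        assert e.downstream_gene_strand_code == -1

    def test_minus_strand_locus_looks_leftward(self):
        genes = {"gA": self.gene("gA", 100, 400, strand="-"),
                 "gB": self.gene("gB", 1300, 1600)}
        [e] = srt.build_locus_catalog([self.feature(900, 1000, strand="-")],
                                      genes)
        assert e.downstream_gene_id == "gA"
        assert e.orientation == "sense"
        assert e.distance_to_gene == 500

    def test_tie_broken_by_strand_match_then_id(self):
        genes = {"gMinus": self.gene("gMinus", 1200, 1500, strand="-"),
                 "gPlus": self.gene("gPlus", 1200, 1500)}
        # same start -> same distance; the locus-strand gene wins
        genes["gMinus"] = srt.GeneModel(
            gene_id="gMinus", chrom="chr1", strand="-", start=1200, end=1400,
            exons=((1200, 1400),), cds_start=1399)
        [e] = srt.build_locus_catalog([self.feature(900, 1000)], genes)
        assert e.downstream_gene_id == "gPlus"

    def test_distance_cap_leaves_locus_unpaired(self):
        genes = {"gA": self.gene("gA", 9000, 9300)}
        [e] = srt.build_locus_catalog([self.feature(900, 1000)], genes,
                                      max_distance=5000)
        assert e.downstream_gene_id == ""
        assert e.orientation == ""

    def test_intronic_locus_flagged(self):
        host = srt.GeneModel(gene_id="host", chrom="chr1", strand="+",
                             start=500, end=3000,
                             exons=((500, 800), (2000, 3000)), cds_start=500)
        genes = {"host": host, "gA": self.gene("gA", 1300, 1600)}
        [e] = srt.build_locus_catalog([self.feature(900, 1000)], genes)
        assert e.in_intron and e.in_intron_of == "host"

    def test_every_feature_yields_one_entry(self, mixed_bundle):
        entries = srt.build_locus_catalog(mixed_bundle.sn_features,
                                          mixed_bundle.gene_models)
        assert len(entries) == len(mixed_bundle.sn_features)
        frame = catalog_to_frame(entries)
        assert frame["locus_id"].is_unique
        # orientation is consistent with the strand codes
        paired = frame[frame["downstream_gene_id"] != ""]
        sense = paired["strand_code"] == paired["downstream_gene_strand_code"]
        assert (paired.loc[sense, "orientation"] == "sense").all()
        assert (paired.loc[~sense, "orientation"] == "antisense").all()
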