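"""Simulator: construction, determinism, and planted-parameter consistency."""

import math

import numpy as np
import pytest

import snreadthrough as srt
from snreadthrough.genome_io import iter_read_blocks
from snreadthrough.synth import SimulationError


def one_locus_layout(chrom_len=10_000, gene_offset=300):
    gene = srt.GeneModel(gene_id="geneA", chrom="chr1", strand="+",
                         start=450 + gene_offset, end=450 + gene_offset + 300,
                         exons=((450 + gene_offset, 450 + gene_offset + 300),),
                         cds_start=450 + gene_offset)
    locus = srt.SnLocusSpec(
        locus_id="u1", sn_class="U1-like", chrom="chr1", start=300,
        end=gene.end, strand="+", mature_end=450,
        downstream_gene_id="geneA", orientation="sense",
        intergenic_length=gene_offset)
    spec = srt.GenomeSpec(chromosomes=(("chr1", chrom_len),), seed=7)
    return spec, [locus], [gene]


class TestBuildToyGenome:
    def test_construction_matches_layout(self):
        spec, loci, genes = one_locus_layout()
        bundle = srt.build_toy_genome(spec, loci, genes)
        assert len(bundle.sequences["chr1"]) == 10_000
        top_level = [l for l in bundle.gff3_text.splitlines()
                     if "\tgene\t" in l or "\tsnRNA\t" in l]
        assert len(top_level) == 2
        assert len(bundle.catalog) == 1
        entry = bundle.catalog[0]
        assert entry.orientation == "sense"
        assert entry.distance_to_gene == 300

    def test_deterministic_given_seed(self):
        spec, loci, genes = one_locus_layout()
        b1 = srt.build_toy_genome(spec, loci, genes)
        b2 = srt.build_toy_genome(spec, loci, genes)
        assert b1.sequences == b2.sequences
        assert b1.gff3_text == b2.gff3_text

    def test_out_of_bounds_locus_rejected(self):
        spec, loci, genes = one_locus_layout(chrom_len=900)
        with pytest.raises(SimulationError, match="bounds"):
            srt.build_toy_genome(spec, loci, genes)

    def test_duplicate_ids_rejected(self):
        spec, loci, genes = one_locus_layout()
        genes.append(genes[0])
        with pytest.raises(SimulationError, match="duplicate"):
            srt.build_toy_genome(spec, loci, genes)

    def test_gene_start_codon_planted(self):
        spec, loci, genes = one_locus_layout()
        bundle = srt.build_toy_genome(spec, loci, genes)
        g = bundle.gene_models["geneA"]
        assert bundle.sequences["chr1"][g.cds_start:g.cds_start + 3] == "ATG"

    def test_genome_spec_validation(self):
        with pytest.raises(SimulationError):
            srt.GenomeSpec(chromosomes=(("c", 100), ("c", 200)))
        with pytest.raises(SimulationError):
            srt.GenomeSpec(chromosomes=(("c", 0),))

    def test_mature_length_must_be_snRNA_sized(self):
        with pytest.raises(SimulationError, match="60-200"):
            srt.SnLocusSpec(locus_id="x", sn_class="U1-like", chrom="c",
                            start=0, end=500, strand="+", mature_end=400)


class TestTranscriptPool:
    def test_fully_processed_pool_is_all_mature(self, mixed_bundle):
        params = srt.SimulationParams(f_unprocessed=0.0, snRNA_copies=50,
                                      mRNA_copies=0, seed=0)
        pool = srt.simulate_transcript_pool(mixed_bundle, params)
        assert {t.category for t in pool} == {"mature_snRNA"}
        for t in pool:
            locus = next(l for l in mixed_bundle.locus_specs
                         if l.locus_id == t.locus_id)
            assert t.blocks == (locus.mature_span,)

    def test_fully_unprocessed_no_retention_splices_everything(self, mixed_bundle):
        params = srt.SimulationParams(f_unprocessed=1.0, ir_prob=0.0,
                                      snRNA_copies=20, mRNA_copies=0, seed=0)
        pool = srt.simulate_transcript_pool(mixed_bundle, params)
        sense = [t for t in pool if t.category == "chimeric_sn_mRNA"]
        assert sense and all(t.retained_introns == () for t in sense)
        for t in sense:
            gene = mixed_bundle.gene_models[t.gene_id]
            for intron in gene.introns:
                for s, e in t.blocks:
                    assert e <= intron[0] or s >= intron[1]

    def test_chimera_count_follows_binomial(self, mixed_bundle):
        f, copies = 0.062, 10_000
        params = srt.SimulationParams(f_unprocessed=f, snRNA_copies=copies,
                                      mRNA_copies=0, seed=42)
        pool = srt.simulate_transcript_pool(mixed_bundle, params)
        per_locus = {}
        for t in pool:
            if t.category in ("chimeric_sn_mRNA", "antisense_chimera"):
                per_locus[t.locus_id] = per_locus.get(t.locus_id, 0) + 1
        sd = math.sqrt(copies * f * (1 - f))
        for locus_id, n in per_locus.items():
            assert abs(n - copies * f) <= 3 * sd

    def test_per_class_fraction_mapping(self, mixed_bundle):
        params = srt.SimulationParams(
            f_unprocessed={"U1-like": 0.0, "U2-like": 1.0, "SL-like": 0.0},
            snRNA_copies=10, mRNA_copies=0, seed=0)
        pool = srt.simulate_transcript_pool(mixed_bundle, params)
        by_locus = {}
        for t in pool:
            by_locus.setdefault(t.locus_id, set()).add(t.category)
        assert by_locus["sn000"] == {"mature_snRNA"}          # U1-like
        assert "mature_snRNA" not in by_locus["sn001"]        # U2-like, f=1

    def test_parameter_validation(self):
        with pytest.raises(SimulationError):
            srt.SimulationParams(f_unprocessed=1.5)
        with pytest.raises(SimulationError):
            srt.SimulationParams(read_length=5)


class TestAlignments:
    def test_mature_snRNA_reads_bounded_by_cleavage_point(self, mixed_bundle):
        locus = mixed_bundle.locus_specs[0]
        pool = [srt.TranscriptRecord(
            transcript_id="m", category="mature_snRNA", chrom=locus.chrom,
            strand="+", blocks=(locus.mature_span,), locus_id=locus.locus_id)]
        params = srt.SimulationParams(fragments_per_kb=700.0, seed=5)
        reads, _ = srt.simulate_alignments(pool, params)
        assert len(reads) > 50
        assert int(reads["end"].max()) <= locus.mature_end
        assert int(reads["start"].min()) >= locus.start

    def test_reads_stay_inside_transcript_blocks(self, knockdown_run):
        pool_blocks = {}
        for t in knockdown_run["pool"]:
            pool_blocks.setdefault((t.chrom, t.strand), set()).add(t.blocks)
        for row in knockdown_run["reads"].sample(200, random_state=0).itertuples():
            blocks = iter_read_blocks(row)
            key = (row.chrom, row.strand)
            ok = any(
                all(any(ts <= s and e <= te for ts, te in tblocks)
                    for s, e in blocks)
                for tblocks in pool_blocks[key])
            assert ok, f"read {blocks} outside every transcript"

    def test_split_reads_cross_spliced_introns(self, mixed_bundle):
        gene = mixed_bundle.gene_models["gene000"]
        locus = mixed_bundle.locus_specs[0]
        blocks = tuple(
            b for b in [(locus.start, gene.exons[0][1])] + list(gene.exons[1:]))
        pool = [srt.TranscriptRecord(
            transcript_id="c", category="chimeric_sn_mRNA", chrom=locus.chrom,
            strand="+", blocks=blocks, locus_id=locus.locus_id,
            gene_id=gene.gene_id)]
        params = srt.SimulationParams(fragments_per_kb=100.0, seed=6)
        reads, _ = srt.simulate_alignments(pool, params)
        split = reads[reads["block_count"] > 1]
        assert len(split) > 0
        cov = srt.load_alignments(reads, mixed_bundle.chrom_sizes)
        junctions = cov[locus.chrom].junctions["+"]
        assert set(gene.introns) <= set(junctions)
        assert sum(junctions.values()) == int(
            (reads["block_count"] - 1).sum())

    def test_total_read_count_tracks_depth_parameter(self, mixed_bundle):
        params = srt.SimulationParams(f_unprocessed=0.0, snRNA_copies=2000,
                                      mRNA_copies=0, fragments_per_kb=40.0,
                                      seed=8)
        pool = srt.simulate_transcript_pool(mixed_bundle, params)
        reads, _ = srt.simulate_alignments(pool, params)
        expected = sum(t.length for t in pool) * params.fragments_per_kb / 1000
        assert abs(len(reads) - expected) <= 3 * math.sqrt(expected)

    def test_same_seed_identical_output(self, mixed_bundle):
        params = srt.SimulationParams(f_unprocessed=0.2, snRNA_copies=100,
                                      mRNA_copies=10, seed=9)
        pool = srt.simulate_transcript_pool(mixed_bundle, params)
        r1, _ = srt.simulate_alignments(pool, params)
        r2, _ = srt.simulate_alignments(pool, params)
        assert r1.equals(r2)

    def test_short_transcripts_skipped_with_warning(self, caplog):
        pool = [srt.TranscriptRecord(
            transcript_id="tiny", category="mature_snRNA", chrom="chr1",
            strand="+", blocks=((0, 5),))]
        params = srt.SimulationParams(seed=0)
        with pytest.raises(SimulationError):
            srt.simulate_alignments([], params)
        import logging
        with caplog.at_level(logging.WARNING):
            reads, truth = srt.simulate_alignments(pool, params)
        assert len(reads) == 0
        assert "skipping" in caplog.text


class TestCountMatrix:
    def test_no_planted_signal_means_equal_group_means(self):
        cohort = srt.CohortParams(n_genes=400, n_samples_per_group=10,
                                  fold_change=1.0, dispersion=0.02, seed=3)
        counts, groups, _ = srt.simulate_count_matrix(cohort)
        means = counts.T.groupby(groups).mean()
        ratio = means.loc["catalytic_kd"] / means.loc["control"]
        assert abs(np.log2(ratio).mean()) < 0.05

    def test_planted_fold_change_recovered(self):
        ids = [f"g{i:05d}" for i in range(1000)]
        planted = frozenset(ids[:200])
        cohort = srt.CohortParams(
            n_genes=1000, n_samples_per_group=3,
            groups=("control", "holder_kd", "catalytic_kd"),
            planted_up={"catalytic_kd": planted}, fold_change=4.0,
            dispersion=0.02, seed=4)
        counts, groups, truth = srt.simulate_count_matrix(cohort)
        kd = counts.loc[sorted(planted), groups[groups == "catalytic_kd"].index]
        ctrl = counts.loc[sorted(planted), groups[groups == "control"].index]
        fold = (kd.mean(axis=1) / ctrl.mean(axis=1)).mean()
        assert abs(fold - 4.0) < 0.4

    def test_kinome_style_catalog_overlap_recorded(self):
        cohort = srt.default_cohort(seed=0)
        _, _, truth = srt.simulate_count_matrix(cohort)
        assert truth["catalog_overlap_k"][("kinase-like", "catalytic_kd")] == 101
        assert truth["catalog_overlap_k"][("phosphatase-like", "catalytic_kd")] == 78
        assert len(truth["geneset_catalogs"]["kinase-like"]) == 438
        assert len(truth["geneset_catalogs"]["phosphatase-like"]) == 206

    def test_planted_up_down_must_be_disjoint(self):
        with pytest.raises(SimulationError):
            srt.CohortParams(planted_up={"g": frozenset({"a"})},
                             planted_down={"g": frozenset({"a"})},
                             groups=("g",))
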