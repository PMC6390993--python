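"""Compare intron retention of chimera-transcribed genes against controls.

Genes transcribed as chimeric sn-mRNAs splice less efficiently; the
retention ratio (intron-overlapping reads / all gene reads) quantifies this
against control genes that have no upstream snRNA.
"""

import snreadthrough as srt

spec, loci, genes = srt.design_readthrough_panel(
    n_loci=5, sn_class="U2-like", seed=0, n_control_genes=5)
bundle = srt.build_toy_genome(spec, loci, genes)
params = srt.SimulationParams(f_unprocessed=0.5, ir_prob=0.165,
                              ir_prob_native=0.01, snRNA_copies=400,
                              mRNA_copies=150, fragments_per_kb=20.0, seed=3)
pool = srt.simulate_transcript_pool(bundle, params)
reads, _ = srt.simulate_alignments(pool, params)

downstream_ids = {e.downstream_gene_id for e in bundle.catalog}
downstream, control = [], []
for gid, gene in sorted(bundle.gene_models.items()):
    group = "downstream_of_snRNA" if gid in downstream_ids else "control"
    r = srt.intron_retention(gene, reads, group=group)
    (downstream if gid in downstream_ids else control).append(r)
    print(f"{gid} ({group}): {r.intronic_read_count}/{r.total_read_count} "
          f"intronic reads, ir_ratio = {r.ir_ratio:.3f}")

cmp = srt.compare_retention(downstream, control)
print(f"\ndownstream vs control: difference of means "
      f"{cmp.mean_difference:.3f}, Welch t = {cmp.t_statistic:.2f}, "
      f"p = {cmp.p_value:.2e}")
# Downstream genes mix chimeric transcripts (per-intron retention 0.165)
# with native mRNA, so their ratio is elevated; controls stay near the
# native retention rate of about 1%.
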