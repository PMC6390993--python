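import pytest

import snreadthrough as srt


@pytest.fixture(scope="session")
def mixed_bundle():
    """Four snRNA->gene units: U1/U2/SL sense plus one antisense U2."""
    spec, loci, genes = srt.design_readthrough_panel(
        n_loci=4,
        sn_class=["U1-like", "U2-like", "SL-like", "U2-like"],
        orientation=["sense", "sense", "sense", "antisense"],
        seed=1,
    )
    return srt.build_toy_genome(spec, loci, genes)


@pytest.fixture(scope="session")
def knockdown_run(mixed_bundle):
    """Deep knockdown-like simulation (half of snRNA transcripts unprocessed)."""
    params = srt.SimulationParams(
        f_unprocessed=0.5, ir_prob=0.165, ir_prob_native=0.01,
        snRNA_copies=500, mRNA_copies=100, fragments_per_kb=30.0, seed=3)
    pool = srt.simulate_transcript_pool(mixed_bundle, params)
    reads, truth = srt.simulate_alignments(pool, params)
    coverage = srt.load_alignments(reads, mixed_bundle.chrom_sizes)
    return {"bundle": mixed_bundle, "params": params, "pool": pool,
            "reads": reads, "truth": truth, "coverage": coverage}


@pytest.fixture(scope="session")
def control_run(mixed_bundle):
    """Control-like simulation: every snRNA transcript properly processed."""
    params = srt.SimulationParams(
        f_unprocessed=0.0, snRNA_copies=500, mRNA_copies=100,
        fragments_per_kb=30.0, seed=4)
    pool = srt.simulate_transcript_pool(mixed_bundle, params)
    reads, _ = srt.simulate_alignments(pool, params)
    coverage = srt.load_alignments(reads, mixed_bundle.chrom_sizes)
    return {"bundle": mixed_bundle, "params": params, "pool": pool,
            "reads": reads, "coverage": coverage}
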