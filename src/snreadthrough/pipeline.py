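"""simulate -> quantify -> report orchestration with one reproducible config.

Every threshold any stage uses lives in :class:`PipelineConfig`, round-trips
through YAML, and is recorded in the run manifest, so a run is fully
described by (config, seed).  Stages are independent: quantify analyses
whatever inputs exist and skips (with a logged notice) stages whose inputs
are missing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .genome_io import (
    build_locus_catalog, catalog_to_frame, load_alignments, parse_annotation,
    read_bed12, read_fasta, write_bed12,
)
from .chimera import call_chimera, calls_to_frame
from .enrichment import enrich, read_gene_sets, write_gene_sets
from .expression import (
    intersect_calls, normalize, pca, phenocluster, sample_distances, simple_de,
)
from .readthrough import readthrough_index, results_to_frame, summarize_by_class
from .splicing import compare_retention, intron_retention, retention_to_frame
from .synth import (
    CohortParams, SimulationParams, build_toy_genome, default_cohort,
    design_readthrough_panel, simulate_alignments, simulate_count_matrix,
    simulate_transcript_pool,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All paths, thresholds and seeds of a pipeline run."""

    outdir: str = "snrt_out"
    seed: int = 0
    genome_seed: int = 0

    # --- simulation scenario (the study-like default panel) ---
    n_loci: int = 8
    sn_classes: tuple[str, ...] = (
        "U1-like", "U1-like", "U2-like", "U2-like",
        "SL-like", "SL-like", "snoRNA-like", "U2-like")
    orientations: tuple[str, ...] = (
        "sense", "sense", "sense", "sense",
        "sense", "sense", "sense", "antisense")
    f_unprocessed: dict = field(default_factory=lambda: {
        "U1-like": 0.014, "U2-like": 0.062, "SL-like": 0.05,
        "snoRNA-like": 0.03})
    ir_prob: float = 0.165
    ir_prob_native: float = 0.01
    snRNA_copies: int = 2000
    mRNA_copies: int = 200
    read_length: int = 50
    fragments_per_kb: float = 20.0
    n_control_genes: int = 4
    simulate_cohort: bool = True
    cohort_n_genes: int = 3000
    cohort_fold_change: float = 4.0
    cohort_dispersion: float = 0.05

    # --- analysis thresholds ---
    max_pairing_distance: int = 5000
    delta: int = 20
    window: int = 50
    tau: float = 0.005
    min_body_reads: int = 50
    covered_threshold: float = 0.8
    ir_mode: str = "any_overlap"
    de_q: float = 0.05
    linkage: str = "average"
    k_clusters: int = 3
    protocol: str = "forward"
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["sn_classes"] = list(d["sn_classes"])
        d["orientations"] = list(d["orientations"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["sn_classes"] = tuple(d["sn_classes"])
        d["orientations"] = tuple(d["orientations"])
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, config: PipelineConfig,
                    files: list[Path]) -> Path:
    cfg = dataclasses.asdict(config)
    manifest = {
        "package": "snreadthrough",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=list).encode()).hexdigest(),
        "config": cfg,
        "files": {p.name: _sha256(p) for p in sorted(files)},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=list))
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Write the synthetic genome bundle, alignments, counts and truth tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("[stage:simulate] start outdir=%s seed=%d", outdir, config.seed)

    spec, loci, genes = design_readthrough_panel(
        n_loci=config.n_loci, sn_class=config.sn_classes,
        orientation=config.orientations, seed=config.genome_seed,
        n_control_genes=config.n_control_genes)
    bundle = build_toy_genome(spec, loci, genes)
    paths = bundle.write(outdir)

    params = SimulationParams(
        f_unprocessed=config.f_unprocessed, ir_prob=config.ir_prob,
        ir_prob_native=config.ir_prob_native, snRNA_copies=config.snRNA_copies,
        mRNA_copies=config.mRNA_copies, read_length=config.read_length,
        fragments_per_kb=config.fragments_per_kb, seed=config.seed)
    pool = simulate_transcript_pool(bundle, params)
    reads, truth = simulate_alignments(pool, params)
    paths["alignments.bed"] = outdir / "alignments.bed"
    write_bed12(reads, paths["alignments.bed"])
    paths["alignment_truth.tsv"] = outdir / "alignment_truth.tsv"
    truth.to_csv(paths["alignment_truth.tsv"], sep="\t", index=False)

    if config.simulate_cohort:
        cohort = default_cohort(seed=config.seed,
                                n_genes=config.cohort_n_genes,
                                fold_change=config.cohort_fold_change,
                                dispersion=config.cohort_dispersion)
        counts, groups, truth_c = simulate_count_matrix(cohort)
        paths["counts.tsv"] = outdir / "counts.tsv"
        counts.to_csv(paths["counts.tsv"], sep="\t")
        paths["sample_groups.tsv"] = outdir / "sample_groups.tsv"
        groups.to_frame().to_csv(paths["sample_groups.tsv"], sep="\t")
        paths["gene_sets.tsv"] = outdir / "gene_sets.tsv"
        write_gene_sets(truth_c["geneset_catalogs"], paths["gene_sets.tsv"])
        planted = [(grp, "up", g) for grp, s in truth_c["planted_up"].items()
                   for g in sorted(s)]
        planted += [(grp, "down", g) for grp, s in truth_c["planted_down"].items()
                    for g in sorted(s)]
        paths["planted_genes.tsv"] = outdir / "planted_genes.tsv"
        pd.DataFrame(planted, columns=["group", "direction", "gene_id"]).to_csv(
            paths["planted_genes.tsv"], sep="\t", index=False)

    paths["manifest.json"] = _write_manifest(outdir, config,
                                             list(paths.values()))
    logger.info("[stage:simulate] done (%d files)", len(paths))
    return paths


def run_quantify(config: PipelineConfig) -> dict[str, Path]:
    """Run every analysis stage whose inputs exist; write one TSV per stage."""
    outdir = Path(config.outdir)
    written: dict[str, Path] = {}
    logger.info("[stage:quantify] start outdir=%s", outdir)

    gff = outdir / "annotation.gff3"
    fasta = outdir / "genome.fa"
    bed = outdir / "alignments.bed"
    if gff.exists() and fasta.exists() and bed.exists():
        genes, sn_features = parse_annotation(gff.read_text())
        catalog = build_locus_catalog(sn_features, genes,
                                      max_distance=config.max_pairing_distance)
        sizes = {c: len(s) for c, s in read_fasta(fasta).items()}
        reads = read_bed12(bed)
        coverage = load_alignments(reads, sizes, protocol=config.protocol)

        results = [readthrough_index(
            e, coverage, read_length=config.read_length, delta=config.delta,
            window=config.window, tau=config.tau,
            min_body_reads=config.min_body_reads) for e in catalog]
        rt_frame = results_to_frame(results, catalog)
        written["readthrough.tsv"] = outdir / "readthrough.tsv"
        rt_frame.to_csv(written["readthrough.tsv"], sep="\t", index=False)
        written["readthrough_by_class.tsv"] = outdir / "readthrough_by_class.tsv"
        summarize_by_class(results, catalog).to_csv(
            written["readthrough_by_class.tsv"], sep="\t", index=False)

        calls = [call_chimera(e, coverage, genes.get(e.downstream_gene_id),
                              covered_threshold=config.covered_threshold)
                 for e in catalog]
        written["chimera.tsv"] = outdir / "chimera.tsv"
        calls_to_frame(calls).to_csv(written["chimera.tsv"], sep="\t",
                                     index=False)

        downstream = {e.downstream_gene_id for e in catalog
                      if e.orientation == "sense" and e.downstream_gene_id}
        retention = [
            intron_retention(g, reads, mode=config.ir_mode,
                             group=("downstream_of_snRNA"
                                    if gid in downstream else "control"))
            for gid, g in sorted(genes.items())
        ]
        written["retention.tsv"] = outdir / "retention.tsv"
        retention_to_frame(retention).to_csv(written["retention.tsv"],
                                             sep="\t", index=False)
        ds = [r for r in retention
              if r.group == "downstream_of_snRNA" and r.defined]
        ctrl = [r for r in retention if r.group == "control" and r.defined]
        if len(ds) >= 2 and len(ctrl) >= 2:
            cmp_res = compare_retention(ds, ctrl)
            written["retention_comparison.tsv"] = outdir / "retention_comparison.tsv"
            pd.DataFrame([dataclasses.asdict(cmp_res)]).to_csv(
                written["retention_comparison.tsv"], sep="\t", index=False)
    else:
        logger.info("[stage:quantify] genome/annotation/alignments missing; "
                    "coverage stages skipped")

    counts_path = outdir / "counts.tsv"
    groups_path = outdir / "sample_groups.tsv"
    if counts_path.exists() and groups_path.exists():
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
        norm = normalize(counts)
        control = [s for s, g in groups.items() if g == "control"]
        de_frames = []
        common_up: set[str] = set()
        for grp in sorted(set(groups) - {"control"}):
            cols = [s for s, g in groups.items() if g == grp]
            if len(cols) < 2 or len(control) < 2:
                continue
            welch = simple_de(counts, cols, control, equal_var=False,
                              alpha=config.de_q)
            pooled = simple_de(counts, cols, control, equal_var=True,
                               alpha=config.de_q)
            up, down = intersect_calls(welch, pooled)
            welch["group"] = grp
            welch["common"] = [
                "up" if g in up else ("down" if g in down else "ns")
                for g in welch["gene_id"]]
            de_frames.append(welch)
            common_up = common_up | up if common_up else up
        if de_frames:
            written["de_calls.tsv"] = outdir / "de_calls.tsv"
            pd.concat(de_frames, ignore_index=True).to_csv(
                written["de_calls.tsv"], sep="\t", index=False)

        dist = sample_distances(norm.log2)
        written["sample_distances.tsv"] = outdir / "sample_distances.tsv"
        dist.to_csv(written["sample_distances.tsv"], sep="\t")
        labels = phenocluster(dist, k=config.k_clusters, method=config.linkage)
        written["phenoclusters.tsv"] = outdir / "phenoclusters.tsv"
        labels.to_frame().to_csv(written["phenoclusters.tsv"], sep="\t")
        coords, ratios = pca(norm.log2)
        coords["variance_explained_PC1"] = ratios[0]
        coords["variance_explained_PC2"] = ratios[1] if len(ratios) > 1 else 0.0
        written["pca.tsv"] = outdir / "pca.tsv"
        coords.to_csv(written["pca.tsv"], sep="\t")

        sets_path = outdir / "gene_sets.tsv"
        if sets_path.exists() and common_up:
            catalogs = read_gene_sets(sets_path)
            table = enrich(common_up, catalogs, universe=set(counts.index))
            written["enrichment.tsv"] = outdir / "enrichment.tsv"
            table.to_csv(written["enrichment.tsv"], sep="\t", index=False)
    else:
        logger.info("[stage:quantify] counts missing; expression and "
                    "enrichment stages skipped")
    logger.info("[stage:quantify] done (%d tables)", len(written))
    return written


def run_report(config: PipelineConfig) -> Path:
    """Assemble a deterministic text summary from the stage TSVs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["# snRNA read-through pipeline report", ""]

    def section(title: str) -> None:
        lines.append(f"## {title}")

    section("Read-through by snRNA class")
    p = outdir / "readthrough_by_class.tsv"
    if p.exists():
        df = pd.read_csv(p, sep="\t")
        for _, r in df.iterrows():
            lines.append(
                f"- {r['sn_class']}: n={int(r['n_loci'])} "
                f"mean rt_index={r['mean_rt_index']:.4f} "
                f"(pooled {r['pooled_rt_index']:.4f}), "
                f"affected={int(r['n_affected'])}, "
                f"mean body depth={r['mean_body_depth']:.1f}")
    else:
        lines.append("- unavailable")
    lines.append("")

    section("Chimeric transcription calls")
    p = outdir / "chimera.tsv"
    if p.exists():
        df = pd.read_csv(p, sep="\t")
        n_sense = int((df["call_type"] == "sense_chimera").sum())
        n_anti = int((df["call_type"] == "antisense_rna").sum())
        lines.append(f"- sense chimeras: {n_sense}")
        lines.append(f"- antisense RNAs: {n_anti}")
        lines.append(f"- no call: {int((df['call_type'] == 'none').sum())}")
    else:
        lines.append("- unavailable")
    lines.append("")

    section("Intron retention")
    p = outdir / "retention_comparison.tsv"
    if p.exists():
        r = pd.read_csv(p, sep="\t").iloc[0]
        lines.append(
            f"- downstream-of-snRNA vs control: diff={r['mean_difference']:.4f}, "
            f"Welch t={r['t_statistic']:.3f}, p={r['p_value']:.3g} "
            f"(n={int(r['n_a'])} vs {int(r['n_b'])})")
    else:
        lines.append("- unavailable")
    lines.append("")

    section("Phenoclusters")
    p = outdir / "phenoclusters.tsv"
    if p.exists():
        df = pd.read_csv(p, sep="\t", index_col=0)
        for c, sub in df.groupby("cluster"):
            lines.append(f"- cluster {c}: {', '.join(sub.index)}")
    else:
        lines.append("- unavailable")
    lines.append("")

    section("Gene-set enrichment (common upregulated genes)")
    p = outdir / "enrichment.tsv"
    if p.exists():
        df = pd.read_csv(p, sep="\t")
        for _, r in df.iterrows():
            lines.append(
                f"- {r['set_name']}: k={int(r['k'])}/K={int(r['K'])}, "
                f"n={int(r['n'])}, N={int(r['N'])}, RF={r['RF']:.2f}, "
                f"p={r['p']:.3g}, q={r['q']:.3g}")
    else:
        lines.append("- unavailable")
    lines.append("")

    path = outdir / "report.txt"
    path.write_text("\n".join(lines))
    logger.info("[stage:report] wrote %s", path)
    return path
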