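"""Ground-truth simulator for snRNA read-through studies.

Generates toy genomes in which snRNA loci of several classes (U1-like,
U2-like, SL-like, snoRNA-like) sit upstream of coding genes in sense or
antisense orientation, transcript pools with a planted fraction of
unprocessed (read-through) snRNA transcripts, strand-specific alignments
under a uniform-fragmentation model, and gene-by-sample count matrices with
planted differentially expressed gene sets.  Every planted parameter is
recorded so downstream estimators can be checked against known truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    GeneModel,
    SnFeature,
    LocusCatalogEntry,
    build_locus_catalog,
    catalog_to_frame,
    write_annotation,
    write_fasta,
    BED12_COLUMNS,
)

logger = logging.getLogger(__name__)

SN_CLASSES = ("U1-like", "U2-like", "SL-like", "snoRNA-like")
STOP_CODONS = ("TAA", "TAG", "TGA")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# parameter types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names/lengths and base composition of the toy genome."""

    chromosomes: tuple[tuple[str, int], ...]
    gc_fraction: float = 0.36
    seed: int = 0

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise SimulationError("duplicate chromosome names")
        if any(n <= 0 for _, n in self.chromosomes):
            raise SimulationError("chromosome lengths must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise SimulationError("gc_fraction outside [0,1]")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)


@dataclass
class SnLocusSpec:
    """One snRNA locus: mature span, cleavage point and downstream partner.

    ``start``/``end`` delimit the primary (pre-cleavage) transcript;
    ``mature_end`` is the genomic coordinate of the 3' cleavage point, so the
    mature snRNA occupies [start, mature_end) on '+' loci and
    [mature_end, end) on '-' loci.
    """

    locus_id: str
    sn_class: str
    chrom: str
    start: int
    end: int
    strand: str
    mature_end: int
    downstream_gene_id: str = ""
    orientation: str = ""
    intergenic_length: int = 0
    in_intron_of: str | None = None

    def __post_init__(self) -> None:
        if self.sn_class not in SN_CLASSES:
            raise SimulationError(f"{self.locus_id}: unknown sn_class {self.sn_class!r}")
        if self.strand not in "+-":
            raise SimulationError(f"{self.locus_id}: bad strand")
        if not self.start < self.mature_end <= self.end:
            raise SimulationError(f"{self.locus_id}: need start < mature_end <= end")
        if not 60 <= self.mature_length <= 200:
            raise SimulationError(
                f"{self.locus_id}: mature snRNA length {self.mature_length} "
                "outside the 60-200 nt range")

    @property
    def mature_length(self) -> int:
        return (self.mature_end - self.start if self.strand == "+"
                else self.end - self.mature_end)

    @property
    def mature_span(self) -> tuple[int, int]:
        return ((self.start, self.mature_end) if self.strand == "+"
                else (self.mature_end, self.end))

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the transcription start (strand-aware)."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class SimulationParams:
    """Transcript-pool and fragmentation parameters.

    ``f_unprocessed`` is the planted read-through fraction f, either a single
    proportion or a per-class mapping; ``ir_prob`` the per-intron retention
    probability inside chimeric sn-mRNAs, ``ir_prob_native`` the same for
    native mRNAs.  Coverage depth is ``fragments_per_kb`` fragment starts per
    transcript kilobase; each fragment yields one stranded read of length at
    most ``read_length`` (forward protocol: read strand = transcript strand).
    """

    f_unprocessed: float | Mapping[str, float] = 0.0
    ir_prob: float = 0.165
    ir_prob_native: float = 0.01
    snRNA_copies: int = 2000
    mRNA_copies: int = 200
    read_length: int = 50
    fragments_per_kb: float = 20.0
    stranded_protocol: str = "forward"
    min_fragment: int = 20
    primary_extension: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        fs = (self.f_unprocessed.values()
              if isinstance(self.f_unprocessed, Mapping) else [self.f_unprocessed])
        for v in list(fs) + [self.ir_prob, self.ir_prob_native]:
            if not 0.0 <= v <= 1.0:
                raise SimulationError("proportions must lie in [0,1]")
        if self.read_length < 20:
            raise SimulationError("read_length must be >= 20")
        if self.stranded_protocol != "forward":
            raise SimulationError("only the forward stranded protocol is simulated")

    def f_for(self, sn_class: str) -> float:
        if isinstance(self.f_unprocessed, Mapping):
            return float(self.f_unprocessed.get(sn_class, 0.0))
        return float(self.f_unprocessed)


@dataclass
class TranscriptRecord:
    """One emitted RNA molecule as an ordered chain of genomic exon blocks."""

    transcript_id: str
    category: str   # mature_snRNA | chimeric_sn_mRNA | native_mRNA | antisense_chimera
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    retained_introns: tuple[int, ...] = ()
    locus_id: str = ""
    gene_id: str = ""

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

@dataclass
class GenomeBundle:
    """A toy genome: sequences, models, locus specs and the truth catalog."""

    spec: GenomeSpec
    sequences: dict[str, str]
    gene_models: dict[str, GeneModel]
    locus_specs: list[SnLocusSpec]
    catalog: list[LocusCatalogEntry]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return self.spec.sizes

    @property
    def sn_features(self) -> list[SnFeature]:
        return [
            SnFeature(locus_id=l.locus_id, sn_class=l.sn_class, chrom=l.chrom,
                      start=l.mature_span[0], end=l.mature_span[1],
                      strand=l.strand)
            for l in self.locus_specs
        ]

    @property
    def gff3_text(self) -> str:
        return write_annotation(self.gene_models.values(), self.sn_features)

    @property
    def truth_catalog(self) -> pd.DataFrame:
        return catalog_to_frame(self.catalog)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome.fa": outdir / "genome.fa",
            "annotation.gff3": outdir / "annotation.gff3",
            "locus_catalog.tsv": outdir / "locus_catalog.tsv",
        }
        write_fasta(self.sequences, paths["genome.fa"])
        paths["annotation.gff3"].write_text(self.gff3_text)
        self.truth_catalog.to_csv(paths["locus_catalog.tsv"], sep="\t", index=False)
        return paths


def _scrub_atgs(seq: list[str], start: int, end: int, strand: str) -> None:
    """Destroy every ATG (transcript-strand reading) within [start, end).

    The substituted base (G->C on '+', C->G on '-') can never be part of a
    new start codon, so one pass suffices.
    """
    if strand == "+":
        for p in range(start, end - 2):
            if seq[p] == "A" and seq[p + 1] == "T" and seq[p + 2] == "G":
                seq[p + 2] = "C"
    else:
        for p in range(start, end - 2):
            if seq[p] == "C" and seq[p + 1] == "A" and seq[p + 2] == "T":
                seq[p] = "G"


def _plant_triplet(seq: list[str], pos: int, strand: str, codon: str = "ATG") -> None:
    """Write ``codon`` so it reads in transcript orientation with its first
    base at genomic coordinate ``pos`` ('+') or ending at ``pos`` ('-')."""
    if strand == "+":
        seq[pos:pos + 3] = list(codon)
    else:
        seq[pos - 2:pos + 1] = list(revcomp(codon))


def build_toy_genome(genome_spec: GenomeSpec,
                     locus_specs: Sequence[SnLocusSpec],
                     gene_models: Sequence[GeneModel]) -> GenomeBundle:
    """Emit a random genome honouring the locus/gene layout.

    The sequence is random at the requested GC content; a start codon is
    planted at each gene's cds_start; SL-like snRNA bodies and their
    intergenic regions are made ATG-free (their chimeras translate from the
    native start) while U1-like and U2-like snRNA bodies get planted upstream
    ATGs, mirroring the sequence properties that decide translatability.
    """
    sizes = genome_spec.sizes
    ids = [l.locus_id for l in locus_specs] + [g.gene_id for g in gene_models]
    if len(set(ids)) != len(ids):
        raise SimulationError("duplicate locus/gene ids")
    for l in locus_specs:
        if l.chrom not in sizes:
            raise SimulationError(f"{l.locus_id}: unknown chromosome")
        if not (0 <= l.start < l.end <= sizes[l.chrom]):
            raise SimulationError(f"{l.locus_id}: outside chromosome bounds")
    by_strand: dict[tuple[str, str], list[GeneModel]] = {}
    for g in gene_models:
        if g.chrom not in sizes:
            raise SimulationError(f"{g.gene_id}: unknown chromosome")
        if not (0 <= g.start < g.end <= sizes[g.chrom]):
            raise SimulationError(f"{g.gene_id}: outside chromosome bounds")
        by_strand.setdefault((g.chrom, g.strand), []).append(g)
    for group in by_strand.values():
        group = sorted(group, key=lambda g: g.start)
        for g1, g2 in zip(group, group[1:]):
            if g1.end > g2.start:
                raise SimulationError(
                    f"gene bodies {g1.gene_id}/{g2.gene_id} overlap on one strand")

    rng = np.random.default_rng(genome_spec.seed)
    gc = genome_spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    sequences: dict[str, list[str]] = {}
    for chrom, n in genome_spec.chromosomes:
        sequences[chrom] = list("".join(
            rng.choice(np.array(list("ACGT")), size=n, p=probs)))

    models = {g.gene_id: g for g in gene_models}
    for g in gene_models:
        _plant_triplet(sequences[g.chrom], g.cds_start, g.strand)

    for l in locus_specs:
        seq = sequences[l.chrom]
        gene = models.get(l.downstream_gene_id)
        if l.sn_class == "SL-like":
            # snRNA body plus intergenic region up to the downstream gene
            if l.strand == "+":
                lo, hi = l.start, gene.start if gene is not None else l.end
            else:
                lo, hi = (gene.end if gene is not None else l.start), l.end
            _scrub_atgs(seq, lo, hi, l.strand)
        elif l.sn_class in ("U1-like", "U2-like"):
            span0, span1 = l.mature_span
            offsets = (10, 45, 80)
            for off in offsets:
                if l.strand == "+":
                    pos = span0 + off
                    if pos + 3 <= span1:
                        _plant_triplet(seq, pos, "+")
                else:
                    pos = span1 - 1 - off
                    if pos - 2 >= span0:
                        _plant_triplet(seq, pos, "-")

    seq_str = {c: "".join(s) for c, s in sequences.items()}
    catalog = build_locus_catalog(
        [SnFeature(l.locus_id, l.sn_class, l.chrom, *l.mature_span, strand=l.strand)
         for l in locus_specs],
        models,
    )
    return GenomeBundle(spec=genome_spec, sequences=seq_str,
                        gene_models=models, locus_specs=list(locus_specs),
                        catalog=catalog)


# ---------------------------------------------------------------------------
# panel designer (convenience layout used by examples, tests and the pipeline)
# ---------------------------------------------------------------------------

def design_readthrough_panel(
    n_loci: int = 6,
    sn_class: str | Sequence[str] = "U2-like",
    orientation: str | Sequence[str] = "sense",
    mature_length: int = 150,
    intergenic_length: int = 300,
    exon_lengths: Sequence[int] = (300, 300, 300, 300),
    intron_lengths: Sequence[int] = (600, 600, 600),
    spacing: int = 1500,
    margin: int = 500,
    gc_fraction: float = 0.36,
    seed: int = 0,
    chrom: str = "chrI",
    n_control_genes: int = 0,
) -> tuple[GenomeSpec, list[SnLocusSpec], list[GeneModel]]:
    """Lay out ``n_loci`` snRNA->gene units along one chromosome.

    Each unit is an snRNA locus followed (strand-aware, '+' throughout) by an
    intergenic gap and a multi-exon gene; orientation 'sense' puts the gene on
    the locus strand, 'antisense' on the opposite strand.  ``n_control_genes``
    appends extra genes with no upstream snRNA (retention controls).
    """
    if len(exon_lengths) != len(intron_lengths) + 1:
        raise SimulationError("need one more exon than introns")
    classes = ([sn_class] * n_loci if isinstance(sn_class, str)
               else list(sn_class))
    orients = ([orientation] * n_loci if isinstance(orientation, str)
               else list(orientation))
    if len(classes) != n_loci or len(orients) != n_loci:
        raise SimulationError("per-locus class/orientation lists must match n_loci")

    gene_len = sum(exon_lengths) + sum(intron_lengths)
    unit = mature_length + intergenic_length + gene_len + spacing
    ctrl_unit = gene_len + spacing
    chrom_len = 2 * margin + n_loci * unit + n_control_genes * ctrl_unit

    def make_gene(gid: str, gstart: int, gstrand: str) -> GeneModel:
        exons = []
        pos = gstart
        for j, elen in enumerate(exon_lengths):
            exons.append((pos, pos + elen))
            pos += elen
            if j < len(intron_lengths):
                pos += intron_lengths[j]
        cds_start = gstart if gstrand == "+" else pos - 1
        return GeneModel(gene_id=gid, chrom=chrom, strand=gstrand,
                         start=gstart, end=pos, exons=tuple(exons),
                         cds_start=cds_start)

    loci, genes = [], []
    for i in range(n_loci):
        base = margin + i * unit
        lstart = base
        mature_end = lstart + mature_length
        gstart = mature_end + intergenic_length
        orient = orients[i]
        gstrand = "+" if orient == "sense" else "-"
        gid = f"gene{i:03d}"
        gene = make_gene(gid, gstart, gstrand)
        genes.append(gene)
        loci.append(SnLocusSpec(
            locus_id=f"sn{i:03d}", sn_class=classes[i], chrom=chrom,
            start=lstart, end=gene.end, strand="+", mature_end=mature_end,
            downstream_gene_id=gid, orientation=orient,
            intergenic_length=intergenic_length,
        ))
    for i in range(n_control_genes):
        gstart = margin + n_loci * unit + i * ctrl_unit
        genes.append(make_gene(f"ctrl{i:03d}", gstart, "+"))
    spec = GenomeSpec(chromosomes=((chrom, chrom_len),),
                      gc_fraction=gc_fraction, seed=seed)
    return spec, loci, genes


# ---------------------------------------------------------------------------
# transcript pool
# ---------------------------------------------------------------------------

def _remove_introns(region: tuple[int, int],
                    introns: Sequence[tuple[int, int]],
                    retained: Sequence[int]) -> tuple[tuple[int, int], ...]:
    """Blocks of ``region`` after splicing out the non-retained introns."""
    keep = set(retained)
    removed = sorted(iv for i, iv in enumerate(introns) if i not in keep)
    blocks = []
    cursor = region[0]
    for s, e in removed:
        if s > cursor:
            blocks.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < region[1]:
        blocks.append((cursor, region[1]))
    return tuple(blocks)


def simulate_transcript_pool(bundle: GenomeBundle,
                             params: SimulationParams) -> list[TranscriptRecord]:
    """Draw the molecule pool with the planted read-through fraction.

    Per locus, Binomial(snRNA_copies, f) transcripts fail 3'-end processing:
    sense-oriented loci yield chimeric sn-mRNAs running into the downstream
    gene with each intron independently retained at ``ir_prob``; antisense
    loci yield antisense chimeras covering the gene on the locus strand.  The
    remainder are mature snRNAs ending at the cleavage point.  Every gene
    additionally emits ``mRNA_copies`` native mRNAs.
    """
    rng = np.random.default_rng(params.seed)
    pool: list[TranscriptRecord] = []

    for locus in bundle.locus_specs:
        f = params.f_for(locus.sn_class)
        n_chim = int(rng.binomial(params.snRNA_copies, f)) if f > 0 else 0
        n_mature = params.snRNA_copies - n_chim
        mature_blocks = (locus.mature_span,)
        pool.extend(
            TranscriptRecord(
                transcript_id=f"{locus.locus_id}.m{i}", category="mature_snRNA",
                chrom=locus.chrom, strand=locus.strand, blocks=mature_blocks,
                locus_id=locus.locus_id)
            for i in range(n_mature)
        )
        gene = bundle.gene_models.get(locus.downstream_gene_id)
        for i in range(n_chim):
            if gene is None:
                # unprocessed primary transcript with nothing downstream
                if locus.strand == "+":
                    blocks = ((locus.start, locus.end),)
                else:
                    blocks = ((locus.start, locus.end),)
                pool.append(TranscriptRecord(
                    transcript_id=f"{locus.locus_id}.c{i}",
                    category="chimeric_sn_mRNA", chrom=locus.chrom,
                    strand=locus.strand, blocks=blocks,
                    locus_id=locus.locus_id))
                continue
            if locus.orientation == "sense":
                introns = gene.introns
                retained = tuple(
                    int(j) for j in np.nonzero(
                        rng.random(len(introns)) < params.ir_prob)[0]
                ) if introns else ()
                region = ((locus.start, gene.end) if locus.strand == "+"
                          else (gene.start, locus.end))
                blocks = _remove_introns(region, introns, retained)
                pool.append(TranscriptRecord(
                    transcript_id=f"{locus.locus_id}.c{i}",
                    category="chimeric_sn_mRNA", chrom=locus.chrom,
                    strand=locus.strand, blocks=blocks,
                    retained_introns=retained, locus_id=locus.locus_id,
                    gene_id=gene.gene_id))
            else:
                region = ((locus.start, gene.end) if locus.strand == "+"
                          else (gene.start, locus.end))
                pool.append(TranscriptRecord(
                    transcript_id=f"{locus.locus_id}.a{i}",
                    category="antisense_chimera", chrom=locus.chrom,
                    strand=locus.strand, blocks=(region,),
                    locus_id=locus.locus_id, gene_id=gene.gene_id))

    for gid, gene in bundle.gene_models.items():
        introns = gene.introns
        for i in range(params.mRNA_copies):
            retained = tuple(
                int(j) for j in np.nonzero(
                    rng.random(len(introns)) < params.ir_prob_native)[0]
            ) if introns else ()
            blocks = _remove_introns((gene.start, gene.end), introns, retained)
            pool.append(TranscriptRecord(
                transcript_id=f"{gid}.n{i}", category="native_mRNA",
                chrom=gene.chrom, strand=gene.strand, blocks=blocks,
                retained_introns=retained, gene_id=gid))
    return pool


def pool_truth(pool: Sequence[TranscriptRecord]) -> pd.DataFrame:
    """Per-locus/gene transcript counts by category (realized ground truth)."""
    rows: dict[tuple[str, str, str], int] = {}
    for t in pool:
        key = (t.locus_id, t.gene_id, t.category)
        rows[key] = rows.get(key, 0) + 1
    return pd.DataFrame(
        [(l, g, c, n) for (l, g, c), n in sorted(rows.items())],
        columns=["locus_id", "gene_id", "category", "n_transcripts"],
    )


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def simulate_alignments(
    pool: Sequence[TranscriptRecord],
    params: SimulationParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fragment the pool into stranded aligned reads (BED12 table).

    Fragment starts are uniform over each transcript; a fragment extends
    ``read_length`` bases 3'-ward, truncated at the transcript end, so no
    read crosses a transcript boundary and interior coverage depth is
    unbiased (expected depth = fragments_per_kb/1000 x read_length at every
    interior base, independent of transcript length).  Reads spanning a
    spliced-out intron are emitted as split (multi-block) reads.  Returns the
    coordinate-sorted read table plus a per-category truth summary.
    """
    if not pool:
        raise SimulationError("empty transcript pool")
    rng = np.random.default_rng(params.seed + 1)
    rho = params.fragments_per_kb / 1000.0
    rl = params.read_length

    # group identical molecules so fragment draws vectorize
    groups: dict[tuple, list] = {}
    for t in pool:
        key = (t.chrom, t.strand, t.blocks)
        rec = groups.setdefault(key, [0, t.category, t.locus_id, t.gene_id])
        rec[0] += 1

    out_chrom, out_start, out_end = [], [], []
    out_strand, out_count, out_sizes, out_offsets = [], [], [], []
    truth_rows = []
    n_skipped = 0

    for (chrom, strand, blocks), (count, category, locus_id, gene_id) in groups.items():
        lens = np.array([e - s for s, e in blocks], dtype=np.int64)
        L = int(lens.sum())
        if L < params.min_fragment:
            n_skipped += count
            logger.warning(
                "skipping %d transcript(s) of length %d < min_fragment %d",
                count, L, params.min_fragment)
            continue
        n = int(rng.poisson(L * rho * count))
        truth_rows.append((category, locus_id, gene_id, count, n))
        if n == 0:
            continue
        ts = rng.integers(0, L, size=n)          # transcript-coordinate starts
        te = np.minimum(ts + rl, L)
        if strand == "+":
            gs, ge = ts, te
        else:
            gs, ge = L - te, L - ts              # genomic-axis offsets
        cum = np.cumsum(lens)
        cumstart = cum - lens
        bstarts = np.array([s for s, _ in blocks], dtype=np.int64)
        bi = np.searchsorted(cum, gs, side="right")
        bj = np.searchsorted(cum, ge - 1, side="right")
        single = bi == bj
        if single.any():
            i = bi[single]
            a = bstarts[i] + (gs[single] - cumstart[i])
            b = a + (ge[single] - gs[single])
            m = int(single.sum())
            out_chrom.append(np.full(m, chrom, dtype=object))
            out_start.append(a)
            out_end.append(b)
            out_strand.append(np.full(m, strand, dtype=object))
            out_count.append(np.ones(m, dtype=np.int64))
            out_sizes.append((b - a).astype(str).astype(object))
            out_offsets.append(np.zeros(m, dtype=np.int64).astype(str).astype(object))
        if (~single).any():
            for g0, g1, i0, i1 in zip(gs[~single], ge[~single],
                                      bi[~single], bj[~single]):
                segs = []
                for k in range(i0, i1 + 1):
                    s = bstarts[k] + max(0, g0 - cumstart[k])
                    e = bstarts[k] + min(lens[k], g1 - cumstart[k])
                    segs.append((int(s), int(e)))
                a = segs[0][0]
                out_chrom.append(np.array([chrom], dtype=object))
                out_start.append(np.array([a], dtype=np.int64))
                out_end.append(np.array([segs[-1][1]], dtype=np.int64))
                out_strand.append(np.array([strand], dtype=object))
                out_count.append(np.array([len(segs)], dtype=np.int64))
                out_sizes.append(np.array(
                    [",".join(str(e - s) for s, e in segs)], dtype=object))
                out_offsets.append(np.array(
                    [",".join(str(s - a) for s, _ in segs)], dtype=object))

    if not out_chrom:
        reads = pd.DataFrame(columns=BED12_COLUMNS)
    else:
        start = np.concatenate(out_start)
        end = np.concatenate(out_end)
        reads = pd.DataFrame({
            "chrom": np.concatenate(out_chrom),
            "start": start,
            "end": end,
            "strand": np.concatenate(out_strand),
            "block_count": np.concatenate(out_count),
            "block_sizes": np.concatenate(out_sizes),
            "block_starts": np.concatenate(out_offsets),
        })
        reads = reads.sort_values(["chrom", "start", "end"], kind="stable",
                                  ignore_index=True)
        reads["name"] = [f"r{i:07d}" for i in range(len(reads))]
        reads["score"] = 0
        reads["thick_start"] = reads["start"]
        reads["thick_end"] = reads["end"]
        reads["item_rgb"] = 0
        reads = reads[BED12_COLUMNS]

    truth = pd.DataFrame(
        truth_rows,
        columns=["category", "locus_id", "gene_id", "n_transcripts", "n_reads"],
    ).groupby(["category", "locus_id", "gene_id"], as_index=False).sum()
    if n_skipped:
        truth.attrs["n_skipped_transcripts"] = n_skipped
    return reads, truth


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

@dataclass
class CohortParams:
    """Planted cohort design for count-matrix simulation.

    Negative-binomial counts (gamma-Poisson) with per-gene base means; genes
    in ``planted_up``/``planted_down`` for a group have their mean multiplied
    or divided by ``fold_change`` in that group's samples.
    """

    n_genes: int = 8000
    n_samples_per_group: int = 3
    groups: tuple[str, ...] = ("control", "holder_kd", "catalytic_kd")
    planted_up: dict[str, frozenset[str]] = field(default_factory=dict)
    planted_down: dict[str, frozenset[str]] = field(default_factory=dict)
    fold_change: float = 4.0
    dispersion: float = 0.05
    base_mean: float = 100.0
    geneset_catalogs: dict[str, frozenset[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for grp in self.groups:
            up = self.planted_up.get(grp, frozenset())
            down = self.planted_down.get(grp, frozenset())
            if up & down:
                raise SimulationError(f"{grp}: planted up/down sets overlap")
        for name, members in self.geneset_catalogs.items():
            if len(members) > self.n_genes:
                raise SimulationError(f"catalog {name} larger than gene universe")

    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]


def default_cohort(seed: int = 0, n_genes: int = 8000,
                   fold_change: float = 4.0,
                   dispersion: float = 0.05) -> CohortParams:
    """The study-like cohort: three groups, shared knockdown response, and
    kinase-/phosphatase-like catalogs overlapping the planted upregulated set
    (overlaps 101/438 and 78/206, i.e. 23% and 38% of each catalog)."""
    if n_genes < 1100:
        raise SimulationError("default cohort needs a universe of >= 1100 genes")
    ids = [f"g{i:05d}" for i in range(n_genes)]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_genes)
    cat_up = frozenset(ids[i] for i in perm[:600])
    cat_down = frozenset(ids[i] for i in perm[600:800])
    # holder response: 90%-overlapping with the catalytic response
    hold_up = frozenset(sorted(cat_up)[:540] + [ids[i] for i in perm[800:860]])
    hold_down = frozenset(sorted(cat_down)[:180] + [ids[i] for i in perm[860:880]])

    up_list = sorted(cat_up)
    rest = [g for g in ids if g not in cat_up]
    kinase = frozenset(up_list[:101] + rest[:437 - 100])
    phosphatase = frozenset(up_list[101:101 + 78] + rest[437 - 100:437 - 100 + 128])
    return CohortParams(
        n_genes=n_genes, groups=("control", "holder_kd", "catalytic_kd"),
        planted_up={"holder_kd": hold_up, "catalytic_kd": cat_up},
        planted_down={"holder_kd": hold_down, "catalytic_kd": cat_down},
        fold_change=fold_change, dispersion=dispersion,
        geneset_catalogs={"kinase-like": kinase, "phosphatase-like": phosphatase},
        seed=seed,
    )


def simulate_count_matrix(
    cohort: CohortParams,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Draw the gene x sample count matrix plus truth labels.

    Returns (counts, sample->group mapping, truth dict with planted sets and
    catalog overlap counts k per (catalog, group) pair).
    """
    rng = np.random.default_rng(cohort.seed)
    ids = cohort.gene_ids()
    base = rng.lognormal(mean=np.log(cohort.base_mean), sigma=1.0,
                         size=cohort.n_genes)
    samples, labels, cols = [], [], []
    idx = {g: i for i, g in enumerate(ids)}
    for grp in cohort.groups:
        mu = base.copy()
        for g in cohort.planted_up.get(grp, ()):  # type: ignore[arg-type]
            mu[idx[g]] *= cohort.fold_change
        for g in cohort.planted_down.get(grp, ()):  # type: ignore[arg-type]
            mu[idx[g]] /= cohort.fold_change
        for r in range(cohort.n_samples_per_group):
            if cohort.dispersion > 0:
                lam = rng.gamma(shape=1.0 / cohort.dispersion,
                                scale=mu * cohort.dispersion)
            else:
                lam = mu
            samples.append(rng.poisson(lam))
            cols.append(f"{grp}_{r + 1}")
            labels.append(grp)
    counts = pd.DataFrame(np.column_stack(samples), index=ids, columns=cols)
    groups = pd.Series(labels, index=cols, name="group")
    overlaps = {
        (cname, grp): len(members & cohort.planted_up.get(grp, frozenset()))
        for cname, members in cohort.geneset_catalogs.items()
        for grp in cohort.groups
    }
    truth = {
        "planted_up": {g: set(s) for g, s in cohort.planted_up.items()},
        "planted_down": {g: set(s) for g, s in cohort.planted_down.items()},
        "geneset_catalogs": {n: set(s) for n, s in cohort.geneset_catalogs.items()},
        "catalog_overlap_k": overlaps,
        "fold_change": cohort.fold_change,
    }
    return counts, groups, truth
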