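"""Standard-format I/O, strand-aware coverage and the snRNA locus catalog.

Internal coordinates are 0-based half-open throughout.  GFF3 I/O converts
to/from the 1-based closed convention of that format; the BED12 dialect used
for alignments is 0-based half-open like the internal one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BED12_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thick_start", "thick_end", "item_rgb",
    "block_count", "block_sizes", "block_starts",
]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


# ---------------------------------------------------------------------------
# gene models and snRNA features
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A protein-coding gene: span, exon chain and translation start.

    ``cds_start`` is the genomic coordinate of the A of the start codon in
    transcript orientation (codon occupies [cds_start, cds_start+3) on '+'
    genes and [cds_start-2, cds_start+1) on '-' genes).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    cds_start: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.start < self.end:
            raise AnnotationError(f"{self.gene_id}: empty span")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise AnnotationError(f"{self.gene_id}: overlapping exons")
        for s, e in exons:
            if not (self.start <= s < e <= self.end):
                raise AnnotationError(f"{self.gene_id}: exon outside span")
        object.__setattr__(self, "exons", exons)
        if not any(s <= self.cds_start < e for s, e in exons):
            raise AnnotationError(f"{self.gene_id}: cds_start not inside an exon")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class SnFeature:
    """A mature snRNA/SL/snoRNA feature as annotated (mature span only)."""

    locus_id: str
    sn_class: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the 3' cleavage point (strand-aware)."""
        return self.end if self.strand == "+" else self.start


@dataclass
class LocusCatalogEntry:
    """One row of the locus catalog: an snRNA paired with its downstream gene."""

    locus_id: str
    sn_class: str
    chrom: str
    start: int
    end: int
    strand_code: int            # sense of the snRNA locus: 1 = '+', -1 = '-'
    downstream_gene_id: str     # empty string when no gene within the cap
    downstream_gene_strand_code: int
    orientation: str            # sense | antisense | '' when unpaired
    distance_to_gene: int
    in_intron: bool
    in_intron_of: str
    processing_affected: bool | None = None

    @property
    def strand(self) -> str:
        return "+" if self.strand_code == 1 else "-"

    @property
    def three_prime_end(self) -> int:
        return self.end if self.strand_code == 1 else self.start


CATALOG_COLUMNS = [
    "locus_id", "sn_class", "chrom", "start", "end", "strand_code",
    "downstream_gene_id", "downstream_gene_strand_code", "orientation",
    "distance_to_gene", "in_intron", "in_intron_of", "processing_affected",
]


def catalog_to_frame(entries: Sequence[LocusCatalogEntry]) -> pd.DataFrame:
    rows = [[getattr(e, c) for c in CATALOG_COLUMNS] for e in entries]
    return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_annotation(gene_models: Iterable[GeneModel],
                     sn_features: Iterable[SnFeature]) -> str:
    """Serialize models to GFF3 text (1-based closed coordinates)."""
    lines = ["##gff-version 3"]

    def row(chrom, ftype, start, end, strand, attrs):
        return "\t".join([
            chrom, "snreadthrough", ftype, str(start + 1), str(end),
            ".", strand, ".", attrs,
        ])

    for g in sorted(gene_models, key=lambda g: (g.chrom, g.start, g.gene_id)):
        lines.append(row(g.chrom, "gene", g.start, g.end, g.strand,
                         f"ID={g.gene_id}"))
        mrna_id = f"{g.gene_id}.t1"
        lines.append(row(g.chrom, "mRNA", g.start, g.end, g.strand,
                         f"ID={mrna_id};Parent={g.gene_id}"))
        for i, (s, e) in enumerate(g.exons, start=1):
            lines.append(row(g.chrom, "exon", s, e, g.strand,
                             f"ID={mrna_id}.e{i};Parent={mrna_id}"))
        # CDS: exon chain clipped 3'-ward of the start codon
        if g.strand == "+":
            cds = [(max(s, g.cds_start), e) for s, e in g.exons if e > g.cds_start]
        else:
            cds = [(s, min(e, g.cds_start + 1)) for s, e in g.exons
                   if s <= g.cds_start]
        for i, (s, e) in enumerate(cds, start=1):
            lines.append(row(g.chrom, "CDS", s, e, g.strand,
                             f"ID={mrna_id}.c{i};Parent={mrna_id}"))
    for f in sorted(sn_features, key=lambda f: (f.chrom, f.start, f.locus_id)):
        lines.append(row(f.chrom, "snRNA", f.start, f.end, f.strand,
                         f"ID={f.locus_id};sn_class={f.sn_class}"))
    return "\n".join(lines) + "\n"


def parse_annotation(gff3_text: str) -> tuple[dict[str, GeneModel], list[SnFeature]]:
    """Parse GFF3 text into gene models and snRNA features.

    Coordinates are converted to the internal 0-based half-open convention.
    """
    for lineno, line in enumerate(gff3_text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise AnnotationError(
                f"line {lineno}: expected 9 tab-separated fields, "
                f"got {len(fields)}")
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise AnnotationError(f"line {lineno}: non-integer coordinates") from exc
        if end < start:
            raise AnnotationError(f"line {lineno}: end < start")
    try:
        db = gffutils.create_db(
            gff3_text, dbfn=":memory:", from_string=True, keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises assorted types for bad input
        raise AnnotationError(f"GFF3 parse failed: {exc}") from exc

    genes: dict[str, GeneModel] = {}
    for g in db.features_of_type("gene"):
        if g.end < g.start:
            raise AnnotationError(f"{g.id}: end < start")
        exons = []
        cds_spans = []
        for mrna in db.children(g, featuretype="mRNA"):
            exons += [(e.start - 1, e.end) for e in db.children(mrna, featuretype="exon")]
            cds_spans += [(c.start - 1, c.end) for c in db.children(mrna, featuretype="CDS")]
        if not exons:
            exons = [(g.start - 1, g.end)]
        if cds_spans:
            cds_start = (min(s for s, _ in cds_spans) if g.strand == "+"
                         else max(e for _, e in cds_spans) - 1)
        else:
            cds_start = exons[0][0] if g.strand == "+" else max(e for _, e in exons) - 1
        genes[g.id] = GeneModel(
            gene_id=g.id, chrom=g.seqid, strand=g.strand,
            start=g.start - 1, end=g.end, exons=tuple(sorted(exons)),
            cds_start=cds_start,
        )
    sn_features = [
        SnFeature(
            locus_id=f.id, sn_class=f.attributes.get("sn_class", ["unknown"])[0],
            chrom=f.seqid, start=f.start - 1, end=f.end, strand=f.strand,
        )
        for f in db.features_of_type("snRNA")
    ]
    return genes, sn_features


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# BED12 alignment tables
# ---------------------------------------------------------------------------

def write_bed12(reads: pd.DataFrame, path: str | Path) -> None:
    reads[BED12_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed12(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=BED12_COLUMNS,
                         dtype={"block_sizes": str, "block_starts": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=BED12_COLUMNS)
    return df


def iter_read_blocks(row) -> list[tuple[int, int]]:
    """Genomic blocks of one BED12 row, 0-based half-open."""
    n = int(row.block_count)
    if n == 1:
        return [(int(row.start), int(row.end))]
    sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
    offsets = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
    start = int(row.start)
    return [(start + o, start + o + s) for o, s in zip(offsets, sizes)]


# ---------------------------------------------------------------------------
# stranded coverage
# ---------------------------------------------------------------------------

@dataclass
class StrandedCoverage:
    """Per-base, per-strand read depth plus junction counts for one chromosome.

    ``depth[strand][b]`` counts read blocks covering base b; ``starts`` counts
    block starts per base (used to count reads over an interval exactly);
    ``junctions[strand][(donor, acceptor)]`` counts split reads spanning the
    gap [donor, acceptor).
    """

    chrom: str
    length: int
    depth: dict[str, np.ndarray] = field(default_factory=dict)
    starts: dict[str, np.ndarray] = field(default_factory=dict)
    junctions: dict[str, dict[tuple[int, int], int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in "+-":
            self.depth.setdefault(s, np.zeros(self.length, dtype=np.int64))
            self.starts.setdefault(s, np.zeros(self.length, dtype=np.int64))
            self.junctions.setdefault(s, {})


def load_alignments(reads: pd.DataFrame | str | Path,
                    chrom_sizes: Mapping[str, int],
                    protocol: str = "forward") -> dict[str, StrandedCoverage]:
    """Build per-chromosome stranded coverage from a BED12 alignment table.

    Under the ``forward`` protocol a read's strand is the transcript strand;
    ``reverse`` flips every read's strand assignment.  Input must be
    coordinate-sorted within each chromosome.
    """
    if protocol not in ("forward", "reverse"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if not isinstance(reads, pd.DataFrame):
        reads = read_bed12(reads)

    coverage = {c: StrandedCoverage(chrom=c, length=n)
                for c, n in chrom_sizes.items()}
    flip = {"+": "-", "-": "+"}

    for chrom, sub in reads.groupby("chrom", sort=False):
        if chrom not in coverage:
            raise ValueError(f"unknown chromosome {chrom!r} in alignments")
        if not sub["start"].is_monotonic_increasing:
            raise ValueError(f"alignments not coordinate-sorted on {chrom}")
        cov = coverage[chrom]
        for strand, ssub in sub.groupby("strand", sort=False):
            s = flip[strand] if protocol == "reverse" else strand
            diff = np.zeros(cov.length + 1, dtype=np.int64)
            sdiff = cov.starts[s]
            single = ssub[ssub["block_count"] == 1]
            if len(single):
                a = single["start"].to_numpy(dtype=np.int64)
                b = single["end"].to_numpy(dtype=np.int64)
                if a.min() < 0 or b.max() > cov.length:
                    raise ValueError(f"read outside chromosome {chrom}")
                np.add.at(diff, a, 1)
                np.add.at(diff, b, -1)
                np.add.at(sdiff, a, 1)
            multi = ssub[ssub["block_count"] > 1]
            junc = cov.junctions[s]
            for row in multi.itertuples():
                blocks = iter_read_blocks(row)
                for (bs, be) in blocks:
                    if bs < 0 or be > cov.length:
                        raise ValueError(f"read outside chromosome {chrom}")
                    diff[bs] += 1
                    diff[be] -= 1
                    sdiff[bs] += 1
                for (_, d), (a2, _) in zip(blocks, blocks[1:]):
                    junc[(d, a2)] = junc.get((d, a2), 0) + 1
            cov.depth[s] += np.cumsum(diff[:-1])
    return coverage


def count_region(coverage: StrandedCoverage, interval: tuple[int, int],
                 strand: str) -> tuple[float, int]:
    """Mean depth and exact read-block count over ``interval`` on ``strand``."""
    a, b = interval
    if not (0 <= a < b <= coverage.length):
        raise ValueError(f"bad interval {interval} on {coverage.chrom}")
    depth = coverage.depth[strand]
    mean = float(depth[a:b].mean())
    # blocks overlapping [a, b) = blocks covering a + blocks starting in (a, b)
    n_blocks = int(depth[a]) + int(coverage.starts[strand][a + 1:b].sum())
    return mean, n_blocks


# ---------------------------------------------------------------------------
# locus catalog
# ---------------------------------------------------------------------------

def build_locus_catalog(sn_features: Sequence[SnFeature],
                        gene_models: Mapping[str, GeneModel],
                        max_distance: int = 5000) -> list[LocusCatalogEntry]:
    """Pair each snRNA feature with its nearest downstream gene.

    "Downstream" is strand-aware from the locus 3' end; the nearest gene on
    either strand within ``max_distance`` is paired.  Ties are broken by
    strand match with the locus, then by gene id.  Every feature yields
    exactly one entry; unpaired loci carry an empty downstream_gene_id.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models.values():
        by_chrom.setdefault(g.chrom, []).append(g)

    entries = []
    for f in sn_features:
        e3 = f.three_prime_end
        best: tuple[int, int, str] | None = None
        best_gene: GeneModel | None = None
        for g in by_chrom.get(f.chrom, []):
            if f.strand == "+":
                if g.start < e3:
                    continue
                dist = g.start - e3
            else:
                if g.end > e3:
                    continue
                dist = e3 - g.end
            if dist > max_distance:
                continue
            key = (dist, 0 if g.strand == f.strand else 1, g.gene_id)
            if best is None or key < best:
                best, best_gene = key, g

        in_intron_of = ""
        for g in by_chrom.get(f.chrom, []):
            if any(s <= f.start and f.end <= e for s, e in g.introns):
                in_intron_of = g.gene_id
                break

        if best_gene is None:
            entries.append(LocusCatalogEntry(
                locus_id=f.locus_id, sn_class=f.sn_class, chrom=f.chrom,
                start=f.start, end=f.end,
                strand_code=1 if f.strand == "+" else -1,
                downstream_gene_id="", downstream_gene_strand_code=0,
                orientation="", distance_to_gene=-1,
                in_intron=bool(in_intron_of), in_intron_of=in_intron_of,
            ))
            continue
        entries.append(LocusCatalogEntry(
            locus_id=f.locus_id, sn_class=f.sn_class, chrom=f.chrom,
            start=f.start, end=f.end,
            strand_code=1 if f.strand == "+" else -1,
            downstream_gene_id=best_gene.gene_id,
            downstream_gene_strand_code=1 if best_gene.strand == "+" else -1,
            orientation="sense" if best_gene.strand == f.strand else "antisense",
            distance_to_gene=best[0],
            in_intron=bool(in_intron_of), in_intron_of=in_intron_of,
        ))
    return entries
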