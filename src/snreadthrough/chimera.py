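"""Chimeric sn-mRNA and cis-antisense RNA calling, plus translation potential.

A sense-oriented snRNA locus whose read-through coverage runs contiguously
through the intergenic region into the downstream gene is called a chimeric
sn-mRNA; an antisense-oriented locus whose coverage blankets the gene body on
the opposite strand is called a cis-antisense RNA.  Translation potential of
a sense chimera is assessed by the first-ATG rule: the chimera translates
from the gene's native start iff no ATG occurs upstream of it in the
transcript.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genome_io import GeneModel, LocusCatalogEntry, StrandedCoverage
from .synth import revcomp, STOP_CODONS


@dataclass
class ChimeraCall:
    locus_id: str
    gene_id: str
    call_type: str                     # sense_chimera | antisense_rna | none
    intergenic_covered_fraction: float
    gene_covered_fraction: float
    spliced_fraction: float            # introns with >=1 supporting junction read
    min_depth_observed: int
    reason: str = ""


@dataclass
class TranslationAssessment:
    transcript_id: str
    upstream_atg_count: int
    first_atg_offset: int              # -1 when no upstream ATG
    classification: str                # native_start | upstream_orf
    uorf_lengths: tuple[int, ...]      # codons until stop, per upstream ATG


def _covered_fraction(depth: np.ndarray, intervals: Sequence[tuple[int, int]],
                      min_depth: int) -> tuple[float, int]:
    total = sum(e - s for s, e in intervals)
    if total == 0:
        return 1.0, 0
    covered = 0
    min_obs = None
    for s, e in intervals:
        seg = depth[s:e]
        covered += int((seg >= min_depth).sum())
        m = int(seg.min()) if e > s else 0
        min_obs = m if min_obs is None else min(min_obs, m)
    return covered / total, (min_obs if min_obs is not None else 0)


def call_chimera(
    entry: LocusCatalogEntry,
    coverage: Mapping[str, StrandedCoverage],
    gene: GeneModel | None,
    covered_threshold: float = 0.8,
    min_depth: int = 1,
) -> ChimeraCall:
    """Call read-through transcription into the downstream gene.

    Covered fractions are computed on the locus strand: the fraction of
    intergenic bases and of downstream-gene exonic bases (sense) or gene-body
    bases (antisense) at depth >= ``min_depth``.  Both must reach
    ``covered_threshold`` for a sense call; the gene-body fraction alone for
    an antisense call.  ``spliced_fraction`` is the share of annotated
    introns supported by at least one junction read on the locus strand.
    """
    if not entry.downstream_gene_id or gene is None:
        return ChimeraCall(
            locus_id=entry.locus_id, gene_id="", call_type="none",
            intergenic_covered_fraction=0.0, gene_covered_fraction=0.0,
            spliced_fraction=float("nan"), min_depth_observed=0,
            reason="no downstream gene")

    cov = coverage[entry.chrom]
    strand = entry.strand
    depth = cov.depth[strand]

    if entry.strand_code == 1:
        intergenic = [(entry.end, gene.start)] if gene.start > entry.end else []
    else:
        intergenic = [(gene.end, entry.start)] if gene.end < entry.start else []
    ig_frac, ig_min = _covered_fraction(depth, intergenic, min_depth)

    if entry.orientation == "sense":
        gene_intervals = list(gene.exons)
    else:
        gene_intervals = [(gene.start, gene.end)]
    g_frac, g_min = _covered_fraction(depth, gene_intervals, min_depth)
    min_obs = min(ig_min, g_min) if intergenic else g_min

    introns = gene.introns
    junc = cov.junctions[strand]
    if introns:
        supported = sum(1 for iv in introns if junc.get(iv, 0) >= 1)
        spliced = supported / len(introns)
    else:
        spliced = 1.0

    if entry.orientation == "sense":
        hit = ig_frac >= covered_threshold and g_frac >= covered_threshold
        call = "sense_chimera" if hit else "none"
    else:
        call = "antisense_rna" if g_frac >= covered_threshold else "none"
    return ChimeraCall(
        locus_id=entry.locus_id, gene_id=gene.gene_id, call_type=call,
        intergenic_covered_fraction=ig_frac, gene_covered_fraction=g_frac,
        spliced_fraction=spliced, min_depth_observed=min_obs,
        reason="" if call != "none" else "insufficient contiguous coverage")


def calls_to_frame(calls: Sequence[ChimeraCall]):
    import pandas as pd

    return pd.DataFrame([{
        "locus_id": c.locus_id, "gene_id": c.gene_id, "call_type": c.call_type,
        "intergenic_covered_fraction": c.intergenic_covered_fraction,
        "gene_covered_fraction": c.gene_covered_fraction,
        "spliced_fraction": c.spliced_fraction,
        "min_depth_observed": c.min_depth_observed, "reason": c.reason,
    } for c in calls])


# ---------------------------------------------------------------------------
# translation potential
# ---------------------------------------------------------------------------

def scan_translation_start(sequence: str, native_cds_offset: int,
                           transcript_id: str = "") -> TranslationAssessment:
    """First-ATG scan of a chimeric transcript sequence.

    Scans 5'->3' for ATG codons strictly upstream of ``native_cds_offset``
    (the transcript coordinate of the downstream gene's own start codon).
    With none, the ribosome's first encountered start is the native one
    (classification ``native_start``); otherwise ``upstream_orf``, and each
    upstream ATG is annotated with its ORF length in codons up to (not
    including) the first in-frame stop, or to the sequence end.
    """
    seq = sequence.upper()
    if not 0 <= native_cds_offset <= len(seq):
        raise ValueError("native_cds_offset outside the sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")

    atgs = [i for i in range(min(native_cds_offset, len(seq) - 2))
            if seq[i:i + 3] == "ATG"]
    uorf_lengths = []
    for i in atgs:
        n = 0
        p = i
        while p + 3 <= len(seq):
            codon = seq[p:p + 3]
            if n > 0 and codon in STOP_CODONS:
                break
            n += 1
            p += 3
        uorf_lengths.append(n)
    return TranslationAssessment(
        transcript_id=transcript_id,
        upstream_atg_count=len(atgs),
        first_atg_offset=atgs[0] if atgs else -1,
        classification="native_start" if not atgs else "upstream_orf",
        uorf_lengths=tuple(uorf_lengths),
    )


def reconstruct_chimera_sequence(
    sequences: Mapping[str, str],
    entry: LocusCatalogEntry,
    gene: GeneModel,
    retained_introns: Sequence[int] = (),
) -> tuple[str, int]:
    """Spliced chimeric transcript sequence and the native start's offset.

    The transcript runs from the snRNA 5' end through the intergenic region
    and the downstream gene to its annotated end, with every intron not in
    ``retained_introns`` spliced out.  Only sense-oriented entries have a
    meaningful native start.
    """
    if entry.orientation != "sense":
        raise ValueError("translation assessment applies to sense chimeras only")
    chrom_seq = sequences[entry.chrom]
    introns = gene.introns
    keep = set(retained_introns)
    removed = sorted(iv for i, iv in enumerate(introns) if i not in keep)
    region = ((entry.start, gene.end) if entry.strand_code == 1
              else (gene.start, entry.end))
    blocks = []
    cursor = region[0]
    for s, e in removed:
        if s > cursor:
            blocks.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < region[1]:
        blocks.append((cursor, region[1]))

    seq = "".join(chrom_seq[s:e] for s, e in blocks)
    # transcript offset of the native start codon's A
    if entry.strand_code == 1:
        offset = 0
        for s, e in blocks:
            if s <= gene.cds_start < e:
                offset += gene.cds_start - s
                break
            offset += e - s
    else:
        seq = revcomp(seq)
        offset = 0
        for s, e in reversed(blocks):
            if s <= gene.cds_start < e:
                offset += e - 1 - gene.cds_start
                break
            offset += e - s
    return seq, offset
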