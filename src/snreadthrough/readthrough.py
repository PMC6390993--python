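"""Read-through quantification at snRNA loci.

The read-through index is a coverage-ratio estimator: mean strand-matched
depth in a window just downstream of the 3' cleavage point divided by mean
depth in the central snRNA body.  Under uniform fragmentation this estimates
the fraction f of snRNA transcripts that escaped 3'-end processing, the
quantity reported as "percent lack of 3' end processing".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .genome_io import LocusCatalogEntry, StrandedCoverage, count_region

logger = logging.getLogger(__name__)


@dataclass
class ReadthroughResult:
    locus_id: str
    rt_index: float          # NaN when the locus is not expressed
    body_mean_depth: float
    downstream_mean_depth: float
    n_body_reads: int
    affected: bool
    ci_low: float
    ci_high: float
    status: str = "ok"       # ok | no-expression

    @property
    def defined(self) -> bool:
        return self.status == "ok"


def _body_window(entry: LocusCatalogEntry, read_length: int,
                 min_window: int = 10) -> tuple[int, int]:
    """Central portion of the mature snRNA, excluding up to ``read_length``
    bases at each edge when the body is long enough."""
    length = entry.end - entry.start
    margin = min(read_length, max(0, (length - min_window) // 2))
    return entry.start + margin, entry.end - margin


def readthrough_index(
    entry: LocusCatalogEntry,
    coverage: Mapping[str, StrandedCoverage],
    read_length: int = 50,
    delta: int = 20,
    window: int = 50,
    tau: float = 0.005,
    min_body_reads: int = 50,
) -> ReadthroughResult:
    """Estimate the unprocessed-transcript fraction at one locus.

    The downstream window sits [delta, delta+window) past the cleavage point
    on the locus strand; ``affected`` requires rt_index >= tau with at least
    ``min_body_reads`` supporting body reads.  A locus with zero body depth
    is flagged ``no-expression`` and its rt_index reported as missing.
    """
    cov = coverage[entry.chrom]
    strand = entry.strand
    body = _body_window(entry, read_length)
    if strand == "+":
        ds = (entry.end + delta, entry.end + delta + window)
    else:
        ds = (entry.start - delta - window, entry.start - delta)
    ds = (max(ds[0], 0), min(ds[1], cov.length))

    body_mean, n_body = count_region(cov, body, strand)
    ds_mean = count_region(cov, ds, strand)[0] if ds[0] < ds[1] else 0.0

    if body_mean == 0.0:
        return ReadthroughResult(
            locus_id=entry.locus_id, rt_index=float("nan"),
            body_mean_depth=0.0, downstream_mean_depth=ds_mean,
            n_body_reads=n_body, affected=False,
            ci_low=float("nan"), ci_high=float("nan"), status="no-expression")

    rt = min(max(ds_mean / body_mean, 0.0), 1.0)
    if n_body > 0:
        k = min(int(round(rt * n_body)), n_body)
        lo, hi = proportion_confint(k, n_body, alpha=0.05, method="wilson")
        lo, hi = min(float(lo), rt), max(float(hi), rt)
    else:
        lo, hi = 0.0, 1.0
    return ReadthroughResult(
        locus_id=entry.locus_id, rt_index=rt, body_mean_depth=body_mean,
        downstream_mean_depth=ds_mean, n_body_reads=n_body,
        affected=(rt >= tau and n_body >= min_body_reads),
        ci_low=lo, ci_high=hi)


def pooled_readthrough(results: Sequence[ReadthroughResult]) -> float:
    """Depth-weighted pooled estimate over loci with defined rt_index."""
    defined = [r for r in results if r.defined]
    if not defined:
        return float("nan")
    num = sum(r.downstream_mean_depth for r in defined)
    den = sum(r.body_mean_depth for r in defined)
    return min(max(num / den, 0.0), 1.0)


def summarize_by_class(
    results: Sequence[ReadthroughResult],
    catalog: Sequence[LocusCatalogEntry],
) -> pd.DataFrame:
    """Per-snRNA-class summary: locus counts, rt_index stats, mean body depth.

    Mean body depth is reported so invariance of snRNA expression across
    conditions (read-through changes, body depth does not) can be tested.
    """
    cls = {e.locus_id: e.sn_class for e in catalog}
    rows = []
    by_class: dict[str, list[ReadthroughResult]] = {}
    for r in results:
        c = cls.get(r.locus_id)
        if c is None:
            logger.warning("locus %s absent from catalog; omitted", r.locus_id)
            continue
        by_class.setdefault(c, []).append(r)
    for c in sorted(by_class):
        rs = by_class[c]
        defined = [r.rt_index for r in rs if r.defined]
        rows.append({
            "sn_class": c,
            "n_loci": len(rs),
            "n_defined": len(defined),
            "mean_rt_index": float(np.mean(defined)) if defined else float("nan"),
            "min_rt_index": float(np.min(defined)) if defined else float("nan"),
            "max_rt_index": float(np.max(defined)) if defined else float("nan"),
            "pooled_rt_index": pooled_readthrough(rs),
            "n_affected": sum(r.affected for r in rs),
            "mean_body_depth": float(np.mean([r.body_mean_depth for r in rs])),
        })
    return pd.DataFrame(rows)


def results_to_frame(results: Sequence[ReadthroughResult],
                     catalog: Sequence[LocusCatalogEntry]) -> pd.DataFrame:
    meta = {e.locus_id: e for e in catalog}
    rows = []
    for r in results:
        e = meta[r.locus_id]
        rows.append({
            "locus_id": r.locus_id, "sn_class": e.sn_class, "chrom": e.chrom,
            "start": e.start, "end": e.end, "strand": e.strand,
            "rt_index": r.rt_index, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "body_mean_depth": r.body_mean_depth,
            "downstream_mean_depth": r.downstream_mean_depth,
            "n_body_reads": r.n_body_reads,
            "affected": r.affected, "status": r.status,
        })
    return pd.DataFrame(rows)
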