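"""Count normalization, simplified differential expression, and
sample-distance phenoclustering.

Counts are normalized by median-of-ratios size factors and log2(n+1)
transformed as a stand-in for the regularized log transform; differential
calls come from a per-gene two-sample t-test with Benjamini-Hochberg control
at q < 0.05, and the dual-engine design of real analyses is emulated by
intersecting the calls of two test variants (Welch and pooled-variance) or of
externally produced DE tables.  Sample relationships are summarized by
Euclidean distances over the log matrix, average-linkage hierarchical
clustering, and PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .enrichment import bh_adjust

logger = logging.getLogger(__name__)

DE_COLUMNS = ["gene_id", "log2fc", "p", "q", "direction"]


@dataclass
class NormalizedMatrix:
    size_factors: pd.Series        # one positive factor per sample
    normalized: pd.DataFrame       # counts / size factor
    log2: pd.DataFrame             # log2(normalized + 1)


def normalize(counts: pd.DataFrame) -> NormalizedMatrix:
    """Median-of-ratios size factors and the log2(normalized + 1) matrix.

    Size factors are per-sample medians of count/geometric-mean ratios over
    genes with all-positive counts; with no such gene the method degrades to
    total-count scaling (logged).
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if positive.any():
        logx = np.log(x[positive])
        gm = np.exp(logx.mean(axis=1))
        s = np.median(x[positive] / gm[:, None], axis=0)
    else:
        logger.warning("no gene with all-positive counts; "
                       "falling back to total-count scaling")
        tot = x.sum(axis=0)
        s = tot / tot.mean()
    factors = pd.Series(s, index=counts.columns, name="size_factor")
    norm = counts / factors
    return NormalizedMatrix(size_factors=factors, normalized=norm,
                            log2=np.log2(norm + 1.0))


def simple_de(counts: pd.DataFrame, group_a: list[str], group_b: list[str],
              equal_var: bool = False, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene t-test on the log matrix, BH-adjusted, direction at q < alpha.

    ``log2fc`` is mean(log2 A) - mean(log2 B).  Genes constant and equal in
    both groups get p = 1.  This is deliberately simple plumbing for
    synthetic cohorts; externally produced DE tables (e.g. from
    negative-binomial engines) can be intersected via ``intersect_calls``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 replicates per group")
    L = normalize(counts).log2
    la = L[group_a].to_numpy()
    lb = L[group_b].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(la, lb, axis=1, equal_var=equal_var)
    lfc = la.mean(axis=1) - lb.mean(axis=1)
    degenerate = np.isnan(p)
    p = np.where(degenerate & (lfc == 0), 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)  # residual degeneracies
    q = bh_adjust(p)
    direction = np.where(q < alpha, np.where(lfc > 0, "up", "down"), "ns")
    return pd.DataFrame({
        "gene_id": counts.index, "log2fc": lfc, "p": p, "q": q,
        "direction": direction,
    }).reset_index(drop=True)


def intersect_calls(calls_1: pd.DataFrame,
                    calls_2: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Common up- and down-regulated gene sets of two DE call tables."""
    u1, u2 = set(calls_1["gene_id"]), set(calls_2["gene_id"])
    if u1 != u2:
        offending = sorted(u1 ^ u2)[:10]
        raise ValueError(f"gene universes differ, e.g. {offending}")
    up = (set(calls_1.loc[calls_1["direction"] == "up", "gene_id"])
          & set(calls_2.loc[calls_2["direction"] == "up", "gene_id"]))
    down = (set(calls_1.loc[calls_1["direction"] == "down", "gene_id"])
            & set(calls_2.loc[calls_2["direction"] == "down", "gene_id"]))
    return up, down


def sample_distances(log_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between samples over the log matrix rows."""
    d = squareform(pdist(log_matrix.to_numpy().T, metric="euclidean"))
    return pd.DataFrame(d, index=log_matrix.columns, columns=log_matrix.columns)


def phenocluster(distances: pd.DataFrame, k: int,
                 method: str = "average") -> pd.Series:
    """Cut an agglomerative tree of the distance matrix into k groups."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > distances.shape[0]:
        raise ValueError("k exceeds the number of samples")
    z = scipy_linkage(squareform(distances.to_numpy(), checks=False),
                      method=method)
    labels = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=distances.index, name="cluster")


def pca(log_matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples over genes: 2-D coordinates + variance explained.

    The variance-explained vector covers all components and sums to 1.
    """
    x = log_matrix.to_numpy().T
    x = x - x.mean(axis=0)
    model = PCA(n_components=min(x.shape), svd_solver="full")
    coords = model.fit_transform(x)
    ratios = model.explained_variance_ratio_
    frame = pd.DataFrame(coords[:, :2], index=log_matrix.columns,
                         columns=["PC1", "PC2"])
    return frame, ratios
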