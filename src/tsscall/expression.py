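"""Cluster expression: CPM/log2 matrices, replicate concordance, and the
promoter-expression-ratio contrast between genes with and without
mutant-specific intragenic TSSs.

Raw counts per (cluster, library) are the library's strand-matched tags
inside the cluster interval.  CPM normalization divides by the library's
genome-wide tag total (not only in-cluster tags); the log2 transform adds
a pseudocount of 1 after CPM scaling, so zero counts map to 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .aggregate import rank_sum_test
from .calling import TSSCluster
from .trackio import TagLibrary

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class ExpressionMatrix:
    """Raw, CPM and log2(CPM + pseudocount) matrices, clusters x libraries."""

    raw: pd.DataFrame
    cpm: pd.DataFrame
    log2: pd.DataFrame
    library_totals: pd.Series
    pseudocount: float


def cluster_counts(
    clusters: Sequence[TSSCluster], libraries: Sequence[TagLibrary]
) -> pd.DataFrame:
    """Raw tag-count matrix: rows = cluster ids, columns = library ids."""
    data = {}
    index = [c.cluster_id or f"cluster{i}" for i, c in enumerate(clusters)]
    for lib in libraries:
        col = np.zeros(len(clusters), dtype=int)
        for i, cluster in enumerate(clusters):
            per_base = lib.counts.get((cluster.interval.chrom, cluster.interval.strand), {})
            col[i] = sum(
                per_base.get(p, 0) for p in range(cluster.interval.start, cluster.interval.end)
            )
        data[lib.library_id] = col
    return pd.DataFrame(data, index=index)


def cpm_log2(
    counts: pd.DataFrame,
    library_totals: Optional[pd.Series] = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ExpressionMatrix:
    """CPM-normalize and log2-transform a raw count matrix.

    ``library_totals`` defaults to the matrix column sums; pass genome-wide
    tag totals when clusters do not capture every tag.
    """
    if library_totals is None:
        library_totals = counts.sum(axis=0).astype(float)
    library_totals = library_totals.reindex(counts.columns).astype(float)
    if (library_totals <= 0).any():
        bad = list(library_totals.index[library_totals <= 0])
        raise ValueError(f"zero-total libraries cannot be CPM-normalized: {bad}")
    cpm = counts.astype(float) * 1e6 / library_totals
    log2 = np.log2(cpm + pseudocount)
    return ExpressionMatrix(
        raw=counts, cpm=cpm, log2=log2, library_totals=library_totals, pseudocount=pseudocount
    )


def quantify(
    clusters: Sequence[TSSCluster],
    libraries: Sequence[TagLibrary],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ExpressionMatrix:
    counts = cluster_counts(clusters, libraries)
    totals = pd.Series(
        {lib.library_id: float(lib.total_tags()) for lib in libraries}
    )
    return cpm_log2(counts, library_totals=totals, pseudocount=pseudocount)


def replicate_correlation(
    matrix: ExpressionMatrix, libraries: Sequence[TagLibrary], genotype: str
) -> dict[tuple[str, str], float]:
    """Pearson r of log2 expression between replicate pairs of a genotype.

    Zero-variance columns yield NaN, reported as such rather than raised.
    """
    libs = [lib for lib in libraries if lib.genotype == genotype]
    if len(libs) < 2:
        raise ValueError(f"genotype {genotype!r} has fewer than 2 replicates")
    out = {}
    for i in range(len(libs)):
        for j in range(i + 1, len(libs)):
            a = matrix.log2[libs[i].library_id].to_numpy()
            b = matrix.log2[libs[j].library_id].to_numpy()
            if np.std(a) == 0 or np.std(b) == 0:
                r = float("nan")
            else:
                r = float(np.corrcoef(a, b)[0, 1])
            out[(libs[i].library_id, libs[j].library_id)] = r
    return out


@dataclass
class PromoterContrast:
    """Two-sample comparison of per-gene promoter log2 expression ratios."""

    statistic: float
    p_value: float
    median_with: float
    median_without: float
    n_with: int
    n_without: int
    ratios_with: np.ndarray
    ratios_without: np.ndarray


def promoter_ratio_contrast(
    clusters: Sequence[TSSCluster],
    matrix: ExpressionMatrix,
    libraries: Sequence[TagLibrary],
    mutant_genotype: str,
    wild_type_genotype: str = "wild_type",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PromoterContrast:
    """Per-gene log2(mutant/wild-type) promoter expression, contrasted
    between genes with and without fact-specific clusters.

    A gene's promoter expression per genotype is the mean CPM of its
    replicates at the gene's promoter-annotated cluster (highest-scoring
    one if several).  The two gene sets are compared by a two-sided
    Wilcoxon rank-sum test.
    """
    mutant_cols = [lib.library_id for lib in libraries if lib.genotype == mutant_genotype]
    wt_cols = [lib.library_id for lib in libraries if lib.genotype == wild_type_genotype]
    if not mutant_cols or not wt_cols:
        raise ValueError("both genotypes need at least one library")

    promoter_cluster: dict[str, TSSCluster] = {}
    genes_with_fact: set[str] = set()
    for cluster in clusters:
        if cluster.gene_id is None:
            continue
        if cluster.category == "fact_specific":
            genes_with_fact.add(cluster.gene_id)
        if cluster.annotation == "promoter":
            current = promoter_cluster.get(cluster.gene_id)
            if current is None or cluster.score > current.score:
                promoter_cluster[cluster.gene_id] = cluster

    n_skipped = 0
    ratios_with, ratios_without = [], []
    for gene_id in sorted(promoter_cluster):
        cluster = promoter_cluster[gene_id]
        cid = cluster.cluster_id
        if cid not in matrix.cpm.index:
            n_skipped += 1
            continue
        mut = float(matrix.cpm.loc[cid, mutant_cols].mean())
        wt = float(matrix.cpm.loc[cid, wt_cols].mean())
        ratio = float(np.log2((mut + pseudocount) / (wt + pseudocount)))
        (ratios_with if gene_id in genes_with_fact else ratios_without).append(ratio)
    if n_skipped:
        logger.info("promoter_ratio_contrast: skipped %d genes without quantified promoter", n_skipped)
    if not ratios_with or not ratios_without:
        raise ValueError("both gene sets (with/without fact-specific TSS) must be non-empty")

    a, b = np.asarray(ratios_with), np.asarray(ratios_without)
    stat, p = rank_sum_test(a, b)
    return PromoterContrast(
        statistic=stat,
        p_value=p,
        median_with=float(np.median(a)),
        median_without=float(np.median(b)),
        n_with=len(a),
        n_without=len(b),
        ratios_with=a,
        ratios_without=b,
    )
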