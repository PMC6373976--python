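"""Cluster annotation via the fixed feature-priority hierarchy.

Each cluster overlaps zero or more feature categories; a single label is
resolved by the fixed priority order

    intergenic < antisense < intron < exon < threeUTR < fiveUTR < proximal < promoter

(lowest to highest).  Genic categories require same-strand overlap;
``antisense`` means overlap with a gene span on the opposite strand;
``intergenic`` is the floor when nothing overlaps.  Gene assignment uses
the nearest same-strand gene overlapping the cluster or within 500 bp
(edge-to-edge); intergenic and antisense clusters get no gene.
"""

from __future__ import annotations

from typing import Optional, Sequence

from intervaltree import IntervalTree

from .calling import TSSCluster
from .genome import FEATURE_CATEGORIES, FeatureSet, GeneModel, GenomicInterval

HIERARCHY = (
    "intergenic",
    "antisense",
    "intron",
    "exon",
    "threeUTR",
    "fiveUTR",
    "proximal",
    "promoter",
)
_PRIORITY = {name: i for i, name in enumerate(HIERARCHY)}

GENE_ASSIGN_MAX_DISTANCE = 500
_NO_GENE_ANNOTATIONS = {"intergenic", "antisense"}


class FeatureIndex:
    """Interval-tree index over a FeatureSet for fast overlap queries."""

    def __init__(self, features: FeatureSet):
        self.features = features
        self._trees: dict[tuple[str, str, str], IntervalTree] = {}
        for category in FEATURE_CATEGORIES:
            for iv in features.category_intervals(category):
                tree = self._trees.setdefault((category, iv.chrom, iv.strand), IntervalTree())
                tree.addi(iv.start, iv.end)
        self._span_trees: dict[tuple[str, str], IntervalTree] = {}
        for strand, spans in features.gene_spans.items():
            for iv in spans:
                tree = self._span_trees.setdefault((iv.chrom, strand), IntervalTree())
                tree.addi(iv.start, iv.end)

    def overlapping_categories(self, interval: GenomicInterval) -> set[str]:
        cats = set()
        for category in FEATURE_CATEGORIES:
            tree = self._trees.get((category, interval.chrom, interval.strand))
            if tree is not None and tree.overlap(interval.start, interval.end):
                cats.add(category)
        opposite = "-" if interval.strand == "+" else "+"
        span_tree = self._span_trees.get((interval.chrom, opposite))
        if span_tree is not None and span_tree.overlap(interval.start, interval.end):
            cats.add("antisense")
        return cats


def overlapping_categories(cluster: TSSCluster, index: FeatureIndex) -> set[str]:
    """Feature categories intersecting the cluster's full interval."""
    return index.overlapping_categories(cluster.interval)


def resolve_annotation(categories: set[str]) -> str:
    """Highest-priority category; intergenic when the set is empty."""
    if not categories:
        return "intergenic"
    unknown = categories - set(HIERARCHY)
    if unknown:
        raise ValueError(f"unknown annotation categories: {sorted(unknown)}")
    return max(categories, key=_PRIORITY.__getitem__)


def assign_gene(
    cluster: TSSCluster,
    genes: Sequence[GeneModel],
    max_distance: int = GENE_ASSIGN_MAX_DISTANCE,
) -> Optional[tuple[str, str]]:
    """Nearest same-strand gene overlapping or within max_distance bp.

    Intergenic and antisense clusters are never assigned a gene.  Ties on
    distance break to the gene with the smaller span start.
    """
    if cluster.annotation in _NO_GENE_ANNOTATIONS:
        return None
    iv = cluster.interval
    best: Optional[tuple[int, int, GeneModel]] = None
    for gene in genes:
        span = gene.span
        if span.chrom != iv.chrom or span.strand != iv.strand:
            continue
        if span.start < iv.end and iv.start < span.end:
            dist = 0
        elif span.start >= iv.end:
            dist = span.start - iv.end  # bases strictly between the edges
        else:
            dist = iv.start - span.end
        if dist > max_distance:
            continue
        key = (dist, span.start)
        if best is None or key < (best[0], best[1]):
            best = (dist, span.start, gene)
    if best is None:
        return None
    return best[2].gene_id, best[2].gene_name


def annotate_clusters(
    clusters: Sequence[TSSCluster],
    features: FeatureSet,
    max_distance: int = GENE_ASSIGN_MAX_DISTANCE,
) -> list[TSSCluster]:
    """Set annotation and gene assignment on every cluster, in place."""
    index = FeatureIndex(features)
    for cluster in clusters:
        cluster.annotation = resolve_annotation(index.overlapping_categories(cluster.interval))
        assigned = assign_gene(cluster, features.genes, max_distance=max_distance)
        if assigned is not None:
            cluster.gene_id, cluster.gene_name = assigned
        else:
            cluster.gene_id = cluster.gene_name = None
    return list(clusters)
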