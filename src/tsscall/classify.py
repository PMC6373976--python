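"""Genotype-contrast classification of TSS clusters and summary tables.

Clusters are partitioned into three categories from their per-genotype
detection flags:

* ``basal`` — detected in wild type and in at least one mutant;
* ``wt_specific`` — detected in wild type only;
* ``fact_specific`` — detected in at least one mutant but not in wild type.

Summaries report counts and percentages (half-away-from-zero rounding,
1 decimal for percentages >= 10, 2 decimals below), the fold ratio of
fact-specific over wild-type-specific counts, the per-mutant Venn triple
for intragenic fact-specific clusters, and the fraction of clusters
containing at least one CAGE peak summit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from .calling import TSSCluster

CATEGORIES = ("basal", "wt_specific", "fact_specific")

#: Fig-style Venn restriction: intragenic annotation classes
VENN_ANNOTATIONS = frozenset({"exon", "intron", "antisense"})


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (the convention behind printed percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_percentage(count: int, total: int) -> float:
    """100*count/total at 1 d.p. when >= 10%, else 2 d.p."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = 100.0 * count / total
    return round_half_away(pct, 1 if pct >= 10 else 2)


def classify(
    cluster: TSSCluster,
    wild_type_genotype: str = "wild_type",
    mutant_genotypes: Optional[Sequence[str]] = None,
) -> str:
    """Category from detection flags; every cluster gets exactly one."""
    flags = cluster.detected_in
    if wild_type_genotype not in flags:
        raise ValueError(f"no detection flag for wild-type genotype {wild_type_genotype!r}")
    if mutant_genotypes is None:
        mutant_genotypes = [g for g in flags if g != wild_type_genotype]
    if not any(flags.values()):
        raise ValueError("cluster with no detection flag set")
    in_wt = flags[wild_type_genotype]
    in_mutant = any(flags.get(m, False) for m in mutant_genotypes)
    if in_wt and in_mutant:
        return "basal"
    if in_wt:
        return "wt_specific"
    return "fact_specific"


def classify_clusters(
    clusters: Sequence[TSSCluster],
    wild_type_genotype: str = "wild_type",
    mutant_genotypes: Optional[Sequence[str]] = None,
) -> list[TSSCluster]:
    for cluster in clusters:
        cluster.category = classify(cluster, wild_type_genotype, mutant_genotypes)
    return list(clusters)


@dataclass
class CategorySummary:
    """Counts, percentages and named fold ratios over a categorical split."""

    counts: dict[str, int]
    total: int
    fold_ratios: dict[str, float] = field(default_factory=dict)

    @property
    def percentages(self) -> dict[str, float]:
        return {k: format_percentage(v, self.total) for k, v in self.counts.items()}

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "percentages": self.percentages,
            "total": self.total,
            "fold_ratios": dict(self.fold_ratios),
        }


def summary_from_counts(counts: dict[str, int]) -> CategorySummary:
    """Build a CategorySummary directly from category counts."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("cannot summarize zero clusters")
    summary = CategorySummary(counts=dict(counts), total=total)
    fact = counts.get("fact_specific", 0)
    wt = counts.get("wt_specific", 0)
    if wt:
        summary.fold_ratios["fact_over_wt"] = round(fact / wt)
        summary.fold_ratios["fact_over_wt_raw"] = fact / wt
    return summary


def summarize(clusters: Sequence[TSSCluster]) -> CategorySummary:
    """Category counts/percentages and the fact/wt fold ratio."""
    counts = {c: 0 for c in CATEGORIES}
    for cluster in clusters:
        if cluster.category not in counts:
            raise ValueError(f"cluster with unknown category {cluster.category!r}")
        counts[cluster.category] += 1
    return summary_from_counts(counts)


def annotation_breakdown(
    clusters: Sequence[TSSCluster], which: Optional[str] = None
) -> CategorySummary:
    """Per-annotation counts/percentages, optionally within one category."""
    selected = [c for c in clusters if which is None or c.category == which]
    if not selected:
        raise ValueError(f"no clusters in category {which!r}")
    counts: dict[str, int] = {}
    for cluster in selected:
        counts[cluster.annotation] = counts.get(cluster.annotation, 0) + 1
    total = sum(counts.values())
    return CategorySummary(counts=counts, total=total)


def mutant_venn(
    clusters: Sequence[TSSCluster],
    mutant_genotypes: Sequence[str],
    annotations: frozenset = VENN_ANNOTATIONS,
) -> dict:
    """Overlap of intragenic fact-specific clusters between the two mutants.

    Returns disjoint counts (first-only, second-only, both) plus the
    percentage of the restricted set detected in both mutants.
    """
    if len(mutant_genotypes) != 2:
        raise ValueError("mutant_venn expects exactly two mutant genotypes")
    m1, m2 = mutant_genotypes
    only1 = only2 = both = 0
    for cluster in clusters:
        if cluster.category != "fact_specific" or cluster.annotation not in annotations:
            continue
        in1 = cluster.detected_in.get(m1, False)
        in2 = cluster.detected_in.get(m2, False)
        if in1 and in2:
            both += 1
        elif in1:
            only1 += 1
        elif in2:
            only2 += 1
    total = only1 + only2 + both
    result = {
        f"{m1}_only": only1,
        f"{m2}_only": only2,
        "both": both,
        "total": total,
    }
    if total:
        result["both_percentage"] = round_half_away(100.0 * both / total, 1)
    return result


def cage_overlap_fraction(
    clusters: Sequence[TSSCluster],
    cage_summits: Iterable[tuple[str, int, str]],
    by_annotation: bool = True,
) -> dict:
    """Fraction of clusters whose interval contains >= 1 CAGE peak summit.

    Strand-matched when the summit is stranded, strand-ignored for '.'
    summits.  Returned per (annotation x category) grouping plus overall
    rows, mirroring a table of All / basal / fact-specific columns.
    """
    summits_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for chrom, pos, strand in cage_summits:
        summits_by_chrom.setdefault(chrom, []).append((pos, strand))

    def has_summit(cluster: TSSCluster) -> bool:
        iv = cluster.interval
        for pos, strand in summits_by_chrom.get(iv.chrom, []):
            if iv.start <= pos < iv.end and strand in (".", iv.strand):
                return True
        return False

    groups: dict[tuple[str, str], list[bool]] = {}
    for cluster in clusters:
        hit = has_summit(cluster)
        anns = ["all"]
        if by_annotation and cluster.annotation:
            anns.append(cluster.annotation)
        cats = ["All", cluster.category or "unclassified"]
        for ann in anns:
            for cat in cats:
                groups.setdefault((ann, cat), []).append(hit)

    out = {}
    for (ann, cat), hits in groups.items():
        out[f"{ann}|{cat}"] = {
            "n": len(hits),
            "n_overlapping": int(sum(hits)),
            "fraction": sum(hits) / len(hits),
        }
    return out
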