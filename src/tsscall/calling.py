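"""TSS cluster calling from multi-library 5'-tag counts.

The calling rule: a genomic base is a TSS candidate for a genotype when at
least ``min_tags`` tags support it in at least ``min_libraries`` libraries
of that genotype.  Candidate positions (union over genotypes, so every
genotype is scored against the same cluster coordinate system) are merged
into clusters whenever consecutive positions are separated by at most
``max_gap`` bases.  Each cluster carries a score (mean tags per library,
over all libraries in the experiment), a summit (base with maximal pooled
count, leftmost on ties), and per-genotype detection flags (a genotype
detects a cluster when the cluster contains at least one of its candidate
positions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .genome import GenomicInterval
from .trackio import TagLibrary, group_by_genotype

DEFAULT_MIN_TAGS = 2
DEFAULT_MIN_LIBRARIES = 2
DEFAULT_MAX_GAP = 20


@dataclass
class CandidatePositionSet:
    """Per-genotype candidate base offsets, keyed (chrom, strand)."""

    positions: dict[str, dict[tuple[str, str], set[int]]]

    def genotypes(self) -> list[str]:
        return sorted(self.positions)

    def union(self) -> dict[tuple[str, str], set[int]]:
        merged: dict[tuple[str, str], set[int]] = {}
        for per_geno in self.positions.values():
            for key, posset in per_geno.items():
                merged.setdefault(key, set()).update(posset)
        return merged


@dataclass
class TSSCluster:
    """A called TSS cluster (one row of the output table)."""

    interval: GenomicInterval
    summit: int
    score: float
    detected_in: dict[str, bool]
    annotation: str = ""
    category: str = ""
    gene_id: Optional[str] = None
    gene_name: Optional[str] = None
    cluster_id: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit must lie within the cluster interval")
        if self.score <= 0:
            raise ValueError("cluster score must be positive")
        if not any(self.detected_in.values()):
            raise ValueError("cluster must be detected in at least one genotype")


def find_candidates(
    libraries: Sequence[TagLibrary],
    min_tags: int = DEFAULT_MIN_TAGS,
    min_libraries: int = DEFAULT_MIN_LIBRARIES,
) -> CandidatePositionSet:
    """Positions supported by >= min_tags tags in >= min_libraries libraries
    of the same genotype."""
    groups = group_by_genotype(libraries)
    for genotype, libs in groups.items():
        if len(libs) < min_libraries:
            raise ValueError(
                f"genotype {genotype!r} has {len(libs)} libraries, "
                f"support rule needs at least {min_libraries}"
            )
    out: dict[str, dict[tuple[str, str], set[int]]] = {}
    for genotype, libs in groups.items():
        per_geno: dict[tuple[str, str], dict[int, int]] = {}
        for lib in libs:
            for key, per_base in lib.counts.items():
                support = per_geno.setdefault(key, {})
                for pos, count in per_base.items():
                    if count >= min_tags:
                        support[pos] = support.get(pos, 0) + 1
        out[genotype] = {
            key: {pos for pos, nlibs in support.items() if nlibs >= min_libraries}
            for key, support in per_geno.items()
        }
        out[genotype] = {k: v for k, v in out[genotype].items() if v}
    return CandidatePositionSet(positions=out)


def cluster_candidates(
    positions: dict[tuple[str, str], set[int]], max_gap: int = DEFAULT_MAX_GAP
) -> list[GenomicInterval]:
    """Merge candidate positions <= max_gap apart into cluster intervals.

    Strands never merge; the cluster interval is [min member, max member + 1).
    """
    clusters = []
    for (chrom, strand), posset in positions.items():
        ordered = sorted(posset)
        if not ordered:
            continue
        run_start = prev = ordered[0]
        for pos in ordered[1:]:
            if pos - prev > max_gap:
                clusters.append(GenomicInterval(chrom, run_start, prev + 1, strand))
                run_start = pos
            prev = pos
        clusters.append(GenomicInterval(chrom, run_start, prev + 1, strand))
    clusters.sort(key=lambda iv: (iv.chrom, iv.start, iv.strand))
    return clusters


def pooled_counts(
    interval: GenomicInterval, libraries: Sequence[TagLibrary]
) -> dict[int, int]:
    """Summed raw tag counts per base over all libraries, within interval."""
    pooled: dict[int, int] = {}
    key = (interval.chrom, interval.strand)
    for lib in libraries:
        per_base = lib.counts.get(key, {})
        # iterate the smaller side: cluster intervals are short
        for pos in range(interval.start, interval.end):
            c = per_base.get(pos, 0)
            if c:
                pooled[pos] = pooled.get(pos, 0) + c
    return pooled


def score_and_summit(
    interval: GenomicInterval, libraries: Sequence[TagLibrary]
) -> tuple[float, int]:
    """Score = total tags in interval / number of libraries; summit = base
    with maximal pooled count (leftmost on ties)."""
    pooled = pooled_counts(interval, libraries)
    total = sum(pooled.values())
    if total == 0:
        raise ValueError(f"no tags in cluster interval {interval}")
    score = total / len(libraries)
    summit = max(sorted(pooled), key=lambda p: pooled[p])
    # max() on sorted keys returns the first maximal element -> leftmost tie
    return score, summit


def detection_flags(
    interval: GenomicInterval, candidates: CandidatePositionSet
) -> dict[str, bool]:
    """True for genotype g iff >=1 base of the interval is a g-candidate."""
    key = (interval.chrom, interval.strand)
    flags = {}
    for genotype in candidates.genotypes():
        posset = candidates.positions[genotype].get(key, set())
        flags[genotype] = any(
            interval.start <= p < interval.end for p in posset
        )
    return flags


def call_tss(
    libraries: Sequence[TagLibrary],
    min_tags: int = DEFAULT_MIN_TAGS,
    min_libraries: int = DEFAULT_MIN_LIBRARIES,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[TSSCluster]:
    """Full calling chain: candidates -> union -> clusters -> score/summit/flags."""
    candidates = find_candidates(libraries, min_tags=min_tags, min_libraries=min_libraries)
    intervals = cluster_candidates(candidates.union(), max_gap=max_gap)
    clusters = []
    for i, interval in enumerate(intervals):
        score, summit = score_and_summit(interval, libraries)
        flags = detection_flags(interval, candidates)
        clusters.append(
            TSSCluster(
                interval=interval,
                summit=summit,
                score=score,
                detected_in=flags,
                cluster_id=f"TSS{i + 1:05d}",
            )
        )
    return clusters
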