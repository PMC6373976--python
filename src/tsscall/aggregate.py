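"""Position-anchored chromatin-signal summarization.

Two aggregation views over unstranded signal tracks, anchored at TSS (or
control) positions:

* boxplot view — the median signal within a 20 bp window centred at each
  anchor ([p-10, p+10)), summarized by median/quartile/1.5*IQR-whisker
  statistics and compared between anchor sets by a two-sided Wilcoxon
  rank-sum test;
* metagene view — the mean signal per offset over a 400 bp window
  (offsets -200..+199, strand-flipped for minus-strand anchors) with
  normal-based 95% confidence bands (mean +- 1.96*sd/sqrt(n)).

Control anchors are sampled uniformly over each gene's exonic bases with a
seeded generator, optionally excluding positions near the gene's 3' end
(run-on-style assays over-report signal at polyadenylation sites).
Single-end read coverage is reconstructed by resizing each read to half
the average insert size, anchored at its 3' end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .genome import GeneModel, five_prime_end
from .trackio import SignalTrack

logger = logging.getLogger(__name__)

DEFAULT_BOX_WIDTH = 20
DEFAULT_METAGENE_WIDTH = 400
CI_MULTIPLIER = 1.96  # normal-based 95% band


@dataclass
class AnchorSet:
    """A labelled list of stranded anchor points."""

    label: str
    anchors: list[tuple[str, int, str]]

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("anchor set label must be non-empty")

    def __len__(self) -> int:
        return len(self.anchors)


def window_median(track: SignalTrack, chrom: str, pos: int, width: int = DEFAULT_BOX_WIDTH) -> float:
    """Median per-base value in [pos - width/2, pos + width/2).

    Absent bases count as 0; the window is clipped at chromosome edges
    (the median is then over the remaining bases).
    """
    half = width // 2
    start, end = pos - half, pos - half + width
    arr = track.values.get(chrom)
    if arr is not None:
        start_c, end_c = max(start, 0), min(end, len(arr))
        if start_c < end_c and (start_c > start or end_c < end):
            return float(np.median(arr[start_c:end_c]))
    return float(np.median(track.window(chrom, start, end)))


def window_medians(track: SignalTrack, anchors: AnchorSet, width: int = DEFAULT_BOX_WIDTH) -> np.ndarray:
    return np.array([window_median(track, c, p, width) for c, p, _ in anchors.anchors])


@dataclass
class MetageneProfile:
    offsets: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int


def metagene(track: SignalTrack, anchors: AnchorSet, width: int = DEFAULT_METAGENE_WIDTH) -> MetageneProfile:
    """Per-offset mean signal across anchors, strand-oriented, with CI.

    Offset o for a plus-strand anchor at p reads track value at p+o; for a
    minus-strand anchor at p-o, so profiles are in transcription
    orientation.  Positions off the chromosome read 0.
    """
    if len(anchors) < 2:
        raise ValueError("metagene needs at least 2 anchors for a confidence band")
    half = width // 2
    offsets = np.arange(-half, width - half)
    rows = np.empty((len(anchors), width))
    for i, (chrom, pos, strand) in enumerate(anchors.anchors):
        if strand == "-":
            window = track.window(chrom, pos - (width - half - 1), pos + half + 1)[::-1]
        else:
            window = track.window(chrom, pos - half, pos + width - half)
        rows[i] = window
    mean = rows.mean(axis=0)
    sd = rows.std(axis=0, ddof=1)
    sem = sd / np.sqrt(len(anchors))
    return MetageneProfile(
        offsets=offsets,
        mean=mean,
        ci_low=mean - CI_MULTIPLIER * sem,
        ci_high=mean + CI_MULTIPLIER * sem,
        n=len(anchors),
    )


def sample_control_positions(
    genes: Sequence[GeneModel],
    seed: int,
    n_per_gene: int = 1,
    min_end_distance: int = 0,
    label: str = "control",
) -> AnchorSet:
    """Uniform random exonic positions per gene, seeded and reproducible.

    Positions closer than ``min_end_distance`` to the gene's 3' end are
    removed after sampling (a post-filter, so genes near the length cutoff
    may contribute fewer than ``n_per_gene`` anchors).  Genes with no
    eligible exonic base are skipped with a logged count.
    """
    rng = np.random.default_rng(seed)
    anchors = []
    n_skipped = 0
    for gene in genes:
        exonic = np.fromiter(
            (p for ex in gene.exons for p in range(ex.start, ex.end)), dtype=int
        )
        if exonic.size == 0:
            n_skipped += 1
            continue
        chosen = rng.choice(exonic, size=n_per_gene, replace=True)
        if min_end_distance > 0:
            three_prime = gene.span.end - 1 if gene.span.strand == "+" else gene.span.start
            chosen = chosen[np.abs(chosen - three_prime) >= min_end_distance]
        if chosen.size == 0:
            n_skipped += 1
            continue
        anchors.extend((gene.span.chrom, int(p), gene.span.strand) for p in chosen)
    if n_skipped:
        logger.info("sample_control_positions: %d genes contributed no anchor", n_skipped)
    return AnchorSet(label=label, anchors=anchors)


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U).

    Exact null distribution when both groups have n <= 25 and no ties
    span the groups; otherwise the normal approximation with tie
    correction.  All-tied input returns p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 25 and b.size <= 25 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_anchor_sets(
    track: SignalTrack,
    set_a: AnchorSet,
    set_b: AnchorSet,
    width: int = DEFAULT_BOX_WIDTH,
) -> tuple[float, float]:
    """Wilcoxon rank-sum on the per-anchor window medians of two sets."""
    return rank_sum_test(window_medians(track, set_a, width), window_medians(track, set_b, width))


@dataclass
class BoxplotStats:
    median: float
    lower_hinge: float
    upper_hinge: float
    whisker_low: float
    whisker_high: float
    n_outliers: int
    n: int


def boxplot_stats(values: Sequence[float]) -> BoxplotStats:
    """Median, quartile hinges, 1.5*IQR whiskers and outlier count.

    Hinges are the 25th/75th percentiles (linear interpolation); whiskers
    are the most extreme data values within 1.5*IQR beyond the hinges.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("boxplot_stats needs at least one value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    return BoxplotStats(
        median=float(med),
        lower_hinge=float(q1),
        upper_hinge=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        n_outliers=int(arr.size - inside.size),
        n=int(arr.size),
    )


def resize_single_end(
    reads: Sequence[tuple[str, int, int, str]],
    insert_size: int,
    chrom_lengths: Optional[dict[str, int]] = None,
    assay: str = "resized",
) -> SignalTrack:
    """Coverage from single-end reads resized to half the insert size.

    Each read becomes an interval of length floor(insert_size/2) ending at
    the read's 3' end and extending toward its 5' side; coverage is the
    per-base count of resized intervals, clipped at chromosome bounds.
    """
    if insert_size <= 0:
        raise ValueError("insert_size must be positive")
    half = insert_size // 2
    if chrom_lengths is None:
        chrom_lengths = {}
        for chrom, start, end, _ in reads:
            chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0), end + half)
    values = {chrom: np.zeros(length, dtype=float) for chrom, length in chrom_lengths.items()}
    for chrom, start, end, strand in reads:
        if strand == "+":
            new_start, new_end = end - half, end
        else:
            new_start, new_end = start, start + half
        arr = values[chrom]
        lo, hi = max(new_start, 0), min(new_end, len(arr))
        if lo < hi:
            arr[lo:hi] += 1
    return SignalTrack(assay=assay, values=values)
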