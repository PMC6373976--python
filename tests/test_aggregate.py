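"""Window medians, metagene profiles, control sampling, Wilcoxon, resizing."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from tsscall import (
    AnchorSet,
    GeneModel,
    GenomicInterval,
    SignalTrack,
    boxplot_stats,
    compare_anchor_sets,
    metagene,
    rank_sum_test,
    resize_single_end,
    sample_control_positions,
    window_median,
)


def track_from(arr, chrom="chr1"):
    return SignalTrack(assay="t", values={chrom: np.asarray(arr, dtype=float)})


def test_window_median_constant_and_step():
    t = track_from(np.full(100, 3.0))
    assert window_median(t, "chr1", 50) == 3.0
    step = track_from([0.0] * 10 + [4.0] * 10)
    assert window_median(step, "chr1", 10) == 2.0  # even-n median = midpoint mean


def test_window_median_matches_naive_oracle():
    rng = np.random.default_rng(0)
    arr = rng.exponential(1.0, size=10_000)
    t = track_from(arr)
    for pos in rng.integers(0, 10_000, size=100):
        lo, hi = max(pos - 10, 0), min(pos + 10, arr.size)
        assert window_median(t, "chr1", int(pos)) == pytest.approx(
            float(np.median(sorted(arr[lo:hi]))), abs=1e-9
        )


def test_metagene_matches_naive_oracle_and_flips_minus_strand():
    rng = np.random.default_rng(1)
    arr = rng.normal(2.0, 0.5, size=5000)
    t = track_from(arr)
    anchors = AnchorSet("a", [("chr1", 1000, "+"), ("chr1", 3000, "+"), ("chr1", 2000, "-")])
    prof = metagene(t, anchors, width=400)
    for idx, o in enumerate(prof.offsets):
        vals = [arr[1000 + o], arr[3000 + o], arr[2000 - o]]
        assert prof.mean[idx] == pytest.approx(np.mean(vals), abs=1e-9)
        sem = np.std(vals, ddof=1) / np.sqrt(3)
        assert prof.ci_high[idx] - prof.mean[idx] == pytest.approx(1.96 * sem, abs=1e-9)


def test_metagene_on_asymmetric_ramp_mirrors_across_strands():
    ramp = np.arange(2000, dtype=float)
    t = track_from(ramp)
    plus = metagene(t, AnchorSet("p", [("chr1", 1000, "+"), ("chr1", 1000, "+")]), 400)
    minus = metagene(t, AnchorSet("m", [("chr1", 1000, "-"), ("chr1", 1000, "-")]), 400)
    # plus reads 1000+o, minus reads 1000-o: the two profiles sum to 2000
    assert np.allclose(plus.mean + minus.mean, 2000.0)


def test_metagene_symmetry_on_symmetric_signal():
    # symmetric bump, strand-balanced anchors -> profile symmetric about 0
    arr = np.zeros(4000)
    center = 2000
    offs = np.arange(-300, 301)
    arr[center + offs] = np.exp(-(offs**2) / (2 * 80.0**2))
    t = track_from(arr)
    anchors = AnchorSet("s", [("chr1", center, "+"), ("chr1", center, "-")])
    prof = metagene(t, anchors, width=400)
    # offsets are -200..199; compare o and -o where both exist
    for o in range(1, 200):
        i_pos = int(np.where(prof.offsets == o)[0][0])
        i_neg = int(np.where(prof.offsets == -o)[0][0])
        assert prof.mean[i_pos] == pytest.approx(prof.mean[i_neg], abs=1e-9)


def test_metagene_with_identical_anchors_has_zero_ci_width():
    t = track_from(np.arange(1000, dtype=float))
    prof = metagene(t, AnchorSet("z", [("chr1", 500, "+"), ("chr1", 500, "+")]), 400)
    assert np.allclose(prof.ci_low, prof.mean)
    assert np.allclose(prof.ci_high, prof.mean)


def test_metagene_requires_two_anchors():
    t = track_from(np.zeros(100))
    with pytest.raises(ValueError, match="at least 2"):
        metagene(t, AnchorSet("one", [("chr1", 50, "+")]))


def one_exon_gene(start, end, strand="+", gid="g"):
    return GeneModel(
        gene_id=gid,
        span=GenomicInterval("chr1", start, end, strand),
        exons=[GenomicInterval("chr1", start, end, strand)],
    )


def test_control_sampling_single_base_and_determinism():
    gene = GeneModel(
        gene_id="g",
        span=GenomicInterval("chr1", 100, 101, "+"),
        exons=[GenomicInterval("chr1", 100, 101, "+")],
    )
    a = sample_control_positions([gene], seed=1)
    assert a.anchors == [("chr1", 100, "+")]
    genes = [one_exon_gene(i * 1000, i * 1000 + 500, gid=f"g{i}") for i in range(50)]
    s1 = sample_control_positions(genes, seed=7)
    s2 = sample_control_positions(genes, seed=7)
    assert s1.anchors == s2.anchors
    assert sample_control_positions(genes, seed=8).anchors != s1.anchors


def test_gene_end_exclusion_filters_short_genes():
    short = one_exon_gene(0, 150)
    out = sample_control_positions([short], seed=1, min_end_distance=200)
    assert out.anchors == []
    # on a long gene, no kept anchor is within 200 bp of the 3' end
    long_genes = [one_exon_gene(0, 5000, strand=s, gid=f"g{s}") for s in "+-"]
    out = sample_control_positions(long_genes, seed=2, n_per_gene=50, min_end_distance=200)
    for gene in long_genes:
        three_prime = gene.span.end - 1 if gene.span.strand == "+" else gene.span.start
        for chrom, p, strand in out.anchors:
            if strand == gene.span.strand:
                assert abs(p - three_prime) >= 200


def test_control_sampling_is_uniform_per_gene():
    gene = one_exon_gene(0, 100)
    counts = np.zeros(100)
    out = sample_control_positions([gene], seed=3, n_per_gene=5000)
    for _, p, _ in out.anchors:
        counts[p] += 1
    chi2 = ((counts - 50.0) ** 2 / 50.0).sum()
    assert chi2 < sps.chi2.ppf(0.99, df=99)


def enumerate_rank_sum_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    n = len(pooled)
    mean_u = n_a * (n - n_a) / 2
    count = total = 0
    for combo in itertools.combinations(range(n), n_a):
        u = ranks[list(combo)].sum() - n_a * (n_a + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


def test_exact_rank_sum_matches_enumeration():
    rng = np.random.default_rng(10)
    for n_a, n_b in [(3, 3), (4, 5), (6, 6), (2, 6)]:
        a = rng.normal(0, 1, n_a)
        b = rng.normal(0.5, 1, n_b)
        _, p = rank_sum_test(a, b)
        assert p == pytest.approx(enumerate_rank_sum_p(a, b), abs=1e-12)


def test_rank_sum_conventions():
    # all values tied across both groups: p = 1 by convention
    assert rank_sum_test(np.ones(5), np.ones(7))[1] == 1.0
    # identical sets: p = 1 (every assignment equally extreme)
    x = np.array([1.0, 2.0, 3.0])
    assert rank_sum_test(x, x)[1] == 1.0


def test_shifted_anchor_sets_detected():
    rng = np.random.default_rng(11)
    arr = rng.normal(1.0, 0.2, size=50_000)
    arr[25_000:] += 1.0
    t = track_from(arr)
    set_a = AnchorSet("a", [("chr1", int(p), "+") for p in rng.integers(100, 24_000, 100)])
    set_b = AnchorSet("b", [("chr1", int(p), "+") for p in rng.integers(26_000, 49_000, 100)])
    stat, p = compare_anchor_sets(t, set_a, set_b)
    assert p < 0.001


def test_boxplot_stats_closed_forms():
    s = boxplot_stats(np.arange(1, 101, dtype=float))
    assert s.median == 50.5
    assert s.upper_hinge - s.lower_hinge == pytest.approx(49.5)
    assert s.n_outliers == 0
    assert s.whisker_low == 1 and s.whisker_high == 100
    const = boxplot_stats([2.0] * 10)
    assert const.median == const.lower_hinge == const.whisker_high == 2.0
    assert const.n_outliers == 0
    spiked = boxplot_stats(list(range(1, 100)) + [1000])
    assert spiked.n_outliers == 1
    assert spiked.whisker_high == 99


def test_boxplot_requires_data():
    with pytest.raises(ValueError):
        boxplot_stats([])


@pytest.mark.parametrize(
    "read,insert,want",
    [
        (("chr1", 100, 150, "+"), 100, (100, 150)),  # read length = half insert
        (("chr1", 100, 175, "+"), 100, (125, 175)),  # anchored at 3' end
        (("chr1", 100, 175, "-"), 100, (100, 150)),  # 3' end at the left on minus
    ],
)
def test_resize_single_end_anchor_arithmetic(read, insert, want):
    track = resize_single_end([read], insert, chrom_lengths={"chr1": 1000})
    covered = np.nonzero(track.values["chr1"])[0]
    assert (covered[0], covered[-1] + 1) == want


def test_resize_total_mass_accounts_for_clipping():
    reads = [("chr1", 0, 30, "-"), ("chr1", 500, 560, "+")]
    track = resize_single_end(reads, 101, chrom_lengths={"chr1": 520})
    # minus read covers [0,50); plus read's [510,560) clips to [510,520)
    assert track.values["chr1"].sum() == 50 + 10
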