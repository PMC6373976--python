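"""Genotype-contrast categories, summary arithmetic, Venn and CAGE overlap."""

import numpy as np
import pytest

from tsscall import (
    GenomicInterval,
    TSSCluster,
    cage_overlap_fraction,
    classify,
    format_percentage,
    mutant_venn,
    round_half_away,
    summarize,
    summary_from_counts,
)


def make_cluster(flags, annotation="exon", start=100, strand="+", category=""):
    c = TSSCluster(
        interval=GenomicInterval("chr1", start, start + 10, strand),
        summit=start,
        score=1.0,
        detected_in=dict(flags),
        annotation=annotation,
    )
    c.category = category
    return c


@pytest.mark.parametrize(
    "flags,want",
    [
        ({"wild_type": True, "spt16": True, "ssrp1": False}, "basal"),
        ({"wild_type": True, "spt16": False, "ssrp1": True}, "basal"),
        ({"wild_type": False, "spt16": False, "ssrp1": True}, "fact_specific"),
        ({"wild_type": False, "spt16": True, "ssrp1": True}, "fact_specific"),
        ({"wild_type": True, "spt16": False, "ssrp1": False}, "wt_specific"),
    ],
)
def test_classification_truth_table(flags, want):
    assert classify(make_cluster(flags)) == want


def test_classify_requires_wild_type_flag_entry():
    with pytest.raises(ValueError, match="wild-type"):
        classify(make_cluster({"spt16": True}), wild_type_genotype="wild_type")


def test_classification_partitions_all_flag_combinations():
    genotypes = ("wild_type", "spt16", "ssrp1")
    for bits in range(1, 8):
        flags = {g: bool(bits >> i & 1) for i, g in enumerate(genotypes)}
        category = classify(make_cluster(flags))
        assert category in ("basal", "wt_specific", "fact_specific")


def test_genome_wide_category_percentages_and_fold_ratio():
    # the three-group split of 96232 clusters
    summary = summary_from_counts(
        {"basal": 77738, "wt_specific": 1023, "fact_specific": 17471}
    )
    assert summary.total == 96232
    pct = summary.percentages
    assert pct["basal"] == 80.8
    assert pct["wt_specific"] == 1.06
    assert summary.fold_ratios["fact_over_wt"] == 17
    # standard rounding gives 18.2 for 17471/96232 = 18.16%
    assert pct["fact_specific"] == 18.2


def test_annotation_percentages_match_reported_values():
    assert format_percentage(30487, 96232) == 31.7  # promoter share
    assert format_percentage(43414, 96232) == 45.1  # exon share
    assert format_percentage(2460, 96232) == 2.56   # intron share, 2 d.p. under 10%


def test_percentages_recomputed_by_brute_force_division():
    rng = np.random.default_rng(4)
    for _ in range(50):
        counts = {f"k{i}": int(c) for i, c in enumerate(rng.integers(0, 5000, size=4))}
        if sum(counts.values()) == 0:
            continue
        summary = summary_from_counts(counts)
        total = sum(counts.values())
        for k, v in counts.items():
            raw = 100 * v / total
            nd = 1 if raw >= 10 else 2
            assert summary.percentages[k] == pytest.approx(round_half_away(raw, nd))
        assert sum(summary.counts.values()) == summary.total


def test_summarize_is_input_order_invariant():
    clusters = [
        make_cluster({"wild_type": True, "spt16": True}, category="basal"),
        make_cluster({"wild_type": False, "spt16": True}, category="fact_specific"),
        make_cluster({"wild_type": True, "spt16": False}, category="wt_specific"),
    ]
    a = summarize(clusters).to_dict()
    b = summarize(clusters[::-1]).to_dict()
    assert a == b


def test_mutant_venn_counts_and_percentage():
    # reported intragenic overlap: 9281 of 11555 in both mutants -> 80.3%
    clusters = []
    for _ in range(9281):
        clusters.append(make_cluster({"wild_type": False, "spt16": True, "ssrp1": True},
                                     category="fact_specific"))
    for _ in range(1500):
        clusters.append(make_cluster({"wild_type": False, "spt16": True, "ssrp1": False},
                                     category="fact_specific"))
    for _ in range(774):
        clusters.append(make_cluster({"wild_type": False, "spt16": False, "ssrp1": True},
                                     category="fact_specific"))
    venn = mutant_venn(clusters, ["spt16", "ssrp1"])
    assert venn["both"] == 9281
    assert venn["total"] == 11555
    assert venn["both_percentage"] == 80.3


def test_venn_restricted_to_intragenic_annotations():
    clusters = [
        make_cluster({"wild_type": False, "spt16": True, "ssrp1": True},
                     annotation="promoter", category="fact_specific"),
        make_cluster({"wild_type": False, "spt16": True, "ssrp1": True},
                     annotation="exon", category="fact_specific"),
        make_cluster({"wild_type": True, "spt16": True, "ssrp1": True},
                     annotation="exon", category="basal"),
    ]
    venn = mutant_venn(clusters, ["spt16", "ssrp1"])
    assert venn["total"] == 1 and venn["both"] == 1


def test_venn_matches_brute_force_set_algebra():
    rng = np.random.default_rng(12)
    clusters = []
    for _ in range(300):
        in1, in2 = bool(rng.integers(2)), bool(rng.integers(2))
        if not (in1 or in2):
            in1 = True
        clusters.append(
            make_cluster({"wild_type": False, "spt16": in1, "ssrp1": in2},
                         annotation=["exon", "intron", "antisense"][rng.integers(3)],
                         category="fact_specific")
        )
    venn = mutant_venn(clusters, ["spt16", "ssrp1"])
    both = sum(1 for c in clusters if c.detected_in["spt16"] and c.detected_in["ssrp1"])
    only1 = sum(1 for c in clusters if c.detected_in["spt16"] and not c.detected_in["ssrp1"])
    assert venn["both"] == both and venn["spt16_only"] == only1
    assert venn["both"] + venn["spt16_only"] + venn["ssrp1_only"] == venn["total"]


def test_cage_overlap_containment_boundaries():
    cluster = make_cluster({"wild_type": True}, category="basal", start=100)  # [100, 110)
    inside = [("chr1", 100, "+"), ("chr1", 109, ".")]
    outside = [("chr1", 110, "+"), ("chr1", 99, "+"), ("chr1", 105, "-")]
    for summits, want in ((inside[:1], 1.0), (inside[1:], 1.0), (outside, 0.0)):
        out = cage_overlap_fraction([cluster], summits)
        assert out["all|All"]["fraction"] == want


def test_cage_overlap_matches_brute_force_count():
    rng = np.random.default_rng(5)
    clusters = [
        make_cluster({"wild_type": True}, category="basal", start=int(s))
        for s in rng.choice(5000, size=80, replace=False)
    ]
    summits = [("chr1", int(p), ".") for p in rng.integers(0, 5200, size=120)]
    out = cage_overlap_fraction(clusters, summits)
    expected = sum(
        1 for c in clusters
        if any(c.interval.start <= p < c.interval.end for _, p, _ in summits)
    )
    assert out["all|All"]["n_overlapping"] == expected
    assert out["all|All"]["n"] == len(clusters)
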