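"""Synthetic study generator: determinism, planted structure, bookkeeping."""

import numpy as np
import pytest

from tsscall import (
    SimulationConfig,
    call_tss,
    emit_libraries,
    emit_signal_tracks,
    generate_genome,
    plant_tss,
    read_truth,
    score_recovery,
    simulate,
    write_bundle,
    write_truth,
)


def cfg(**kw):
    kw.setdefault("seed", 42)
    return SimulationConfig(**kw)


def test_config_rejects_inverted_means():
    with pytest.raises(ValueError, match="mu_fact"):
        cfg(mu_promoter=10, mu_fact=50)


def test_empty_genome():
    genes, lengths = generate_genome(cfg(n_genes=0))
    assert genes == []
    assert len(lengths) == 2


def test_genome_is_deterministic_and_valid():
    a, _ = generate_genome(cfg(n_genes=100))
    b, _ = generate_genome(cfg(n_genes=100))
    assert [(g.gene_id, g.span, tuple(g.exons)) for g in a] == [
        (g.gene_id, g.span, tuple(g.exons)) for g in b
    ]
    for g in a:
        g.validate()  # exon ordering/containment invariants
    # non-overlapping genes per chromosome
    by_chrom = {}
    for g in a:
        by_chrom.setdefault(g.span.chrom, []).append(g.span)
    for spans in by_chrom.values():
        spans.sort(key=lambda s: s.start)
        for s1, s2 in zip(spans, spans[1:]):
            assert s1.end <= s2.start


def test_infeasible_packing_errors():
    with pytest.raises(ValueError, match="pack"):
        generate_genome(cfg(n_genes=500, chrom_length=20_000))


def test_planted_truth_structure():
    genes, _ = generate_genome(cfg())
    truth = plant_tss(genes, cfg())
    promoters = truth.of_kind("promoter")
    assert len(promoters) == len(genes)
    genotypes = set(cfg().genotypes)
    for rec in promoters:
        assert set(rec.active_genotypes) == genotypes
        assert rec.expected_category == "basal"
    for rec in truth.of_kind("fact_specific_exonic", "fact_specific_intronic"):
        assert set(rec.active_genotypes) <= {"spt16", "ssrp1"}
        assert rec.expected_category == "fact_specific"
    # pairwise separation guarantees single clusters under jitter
    min_sep = cfg().min_planted_separation
    per_key = {}
    for rec in truth.planted:
        per_key.setdefault((rec.chrom, rec.strand), []).append(rec.position)
    for positions in per_key.values():
        positions.sort()
        assert all(b - a >= min_sep for a, b in zip(positions, positions[1:]))


def test_fact_fraction_extremes():
    genes, _ = generate_genome(cfg())
    none = plant_tss(genes, cfg(fact_fraction=0.0))
    assert none.of_kind("fact_specific_exonic", "fact_specific_intronic") == []
    every = plant_tss(genes, cfg(fact_fraction=1.0, fact_intronic_fraction=0.0))
    fact = every.of_kind("fact_specific_exonic")
    assert len(fact) >= 0.95 * len(genes)  # a few genes may lack eligible bases
    by_gene = {g.gene_id: g for g in genes}
    for rec in fact:
        gene = by_gene[rec.gene_id]
        assert gene.span.start <= rec.position < gene.span.end


def test_mutant_only_sites_have_no_wild_type_tags():
    bundle = simulate(cfg())
    for rec in bundle.truth.of_kind("fact_specific_exonic", "fact_specific_intronic"):
        for lib in bundle.libraries:
            if lib.genotype == "wild_type":
                window = range(rec.position - 5, rec.position + 6)
                assert all(lib.count_at(rec.chrom, rec.strand, p) == 0 for p in window)


def test_negative_binomial_mean_calibration():
    config = cfg(n_genes=500, chrom_length=600_000, mu_promoter=50, dispersion=10)
    genes, _ = generate_genome(config)
    truth = plant_tss(genes, config)
    libs = emit_libraries(truth, config)
    lib = libs[0]
    per_site = []
    for rec in truth.of_kind("promoter"):
        per_site.append(
            sum(
                lib.count_at(rec.chrom, rec.strand, p)
                for p in range(rec.position - 5, rec.position + 6)
            )
        )
    assert np.mean(per_site) == pytest.approx(50, rel=0.10)


def test_noise_only_genome_calls_nothing():
    config = cfg(n_genes=0, noise_rate_per_kb=2.0)
    genes, _ = generate_genome(config)
    truth = plant_tss(genes, config)
    libs = emit_libraries(truth, config)
    assert call_tss(libs) == []


def test_supra_threshold_noise_mode_does_seed_clusters():
    config = cfg(n_genes=0, noise_rate_per_kb=0.2, supra_threshold_noise=True)
    truth = plant_tss([], config)
    libs = emit_libraries(truth, config)
    assert len(call_tss(libs)) > 0


def test_signal_tracks_plant_enrichment_where_expected():
    config = cfg(signal_noise_sd=0.05)
    genes, _ = generate_genome(config)
    truth = plant_tss(genes, config)
    tracks = emit_signal_tracks(truth, config, genes=genes)
    fact = truth.of_kind("fact_specific_exonic", "fact_specific_intronic")
    at_fact = np.mean([tracks["h3k4me1"].value_at(r.chrom, r.position) for r in fact])
    # amplitude above (baseline + gene-body-free) level, averaged over sites
    assert at_fact == pytest.approx(config.signal_baseline + config.signal_amplitude, abs=0.15)
    me3_at_fact = np.mean([tracks["h3k4me3"].value_at(r.chrom, r.position) for r in fact])
    assert me3_at_fact < at_fact - 0.5  # promoter-mark bumps absent at fact sites


def test_flat_track_when_amplitude_zero():
    config = cfg(signal_amplitude=0.0, signal_noise_sd=0.01)
    genes, _ = generate_genome(config)
    truth = plant_tss(genes, config)
    tracks = emit_signal_tracks(truth, config, genes=None)
    arr = tracks["h3k4me1"].values["chr1"]
    assert arr.mean() == pytest.approx(config.signal_baseline, abs=0.01)
    assert arr.std() < 0.05


def test_bundle_write_is_byte_identical_across_runs(tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_bundle(simulate(cfg(n_genes=30)), d1)
    write_bundle(simulate(cfg(n_genes=30)), d2)
    files1 = sorted(p.name for p in d1.iterdir())
    assert files1 == sorted(p.name for p in d2.iterdir())
    for name in files1:
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_truth_round_trip(tmp_path):
    bundle = simulate(cfg(n_genes=20))
    path = tmp_path / "truth.tsv"
    write_truth(bundle.truth, path)
    back = read_truth(path)
    assert back.records == bundle.truth.records


def test_score_recovery_degenerate_inputs():
    bundle = simulate(cfg(n_genes=10))
    report = score_recovery([], bundle.truth)
    assert report.overall_precision is None
    assert report.n_noise_clusters == 0
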