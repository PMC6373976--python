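"""Synthetic TSS-seq study generator with planted ground truth.

Emulates the data shape of a two-replicate, three-genotype 5'-tag
experiment (wild type plus two histone-chaperone mutants):

* a genome of non-overlapping, alternating-strand genes with exon/intron
  structure;
* a promoter TSS planted at every gene's 5' end, active in all genotypes
  (expected category: basal);
* an intragenic TSS planted in a fraction ``fact_fraction`` of genes,
  active only in the mutant genotypes and at a lower mean tag count than
  promoters (expected category: fact_specific);
* background noise as strictly sub-threshold singleton tags (one tag in
  one library), which the support rule must reject;
* smooth signal tracks: an H3K4me1-style track with Gaussian enrichment
  planted at the intragenic mutant-specific sites, an H3K4me3-style track
  with enrichment at promoters, and an MNase-style track elevated over
  gene bodies.

Tag counts are negative-binomial (mean mu, dispersion k; variance
mu + mu^2/k) with small geometric positional jitter, capped so each
planted site always collapses into a single <= 20 bp cluster.  All
randomness flows from one seed through spawned child generators, so each
emission stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .calling import DEFAULT_MAX_GAP, DEFAULT_MIN_LIBRARIES, DEFAULT_MIN_TAGS, TSSCluster
from .genome import GeneModel, GenomicInterval, write_gff3
from .trackio import (
    LibraryManifest,
    SignalTrack,
    TagLibrary,
    signal_track_to_bedgraph,
    write_bedgraph,
)

JITTER_CAP = 5  # max |positional jitter| in bases

TRUTH_KINDS = ("promoter", "fact_specific_exonic", "fact_specific_intronic", "noise")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults describe the reference condition used throughout the test
    suite: 200 genes, 2 replicates x 3 genotypes, promoter tag mean 50 and
    intragenic mutant-specific mean 10 (dispersion 10), 30% of genes
    carrying a mutant-specific intragenic TSS.
    """

    seed: int  # mandatory; all randomness derives from it
    n_chrom: int = 2
    chrom_length: int = 250_000
    n_genes: int = 200
    exon_count_range: tuple[int, int] = (1, 4)
    exon_length_range: tuple[int, int] = (150, 500)
    intron_length_range: tuple[int, int] = (60, 200)
    intergenic_gap_range: tuple[int, int] = (300, 1500)
    genotypes: dict[str, int] = field(
        default_factory=lambda: {"wild_type": 2, "spt16": 2, "ssrp1": 2}
    )
    wild_type: str = "wild_type"
    mu_promoter: float = 50.0
    mu_fact: float = 10.0
    dispersion: float = 10.0
    fact_fraction: float = 0.3
    fact_intronic_fraction: float = 0.1
    fact_both_mutants_prob: float = 0.8
    noise_rate_per_kb: float = 0.5
    supra_threshold_noise: bool = False  # "confusable noise" mode
    signal_baseline: float = 1.0
    signal_amplitude: float = 1.0
    signal_sigma: float = 75.0
    signal_noise_sd: float = 0.1
    jitter_p: float = 0.7
    max_gap: int = DEFAULT_MAX_GAP

    def __post_init__(self) -> None:
        if self.mu_fact >= self.mu_promoter:
            raise ValueError("mu_fact must be below mu_promoter (intragenic TSSs are weaker)")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.fact_fraction <= 1:
            raise ValueError("fact_fraction must be in [0, 1]")

    @property
    def mutants(self) -> list[str]:
        return [g for g in self.genotypes if g != self.wild_type]

    @property
    def min_planted_separation(self) -> int:
        # guarantees jittered tags from two planted sites never co-cluster
        return self.max_gap + 2 * JITTER_CAP + 1

    def chrom_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chrom)}


@dataclass
class TruthRecord:
    chrom: str
    position: int
    strand: str
    kind: str
    active_genotypes: tuple[str, ...]
    gene_id: Optional[str]
    expected_category: Optional[str]


@dataclass
class PlantedTruth:
    records: list[TruthRecord]

    def of_kind(self, *kinds: str) -> list[TruthRecord]:
        return [r for r in self.records if r.kind in kinds]

    @property
    def planted(self) -> list[TruthRecord]:
        return [r for r in self.records if r.kind != "noise"]


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_genome(config: SimulationConfig) -> tuple[list[GeneModel], dict[str, int]]:
    """Non-overlapping alternating-strand genes drawn from config ranges."""
    rng = _child_rngs(config.seed, 4)[0]
    lengths = config.chrom_lengths()
    chrom_names = list(lengths)
    genes: list[GeneModel] = []
    per_chrom = [config.n_genes // config.n_chrom] * config.n_chrom
    for i in range(config.n_genes % config.n_chrom):
        per_chrom[i] += 1
    gene_no = 0
    for chrom, n_here in zip(chrom_names, per_chrom):
        cursor = int(rng.integers(*config.intergenic_gap_range, endpoint=True))
        # leave headroom for upstream promoter/proximal windows
        cursor = max(cursor, 600)
        for _ in range(n_here):
            n_exons = int(rng.integers(*config.exon_count_range, endpoint=True))
            exon_lens = rng.integers(*config.exon_length_range, size=n_exons, endpoint=True)
            intron_lens = rng.integers(*config.intron_length_range, size=max(n_exons - 1, 0), endpoint=True)
            gene_len = int(exon_lens.sum() + intron_lens.sum())
            if cursor + gene_len > lengths[chrom] - 600:
                raise ValueError(
                    f"cannot pack {n_here} genes into {chrom} of length {lengths[chrom]}"
                )
            strand = "+" if gene_no % 2 == 0 else "-"
            exons = []
            pos = cursor
            for j in range(n_exons):
                exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[j]), strand))
                pos += int(exon_lens[j])
                if j < n_exons - 1:
                    pos += int(intron_lens[j])
            gene_no += 1
            genes.append(
                GeneModel(
                    gene_id=f"SYNG{gene_no:04d}",
                    gene_name=f"g{gene_no}",
                    span=GenomicInterval(chrom, cursor, pos, strand),
                    exons=exons,
                )
            )
            cursor = pos + int(rng.integers(*config.intergenic_gap_range, endpoint=True))
    return genes, lengths


def plant_tss(genes: Sequence[GeneModel], config: SimulationConfig) -> PlantedTruth:
    """Plant promoter, mutant-specific intragenic, and noise TSS positions."""
    rng = _child_rngs(config.seed, 4)[1]
    all_genotypes = tuple(config.genotypes)
    mutants = config.mutants
    min_sep = config.min_planted_separation
    records: list[TruthRecord] = []
    for gene in genes:
        g = gene.span.start if gene.span.strand == "+" else gene.span.end - 1
        records.append(
            TruthRecord(
                chrom=gene.span.chrom,
                position=g,
                strand=gene.span.strand,
                kind="promoter",
                active_genotypes=all_genotypes,
                gene_id=gene.gene_id,
                expected_category="basal",
            )
        )
    fact_genes = [gene for gene in genes if rng.random() < config.fact_fraction]
    for gene in fact_genes:
        g = gene.span.start if gene.span.strand == "+" else gene.span.end - 1
        want_intron = (
            len(gene.exons) > 1 and rng.random() < config.fact_intronic_fraction
        )
        if want_intron:
            pool = [
                p
                for a, b in zip(gene.exons, gene.exons[1:])
                for p in range(a.end, b.start)
            ]
            kind = "fact_specific_intronic"
        else:
            pool = [p for ex in gene.exons for p in range(ex.start, ex.end)]
            kind = "fact_specific_exonic"
        # keep clear of the promoter cluster and the promoter feature window
        eligible = [p for p in pool if abs(p - g) > max(min_sep, 120)]
        if not eligible:
            continue
        pos = int(rng.choice(eligible))
        if rng.random() < config.fact_both_mutants_prob:
            active = tuple(mutants)
        else:
            active = (mutants[int(rng.integers(len(mutants)))],)
        records.append(
            TruthRecord(
                chrom=gene.span.chrom,
                position=pos,
                strand=gene.span.strand,
                kind=kind,
                active_genotypes=active,
                gene_id=gene.gene_id,
                expected_category="fact_specific",
            )
        )
    lengths = config.chrom_lengths()
    total_kb = sum(lengths.values()) / 1000.0
    n_noise = int(rng.poisson(config.noise_rate_per_kb * total_kb))
    chroms = list(lengths)
    for _ in range(n_noise):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(lengths[chrom]))
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(
            TruthRecord(
                chrom=chrom,
                position=pos,
                strand=strand,
                kind="noise",
                active_genotypes=(),
                gene_id=None,
                expected_category=None,
            )
        )
    return PlantedTruth(records=records)


def _negbin(rng: np.random.Generator, mu: float, k: float) -> int:
    return int(rng.negative_binomial(k, k / (k + mu)))


def emit_libraries(
    truth: PlantedTruth, config: SimulationConfig
) -> list[TagLibrary]:
    """Per-library tag counts at planted sites, plus singleton noise tags."""
    rng = _child_rngs(config.seed, 4)[2]
    lengths = config.chrom_lengths()
    libraries: list[TagLibrary] = []
    for genotype, n_reps in config.genotypes.items():
        for rep in range(1, n_reps + 1):
            libraries.append(
                TagLibrary(library_id=f"{genotype}_rep{rep}", genotype=genotype, replicate=rep)
            )

    def place_tags(lib: TagLibrary, rec: TruthRecord, n_tags: int) -> None:
        if n_tags <= 0:
            return
        magnitudes = np.minimum(rng.geometric(config.jitter_p, size=n_tags) - 1, JITTER_CAP)
        signs = rng.choice([-1, 1], size=n_tags)
        length = lengths[rec.chrom]
        for m, s in zip(magnitudes, signs):
            pos = int(np.clip(rec.position + s * m, 0, length - 1))
            lib.add(rec.chrom, rec.strand, pos)

    for rec in truth.planted:
        mu = config.mu_promoter if rec.kind == "promoter" else config.mu_fact
        for lib in libraries:
            if lib.genotype in rec.active_genotypes:
                place_tags(lib, rec, _negbin(rng, mu, config.dispersion))

    noise_records = truth.of_kind("noise")
    for rec in noise_records:
        if config.supra_threshold_noise:
            genotype = list(config.genotypes)[int(rng.integers(len(config.genotypes)))]
            for lib in libraries:
                if lib.genotype == genotype:
                    lib.add(rec.chrom, rec.strand, rec.position, DEFAULT_MIN_TAGS)
        else:
            lib = libraries[int(rng.integers(len(libraries)))]
            lib.add(rec.chrom, rec.strand, rec.position, 1)
    return libraries


def emit_signal_tracks(
    truth: PlantedTruth,
    config: SimulationConfig,
    genes: Optional[Sequence[GeneModel]] = None,
) -> dict[str, SignalTrack]:
    """H3K4me1-, H3K4me3- and MNase-style tracks with planted structure."""
    rng = _child_rngs(config.seed, 4)[3]
    lengths = config.chrom_lengths()
    sigma = config.signal_sigma
    span = int(4 * sigma)
    offsets = np.arange(-span, span + 1)
    bump = np.exp(-(offsets**2) / (2 * sigma**2))

    def new_values() -> dict[str, np.ndarray]:
        return {
            chrom: np.full(length, config.signal_baseline, dtype=float)
            for chrom, length in lengths.items()
        }

    def add_bump(values: dict[str, np.ndarray], chrom: str, pos: int, amplitude: float) -> None:
        arr = values[chrom]
        lo, hi = max(pos - span, 0), min(pos + span + 1, len(arr))
        arr[lo:hi] += amplitude * bump[lo - (pos - span) : hi - (pos - span)]

    me1 = new_values()
    me3 = new_values()
    mnase = new_values()
    for rec in truth.planted:
        if rec.kind.startswith("fact_specific"):
            add_bump(me1, rec.chrom, rec.position, config.signal_amplitude)
        elif rec.kind == "promoter":
            add_bump(me3, rec.chrom, rec.position, config.signal_amplitude)
    if genes:
        for gene in genes:
            mnase[gene.span.chrom][gene.span.start : gene.span.end] += 0.5
    for values in (me1, me3, mnase):
        for chrom, arr in values.items():
            arr += rng.normal(0.0, config.signal_noise_sd, size=arr.size)
            np.maximum(arr, 0.0, out=arr)
    return {
        "h3k4me1": SignalTrack(assay="h3k4me1", values=me1),
        "h3k4me3": SignalTrack(assay="h3k4me3", values=me3),
        "mnase": SignalTrack(assay="mnase", values=mnase),
    }


@dataclass
class RecoveryReport:
    recall_by_kind: dict[str, float]
    overall_precision: Optional[float]
    category_agreement: Optional[float]
    n_noise_clusters: int
    n_supra_threshold: dict[str, int]

    def to_dict(self) -> dict:
        return asdict(self)


def score_recovery(
    clusters: Sequence[TSSCluster],
    truth: PlantedTruth,
    max_dist: int = DEFAULT_MAX_GAP,
    libraries: Optional[Sequence[TagLibrary]] = None,
    min_tags: int = DEFAULT_MIN_TAGS,
    min_libraries: int = DEFAULT_MIN_LIBRARIES,
) -> RecoveryReport:
    """Recall/precision of called clusters against the planted truth.

    A planted record is *recovered* when a called cluster of its expected
    category lies within ``max_dist`` bases.  When ``libraries`` are
    given, recall is restricted to supra-threshold records — those whose
    emitted counts actually pass the support rule for an active genotype —
    since sites the negative-binomial draw left under-supported are
    invisible to any caller.  Precision is the fraction of called
    clusters attributable to a planted site; the remainder are counted as
    noise clusters.
    """
    from .calling import find_candidates  # local import avoids cycle at module load

    def near(cluster: TSSCluster, rec: TruthRecord) -> bool:
        iv = cluster.interval
        if iv.chrom != rec.chrom or iv.strand != rec.strand:
            return False
        return iv.start - max_dist <= rec.position < iv.end + max_dist

    supra: dict[int, bool] = {}
    if libraries is not None:
        candidates = find_candidates(libraries, min_tags=min_tags, min_libraries=min_libraries)
        for i, rec in enumerate(truth.planted):
            ok = False
            for genotype in rec.active_genotypes:
                posset = candidates.positions.get(genotype, {}).get((rec.chrom, rec.strand), set())
                if any(abs(p - rec.position) <= max_dist for p in posset):
                    ok = True
                    break
            supra[i] = ok
    else:
        supra = {i: True for i in range(len(truth.planted))}

    recall_by_kind: dict[str, float] = {}
    n_supra: dict[str, int] = {}
    matched_categories: list[bool] = []
    planted = truth.planted
    for kind in ("promoter", "fact_specific_exonic", "fact_specific_intronic"):
        idx = [i for i, r in enumerate(planted) if r.kind == kind and supra[i]]
        n_supra[kind] = len(idx)
        if not idx:
            continue
        hits = 0
        for i in idx:
            rec = planted[i]
            nearby = [c for c in clusters if near(c, rec)]
            if any(c.category == rec.expected_category for c in nearby):
                hits += 1
            if nearby:
                matched_categories.append(
                    any(c.category == rec.expected_category for c in nearby)
                )
        recall_by_kind[kind] = hits / len(idx)

    if clusters:
        attributable = sum(
            1 for c in clusters if any(near(c, r) for r in planted)
        )
        precision = attributable / len(clusters)
        n_noise_clusters = len(clusters) - attributable
    else:
        precision = None
        n_noise_clusters = 0
    agreement = (
        sum(matched_categories) / len(matched_categories) if matched_categories else None
    )
    return RecoveryReport(
        recall_by_kind=recall_by_kind,
        overall_precision=precision,
        category_agreement=agreement,
        n_noise_clusters=n_noise_clusters,
        n_supra_threshold=n_supra,
    )


# ---------------------------------------------------------------------------
# On-disk bundle in the exact formats the pipeline consumes
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["chrom", "position", "strand", "kind", "active_genotypes", "gene_id", "expected_category"]


def write_truth(truth: PlantedTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for r in truth.records:
            fh.write(
                f"{r.chrom}\t{r.position}\t{r.strand}\t{r.kind}\t"
                f"{','.join(r.active_genotypes)}\t{r.gene_id or '.'}\t"
                f"{r.expected_category or '.'}\n"
            )


def read_truth(path) -> PlantedTruth:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRUTH_COLUMNS:
            raise ValueError(f"{path}: unexpected truth header {header}")
        for line in fh:
            chrom, pos, strand, kind, active, gene_id, cat = line.rstrip("\n").split("\t")
            records.append(
                TruthRecord(
                    chrom=chrom,
                    position=int(pos),
                    strand=strand,
                    kind=kind,
                    active_genotypes=tuple(a for a in active.split(",") if a),
                    gene_id=None if gene_id == "." else gene_id,
                    expected_category=None if cat == "." else cat,
                )
            )
    return PlantedTruth(records=records)


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    genes: list[GeneModel]
    chrom_lengths: dict[str, int]
    truth: PlantedTruth
    libraries: list[TagLibrary]
    tracks: dict[str, SignalTrack]


def simulate(config: SimulationConfig) -> SimulatedBundle:
    """Run every generation stage in memory."""
    genes, lengths = generate_genome(config)
    truth = plant_tss(genes, config)
    libraries = emit_libraries(truth, config)
    tracks = emit_signal_tracks(truth, config, genes=genes)
    return SimulatedBundle(
        config=config,
        genes=genes,
        chrom_lengths=lengths,
        truth=truth,
        libraries=libraries,
        tracks=tracks,
    )


def write_bundle(bundle: SimulatedBundle, outdir) -> dict[str, Path]:
    """Write the bundle as GFF3 + manifest/bedGraphs + truth + signal tracks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.gff3"
    write_gff3(bundle.genes, paths["genome"], chrom_lengths=bundle.chrom_lengths)
    rows = []
    for lib in bundle.libraries:
        plus = outdir / f"{lib.library_id}.plus.bedgraph"
        minus = outdir / f"{lib.library_id}.minus.bedgraph"
        for strand, path in (("+", plus), ("-", minus)):
            sparse: dict[str, dict[int, float]] = {}
            for (chrom, s), per_base in lib.counts.items():
                if s == strand:
                    sparse.setdefault(chrom, {}).update(
                        {p: float(v) for p, v in per_base.items()}
                    )
            write_bedgraph(sparse, path)
        rows.append(
            {
                "library_id": lib.library_id,
                "genotype": lib.genotype,
                "replicate": str(lib.replicate),
                "plus_path": plus.name,
                "minus_path": minus.name,
            }
        )
    paths["manifest"] = outdir / "manifest.tsv"
    LibraryManifest(rows=rows).write(paths["manifest"])
    paths["truth"] = outdir / "truth.tsv"
    write_truth(bundle.truth, paths["truth"])
    for assay, track in bundle.tracks.items():
        paths[assay] = outdir / f"{assay}.bedgraph"
        signal_track_to_bedgraph(track, paths[assay])
    return paths
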