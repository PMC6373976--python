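"""End-to-end orchestration: one config in, one reproducible output bundle out.

Stage order: load genome and tag libraries -> call TSS clusters ->
annotate against derived features -> classify by genotype contrast ->
quantify expression -> (optionally) CAGE overlap and signal aggregation.
Every output is a pure function of (inputs, config, seed); the run
manifest records the parameters actually used plus input checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import aggregate as agg
from .annotate import annotate_clusters
from .calling import (
    DEFAULT_MAX_GAP,
    DEFAULT_MIN_LIBRARIES,
    DEFAULT_MIN_TAGS,
    TSSCluster,
    call_tss,
)
from .classify import (
    annotation_breakdown,
    cage_overlap_fraction,
    classify_clusters,
    mutant_venn,
    summarize,
)
from .expression import quantify, replicate_correlation
from .genome import build_feature_set, read_gff3
from .trackio import (
    LibraryManifest,
    load_libraries,
    read_bed_points,
    read_bedgraph,
    signal_track_from_bedgraph,
)

logger = logging.getLogger(__name__)

CLUSTER_COLUMNS = [
    "Chr", "Start", "End", "Strand", "Score", "Summit",
    "Annotation", "Category", "Gene_ID", "Gene_name",
]


@dataclass
class PipelineConfig:
    manifest: Path
    genome: Path
    outdir: Path
    cage: Optional[Path] = None
    tracks: dict[str, Path] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    min_tags: int = DEFAULT_MIN_TAGS
    min_libraries: int = DEFAULT_MIN_LIBRARIES
    max_gap: int = DEFAULT_MAX_GAP
    pseudocount: float = 1.0
    box_width: int = 20
    metagene_width: int = 400
    seed: int = 0
    wild_type: str = "wild_type"
    mutants: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = Path(path).parent
        for key in ("manifest", "genome", "outdir", "cage"):
            if raw.get(key):
                raw[key] = base / raw[key]
        raw["tracks"] = {k: base / v for k, v in (raw.get("tracks") or {}).items()}
        return cls(**raw)


def write_clusters_tsv(clusters, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CLUSTER_COLUMNS) + "\n")
        for c in clusters:
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t"
                f"{c.interval.strand}\t{c.score:.6g}\t{c.summit}\t"
                f"{c.annotation or '.'}\t{c.category or '.'}\t"
                f"{c.gene_id or '.'}\t{c.gene_name or '.'}\n"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Format and consistency checks; returns a list of failure messages."""
    failures: list[str] = []
    if not Path(config.genome).exists():
        failures.append(f"genome file missing: {config.genome}")
        genes = []
    else:
        try:
            genes = read_gff3(config.genome)
        except ValueError as exc:
            failures.append(f"genome: {exc}")
            genes = []
    genome_chroms = {g.span.chrom for g in genes}
    if not Path(config.manifest).exists():
        failures.append(f"manifest missing: {config.manifest}")
        return failures
    try:
        manifest = LibraryManifest.read(config.manifest)
    except ValueError as exc:
        failures.append(str(exc))
        return failures
    base = Path(config.manifest).parent
    genotype_reps: dict[str, int] = {}
    track_chroms: set[str] = set()
    for row in manifest.rows:
        genotype_reps[row["genotype"]] = genotype_reps.get(row["genotype"], 0) + 1
        for key in ("plus_path", "minus_path"):
            p = Path(row[key])
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                failures.append(f"{row['library_id']}: missing file {p}")
                continue
            try:
                track_chroms.update(read_bedgraph(p).keys())
            except ValueError as exc:
                failures.append(str(exc))
    for genotype, n in genotype_reps.items():
        if n < config.min_libraries:
            failures.append(
                f"genotype {genotype!r} has {n} libraries; support rule needs {config.min_libraries}"
            )
    if config.wild_type not in genotype_reps:
        failures.append(f"wild-type genotype {config.wild_type!r} absent from manifest")
    orphan = track_chroms - genome_chroms
    if genome_chroms and orphan:
        failures.append(f"chromosomes in tag tracks but not in genome: {sorted(orphan)}")
    return failures


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the output bundle under config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genes = read_gff3(config.genome)
    features = build_feature_set(genes)
    manifest = LibraryManifest.read(config.manifest)
    libraries = load_libraries(manifest, base_dir=Path(config.manifest).parent)
    genotypes = sorted({lib.genotype for lib in libraries})
    if config.wild_type not in genotypes:
        raise ValueError(f"wild-type genotype {config.wild_type!r} not in manifest")
    mutants = config.mutants or [g for g in genotypes if g != config.wild_type]
    missing = [m for m in mutants if m not in genotypes]
    if missing:
        raise ValueError(f"mutant genotypes absent from manifest: {missing}")

    clusters = call_tss(
        libraries,
        min_tags=config.min_tags,
        min_libraries=config.min_libraries,
        max_gap=config.max_gap,
    )
    annotate_clusters(clusters, features)
    classify_clusters(clusters, wild_type_genotype=config.wild_type, mutant_genotypes=mutants)
    write_clusters_tsv(clusters, outdir / "clusters.tsv")

    summary: dict = {"n_clusters": len(clusters)}
    if clusters:
        summary["categories"] = summarize(clusters).to_dict()
        summary["annotation_all"] = annotation_breakdown(clusters).to_dict()
        for which in ("basal", "fact_specific"):
            if any(c.category == which for c in clusters):
                summary[f"annotation_{which}"] = annotation_breakdown(clusters, which).to_dict()
        if len(mutants) == 2:
            summary["mutant_venn"] = mutant_venn(clusters, mutants)
        if config.cage:
            cage = read_bed_points(config.cage)
            summary["cage_overlap"] = cage_overlap_fraction(clusters, cage)

    expr = quantify(clusters, libraries, pseudocount=config.pseudocount) if clusters else None
    if expr is not None:
        expr.log2.to_csv(outdir / "expression_log2cpm.tsv", sep="\t")
        correlations = {}
        for genotype in genotypes:
            libs = [l for l in libraries if l.genotype == genotype]
            if len(libs) >= 2:
                correlations[genotype] = {
                    f"{a}|{b}": r
                    for (a, b), r in replicate_correlation(expr, libraries, genotype).items()
                }
        summary["replicate_correlation"] = correlations

    if config.tracks and clusters:
        summary["aggregation"] = _aggregate_tracks(config, clusters, features)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)

    run_manifest = {
        "parameters": {
            k: str(v) if isinstance(v, Path) else v
            for k, v in dataclasses.asdict(config).items()
            if k != "tracks"
        },
        "tracks": {k: str(v) for k, v in config.tracks.items()},
        "seed": config.seed,
        "input_checksums": {
            "genome": _sha256(Path(config.genome)),
            "manifest": _sha256(Path(config.manifest)),
        },
        "n_clusters": len(clusters),
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2)
    return summary


def _aggregate_tracks(config: PipelineConfig, clusters, features) -> dict:
    """Boxplot/metagene statistics per signal track over the TSS anchor sets."""
    chrom_lengths = dict(config.chrom_lengths)
    if not chrom_lengths:
        for gene in features.genes:
            chrom_lengths[gene.span.chrom] = max(
                chrom_lengths.get(gene.span.chrom, 0), gene.span.end + 1000
            )

    def anchors_for(predicate, label) -> agg.AnchorSet:
        return agg.AnchorSet(
            label=label,
            anchors=[
                (c.interval.chrom, c.summit, c.interval.strand)
                for c in clusters
                if predicate(c)
            ],
        )

    sets = {
        "promoter_TSS": anchors_for(lambda c: c.annotation == "promoter", "promoter_TSS"),
        "basal_exonic_TSS": anchors_for(
            lambda c: c.annotation == "exon" and c.category == "basal", "basal_exonic_TSS"
        ),
        "fact_specific_exonic_TSS": anchors_for(
            lambda c: c.annotation == "exon" and c.category == "fact_specific",
            "fact_specific_exonic_TSS",
        ),
    }
    genes_by_id = {g.gene_id: g for g in features.genes}
    for which, label in (("basal", "control_basal"), ("fact_specific", "control_fact")):
        gene_ids = sorted(
            {
                c.gene_id
                for c in clusters
                if c.category == which and c.annotation == "exon" and c.gene_id
            }
        )
        sets[label] = agg.sample_control_positions(
            [genes_by_id[g] for g in gene_ids], seed=config.seed, label=label
        )

    out: dict = {}
    for assay, path in config.tracks.items():
        track = signal_track_from_bedgraph(path, assay, chrom_lengths)
        per_assay: dict = {}
        for label, anchor_set in sets.items():
            if len(anchor_set) == 0:
                continue
            medians = agg.window_medians(track, anchor_set, config.box_width)
            per_assay[label] = dataclasses.asdict(agg.boxplot_stats(medians))
        pairs = [
            ("fact_specific_exonic_TSS", "control_fact"),
            ("basal_exonic_TSS", "control_basal"),
            ("fact_specific_exonic_TSS", "basal_exonic_TSS"),
        ]
        tests = {}
        for a, b in pairs:
            if len(sets[a]) and len(sets[b]):
                stat, p = agg.compare_anchor_sets(track, sets[a], sets[b], config.box_width)
                tests[f"{a}_vs_{b}"] = {"statistic": stat, "p_value": p}
        per_assay["wilcoxon"] = tests
        out[assay] = per_assay
    return out
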