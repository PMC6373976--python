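"""Gene models and derived annotation features.

A genome here is a set of single-isoform gene models (span, exons, optional
UTRs) on named chromosomes. From each gene we derive the feature regions
used to annotate TSS clusters:

* ``promoter`` — a symmetric 201-base window centred on the gene's 5' end
  (the 5'-end base plus 100 bases on each side);
* ``proximal`` — the 400-base window immediately upstream of the promoter
  window, in transcription orientation;
* ``exon`` / ``intron`` — the gene's exons and the gaps between them;
* ``fiveUTR`` / ``threeUTR`` — optional UTR sub-features.

All coordinates are 0-based half-open internally; GFF input (1-based,
inclusive) is converted on read.  Windows running off a chromosome edge are
clipped, never rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: genic feature categories, in no particular order
FEATURE_CATEGORIES = ("promoter", "proximal", "fiveUTR", "exon", "intron", "threeUTR")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded or unstranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """One gene: stranded span, ordered disjoint exons, optional UTRs."""

    gene_id: str
    span: GenomicInterval
    exons: list[GenomicInterval]
    gene_name: str = ""
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.span.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: span must be stranded")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: exons must be non-empty")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.span.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.span.start or ex.end > self.span.end:
                raise ValueError(f"gene {self.gene_id}: exon outside span")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons unsorted or overlapping")
            prev_end = ex.end
        exonic = _interval_base_set(self.exons)
        for utr in self.utr5 + self.utr3:
            if not set(range(utr.start, utr.end)) <= exonic:
                raise ValueError(f"gene {self.gene_id}: UTR outside exon union")


def _interval_base_set(intervals: Iterable[GenomicInterval]) -> set[int]:
    bases: set[int] = set()
    for iv in intervals:
        bases.update(range(iv.start, iv.end))
    return bases


def five_prime_end(gene: GeneModel) -> int:
    """Base offset of the gene's 5' end (start on '+', last base on '-')."""
    if gene.span.strand == "+":
        return gene.span.start
    return gene.span.end - 1


def derive_promoter(gene: GeneModel, flank: int = 100) -> GenomicInterval:
    """Symmetric (2*flank + 1)-base promoter window around the 5'-end base.

    Strand-independent by construction; clipped at the chromosome start.
    """
    g = five_prime_end(gene)
    start = max(0, g - flank)
    return GenomicInterval(gene.span.chrom, start, g + flank + 1, gene.span.strand)


def derive_proximal(
    gene: GeneModel, upstream: int = 500, promoter_flank: int = 100
) -> Optional[GenomicInterval]:
    """The window strictly upstream of the promoter window.

    On '+': [g-upstream, g-promoter_flank); mirrored on '-'. Clipped at the
    chromosome start; ``None`` if clipping empties the window.
    """
    g = five_prime_end(gene)
    if gene.span.strand == "+":
        start, end = g - upstream, g - promoter_flank
    else:
        start, end = g + promoter_flank + 1, g + upstream + 1
    start = max(0, start)
    if start >= end:
        return None
    return GenomicInterval(gene.span.chrom, start, end, gene.span.strand)


def derive_introns(gene: GeneModel) -> list[GenomicInterval]:
    """Gaps between consecutive exons; empty for single-exon genes."""
    introns = []
    for a, b in zip(gene.exons, gene.exons[1:]):
        if b.start > a.end:
            introns.append(GenomicInterval(gene.span.chrom, a.end, b.start, gene.span.strand))
    return introns


@dataclass
class FeatureSet:
    """Per-category feature intervals plus per-strand gene spans.

    Categories may overlap one another; resolving a single annotation per
    cluster is the annotator's job, not the feature set's.
    """

    features: dict[str, list[GenomicInterval]]
    gene_spans: dict[str, list[GenomicInterval]]  # keyed by strand
    genes: list[GeneModel]

    def category_intervals(self, category: str) -> list[GenomicInterval]:
        return self.features.get(category, [])


def build_feature_set(genes: Sequence[GeneModel]) -> FeatureSet:
    """Derive all annotation features from a collection of gene models."""
    features: dict[str, list[GenomicInterval]] = {c: [] for c in FEATURE_CATEGORIES}
    spans: dict[str, list[GenomicInterval]] = {"+": [], "-": []}
    for gene in genes:
        gene.validate()
        features["promoter"].append(derive_promoter(gene))
        prox = derive_proximal(gene)
        if prox is not None:
            features["proximal"].append(prox)
        features["exon"].extend(gene.exons)
        features["intron"].extend(derive_introns(gene))
        features["fiveUTR"].extend(gene.utr5)
        features["threeUTR"].extend(gene.utr3)
        spans[gene.span.strand].append(gene.span)
    return FeatureSet(features=features, gene_spans=spans, genes=list(genes))


def base_composition(genes: Sequence[GeneModel]) -> dict[str, float]:
    """Total exonic and intronic bases (per-chromosome unions, deduplicated).

    Returns ``{"exon": ..., "intron": ..., "ratio": exon/intron}``; the ratio
    is ``inf`` when there are no intronic bases.
    """
    exon_by_chrom: dict[str, set[int]] = {}
    intron_by_chrom: dict[str, set[int]] = {}
    for gene in genes:
        exon_by_chrom.setdefault(gene.span.chrom, set()).update(
            _interval_base_set(gene.exons)
        )
        intron_by_chrom.setdefault(gene.span.chrom, set()).update(
            _interval_base_set(derive_introns(gene))
        )
    n_exon = sum(len(s) for s in exon_by_chrom.values())
    n_intron = sum(len(s) for s in intron_by_chrom.values())
    ratio = n_exon / n_intron if n_intron else float("inf")
    return {"exon": float(n_exon), "intron": float(n_intron), "ratio": ratio}


# ---------------------------------------------------------------------------
# GFF3-dialect reader
# ---------------------------------------------------------------------------

_KNOWN_TYPES = {"gene", "exon", "five_prime_UTR", "three_prime_UTR"}


def _parse_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path) -> list[GeneModel]:
    """Read gene models from a GFF3-dialect file.

    Recognized feature types: ``gene``, ``exon``, ``five_prime_UTR``,
    ``three_prime_UTR``; sub-features attach to their gene via the
    ``Parent`` attribute (or ``ID`` prefix match).  Unknown types are
    ignored with a logged count.  GFF coordinates (1-based inclusive) are
    converted to 0-based half-open.
    """
    genes: dict[str, dict] = {}
    order: list[str] = []
    n_ignored = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, ftype, start1, end1, _score, strand, _frame, attr_text = fields
            if ftype not in _KNOWN_TYPES:
                n_ignored += 1
                continue
            try:
                start = int(start1) - 1
                end = int(end1)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            attrs = _parse_attributes(attr_text)
            if ftype == "gene":
                gid = attrs.get("ID", "")
                if not gid:
                    raise ValueError(f"{path}:{lineno}: gene without ID")
                genes[gid] = {
                    "span": GenomicInterval(chrom, start, end, strand),
                    "name": attrs.get("Name", ""),
                    "exons": [],
                    "utr5": [],
                    "utr3": [],
                }
                order.append(gid)
            else:
                parent = attrs.get("Parent") or attrs.get("ID", "").rsplit(".", 1)[0]
                if parent not in genes:
                    raise ValueError(f"{path}:{lineno}: {ftype} with unknown Parent {parent!r}")
                iv = GenomicInterval(chrom, start, end, strand)
                key = {"exon": "exons", "five_prime_UTR": "utr5", "three_prime_UTR": "utr3"}[ftype]
                genes[parent][key].append(iv)
    if n_ignored:
        logger.info("read_gff3: ignored %d records of unknown feature types", n_ignored)
    models = []
    for gid in order:
        rec = genes[gid]
        models.append(
            GeneModel(
                gene_id=gid,
                gene_name=rec["name"],
                span=rec["span"],
                exons=sorted(rec["exons"], key=lambda iv: iv.start),
                utr5=sorted(rec["utr5"], key=lambda iv: iv.start),
                utr3=sorted(rec["utr3"], key=lambda iv: iv.start),
            )
        )
    return models


def write_gff3(genes: Sequence[GeneModel], path, chrom_lengths: Optional[dict] = None) -> None:
    """Write gene models in the same GFF3 dialect ``read_gff3`` accepts."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if chrom_lengths:
            for chrom, length in sorted(chrom_lengths.items()):
                fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for gene in genes:
            s = gene.span
            attrs = f"ID={gene.gene_id}"
            if gene.gene_name:
                attrs += f";Name={gene.gene_name}"
            fh.write(
                f"{s.chrom}\ttsscall\tgene\t{s.start + 1}\t{s.end}\t.\t{s.strand}\t.\t{attrs}\n"
            )
            for i, ex in enumerate(gene.exons, 1):
                fh.write(
                    f"{ex.chrom}\ttsscall\texon\t{ex.start + 1}\t{ex.end}\t.\t{s.strand}\t.\t"
                    f"ID={gene.gene_id}.exon{i};Parent={gene.gene_id}\n"
                )
            for label, utrs in (("five_prime_UTR", gene.utr5), ("three_prime_UTR", gene.utr3)):
                for i, u in enumerate(utrs, 1):
                    fh.write(
                        f"{u.chrom}\ttsscall\t{label}\t{u.start + 1}\t{u.end}\t.\t{s.strand}\t.\t"
                        f"ID={gene.gene_id}.{label}{i};Parent={gene.gene_id}\n"
                    )
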