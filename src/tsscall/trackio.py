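"""Track and interval I/O: bedGraph, BED points, library manifests.

The pipeline's exchange dialect for coverage is 4-column bedGraph
(chrom, start, end, value; 0-based half-open), the native output of
``bedtools genomecov -bg``.  5'-tag libraries are a pair of stranded
bedGraph files per library with integer per-base tag counts; chromatin
signal tracks are unstranded real-valued bedGraphs.  Sparse contract
throughout: an absent base carries value 0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np


class BedGraphError(ValueError):
    """Malformed bedGraph/BED input, carrying the offending line number."""


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path) -> dict[str, dict[int, float]]:
    """Read a bedGraph file into ``{chrom: {base: value}}``.

    Interval records are expanded to per-base values.  Overlapping records
    are an error; ``track``/``browser`` header lines are skipped.
    """
    values: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise BedGraphError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise BedGraphError(f"{path}:{lineno}: non-numeric field") from exc
            if start < 0 or end <= start:
                raise BedGraphError(f"{path}:{lineno}: bad interval [{start}, {end})")
            per_base = values.setdefault(chrom, {})
            for pos in range(start, end):
                if pos in per_base:
                    raise BedGraphError(f"{path}:{lineno}: overlapping record at {chrom}:{pos}")
                per_base[pos] = value
    return values


def write_bedgraph(values: dict[str, dict[int, float]], path) -> None:
    """Write ``{chrom: {base: value}}`` as canonical bedGraph.

    Maximal runs of adjacent equal values become single records; output is
    sorted by chrom then start; zero values are omitted (sparse contract).
    """
    with open(path, "w") as fh:
        for chrom in sorted(values):
            per_base = values[chrom]
            positions = sorted(p for p, v in per_base.items() if v != 0)
            i = 0
            while i < len(positions):
                start = positions[i]
                value = per_base[start]
                j = i
                while (
                    j + 1 < len(positions)
                    and positions[j + 1] == positions[j] + 1
                    and per_base[positions[j + 1]] == value
                ):
                    j += 1
                val_text = f"{int(value)}" if value == int(value) else repr(value)
                fh.write(f"{chrom}\t{start}\t{positions[j] + 1}\t{val_text}\n")
                i = j + 1


def read_bed_points(path) -> list[tuple[str, int, str]]:
    """Read BED records as points ``(chrom, position, strand)``, sorted.

    A 1-base record's point is its start; a longer interval's point is its
    floor midpoint.  Strand is taken from column 6 when present, else '.'.
    """
    points = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedGraphError(f"{path}:{lineno}: expected >=3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedGraphError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if start < 0 or end <= start:
                raise BedGraphError(f"{path}:{lineno}: bad interval [{start}, {end})")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            pos = start if end - start == 1 else (start + end) // 2
            points.append((chrom, pos, strand))
    return sorted(points)


def write_bed_points(points: Iterable[tuple[str, int, str]], path) -> None:
    with open(path, "w") as fh:
        for chrom, pos, strand in points:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t.\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# Tag libraries and manifests
# ---------------------------------------------------------------------------

@dataclass
class TagLibrary:
    """One sequencing library's stranded per-base 5'-tag counts."""

    library_id: str
    genotype: str
    replicate: int
    counts: dict[tuple[str, str], dict[int, int]] = field(default_factory=dict)

    def count_at(self, chrom: str, strand: str, pos: int) -> int:
        return self.counts.get((chrom, strand), {}).get(pos, 0)

    def add(self, chrom: str, strand: str, pos: int, n: int = 1) -> None:
        per_base = self.counts.setdefault((chrom, strand), {})
        per_base[pos] = per_base.get(pos, 0) + n

    def total_tags(self) -> int:
        return sum(sum(d.values()) for d in self.counts.values())


@dataclass
class SignalTrack:
    """Unstranded real-valued per-base coverage for one assay.

    Stored dense per chromosome; positions outside the stored arrays read
    as 0 (the bedGraph sparsity contract).
    """

    assay: str
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Values over [start, end), zero-filled outside the chromosome."""
        out = np.zeros(end - start, dtype=float)
        arr = self.values.get(chrom)
        if arr is None:
            return out
        lo, hi = max(start, 0), min(end, len(arr))
        if lo < hi:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def value_at(self, chrom: str, pos: int) -> float:
        arr = self.values.get(chrom)
        if arr is None or not (0 <= pos < len(arr)):
            return 0.0
        return float(arr[pos])


def signal_track_from_bedgraph(path, assay: str, chrom_lengths: dict[str, int]) -> SignalTrack:
    sparse = read_bedgraph(path)
    values = {chrom: np.zeros(length, dtype=float) for chrom, length in chrom_lengths.items()}
    for chrom, per_base in sparse.items():
        if chrom not in values:
            raise BedGraphError(f"{path}: unknown chromosome {chrom!r}")
        arr = values[chrom]
        for pos, val in per_base.items():
            if pos >= len(arr):
                raise BedGraphError(f"{path}: position {pos} beyond {chrom} length {len(arr)}")
            arr[pos] = val
    return SignalTrack(assay=assay, values=values)


def signal_track_to_bedgraph(track: SignalTrack, path) -> None:
    sparse = {
        chrom: {int(i): float(v) for i, v in enumerate(arr) if v != 0}
        for chrom, arr in track.values.items()
    }
    write_bedgraph(sparse, path)


MANIFEST_COLUMNS = ["library_id", "genotype", "replicate", "plus_path", "minus_path"]


@dataclass
class LibraryManifest:
    """Rows of (library_id, genotype, replicate, plus/minus bedGraph paths)."""

    rows: list[dict]

    @classmethod
    def read(cls, path) -> "LibraryManifest":
        with open(path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or [])
            if missing:
                raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
            rows = [dict(row) for row in reader]
        ids = [r["library_id"] for r in rows]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{path}: duplicate library_id in manifest")
        return cls(rows=rows)

    def write(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS, delimiter="\t")
            writer.writeheader()
            for row in self.rows:
                writer.writerow({k: row[k] for k in MANIFEST_COLUMNS})


def load_libraries(manifest: LibraryManifest, base_dir: Optional[Path] = None) -> list[TagLibrary]:
    """Load one TagLibrary per manifest row; tag values must be integers."""
    base = Path(base_dir) if base_dir else Path(".")
    libraries = []
    for row in manifest.rows:
        lib = TagLibrary(
            library_id=row["library_id"],
            genotype=row["genotype"],
            replicate=int(row["replicate"]),
        )
        for strand, key in (("+", "plus_path"), ("-", "minus_path")):
            path = Path(row[key])
            if not path.is_absolute():
                path = base / path
            for chrom, per_base in read_bedgraph(path).items():
                store = lib.counts.setdefault((chrom, strand), {})
                for pos, val in per_base.items():
                    if val != int(val):
                        raise ValueError(
                            f"{path}: non-integer tag count {val} at {chrom}:{pos}"
                        )
                    store[pos] = store.get(pos, 0) + int(val)
        libraries.append(lib)
    return libraries


def group_by_genotype(libraries: Iterable[TagLibrary]) -> dict[str, list[TagLibrary]]:
    groups: dict[str, list[TagLibrary]] = {}
    for lib in libraries:
        groups.setdefault(lib.genotype, []).append(lib)
    return groups
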