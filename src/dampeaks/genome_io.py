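"""Input/output of genomic file formats and the core data containers.

Everything downstream operates on two light-weight containers built here:
:class:`Genome` (ordered chromosome names and lengths, optionally the
positions of the 4-bp palindromic motif GATC recognised by DpnI) and
:class:`ReadSet` (per-chromosome sorted read anchor positions).

Coordinates are 0-based half-open throughout, matching the BED family of
formats this module reads and writes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np

__all__ = [
    "Genome",
    "ReadSet",
    "GenomeFormatError",
    "load_chrom_sizes",
    "find_gatc_sites",
    "gatc_distances",
    "load_reads",
    "write_bedgraph",
    "write_bed",
    "read_bed_intervals",
]

GATC = "GATC"
Anchor = Literal["five_prime", "midpoint"]


class GenomeFormatError(ValueError):
    """Raised for malformed genomic input files."""


@dataclass
class Genome:
    """Ordered chromosomes with lengths, plus optional GATC site index.

    Parameters
    ----------
    chroms
        Ordered ``(name, length)`` pairs; names unique, lengths positive.
    gatc_sites
        Optional map chromosome -> strictly increasing array of 0-based
        GATC start positions (each within ``[0, length - 4]``).
    """

    chroms: list[tuple[str, int]]
    gatc_sites: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise GenomeFormatError("duplicate chromosome names")
        for name, length in self.chroms:
            if length <= 0:
                raise GenomeFormatError(f"non-positive length for {name!r}")
        if self.gatc_sites is not None:
            lengths = dict(self.chroms)
            for name, sites in self.gatc_sites.items():
                sites = np.asarray(sites, dtype=np.int64)
                self.gatc_sites[name] = sites
                if sites.size and (
                    sites[0] < 0
                    or sites[-1] > lengths[name] - 4
                    or np.any(np.diff(sites) <= 0)
                ):
                    raise GenomeFormatError(
                        f"invalid GATC sites for {name!r}: must be strictly "
                        f"increasing within [0, length-4]"
                    )

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chroms]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chroms)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths


@dataclass
class ReadSet:
    """Per-chromosome sorted read anchor positions.

    ``total_mapped`` counts every ingested record and is the denominator
    for reads-per-million scaling; it may exceed the sum of stored
    positions only if positions were dropped explicitly (never here).
    """

    positions: dict[str, np.ndarray]
    total_mapped: int
    label: str = ""

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            self.positions[chrom] = pos
        n = sum(p.size for p in self.positions.values())
        if self.total_mapped < n:
            raise ValueError(
                f"total_mapped ({self.total_mapped}) < stored positions ({n})"
            )

    @property
    def n_positions(self) -> int:
        return sum(p.size for p in self.positions.values())


def load_chrom_sizes(path: str | Path) -> Genome:
    """Parse a two-column whitespace-delimited ``chrom.sizes`` file."""
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise GenomeFormatError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            name, length_s = fields
            try:
                length = int(length_s)
            except ValueError:
                raise GenomeFormatError(
                    f"{path}: line {lineno}: non-integer length {length_s!r}"
                ) from None
            if length <= 0:
                raise GenomeFormatError(
                    f"{path}: line {lineno}: non-positive length {length}"
                )
            if name in seen:
                raise GenomeFormatError(
                    f"{path}: line {lineno}: duplicate chromosome {name!r}"
                )
            seen.add(name)
            chroms.append((name, length))
    if not chroms:
        raise GenomeFormatError(f"{path}: no chromosomes")
    return Genome(chroms=chroms)


def _scan_gatc(seq: str) -> np.ndarray:
    # GATC is its own reverse complement, so a single-strand scan suffices,
    # and a 4-bp motif cannot overlap itself.
    return np.array(
        [m.start() for m in re.finditer(GATC, seq.upper())], dtype=np.int64
    )


def find_gatc_sites(fasta: str | Path, genome: Genome) -> Genome:
    """Locate all GATC occurrences in a FASTA, case-insensitively.

    Sequence names must be a subset of the genome's chromosomes and
    lengths must agree exactly.
    """
    from pyfaidx import Fasta

    lengths = genome.lengths
    sites: dict[str, np.ndarray] = {}
    with Fasta(str(fasta)) as fa:
        for name in fa.keys():
            if name not in lengths:
                raise GenomeFormatError(
                    f"FASTA sequence {name!r} absent from genome"
                )
            seq = str(fa[name][:])
            if len(seq) != lengths[name]:
                raise GenomeFormatError(
                    f"length mismatch for {name!r}: FASTA {len(seq)}, "
                    f"genome {lengths[name]}"
                )
            sites[name] = _scan_gatc(seq)
    return Genome(chroms=list(genome.chroms), gatc_sites=sites)


def gatc_distances(genome: Genome) -> dict[str, np.ndarray]:
    """Distances between adjacent GATC site starts, per chromosome.

    A chromosome with fewer than two sites contributes an empty array.
    """
    if genome.gatc_sites is None:
        raise ValueError("gatc_sites not populated; run find_gatc_sites first")
    return {
        chrom: np.diff(sites) if sites.size >= 2 else np.array([], dtype=np.int64)
        for chrom, sites in genome.gatc_sites.items()
    }


def _anchor_bed(start: int, end: int, strand: str, anchor: Anchor) -> int:
    if anchor == "midpoint":
        return (start + end) // 2
    # five_prime: 5' end of a minus-strand read is its last base
    return end - 1 if strand == "-" else start


def _load_reads_bed(
    path: Path, genome: Genome, anchor: Anchor
) -> tuple[dict[str, list[int]], int, int]:
    positions: dict[str, list[int]] = {name: [] for name in genome.names}
    lengths = genome.lengths
    total = 0
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GenomeFormatError(
                    f"{path}: line {lineno}: BED needs >= 3 columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise GenomeFormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if chrom not in lengths:
                skipped += 1
                continue
            strand = fields[5] if len(fields) >= 6 else "+"
            pos = _anchor_bed(start, end, strand, anchor)
            pos = min(max(pos, 0), lengths[chrom] - 1)
            positions[chrom].append(pos)
            total += 1
    return positions, total, skipped


def _load_reads_alignment(
    path: Path, genome: Genome, anchor: Anchor
) -> tuple[dict[str, list[int]], int, int]:
    import pysam

    positions: dict[str, list[int]] = {name: [] for name in genome.names}
    lengths = genome.lengths
    total = 0
    skipped = 0
    mode = "r" if path.suffix.lower() == ".sam" else "rb"
    with pysam.AlignmentFile(str(path), mode) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            chrom = aln.reference_name
            if chrom not in lengths:
                skipped += 1
                continue
            start, end = aln.reference_start, aln.reference_end
            if end is None:
                end = start + (aln.query_length or 1)
            strand = "-" if aln.is_reverse else "+"
            pos = _anchor_bed(start, end, strand, anchor)
            pos = min(max(pos, 0), lengths[chrom] - 1)
            positions[chrom].append(pos)
            total += 1
    return positions, total, skipped


def load_reads(
    path: str | Path,
    genome: Genome,
    anchor: Anchor = "five_prime",
    label: str = "",
) -> tuple[ReadSet, int]:
    """Ingest mapped reads from BED (>= 3 columns) or SAM/BAM.

    Each record is reduced to a single anchor coordinate: its 5' end
    (strand-aware; default) or its midpoint. Anchors are clipped to
    chromosome bounds; records on chromosomes absent from the genome are
    skipped and tallied.

    Returns
    -------
    (ReadSet, int)
        The read set and the number of skipped records.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".bam", ".sam", ".cram"}:
        raw, total, skipped = _load_reads_alignment(path, genome, anchor)
    else:
        raw, total, skipped = _load_reads_bed(path, genome, anchor)
    if total == 0:
        raise GenomeFormatError(f"{path}: empty read set")
    positions = {
        chrom: np.sort(np.asarray(pos, dtype=np.int64))
        for chrom, pos in raw.items()
    }
    return ReadSet(positions=positions, total_mapped=total, label=label or path.stem), skipped


def write_bedgraph(
    values: Mapping[str, np.ndarray],
    window_size: int,
    genome: Genome,
    path: str | Path,
    skip_zero: bool = True,
) -> None:
    """Write per-window values as BedGraph (0-based half-open intervals).

    The final window of a chromosome is truncated at the chromosome end.
    Zero-valued windows are omitted by default to keep files small.
    """
    lengths = genome.lengths
    with open(path, "w") as out:
        for chrom in genome.names:
            if chrom not in values:
                continue
            v = values[chrom]
            length = lengths[chrom]
            for w, val in enumerate(v):
                if skip_zero and val == 0:
                    continue
                start = w * window_size
                end = min(start + window_size, length)
                out.write(f"{chrom}\t{start}\t{end}\t{val:g}\n")


def write_bed(peaks: "Iterable", path: str | Path, extra: bool = False) -> None:
    """Write peaks as BED6: name=id, score=min(1000, round(strength*250)).

    With ``extra=True``, three columns follow: exact strength (log2
    units), number of component windows, and significance class.
    """
    with open(path, "w") as out:
        for p in peaks:
            score = min(1000, round(p.strength * 250))
            line = f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\t{score}\t."
            if extra:
                cls = "significant" if p.significant else "nonsignificant"
                line += f"\t{p.strength:.6g}\t{p.n_windows}\t{cls}"
            out.write(line + "\n")


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int, str, float]]:
    """Read BED intervals back as (chrom, start, end, name, score/250) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else ""
            score = float(f[4]) / 250.0 if len(f) > 4 else 0.0
            out.append((f[0], int(f[1]), int(f[2]), name, score))
    return out
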