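"""Window thresholding, peak merging, and peak-to-gene assignment.

Windows with enrichment y >= MFC95 are significant; windows with
0 <= y < MFC95 are pooled as non-significant (used for the replicate
consistency analysis, which needs a tail of weak calls). Selected
windows are merged into peaks by bridging genomic gaps up to
``merge_gap`` bp (default 1000 bp — the scale below which nearly all
adjacent DpnI GATC fragments fall, so nearby significant windows on one
methylated fragment cluster are joined). A peak's strength is the
maximum enrichment over its selected component windows only; bridged
gap windows do not contribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal import EnrichmentTrack

__all__ = [
    "Peak",
    "PeakSet",
    "call_significant_windows",
    "pool_nonsignificant_windows",
    "merge_windows",
    "assign_peaks_to_genes",
    "candidate_genes",
]


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    strength: float
    n_windows: int
    significant: bool
    id: str = ""


@dataclass
class PeakSet:
    """Peaks sorted by (chromosome order, start) plus the parameters used."""

    peaks: list[Peak]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def strengths(self) -> np.ndarray:
        return np.array([p.strength for p in self.peaks])


def call_significant_windows(
    enrichment: EnrichmentTrack, threshold: float
) -> dict[str, np.ndarray]:
    """Indices of windows with y >= threshold, per chromosome."""
    return {c: np.flatnonzero(y >= threshold) for c, y in enrichment.y.items()}


def pool_nonsignificant_windows(
    enrichment: EnrichmentTrack, threshold: float
) -> dict[str, np.ndarray]:
    """Indices of windows with 0 <= y < threshold, per chromosome."""
    return {
        c: np.flatnonzero((y >= 0) & (y < threshold))
        for c, y in enrichment.y.items()
    }


def merge_windows(
    window_indices: dict[str, np.ndarray],
    enrichment: EnrichmentTrack,
    genome,
    merge_gap: int = 1000,
    significant: bool = True,
    id_prefix: str = "peak",
) -> PeakSet:
    """Merge selected windows into peaks, bridging gaps up to merge_gap bp.

    Two consecutive selected windows on a chromosome join the same peak
    when the gap from the end of one window to the start of the next is
    <= merge_gap. The peak spans from the start of its first selected
    window to the end of its last (gaps are bridged, never padded); the
    terminal window is truncated at the chromosome end.
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    w = enrichment.window_size
    lengths = genome.lengths
    peaks: list[Peak] = []
    for chrom in genome.names:
        idx = window_indices.get(chrom)
        if idx is None or len(idx) == 0:
            continue
        idx = np.sort(np.asarray(idx))
        y = enrichment.y[chrom]
        length = lengths[chrom]
        # gap between window i and j (j > i): j*w - (i+1)*w
        breaks = np.flatnonzero((idx[1:] - idx[:-1] - 1) * w > merge_gap) + 1
        for run in np.split(idx, breaks):
            start = int(run[0]) * w
            end = min((int(run[-1]) + 1) * w, length)
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=start,
                    end=end,
                    strength=float(np.max(y[run])),
                    n_windows=len(run),
                    significant=significant,
                )
            )
    for i, p in enumerate(peaks, start=1):
        p.id = f"{id_prefix}_{i}"
    return PeakSet(
        peaks=peaks,
        provenance={"merge_gap": merge_gap, "window_size": w},
    )


@dataclass
class GeneRegion:
    """A gene body extended upstream of its transcription start."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"


def _extended_interval(g: GeneRegion, upstream: int) -> tuple[int, int]:
    if g.strand == "-":
        return g.start, g.end + upstream
    return max(0, g.start - upstream), g.end


def assign_peaks_to_genes(
    peaks: PeakSet, genes: list[GeneRegion], upstream: int = 2500
) -> dict[str, int]:
    """Count peaks overlapping each gene body + upstream promoter region.

    A peak is assigned to a gene when it overlaps the gene body extended
    ``upstream`` bp past the transcription start (strand-aware) by at
    least one base. Genes without a recognised strand are treated as
    plus-strand.
    """
    counts: dict[str, int] = {g.gene_id: 0 for g in genes}
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        if g.strand not in {"+", "-"}:
            g = GeneRegion(g.gene_id, g.chrom, g.start, g.end, "+")
        s, e = _extended_interval(g, upstream)
        by_chrom.setdefault(g.chrom, []).append((s, e, g.gene_id))
    for p in peaks:
        for s, e, gid in by_chrom.get(p.chrom, ()):
            if p.start < e and s < p.end:
                counts[gid] += 1
    return counts


def candidate_genes(
    counts_female: dict[str, int], counts_male: dict[str, int]
) -> list[str]:
    """Genes with a peak in each sex, or at least two peaks in one sex."""
    genes = set(counts_female) | set(counts_male)
    out = []
    for g in sorted(genes):
        f = counts_female.get(g, 0)
        m = counts_male.get(g, 0)
        if (f >= 1 and m >= 1) or f >= 2 or m >= 2:
            out.append(g)
    return out
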