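"""Windowed signal tracks and per-window log2 enrichment.

The genome is tiled into non-overlapping fixed-width windows (default
100 bp, the typical scale of a transcription-factor binding site). Raw
anchor counts per window are pseudocount-adjusted, scaled to reads per
million mapped reads (RPM), smoothed with a truncated Gaussian kernel,
and the treatment/control ratio is expressed per window as

    y_i = log2(x_i / c_i)

where x_i and c_i are the smoothed RPM of treatment and control in
window i. The mask of windows with y_i > 0 is carried alongside, since
the null statistic downstream is the median over positive windows only.

Order of operations is fixed: count -> add pseudocount -> RPM -> smooth
-> log2 ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import Genome, ReadSet

__all__ = [
    "WindowTrack",
    "EnrichmentTrack",
    "n_windows",
    "bin_reads",
    "scale_rpm",
    "smooth_gaussian",
    "compute_enrichment",
]


def n_windows(length: int, window_size: int) -> int:
    """Number of windows tiling ``length`` bp; the last may be partial."""
    return -(-length // window_size)


@dataclass
class WindowTrack:
    """Per-chromosome windowed signal: raw counts, RPM, smoothed RPM."""

    window_size: int
    sample_total: int
    raw_counts: dict[str, np.ndarray]
    rpm: dict[str, np.ndarray] = field(default_factory=dict)
    smoothed: dict[str, np.ndarray] = field(default_factory=dict)
    label: str = ""


@dataclass
class EnrichmentTrack:
    """Per-window log2 treatment/control ratio and the positive mask."""

    window_size: int
    y: dict[str, np.ndarray]
    positive_mask: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.positive_mask:
            self.positive_mask = {c: v > 0 for c, v in self.y.items()}

    def pooled_y(self) -> np.ndarray:
        """All window values concatenated across chromosomes."""
        return np.concatenate(list(self.y.values())) if self.y else np.array([])


def bin_reads(reads: ReadSet, genome: Genome, window_size: int = 100) -> WindowTrack:
    """Count read anchors into non-overlapping windows of ``window_size`` bp.

    Window w receives anchors p with floor(p / window_size) == w.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    counts: dict[str, np.ndarray] = {}
    for chrom, length in genome.chroms:
        nw = n_windows(length, window_size)
        pos = reads.positions.get(chrom)
        if pos is None or pos.size == 0:
            counts[chrom] = np.zeros(nw, dtype=np.int64)
        else:
            counts[chrom] = np.bincount(pos // window_size, minlength=nw).astype(
                np.int64
            )
    return WindowTrack(
        window_size=window_size,
        sample_total=reads.total_mapped,
        raw_counts=counts,
        label=reads.label,
    )


def scale_rpm(
    track: WindowTrack, pseudocount: float = 1.0, scale_total: int | None = None
) -> WindowTrack:
    """Scale (count + pseudocount) to reads per million mapped reads.

    ``scale_total`` defaults to the track's own sample total; for a
    resampled control it should be the resampled total, so resampling
    perturbs the spatial pattern rather than the global depth.
    """
    total = track.sample_total if scale_total is None else scale_total
    if total <= 0:
        raise ValueError("scale_total must be positive")
    track.rpm = {
        chrom: (c + pseudocount) * 1e6 / total for chrom, c in track.raw_counts.items()
    }
    return track


def _gaussian_kernel(sigma: float) -> np.ndarray:
    """Gaussian kernel truncated at +/- 4 sigma, normalised to sum 1."""
    radius = max(1, int(np.ceil(4.0 * sigma)))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth_gaussian(track: WindowTrack, bandwidth_windows: float = 1.0) -> WindowTrack:
    """Smooth the RPM vectors with a truncated, edge-renormalised Gaussian.

    The kernel has standard deviation ``bandwidth_windows`` (in window
    units) and support +/- 4 sigma. Near chromosome edges the kernel is
    renormalised over its in-range support, so a constant vector stays
    exactly constant. Bandwidth 0 copies the input.
    """
    if bandwidth_windows < 0:
        raise ValueError("bandwidth must be >= 0")
    if not track.rpm:
        raise ValueError("rpm not computed; call scale_rpm first")
    if bandwidth_windows == 0:
        track.smoothed = {c: v.copy() for c, v in track.rpm.items()}
        return track
    kernel = _gaussian_kernel(bandwidth_windows)
    smoothed: dict[str, np.ndarray] = {}
    for chrom, v in track.rpm.items():
        num = np.convolve(v, kernel, mode="same")
        # in-range kernel mass per position, for edge renormalisation
        denom = np.convolve(np.ones_like(v), kernel, mode="same")
        smoothed[chrom] = num / denom
    track.smoothed = smoothed
    return track


def compute_enrichment(
    treatment: WindowTrack, control: WindowTrack
) -> EnrichmentTrack:
    """Per-window log2 ratio of smoothed treatment RPM over control RPM.

    The pseudocount policy guarantees both operands are strictly
    positive, so every value is finite.
    """
    if treatment.window_size != control.window_size:
        raise ValueError("window grids differ between treatment and control")
    if not treatment.smoothed or not control.smoothed:
        raise ValueError("smoothed tracks required; call smooth_gaussian first")
    y: dict[str, np.ndarray] = {}
    for chrom, x in treatment.smoothed.items():
        c = control.smoothed.get(chrom)
        if c is None or c.shape != x.shape:
            raise ValueError(f"window grid mismatch on {chrom!r}")
        y[chrom] = np.log2(x / c)
    return EnrichmentTrack(window_size=treatment.window_size, y=y)
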