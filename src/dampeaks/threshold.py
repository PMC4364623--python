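"""Resampling null distribution of the median fold change (MFC).

The background adenine-methylation signal in the Dam-only control is
highly non-uniform, so a parametric null is not trusted. Instead, a
fraction of the control reads (default 90%) is repeatedly retained at
random, the windowed log2 enrichment of treatment over the resampled
control is recomputed, and the median over positive-enrichment windows
(the MFC) is recorded. Over N iterations (default 200) this yields an
empirical null for "typical" positive enrichment; the 95th percentile
of the MFC values (MFC95) is the genome-wide significance cutoff.

Subsampling is WITHOUT replacement — removal of reads, not a classical
with-replacement bootstrap — stratified per reference sequence so that
chromosome arms keep their relative depth. The treatment track is never
resampled and is computed once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import Genome, ReadSet
from .signal import bin_reads, compute_enrichment, scale_rpm, smooth_gaussian

__all__ = [
    "ResampleConfig",
    "MFCDistribution",
    "resample_control",
    "compute_mfc",
    "percentile_linear",
    "build_null",
]


@dataclass
class ResampleConfig:
    """Parameters of the resampling null.

    fraction : retained fraction of control reads per chromosome (0, 1].
    iterations : number of resampling rounds.
    seed : master seed; per-iteration streams are spawned from it.
    percentile : percentile of the MFC distribution used as the cutoff.
    """

    fraction: float = 0.9
    iterations: int = 200
    seed: int = 0
    percentile: float = 95.0

    def __post_init__(self) -> None:
        if not (0 < self.fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (0 < self.percentile < 100):
            raise ValueError("percentile must be in (0, 100)")


@dataclass
class MFCDistribution:
    """Null MFC values, one per iteration, and the derived cutoff."""

    mfc_values: np.ndarray
    mfc95: float
    config: ResampleConfig


def resample_control(
    control: ReadSet, fraction: float, rng: np.random.Generator
) -> ReadSet:
    """Retain a uniform random subset of reads, per chromosome.

    Exactly round(fraction * n) reads are kept on each chromosome,
    without replacement; output positions remain sorted.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    positions: dict[str, np.ndarray] = {}
    total = 0
    for chrom, pos in control.positions.items():
        n = pos.size
        k = int(round(fraction * n))
        if k >= n:
            kept = pos.copy()
        elif k == 0:
            kept = pos[:0]
        else:
            idx = rng.choice(n, size=k, replace=False)
            kept = np.sort(pos[idx])
        positions[chrom] = kept
        total += kept.size
    return ReadSet(positions=positions, total_mapped=total, label=control.label)


def compute_mfc(enrichment) -> float:
    """Median of the positive per-window enrichments, pooled genome-wide.

    Raises if no window has y > 0 (the statistic is then undefined).
    """
    y = enrichment.pooled_y()
    positive = y[y > 0]
    if positive.size == 0:
        raise ValueError("no positive enrichment; MFC undefined")
    return float(np.median(positive))


def percentile_linear(values: np.ndarray, q: float) -> float:
    """Percentile by linear interpolation between order statistics (type 7)."""
    return float(np.percentile(np.asarray(values, dtype=float), q))


def build_null(
    treatment: ReadSet,
    control: ReadSet,
    genome: Genome,
    cfg: ResampleConfig,
    window_size: int = 100,
    pseudocount: float = 1.0,
    bandwidth_windows: float = 1.0,
) -> MFCDistribution:
    """Run the resampling loop and derive the MFC95 cutoff.

    Per iteration: subsample the control, re-bin/scale/smooth it (RPM
    scaled by the RESAMPLED total), recompute enrichment against the
    fixed treatment track, and record the MFC. Deterministic given
    ``cfg.seed``; per-iteration random streams are spawned from a single
    seed sequence so iterations are order-independent.
    """
    t_track = smooth_gaussian(
        scale_rpm(bin_reads(treatment, genome, window_size), pseudocount),
        bandwidth_windows,
    )
    child_seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.iterations)
    mfcs = np.empty(cfg.iterations)
    for i in range(cfg.iterations):
        rng = np.random.default_rng(child_seeds[i])
        sub = resample_control(control, cfg.fraction, rng)
        c_track = smooth_gaussian(
            scale_rpm(bin_reads(sub, genome, window_size), pseudocount),
            bandwidth_windows,
        )
        enr = compute_enrichment(t_track, c_track)
        try:
            mfcs[i] = compute_mfc(enr)
        except ValueError as exc:
            raise ValueError(f"iteration {i}: {exc}") from exc
    mfc95 = percentile_linear(mfcs, cfg.percentile)
    return MFCDistribution(mfc_values=mfcs, mfc95=mfc95, config=cfg)
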