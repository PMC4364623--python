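"""Replicate reproducibility: peak matching and the correspondence curve.

Peaks from two biological replicates (pooled significant plus
non-significant calls) are matched one-to-one when they share at least
50% of base pairs relative to the smaller peak. Matched peaks are
ranked by strength within each replicate, and the correspondence curve

    psi(t) = |{pairs with rank_a <= t*n and rank_b <= t*n}| / n

tracks how consistently the two replicates agree on their top-t
fraction. For reproducible rankings psi grows with slope ~1; where the
slope decays toward 0, agreement has degraded to chance — the decay
point marks the onset of irreproducibility, and pairs ranked before it
are declared reproducible.

This module computes the exact correspondence curve and an empirical
rank-discordance diagnostic; it does not fit the two-component copula
mixture model of full IDR inference. Externally computed per-pair idr
values can be attached to pairs for users who run that model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .peaks import Peak, PeakSet

__all__ = [
    "MatchedPeakPair",
    "CorrespondenceCurve",
    "match_peaks",
    "rank_peaks",
    "correspondence_curve",
    "find_decay_point",
    "local_idr_diagnostic",
]


@dataclass
class MatchedPeakPair:
    peak_a: Peak
    peak_b: Peak
    overlap_bp: int
    overlap_fraction: float
    rank_a: int = 0
    rank_b: int = 0
    idr: float | None = None  # externally computed local idr, if any


@dataclass
class CorrespondenceCurve:
    t_grid: np.ndarray
    psi: np.ndarray
    psi_prime: np.ndarray
    n_pairs: int
    decay_t: float | None = None
    n_reproducible: int = 0


def _overlap(a: Peak, b: Peak) -> int:
    return min(a.end, b.end) - max(a.start, b.start)


def match_peaks(
    set_a: PeakSet, set_b: PeakSet, min_fraction: float = 0.5
) -> list[MatchedPeakPair]:
    """Greedy one-to-one matching of overlapping peaks across replicates.

    Candidates are all pairs overlapping by >= min_fraction of the
    smaller peak's width. Pairs are accepted in order of descending
    overlap_bp (ties: larger smaller-peak width first, then leftmost);
    each peak joins at most one pair.
    """
    by_chrom_b: dict[str, list[Peak]] = {}
    for p in set_b:
        by_chrom_b.setdefault(p.chrom, []).append(p)
    for lst in by_chrom_b.values():
        lst.sort(key=lambda p: p.start)

    candidates: list[tuple[int, int, int, int, Peak, Peak]] = []
    for a in set_a:
        blist = by_chrom_b.get(a.chrom, [])
        for b in blist:
            if b.start >= a.end:
                break
            ov = _overlap(a, b)
            if ov <= 0:
                continue
            min_w = min(a.end - a.start, b.end - b.start)
            if ov / min_w >= min_fraction:
                candidates.append((ov, min_w, a.start, b.start, a, b))
    # descending overlap, then descending min-width, then leftmost
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2], c[3]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[MatchedPeakPair] = []
    for ov, min_w, _, _, a, b in candidates:
        if id(a) in used_a or id(b) in used_b:
            continue
        used_a.add(id(a))
        used_b.add(id(b))
        pairs.append(
            MatchedPeakPair(
                peak_a=a, peak_b=b, overlap_bp=ov, overlap_fraction=ov / min_w
            )
        )
    pairs.sort(key=lambda pr: (pr.peak_a.chrom, pr.peak_a.start))
    return pairs


def _ranks(peaks: list[Peak]) -> np.ndarray:
    """1-based ranks, 1 = strongest; strength ties broken leftmost-first."""
    order = sorted(
        range(len(peaks)),
        key=lambda i: (-peaks[i].strength, peaks[i].chrom, peaks[i].start),
    )
    ranks = np.empty(len(peaks), dtype=np.int64)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return ranks


def rank_peaks(pairs: list[MatchedPeakPair]) -> list[MatchedPeakPair]:
    """Assign within-replicate strength ranks (1 = strongest) to each pair."""
    ra = _ranks([p.peak_a for p in pairs])
    rb = _ranks([p.peak_b for p in pairs])
    for p, a, b in zip(pairs, ra, rb):
        p.rank_a = int(a)
        p.rank_b = int(b)
    return pairs


def correspondence_curve(
    pairs: list[MatchedPeakPair], t_grid: np.ndarray | None = None
) -> CorrespondenceCurve:
    """Fraction of pairs jointly in both replicates' top-t fractions.

    The slope is estimated by central finite differences on the grid
    (one-sided at the ends).
    """
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 matched pairs")
    if any(p.rank_a == 0 for p in pairs):
        pairs = rank_peaks(pairs)
    if t_grid is None:
        t_grid = np.arange(1, 101) / 100.0
    t_grid = np.asarray(t_grid, dtype=float)
    ra = np.array([p.rank_a for p in pairs])
    rb = np.array([p.rank_b for p in pairs])
    psi = np.array(
        [np.sum((ra <= t * n) & (rb <= t * n)) / n for t in t_grid]
    )
    psi_prime = np.gradient(psi, t_grid)
    return CorrespondenceCurve(
        t_grid=t_grid, psi=psi, psi_prime=psi_prime, n_pairs=n
    )


def find_decay_point(
    curve: CorrespondenceCurve, slope_drop: float = 0.5, persistence: int = 3
) -> tuple[float | None, int]:
    """Locate where the correspondence-curve slope collapses.

    The reference slope is the median of psi' over the initial 20% of
    the grid. The decay point is the smallest t where psi' falls below
    ``slope_drop`` times the reference and stays below for at least
    ``persistence`` consecutive grid points. If the slope never
    collapses, decay_t = 1 and every pair is reproducible; a flat curve
    (reference slope ~ 0) yields decay_t = None.
    """
    t, sp = curve.t_grid, curve.psi_prime
    if len(t) < persistence:
        raise ValueError(f"need at least {persistence} grid points")
    n_head = max(1, int(np.ceil(0.2 * len(t))))
    ref = float(np.median(sp[:n_head]))
    if ref <= 1e-12:
        curve.decay_t = None
        curve.n_reproducible = 0
        return None, 0
    below = sp < slope_drop * ref
    for i in range(len(t) - persistence + 1):
        if below[i : i + persistence].all():
            decay_t = float(t[i])
            curve.decay_t = decay_t
            curve.n_reproducible = int(np.floor(decay_t * curve.n_pairs))
            return decay_t, curve.n_reproducible
    curve.decay_t = 1.0
    curve.n_reproducible = curve.n_pairs
    return 1.0, curve.n_pairs


def local_idr_diagnostic(pairs: list[MatchedPeakPair]) -> np.ndarray:
    """Empirical per-pair irreproducibility score in [0, 1].

    The raw discordance |rank_a - rank_b| / n is calibrated through its
    empirical distribution function over discordant pairs, so scores are
    monotone in rank discordance, perfectly concordant pairs score 0,
    and the most discordant pair scores 1. This is a diagnostic, not a
    model-based local idr.
    """
    n = len(pairs)
    if n < 10:
        raise ValueError("need at least 10 matched pairs")
    if any(p.rank_a == 0 for p in pairs):
        pairs = rank_peaks(pairs)
    d = np.array([abs(p.rank_a - p.rank_b) for p in pairs], dtype=float) / n
    pos = d[d > 0]
    if pos.size == 0:
        return np.zeros(n)
    sorted_pos = np.sort(pos)
    # ECDF over discordant pairs; exact zeros stay exactly zero
    scores = np.searchsorted(sorted_pos, d, side="right") / pos.size
    scores[d == 0] = 0.0
    return scores
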