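"""Synthetic DamID-seq data with the statistical structure the method assumes.

The generator emulates three features of real DamID-seq libraries:

* GATC (DpnI) sites placed by a homogeneous Poisson process, so
  inter-site distances are i.i.d. exponential (rate ~ 1/256 per bp in
  a fly-like genome, putting ~98% of fragment lengths under 1 kb);
* a non-uniform background methylation propensity SHARED between the
  treatment and the Dam-only control — a log-scale Gaussian random
  field over GATC fragments with tunable correlation length and
  dispersion, reproducing the observation that control read pile-ups
  co-locate with treatment pile-ups;
* localized treatment-only enrichment: fragments intersecting a truth
  binding region carry a multiplicative methylation propensity
  ``site_effect`` in the treatment sample only.

Reads are drawn per sample multinomially over fragments in proportion
to these propensities and anchored at one of the fragment's two GATC
ends (DpnI cuts at methylated GATC), chosen uniformly. Everything is
deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genome_io import Genome, ReadSet

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genome",
    "simulate_reads",
    "emit_fasta",
    "write_fixture",
    "load_fixture_config",
]

MIN_TRUTH_SEPARATION = 5_000  # bp between truth regions, keeps scoring unambiguous


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    chrom_lengths : chromosome lengths in bp (names auto-generated as
        chr1, chr2, ... unless ``chrom_names`` is given).
    gatc_rate : Poisson rate of GATC sites per bp; 1/256 matches the
        expected density of a 4-bp motif in a uniform-composition genome
        and the fly-like regime where ~98% of fragment lengths are <1 kb.
    n_sites : number of truth binding regions.
    site_effect : multiplicative methylation propensity at truth
        regions (treatment only); 1 = null dataset.
    site_halfwidth : bp of elevated propensity either side of a binding
        point. Dam methylation spreads over kb-scale neighbourhoods of
        a binding site, hence the 2.5 kb default.
    correlation_length, dispersion : parameters of the shared log-scale
        Gaussian background field over fragments (exponential
        covariance; dispersion is the log SD).
    depth_treatment, depth_control : reads drawn per sample.
    """

    chrom_lengths: list[int] = field(default_factory=lambda: [5_000_000])
    chrom_names: list[str] | None = None
    gatc_rate: float = 1.0 / 256.0
    n_sites: int = 100
    site_effect: float = 8.0
    site_halfwidth: int = 2_500
    correlation_length: float = 10_000.0
    dispersion: float = 1.0
    depth_treatment: int = 200_000
    depth_control: int = 200_000
    read_length: int = 76
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gatc_rate <= 0:
            raise ValueError("gatc_rate must be positive")
        if self.depth_treatment <= 0 or self.depth_control <= 0:
            raise ValueError("depths must be positive")
        if self.site_effect < 1:
            raise ValueError("site_effect must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.chrom_names is None:
            self.chrom_names = [f"chr{i+1}" for i in range(len(self.chrom_lengths))]

    @property
    def chroms(self) -> list[tuple[str, int]]:
        return list(zip(self.chrom_names, self.chrom_lengths))


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset: binding regions and weights."""

    truth_regions: list[tuple[str, int, int]]
    fragment_weights: dict[str, np.ndarray]
    config: SimConfig


def _draw_sites(length: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson-process site positions; gaps < 4 bp are redrawn (no overlap)."""
    mean_gap = 1.0 / rate
    est = int(length * rate * 1.3) + 20
    sites: list[np.ndarray] = []
    pos = 0.0
    while pos <= length - 4:
        gaps = rng.exponential(mean_gap, size=est)
        bad = gaps < 4
        while bad.any():
            gaps[bad] = rng.exponential(mean_gap, size=int(bad.sum()))
            bad = gaps < 4
        cum = pos + np.cumsum(gaps)
        sites.append(cum)
        pos = cum[-1]
    s = np.floor(np.concatenate(sites)).astype(np.int64)
    s = s[s <= length - 4]
    return np.unique(s)


def simulate_genome(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> Genome:
    """Genome with GATC sites from a homogeneous Poisson process."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    sites = {
        name: _draw_sites(length, cfg.gatc_rate, rng)
        for name, length in cfg.chroms
    }
    return Genome(chroms=cfg.chroms, gatc_sites=sites)


def _place_truth_regions(
    cfg: SimConfig, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Rejection-sample binding points >= 5 kb apart, regions in bounds."""
    lengths = np.array(cfg.chrom_lengths, dtype=float)
    probs = lengths / lengths.sum()
    hw = cfg.site_halfwidth
    placed: dict[str, list[int]] = {n: [] for n in cfg.chrom_names}
    regions: list[tuple[str, int, int]] = []
    attempts = 0
    while len(regions) < cfg.n_sites:
        attempts += 1
        if attempts > 1000 * max(1, cfg.n_sites):
            raise RuntimeError(
                "cannot place truth regions: genome too small for "
                f"{cfg.n_sites} regions >= {MIN_TRUTH_SEPARATION} bp apart"
            )
        ci = rng.choice(len(lengths), p=probs)
        chrom = cfg.chrom_names[ci]
        length = cfg.chrom_lengths[ci]
        if length < 2 * hw + 2:
            continue
        p = int(rng.integers(hw, length - hw))
        if any(abs(p - q) < MIN_TRUTH_SEPARATION + 2 * hw for q in placed[chrom]):
            continue
        placed[chrom].append(p)
        regions.append((chrom, p - hw, p + hw))
    regions.sort(key=lambda r: (cfg.chrom_names.index(r[0]), r[1]))
    return regions


def _background_field(
    midpoints: np.ndarray, corr_length: float, dispersion: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stationary Gaussian field with exponential covariance, evaluated at
    the fragment midpoints via its AR(1) (Ornstein-Uhlenbeck) construction."""
    n = midpoints.size
    z = np.empty(n)
    eps = rng.standard_normal(n)
    z[0] = eps[0]
    if n > 1:
        rho = np.exp(-np.diff(midpoints) / corr_length)
        scale = np.sqrt(1.0 - rho**2)
        for k in range(1, n):
            z[k] = rho[k - 1] * z[k - 1] + scale[k - 1] * eps[k]
    return np.exp(dispersion * z)


def simulate_reads(
    genome: Genome, cfg: SimConfig, read_seed: int | None = None
) -> tuple[ReadSet, ReadSet, SimTruth]:
    """Draw treatment and control read sets over GATC fragments.

    Both samples share one background field; only the treatment sees the
    ``site_effect`` multiplier at truth regions. Each read is anchored
    at one of its fragment's two GATC site starts, chosen uniformly.

    ``read_seed`` replaces only the read-drawing stream: calling twice
    with different read seeds yields biological replicates that share
    truth regions and background field but have independent reads.
    """
    if genome.gatc_sites is None:
        raise ValueError("genome has no GATC sites")
    ss = np.random.SeedSequence(cfg.seed).spawn(4)
    # spawn(1)[0] seeds the genome in simulate_genome; use dedicated streams here
    rng_truth = np.random.default_rng(ss[1])
    rng_field = np.random.default_rng(ss[2])
    rng_reads = np.random.default_rng(
        ss[3] if read_seed is None else np.random.SeedSequence(read_seed)
    )

    truth_regions = (
        _place_truth_regions(cfg, rng_truth) if cfg.n_sites > 0 else []
    )

    frag_chrom: list[str] = []
    frag_left: list[np.ndarray] = []
    frag_right: list[np.ndarray] = []
    weights_bg: list[np.ndarray] = []
    in_truth: list[np.ndarray] = []
    for chrom, _ in genome.chroms:
        sites = genome.gatc_sites[chrom]
        if sites.size < 2:
            continue
        left, right = sites[:-1], sites[1:]
        mid = (left + right) / 2.0
        b = _background_field(mid, cfg.correlation_length, cfg.dispersion, rng_field)
        hit = np.zeros(left.size, dtype=bool)
        for rc, rs, re in truth_regions:
            if rc == chrom:
                hit |= (left < re) & (rs < right)
        frag_chrom.extend([chrom] * left.size)
        frag_left.append(left)
        frag_right.append(right)
        weights_bg.append(b)
        in_truth.append(hit)
    if not frag_left:
        raise ValueError("no GATC fragments; need >= 2 sites on a chromosome")

    left = np.concatenate(frag_left)
    right = np.concatenate(frag_right)
    bg = np.concatenate(weights_bg)
    hit = np.concatenate(in_truth)
    chrom_arr = np.array(frag_chrom)

    w_control = bg
    w_treat = np.where(hit, bg * cfg.site_effect, bg)

    def _draw(weights: np.ndarray, depth: int, label: str) -> ReadSet:
        counts = rng_reads.multinomial(depth, weights / weights.sum())
        nz = np.flatnonzero(counts)
        at_left = rng_reads.binomial(counts[nz], 0.5)
        positions: dict[str, np.ndarray] = {c: np.array([], dtype=np.int64)
                                            for c, _ in genome.chroms}
        anchors = np.repeat(
            np.stack([left[nz], right[nz]], axis=1).ravel(),
            np.stack([at_left, counts[nz] - at_left], axis=1).ravel(),
        )
        frag_of = np.repeat(nz, counts[nz])
        for chrom, _ in genome.chroms:
            mask = chrom_arr[frag_of] == chrom
            positions[chrom] = np.sort(anchors[mask])
        return ReadSet(positions=positions, total_mapped=depth, label=label)

    treatment = _draw(w_treat, cfg.depth_treatment, "treatment")
    control = _draw(w_control, cfg.depth_control, "control")
    per_chrom_weights = {
        c: w_treat[chrom_arr == c] for c, _ in genome.chroms
    }
    truth = SimTruth(
        truth_regions=truth_regions,
        fragment_weights=per_chrom_weights,
        config=cfg,
    )
    return treatment, control, truth


def emit_fasta(genome: Genome, path: str | Path, seed: int = 0) -> None:
    """Write a FASTA whose GATC occurrences are exactly the genome's sites.

    Filler bases are drawn from {A, C, T}; with no other G in the
    sequence, GATC can occur only where planted.
    """
    if genome.gatc_sites is None:
        raise ValueError("genome has no GATC sites")
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACT", dtype="S1")
    with open(path, "w") as out:
        for chrom, length in genome.chroms:
            seq = rng.choice(alphabet, size=length)
            for s in genome.gatc_sites[chrom]:
                seq[s : s + 4] = np.frombuffer(b"GATC", dtype="S1")
            out.write(f">{chrom}\n")
            text = seq.tobytes().decode()
            for i in range(0, length, 80):
                out.write(text[i : i + 80] + "\n")


def write_fixture(
    outdir: str | Path,
    treatment: ReadSet,
    control: ReadSet,
    genome: Genome,
    truth: SimTruth,
    fasta: bool = False,
) -> None:
    """Write a reproducible on-disk fixture: read BEDs, chrom.sizes,
    truth BED, and a JSON echo of the full configuration."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    lengths = genome.lengths

    def _write_reads(rs: ReadSet, path: Path) -> None:
        with open(path, "w") as out:
            i = 0
            for chrom, _ in genome.chroms:
                for p in rs.positions.get(chrom, ()):
                    end = min(int(p) + cfg.read_length, lengths[chrom])
                    out.write(f"{chrom}\t{p}\t{end}\tr{i}\t0\t+\n")
                    i += 1

    _write_reads(treatment, outdir / "treatment.bed")
    _write_reads(control, outdir / "control.bed")
    with open(outdir / "chrom.sizes", "w") as out:
        for chrom, length in genome.chroms:
            out.write(f"{chrom}\t{length}\n")
    with open(outdir / "truth.bed", "w") as out:
        for chrom, start, end in truth.truth_regions:
            out.write(f"{chrom}\t{start}\t{end}\n")
    echo = asdict(cfg)
    with open(outdir / "config.json", "w") as out:
        json.dump(echo, out, indent=2)
    if fasta:
        emit_fasta(genome, outdir / "genome.fa", seed=cfg.seed)


def load_fixture_config(outdir: str | Path) -> SimConfig:
    """Re-read the configuration echo written by :func:`write_fixture`."""
    with open(Path(outdir) / "config.json") as fh:
        return SimConfig(**json.load(fh))
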