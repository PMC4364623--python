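import numpy as np
import pytest

import dampeaks as dp
from dampeaks.simulate import MIN_TRUTH_SEPARATION


class TestSimulateGenome:
    def test_site_count_matches_poisson_expectation(self):
        cfg = dp.SimConfig(chrom_lengths=[10_000_000], seed=0)
        g = dp.simulate_genome(cfg)
        n = g.gatc_sites["chr1"].size
        mean = 10_000_000 / 256
        assert abs(n - mean) < 3 * np.sqrt(mean)

    def test_distances_follow_exponential_cdf(self):
        cfg = dp.SimConfig(chrom_lengths=[10_000_000], seed=1)
        g = dp.simulate_genome(cfg)
        d = np.concatenate(list(dp.gatc_distances(g).values()))
        frac = np.mean(d < 1000)
        expected = 1 - np.exp(-1000 / 256)  # ~0.980
        assert frac == pytest.approx(expected, abs=0.01)

    def test_deterministic_given_seed(self):
        cfg = dp.SimConfig(chrom_lengths=[200_000], seed=5)
        a = dp.simulate_genome(cfg)
        b = dp.simulate_genome(cfg)
        assert np.array_equal(a.gatc_sites["chr1"], b.gatc_sites["chr1"])

    def test_minimum_gap_of_four_bp(self):
        cfg = dp.SimConfig(chrom_lengths=[100_000], gatc_rate=0.2, seed=2)
        g = dp.simulate_genome(cfg)
        assert np.all(np.diff(g.gatc_sites["chr1"]) >= 4)

    def test_fasta_sites_are_exactly_the_drawn_sites(self, tmp_path):
        cfg = dp.SimConfig(chrom_lengths=[30_000], seed=3)
        g = dp.simulate_genome(cfg)
        fa = tmp_path / "g.fa"
        dp.emit_fasta(g, fa, seed=3)
        rescanned = dp.find_gatc_sites(fa, dp.Genome(chroms=g.chroms))
        assert np.array_equal(
            rescanned.gatc_sites["chr1"], g.gatc_sites["chr1"]
        )


class TestSimulateReads:
    def test_read_counts_and_anchor_validity(self, small_sim):
        cfg, genome, treatment, control, _ = small_sim
        assert treatment.n_positions == cfg.depth_treatment
        assert control.n_positions == cfg.depth_control
        sites = set(genome.gatc_sites["chr1"].tolist())
        sample = treatment.positions["chr1"][:500]
        assert all(int(p) in sites for p in sample)

    def test_truth_regions_separated_and_in_bounds(self, small_sim):
        cfg, genome, _, _, truth = small_sim
        regions = truth.truth_regions
        assert len(regions) == cfg.n_sites
        length = genome.lengths["chr1"]
        for chrom, s, e in regions:
            assert 0 <= s < e <= length
        starts = sorted(s for _, s, _ in regions)
        gaps = np.diff(starts) - 2 * cfg.site_halfwidth
        assert np.all(gaps >= MIN_TRUTH_SEPARATION)

    def test_deterministic_given_seed(self):
        cfg = dp.SimConfig(
            chrom_lengths=[300_000], n_sites=3,
            depth_treatment=5000, depth_control=5000, seed=9,
        )
        g = dp.simulate_genome(cfg)
        t1, c1, tr1 = dp.simulate_reads(g, cfg)
        t2, c2, tr2 = dp.simulate_reads(g, cfg)
        assert np.array_equal(t1.positions["chr1"], t2.positions["chr1"])
        assert np.array_equal(c1.positions["chr1"], c2.positions["chr1"])
        assert tr1.truth_regions == tr2.truth_regions

    def test_truth_windows_more_enriched_than_background(self, small_sim):
        cfg, genome, treatment, control, truth = small_sim
        tt = dp.smooth_gaussian(dp.scale_rpm(dp.bin_reads(treatment, genome)), 1)
        ct = dp.smooth_gaussian(dp.scale_rpm(dp.bin_reads(control, genome)), 1)
        y = dp.compute_enrichment(tt, ct).y["chr1"]
        in_truth = np.zeros(len(y), dtype=bool)
        for _, s, e in truth.truth_regions:
            in_truth[s // 100 : e // 100 + 1] = True
        assert y[in_truth].mean() > y[~in_truth].mean() + 1.0

    def test_null_background_correlates_between_samples(self):
        # shared methylation-propensity field: control pile-ups co-locate
        # with treatment pile-ups even without any binding signal
        cfg = dp.SimConfig(
            chrom_lengths=[2_000_000], n_sites=0, site_effect=1.0,
            dispersion=1.5, depth_treatment=100_000, depth_control=100_000,
            seed=21,
        )
        g = dp.simulate_genome(cfg)
        t, c, _ = dp.simulate_reads(g, cfg)
        tc = dp.bin_reads(t, g, 1000).raw_counts["chr1"]
        cc = dp.bin_reads(c, g, 1000).raw_counts["chr1"]
        r = np.corrcoef(np.log1p(tc), np.log1p(cc))[0, 1]
        assert r > 0.5

    def test_null_is_label_exchangeable(self):
        # with site_effect=1 swapping treatment/control labels should not
        # systematically change the significant-window rate
        diffs = []
        for seed in range(4):
            cfg = dp.SimConfig(
                chrom_lengths=[500_000], n_sites=0, site_effect=1.0,
                depth_treatment=30_000, depth_control=30_000, seed=seed,
            )
            g = dp.simulate_genome(cfg)
            t, c, _ = dp.simulate_reads(g, cfg)

            def rate(a, b):
                null = dp.build_null(
                    a, b, g, dp.ResampleConfig(iterations=20, seed=seed)
                )
                ta = dp.smooth_gaussian(dp.scale_rpm(dp.bin_reads(a, g)), 1)
                tb = dp.smooth_gaussian(dp.scale_rpm(dp.bin_reads(b, g)), 1)
                y = dp.compute_enrichment(ta, tb).pooled_y()
                return np.mean(y >= null.mfc95)

            diffs.append(rate(t, c) - rate(c, t))
        assert abs(np.mean(diffs)) < 0.1

    def test_recovery_improves_with_effect_size(self):
        def sensitivity(effect, seed=31):
            cfg = dp.SimConfig(
                chrom_lengths=[1_000_000], n_sites=8, site_effect=effect,
                depth_treatment=50_000, depth_control=50_000, seed=seed,
            )
            g = dp.simulate_genome(cfg)
            t, c, truth = dp.simulate_reads(g, cfg)
            null = dp.build_null(
                t, c, g, dp.ResampleConfig(iterations=30, seed=seed)
            )
            tt = dp.smooth_gaussian(dp.scale_rpm(dp.bin_reads(t, g)), 1)
            ct = dp.smooth_gaussian(dp.scale_rpm(dp.bin_reads(c, g)), 1)
            enr = dp.compute_enrichment(tt, ct)
            ps = dp.merge_windows(
                dp.call_significant_windows(enr, null.mfc95), enr, g, 1000
            )
            hits = sum(
                any(p.chrom == ch and p.start < e and s < p.end for p in ps)
                for ch, s, e in truth.truth_regions
            )
            return hits / len(truth.truth_regions)

        assert sensitivity(8.0) >= sensitivity(1.5)


class TestFixture:
    def test_round_trip_reproduces_read_sets(self, tmp_path, small_sim):
        cfg, genome, treatment, control, truth = small_sim
        dp.write_fixture(tmp_path, treatment, control, genome, truth)
        g2 = dp.load_chrom_sizes(tmp_path / "chrom.sizes")
        assert g2.chroms == genome.chroms
        t2, _ = dp.load_reads(tmp_path / "treatment.bed", g2)
        assert np.array_equal(t2.positions["chr1"], treatment.positions["chr1"])
        assert t2.total_mapped == treatment.total_mapped

    def test_truth_bed_and_config_echo(self, tmp_path, small_sim):
        cfg, genome, treatment, control, truth = small_sim
        dp.write_fixture(tmp_path, treatment, control, genome, truth)
        from dampeaks.genome_io import read_bed_intervals
        from dampeaks.simulate import load_fixture_config

        rows = read_bed_intervals(tmp_path / "truth.bed")
        assert [(r[0], r[1], r[2]) for r in rows] == truth.truth_regions
        echo = load_fixture_config(tmp_path)
        assert echo.seed == cfg.seed
        assert echo.site_effect == cfg.site_effect
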