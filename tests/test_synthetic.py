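import numpy as np
import pandas as pd
import pytest

import damscan as d
from damscan.synthetic import (
    DEFAULT_TIMEPOINTS,
    PATTERN_ANCHORS,
    make_site_truths,
    simulate_sample_ipds,
    write_genome_fasta,
    write_table,
)


class TestConfigValidation:
    def test_pattern_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            d.SimulationConfig(pattern_mix={"A": 0.5, "constant": 0.4})

    def test_methylated_law_must_be_shifted_up(self):
        with pytest.raises(ValueError, match="mu_meth"):
            d.SimulationConfig(mu_meth=0.0, mu_unmeth=0.5)

    def test_timepoints_strictly_increasing(self):
        with pytest.raises(ValueError, match="increasing"):
            d.SimulationConfig(timepoints_h=(8, 8, 24))


class TestGenerateGenome:
    def test_planted_count_found_by_scanner(self):
        genome, sites = d.generate_genome(400, 10, seed=1)
        assert len(sites) == 20  # 10 duplex occurrences, 2 stranded adenines each
        found = d.scan_motif(genome, "GATC", 1)
        assert len(found) == 20

    def test_seed_determinism(self):
        g1, _ = d.generate_genome(400, 10, seed=1)
        g2, _ = d.generate_genome(400, 10, seed=1)
        assert g1.residues == g2.residues
        g3, _ = d.generate_genome(400, 10, seed=2)
        assert g1.residues != g3.residues

    def test_impossible_density_errors(self):
        with pytest.raises(ValueError):
            d.generate_genome(30, 10, seed=1)


class TestSampleIpds:
    def make_truths(self, n_duplex, seed=0, coverage=50.0, **cfg_kw):
        cfg = d.SimulationConfig(
            genome_length=40 * n_duplex,
            gatc_count_target=n_duplex,
            coverage_mean=coverage,
            pattern_mix={"constant": 1.0},
            background_sites=0,
            seed=seed,
            **cfg_kw,
        )
        genome, sites = d.generate_genome(cfg.genome_length, n_duplex, seed)
        return cfg, make_site_truths(sites, cfg, seed + 1, genome=genome)

    def test_dam_control_mean_log_ipd_matches_unmethylated_law(self):
        cfg, truths = self.make_truths(120, seed=5)
        df = simulate_sample_ipds(truths, None, cfg, seed=7, role="dam_control")
        logs = np.log(df["ipd"][df["ipd"] <= 50_000])
        assert logs.size >= 10_000
        se = cfg.sigma_unmeth / np.sqrt(logs.size)
        assert abs(logs.mean() - cfg.mu_unmeth) < 3 * se + 0.02  # outlier-filter slack

    def test_fully_methylated_sites_all_exceed_control_mean(self):
        cfg, truths = self.make_truths(100, seed=3, outlier_rate=0.0, mu_meth=0.9)
        fcols = [c for c in truths.columns if c.startswith("f_")]
        truths[fcols] = 1.0
        wt = simulate_sample_ipds(truths, 8.0, cfg, seed=10)
        dam = simulate_sample_ipds(truths, None, cfg, seed=11, role="dam_control")
        wt_means = np.log(wt["ipd"]).groupby(
            [wt["position"], wt["strand"]]
        ).mean()
        ctrl_means = np.log(dam["ipd"]).groupby([dam["position"], dam["strand"]]).mean()
        assert (wt_means > ctrl_means).all()

    def test_outlier_rate_binomial_band(self):
        cfg, truths = self.make_truths(100, seed=2, outlier_rate=0.01)
        df = simulate_sample_ipds(truths, None, cfg, seed=4, role="dam_control")
        n = len(df)
        frac = (df["ipd"] > 50_000).mean()
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(frac - 0.01) < 3 * se

    def test_control_roles_force_unmethylated_law(self):
        cfg, truths = self.make_truths(20, seed=1)
        wga = simulate_sample_ipds(truths, None, cfg, seed=2, role="wga_control")
        assert (wga["role"] == "wga_control").all()
        assert wga["time_h"].isna().all()


class TestPatternTemplates:
    def test_pattern_a_flat_then_monotone(self):
        f = d.pattern_fraction("A", DEFAULT_TIMEPOINTS)
        assert f[0] == f[1]
        assert (np.diff(f[1:]) >= 0).all()

    def test_pattern_c_peaks_at_72h(self):
        f = d.pattern_fraction("C", DEFAULT_TIMEPOINTS)
        assert DEFAULT_TIMEPOINTS[int(np.argmax(f))] == 72

    def test_pattern_b_declines_then_recovers(self):
        f = dict(zip(DEFAULT_TIMEPOINTS, d.pattern_fraction("B", DEFAULT_TIMEPOINTS)))
        assert f[72] < f[24]
        assert f[120] > f[72]

    def test_pattern_d_peaks_at_24h_and_rises_late(self):
        f = dict(zip(DEFAULT_TIMEPOINTS, d.pattern_fraction("D", DEFAULT_TIMEPOINTS)))
        assert max(f, key=f.get) == 24
        assert f[120] > f[72]

    def test_constant_sites_identical_everywhere(self):
        f = d.pattern_fraction("constant", DEFAULT_TIMEPOINTS)
        assert np.ptp(f) == 0

    def test_fractions_always_within_unit_interval(self):
        t = np.linspace(8, 120, 57)
        for lab in list(PATTERN_ANCHORS) + ["none"]:
            f = d.pattern_fraction(lab, t)
            assert ((0 <= f) & (f <= 1)).all()


class TestTimecourse:
    def test_truth_conservation(self, small_timecourse):
        emitted = set(
            map(tuple, small_timecourse.ipd_table[["position", "strand"]].drop_duplicates().values)
        )
        ledger = list(map(tuple, small_timecourse.truths[["position", "strand"]].values))
        assert emitted == set(ledger)
        assert len(ledger) == len(set(ledger))  # exactly once

    def test_bundle_determinism(self, small_timecourse):
        cfg = d.SimulationConfig(
            genome_length=6000,
            gatc_count_target=60,
            coverage_mean=30,
            pattern_mix={"A": 0.1, "B": 0.1, "C": 0.1, "D": 0.1, "constant": 0.6},
            seed=11,
        )
        again = d.simulate_timecourse(cfg)
        pd.testing.assert_frame_equal(small_timecourse.ipd_table, again.ipd_table)
        pd.testing.assert_frame_equal(small_timecourse.truths, again.truths)

    def test_dam_control_law_matches_timepoint_at_f0(self):
        """dam-control draws are exchangeable with a timepoint sample at f=0."""
        from damscan.detection import wilcoxon_site

        cfg = d.SimulationConfig(
            genome_length=2000, gatc_count_target=40, pattern_mix={"constant": 1.0},
            background_sites=0, seed=21,
        )
        genome, sites = d.generate_genome(2000, 40, 1)
        truths = make_site_truths(sites, cfg, 2, genome=genome)
        truths[[c for c in truths.columns if c.startswith("f_")]] = 0.0
        a = simulate_sample_ipds(truths, 8.0, cfg, seed=100)
        b = simulate_sample_ipds(truths, None, cfg, seed=200, role="dam_control")
        out = wilcoxon_site(a["ipd"].to_numpy(), b["ipd"].to_numpy())
        assert out.p_value > 0.01


class TestLcms:
    def test_noiseless_identity(self):
        from damscan.assays import mea_fraction

        peaks = d.simulate_lcms_run(0.37, 0.0, 3, seed=1)
        assert mea_fraction(peaks, "sample") == pytest.approx(0.37, abs=1e-12)

    def test_dam_control_has_zero_mea_area(self):
        peaks = d.simulate_lcms_run(0.0, 0.05, 3, seed=2)
        assert (peaks.loc[peaks["analyte"] == "meA", "peak_area"] == 0).all()

    def test_mean_recovery_within_delta_method_bound(self):
        from damscan.assays import mea_fraction

        peaks = d.simulate_lcms_run(0.5, 0.05, 9, seed=3)
        recovered = mea_fraction(peaks, "sample")
        assert abs(recovered - 0.5) < 3 * (0.05 / np.sqrt(9)) * 0.5

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            d.simulate_lcms_run(1.5, 0.0, 3, seed=1)


class TestQpcr:
    def test_fold_one_noiseless_gives_identical_ct(self):
        plate = d.simulate_qpcr_plate({"dnaE": 1.0}, 0.0, seed=1)
        wide = plate.pivot_table(index=["time_h", "replicate"], columns="strain", values="ct")
        assert (wide["WT"] == wide["dam"]).all()

    def test_fold_four_noiseless_gives_delta_ct_two(self):
        plate = d.simulate_qpcr_plate({"nanC": 4.0}, 0.0, seed=1)
        at72 = plate[plate["time_h"] == 72.0]
        dct = at72[at72["strain"] == "dam"]["ct"].iloc[0] - at72[at72["strain"] == "WT"]["ct"].iloc[0]
        assert dct == pytest.approx(2.0, abs=1e-12)

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            d.simulate_qpcr_plate({"x": 0.0}, 0.0, seed=1)

    def test_fold_estimator_unbiased_over_many_plates(self):
        from damscan.assays import relative_expression

        folds = []
        for s in range(400):
            plate = d.simulate_qpcr_plate({"g": 4.0}, 0.1, seed=s)
            fold, _, _ = relative_expression(plate, "g", 72.0)
            folds.append(fold)
        mean = np.mean(folds)
        mc_se = np.std(folds, ddof=1) / np.sqrt(len(folds))
        assert abs(mean - 4.0) < 3 * mc_se + 0.02  # log-normal Jensen slack


class TestWriters:
    def test_overwrite_flag_respected(self, tmp_path, small_timecourse):
        path = tmp_path / "truth.tsv"
        write_table(small_timecourse.truths, path)
        with pytest.raises(FileExistsError):
            write_table(small_timecourse.truths, path)
        write_table(small_timecourse.truths, path, overwrite=True)

    def test_fasta_roundtrip(self, tmp_path, small_timecourse):
        path = tmp_path / "g.fasta"
        write_genome_fasta(small_timecourse.genome, path)
        back = d.read_fasta(path)[0]
        assert back.residues == small_timecourse.genome.residues
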