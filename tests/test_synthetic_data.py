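import numpy as np
import pandas as pd
import pytest

from tfcoverage import WorldConfig, generate_world, gini, load_world, write_world
from tfcoverage.coverage import intersect_any, make_promoter_windows
from tfcoverage.inventory import experiment_counts
from tfcoverage.synthetic_data import (PlantingError, generate_expression,
                                       generate_metadata, generate_peaks,
                                       generate_tss, class_map, tf_names)


def _cfg(**kw):
    base = dict(n_tfs=20, n_cell_types=10, n_classes=4, n_experiments=100,
                n_tss=50, n_snps=50, peaks_per_experiment=10, seed=0)
    base.update(kw)
    return WorldConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"pi_expressed": 1.5}, {"mu_low": 5.0, "mu_high": 1.0},
        {"tss_enrichment": -0.1}, {"n_tss": 5, "n_tfs": 20},
        {"genome": (("chr1", 100),), "peak_width": 200},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            _cfg(**kw)

    def test_round_trips_through_dict(self):
        cfg = _cfg(seed=9)
        assert WorldConfig.from_dict(cfg.to_dict()) == cfg


class TestMetadata:
    def test_uniform_attachment_has_low_gini(self):
        ginis = []
        for seed in range(20):
            cfg = _cfg(n_tfs=10, n_experiments=500, attachment_strength=0.0,
                       seed=300 + seed)
            meta = generate_metadata(cfg)
            counts = experiment_counts(meta, by="tf",
                                       universe=tf_names(cfg))
            ginis.append(gini(counts.to_numpy()))
        assert np.mean(ginis) < 0.3

    def test_strong_attachment_has_high_gini(self):
        ginis = []
        for seed in range(20):
            cfg = _cfg(n_tfs=10, n_experiments=500, attachment_strength=5.0,
                       seed=300 + seed)
            meta = generate_metadata(cfg)
            counts = experiment_counts(meta, by="tf",
                                       universe=tf_names(cfg))
            ginis.append(gini(counts.to_numpy()))
        assert np.mean(ginis) > 0.6

    def test_same_seed_byte_identical(self):
        cfg = _cfg(seed=5)
        a, b = generate_metadata(cfg), generate_metadata(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_dates_within_configured_years(self):
        cfg = _cfg(years=(2010, 2012))
        years = generate_metadata(cfg)["deposit_date"].dt.year
        assert years.between(2010, 2012).all()


class TestExpression:
    def test_zero_sigma_values_are_exactly_component_means(self):
        cfg = _cfg(sigma=0.0, mu_low=0.0, mu_high=4.0)
        expr, truth = generate_expression(cfg)
        vals = np.unique(expr.to_numpy())
        np.testing.assert_allclose(np.sort(vals), [1.0, np.exp(4.0)])
        high = expr.to_numpy() > 2.0
        gi, ci = np.nonzero(high)
        got = {(expr.index[i], expr.columns[j]) for i, j in zip(gi, ci)}
        assert got == set(truth)

    def test_pi_one_has_no_low_component(self):
        cfg = _cfg(pi_expressed=1.0, sigma=0.0)
        expr, truth = generate_expression(cfg)
        assert (expr.to_numpy() == np.exp(cfg.mu_high)).all()
        assert len(truth) == expr.size

    def test_stepminer_recovery_at_four_sigma_separation(self):
        # separation (mu_high - mu_low)/sigma = 4 -> per-pair accuracy >= .95
        from tfcoverage import call_expression
        total = correct = 0
        for seed in range(10):
            cfg = _cfg(n_tfs=15, n_cell_types=25, n_tss=40, mu_low=0.0,
                       mu_high=4.0, sigma=1.0, seed=500 + seed)
            expr, truth = generate_expression(cfg)
            tfs = tf_names(cfg)
            res = call_expression(expr.loc[tfs])
            calls = res.calls.fillna(False).astype(bool)
            truth_tf = {(g, c) for g, c in truth if g in set(tfs)}
            for tf in tfs:
                for cl in expr.columns:
                    total += 1
                    correct += (bool(calls.loc[tf, cl])
                                == ((tf, cl) in truth_tf))
        assert correct / total >= 0.95


class TestPeaks:
    def test_full_enrichment_single_tss_all_peaks_overlap(self):
        cfg = _cfg(n_tfs=4, n_tss=4, n_cell_types=4, n_experiments=20,
                   tss_enrichment=1.0, pi_expressed=1.0,
                   genome=(("chr1", 50_000),))
        meta = generate_metadata(cfg)
        tss = generate_tss(cfg).iloc[:1]
        _, truth = generate_expression(cfg)
        # restrict truth to the single gene so all enriched peaks target it
        truth1 = frozenset(p for p in truth if p[0] == tss["gene"].iloc[0])
        peaks = generate_peaks(cfg, meta, tss, truth1)
        windows = make_promoter_windows(tss, flank=cfg.flank)
        for df in peaks.values():
            assert intersect_any(windows, df).all() or len(df) == 0
            assert intersect_any(df, windows).all()

    def test_zero_enrichment_background_overlap_rate(self):
        cfg = _cfg(n_tfs=5, n_tss=5, n_cell_types=5, n_experiments=100,
                   tss_enrichment=0.0, peaks_per_experiment=20,
                   genome=(("chr1", 1_000_000),), seed=8)
        meta = generate_metadata(cfg)
        tss = generate_tss(cfg)
        _, truth = generate_expression(cfg)
        peaks = generate_peaks(cfg, meta, tss, truth)
        windows = make_promoter_windows(tss, flank=cfg.flank)
        all_peaks = pd.concat(peaks.values(), ignore_index=True)
        frac = intersect_any(all_peaks, windows).mean()
        # a random peak overlaps a window iff its start falls within
        # ~(window + peak width) bp of a TSS
        n_peaks = len(all_peaks)
        p_hit = min(1.0, 5 * (2 * cfg.flank + 1 + cfg.peak_width) / 1_000_000)
        sd = np.sqrt(p_hit * (1 - p_hit) / n_peaks)
        assert abs(frac - p_hit) <= 4 * sd + 1e-3

    def test_zero_peaks_per_experiment_gives_empty_beds(self):
        cfg = _cfg(peaks_per_experiment=0)
        w = generate_world(cfg)
        assert all(len(df) == 0 for df in w.peaks.values())
        from tfcoverage import gwas_snp_cover_ratio
        r = gwas_snp_cover_ratio(w.snps, w.peaks, w.metadata,
                                 sorted(set(w.class_map))[0], level="class",
                                 year=2030)
        assert r.ratio == 0.0

    def test_tf_specific_mode_repeated_experiments_add_nothing(self):
        cfg = _cfg(tf_specific_peaks=True)
        w = generate_world(cfg)
        by_tf = w.metadata.groupby("antigen")["experiment_id"].apply(list)
        for tf, ids in by_tf.items():
            if len(ids) > 1:
                pd.testing.assert_frame_equal(w.peaks[ids[0]],
                                              w.peaks[ids[1]])


class TestDegAndGems:
    def test_planted_gems_satisfy_all_predicates(self, small_world):
        w = small_world
        cfg = w.config
        measured = set(zip(w.metadata["antigen"],
                           w.metadata["cell_type_class"]))
        deg_max = w.deg.groupby(["tf", "sample"])["n_deg"].max()
        for tf, cls in w.truth.planted_gems:
            assert (tf, cls) in w.truth.expressed_tf_class
            assert (tf, cls) not in measured
            assert tf in set(w.markers["tf"])
            assert deg_max[(tf, cls)] > cfg.deg_threshold

    def test_null_shift_pvalues_are_calibrated(self):
        # delta = 0: two-sided Wilcoxon rejects at ~ alpha
        from tfcoverage import compare_deg_groups
        from tfcoverage.synthetic_data import (generate_deg_and_markers,
                                               generate_expression,
                                               generate_metadata)
        rejections = n_valid = 0
        for seed in range(200):
            cfg = _cfg(n_tfs=40, marker_shift=0.0, n_planted_gems=0,
                       seed=7000 + seed)
            meta = generate_metadata(cfg)
            _, truth = generate_expression(cfg)
            deg, _, _, marker_tfs = generate_deg_and_markers(cfg, meta, truth)
            if not marker_tfs or len(marker_tfs) == cfg.n_tfs:
                continue
            res = compare_deg_groups(deg, "marker_vs_nonmarker",
                                     marker_tfs=marker_tfs)
            n_valid += 1
            rejections += res.test.p_value < 0.05
        assert abs(rejections / n_valid - 0.05) <= 0.03

    def test_infeasible_planting_raises(self):
        # 1 TF, 1 cell type, plenty of experiments: every expressed pair
        # is measured, so nothing can be planted
        cfg = _cfg(n_tfs=1, n_cell_types=1, n_classes=1, n_tss=2,
                   n_experiments=50, pi_expressed=1.0, n_planted_gems=1)
        with pytest.raises(PlantingError):
            generate_world(cfg)


class TestWorldDeterminismAndRoundTrip:
    def test_same_seed_full_world_identical(self):
        cfg = _cfg(seed=123)
        a, b = generate_world(cfg), generate_world(cfg)
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.deg, b.deg)
        assert a.truth.planted_gems == b.truth.planted_gems
        for e in a.peaks:
            pd.testing.assert_frame_equal(a.peaks[e], b.peaks[e])

    def test_write_then_load_preserves_world(self, tmp_path, small_world):
        write_world(small_world, tmp_path / "w")
        back = load_world(tmp_path / "w")
        assert back.config == small_world.config
        pd.testing.assert_frame_equal(back.metadata, small_world.metadata)
        assert back.truth.planted_gems == small_world.truth.planted_gems
        assert set(back.peaks) == set(small_world.peaks)
        np.testing.assert_allclose(back.expression.to_numpy(),
                                   small_world.expression.to_numpy(),
                                   atol=5e-7)

    def test_write_twice_byte_identical(self, tmp_path, small_world):
        write_world(small_world, tmp_path / "a")
        write_world(small_world, tmp_path / "b")
        for rel in ("metadata.tsv", "expression.tsv", "deg.tsv",
                    "manifest.yaml", "peaks/EXP000001.bed"):
            assert (tmp_path / "a" / rel).read_bytes() == \
                (tmp_path / "b" / rel).read_bytes()
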