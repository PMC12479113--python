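import numpy as np
import pandas as pd
import pytest

from tfcoverage import (gwas_snp_cover_ratio, intersect_any,
                        make_promoter_windows, reg_tf_cover_ratio,
                        top_quartile_genes)
from tfcoverage.coverage import gwas_series, reg_tf_series

from conftest import random_intervals


def per_base_overlap(queries, peaks):
    """Oracle: explicit base-set intersection per chromosome."""
    covered = {}
    for r in peaks.itertuples(index=False):
        covered.setdefault(r.chrom, set()).update(range(r.start, r.end))
    return np.array([bool(covered.get(q.chrom, set())
                          & set(range(q.start, q.end)))
                     for q in queries.itertuples(index=False)])


class TestPromoterWindows:
    def test_standard_window(self):
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [1000], "gene": ["G"]})
        w = make_promoter_windows(tss, flank=500)
        assert (w.loc[0, "start"], w.loc[0, "end"]) == (499, 1500)
        assert w.loc[0, "end"] - w.loc[0, "start"] == 1001

    def test_clipped_at_chromosome_start(self):
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "gene": ["G"]})
        w = make_promoter_windows(tss, flank=500)
        assert (w.loc[0, "start"], w.loc[0, "end"]) == (0, 600)

    def test_zero_flank_is_single_base(self):
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [50], "gene": ["G"]})
        w = make_promoter_windows(tss, flank=0)
        assert (w.loc[0, "start"], w.loc[0, "end"]) == (49, 50)


class TestIntersectAny:
    def test_contained_peak_overlaps(self):
        q = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        p = pd.DataFrame({"chrom": ["chr1"], "start": [150], "end": [160]})
        assert intersect_any(q, p).tolist() == [True]

    def test_abutting_half_open_does_not_overlap(self):
        q = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        p = pd.DataFrame({"chrom": ["chr1"], "start": [200], "end": [300]})
        assert intersect_any(q, p).tolist() == [False]

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(77)
        q = random_intervals(rng, 200)
        p = random_intervals(rng, 200)
        np.testing.assert_array_equal(intersect_any(q, p),
                                      per_base_overlap(q, p))


class TestTopQuartile:
    def test_distinct_values_take_top(self):
        s = pd.Series(range(8), index=[f"g{i}" for i in range(8)])
        assert set(top_quartile_genes(s)) == {"g7", "g6"}

    def test_ceiling_rule(self):
        s = pd.Series([5, 4, 3, 2, 1], index=list("abcde"))
        assert top_quartile_genes(s) == ["a", "b"]  # ceil(1.25) = 2

    def test_ties_break_by_symbol_deterministically(self):
        s = pd.Series([9, 5, 5, 1], index=["d", "c", "a", "b"])
        first = top_quartile_genes(s, fraction=0.5)
        assert first == ["d", "a"]
        assert top_quartile_genes(s, fraction=0.5) == first

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            top_quartile_genes(pd.Series([1, 2, 3], index=list("abc")))


def _mini_world():
    """4 genes for line L1 (top-25% => 1 gene per 4) -- built by hand."""
    expr = pd.DataFrame(
        {"L1": [10.0, 8.0, 6.0, 4.0, 3.0, 2.0, 1.0, 0.5]},
        index=[f"g{i}" for i in range(8)])
    tss = pd.DataFrame({"chrom": "chr1",
                        "start": [1000 * (i + 1) for i in range(8)],
                        "end": [1000 * (i + 1) + 1 for i in range(8)],
                        "gene": [f"g{i}" for i in range(8)]})
    meta = pd.DataFrame({
        "experiment_id": ["E1", "E2"],
        "antigen": ["A", "B"],
        "cell_type": ["L1", "L1"],
        "cell_type_class": ["C1", "C1"],
        "deposit_date": pd.to_datetime(["2010-01-01", "2015-01-01"]),
    })
    return expr, tss, meta


class TestRegTfCoverRatio:
    def test_three_of_four_covered(self):
        expr, tss, meta = _mini_world()
        # top 25% of 8 genes = g0, g1; cover only g0's window
        peaks = {"E1": pd.DataFrame({"chrom": ["chr1"], "start": [950],
                                     "end": [1050]})}
        # use 4 genes so the quartile is 1 gene, then widen: use fraction 0.5
        r = reg_tf_cover_ratio(expr, tss, peaks, meta, "L1", 2020,
                               top_fraction=0.5)
        assert r.denominator == 4
        assert r.numerator == 1
        assert r.ratio == pytest.approx(0.25)

    def test_hand_ratio_three_quarters(self):
        expr, tss, meta = _mini_world()
        peaks = {"E1": pd.DataFrame({"chrom": "chr1",
                                     "start": [950, 1950, 2950],
                                     "end": [1050, 2050, 3050]})}
        r = reg_tf_cover_ratio(expr, tss, peaks, meta, "L1", 2020,
                               top_fraction=0.5)
        assert (r.numerator, r.denominator) == (3, 4)
        assert r.ratio == pytest.approx(0.75)

    def test_no_experiments_before_year_gives_zero(self):
        expr, tss, meta = _mini_world()
        peaks = {"E1": pd.DataFrame({"chrom": ["chr1"], "start": [950],
                                     "end": [1050]})}
        r = reg_tf_cover_ratio(expr, tss, peaks, meta, "L1", 2005)
        assert r.ratio == 0.0

    def test_absent_cell_line_rejected(self):
        expr, tss, meta = _mini_world()
        with pytest.raises(KeyError):
            reg_tf_cover_ratio(expr, tss, {}, meta, "L9", 2020)

    def test_matches_brute_force_on_synthetic_world(self, small_world):
        w = small_world
        line = w.metadata["cell_type"].value_counts().index[0]
        year = 2015
        r = reg_tf_cover_ratio(w.expression, w.tss, w.peaks, w.metadata,
                               line, year)
        genes = top_quartile_genes(w.expression[line])
        meta = w.metadata
        ids = meta["experiment_id"][
            (meta["cell_type"] == line)
            & (pd.to_datetime(meta["deposit_date"]).dt.year <= year)]
        pooled = pd.concat([w.peaks[e] for e in ids], ignore_index=True)
        windows = make_promoter_windows(w.tss[w.tss["gene"].isin(genes)])
        hits = per_base_overlap(windows, pooled)
        covered = {g for g, h in zip(windows["gene"], hits) if h}
        assert r.numerator == len(covered)
        assert r.denominator == len(genes)


class TestGwasCoverRatio:
    def _snps(self, n=10):
        return pd.DataFrame({"rsid": [f"rs{i}" for i in range(n)],
                             "chrom": "chr1",
                             "pos": [100 * (i + 1) for i in range(n)],
                             "start": [100 * (i + 1) - 1 for i in range(n)],
                             "end": [100 * (i + 1) for i in range(n)]})

    def test_three_of_ten(self):
        _, _, meta = _mini_world()
        snps = self._snps()
        peaks = {"E1": pd.DataFrame({"chrom": ["chr1"], "start": [50],
                                     "end": [350]})}  # covers rs0..rs2
        r = gwas_snp_cover_ratio(snps, peaks, meta, "C1", level="class",
                                 year=2020)
        assert (r.numerator, r.denominator) == (3, 10)
        assert r.ratio == pytest.approx(0.3)

    def test_year_before_first_experiment_is_zero(self):
        _, _, meta = _mini_world()
        peaks = {"E1": pd.DataFrame({"chrom": ["chr1"], "start": [50],
                                     "end": [350]})}
        r = gwas_snp_cover_ratio(self._snps(), peaks, meta, "C1",
                                 level="class", year=2005)
        assert r.ratio == 0.0

    def test_empty_snp_table_rejected(self):
        _, _, meta = _mini_world()
        with pytest.raises(ValueError):
            gwas_snp_cover_ratio(self._snps(0), {}, meta, "C1", year=2020)

    def test_matches_per_snp_oracle_on_synthetic_world(self, small_world):
        w = small_world
        cls = w.metadata["cell_type_class"].value_counts().index[0]
        year = 2014
        r = gwas_snp_cover_ratio(w.snps, w.peaks, w.metadata, cls,
                                 level="class", year=year)
        meta = w.metadata
        ids = meta["experiment_id"][
            (meta["cell_type_class"] == cls)
            & (pd.to_datetime(meta["deposit_date"]).dt.year <= year)]
        pooled = pd.concat([w.peaks[e] for e in ids], ignore_index=True)
        np.testing.assert_array_equal(
            r.covered.to_numpy(), per_base_overlap(w.snps, pooled))


class TestAnnualSeries:
    def test_single_year_world_is_step_function(self):
        expr, tss, meta = _mini_world()
        meta = meta.assign(deposit_date=pd.Timestamp("2012-06-01"))
        peaks = {"E1": pd.DataFrame({"chrom": ["chr1"], "start": [950],
                                     "end": [1050]}),
                 "E2": pd.DataFrame({"chrom": ["chr1"], "start": [1950],
                                     "end": [2050]})}
        s = reg_tf_series(expr, tss, peaks, meta, "L1",
                          range(2010, 2016), top_fraction=0.5)
        assert s.ratios[:2].tolist() == [0.0, 0.0]
        assert (s.ratios[2:] == s.ratios[2]).all()
        assert s.ratios[2] == pytest.approx(0.5)

    def test_monotone_and_split_invariant(self, small_world):
        w = small_world
        cls = w.metadata["cell_type_class"].value_counts().index[0]
        years = range(2005, 2024)
        s = gwas_series(w.snps, w.peaks, w.metadata, cls, years,
                        level="class")
        assert (np.diff(s.ratios) >= 0).all()
        assert ((0 <= s.ratios) & (s.ratios <= 1)).all()
        # splitting each peak file in two leaves the series unchanged
        split = {}
        for e, df in w.peaks.items():
            half = len(df) // 2
            split[e + "a"] = df.iloc[:half]
            split[e + "b"] = df.iloc[half:]
        meta2 = pd.concat([w.metadata.assign(
            experiment_id=w.metadata["experiment_id"] + suf)
            for suf in ("a", "b")], ignore_index=True)
        s2 = gwas_series(w.snps, split, meta2, cls, years, level="class")
        np.testing.assert_array_equal(s.numerators, s2.numerators)

    def test_irrelevant_experiment_leaves_series_unchanged(self, small_world):
        w = small_world
        cls = w.metadata["cell_type_class"].value_counts().index[0]
        years = range(2005, 2024)
        base = gwas_series(w.snps, w.peaks, w.metadata, cls, years,
                           level="class")
        extra_meta = pd.concat([w.metadata, pd.DataFrame({
            "experiment_id": ["EXTRA"], "antigen": ["TFX"],
            "cell_type": [w.metadata["cell_type"].iloc[0]],
            "cell_type_class": [cls],
            "deposit_date": [pd.Timestamp("2006-01-01")]})],
            ignore_index=True)
        peaks = dict(w.peaks)
        peaks["EXTRA"] = pd.DataFrame({"chrom": ["chrZ"], "start": [0],
                                       "end": [10]})  # overlaps nothing
        s2 = gwas_series(w.snps, peaks, extra_meta, cls, years, level="class")
        np.testing.assert_array_equal(base.numerators, s2.numerators)
        # an experiment covering everything drives the ratio to 1
        peaks["EXTRA"] = pd.DataFrame(
            {"chrom": [c for c, _ in w.config.genome], "start": 0,
             "end": [n for _, n in w.config.genome]})
        s3 = gwas_series(w.snps, peaks, extra_meta, cls, years, level="class")
        assert (s3.ratios[1:] == 1.0).all()

    def test_replay_from_stored_parts_is_identical(self, small_world):
        w = small_world
        cls = w.metadata["cell_type_class"].value_counts().index[0]
        s = gwas_series(w.snps, w.peaks, w.metadata, cls, range(2005, 2024),
                        level="class")
        frame = s.to_frame()
        np.testing.assert_allclose(
            frame["numerator"] / frame["denominator"], s.ratios)
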