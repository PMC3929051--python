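"""Fixation-index tests; the oracle is a straight-line scalar
transcription of the corrected-estimator formulas, kept independent of
the vectorised implementation path."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bovscan.fst import (
    ScanResult,
    annotate_regions,
    call_outlier_regions,
    fst_profile,
    genomewide_fst,
    nei_chesser_locus,
    one_vs_rest_profiles,
    quantile_thresholds,
    scan,
    window_average,
)
from bovscan.genotype import MISSING
from bovscan.simulate import (
    SelectedBlock,
    SimulationConfig,
    expected_gst,
    simulate_panel,
)

from conftest import make_gm


def fst_oracle(counts):
    """Independent plain-Python evaluation of the five formulas."""
    counts = [c for c in counts if sum(c) > 0]
    s = len(counts)
    ns = [a + b + c for a, b, c in counts]
    n_tilde = s / sum(1.0 / n for n in ns)
    xs = [(het + 2 * hom_b) / (2.0 * n) for (_, het, hom_b), n in zip(counts, ns)]
    h_obs = sum(het / n for (_, het, _), n in zip(counts, ns)) / s
    mean_sum_x2 = sum(x * x + (1 - x) * (1 - x) for x in xs) / s
    h_s = (n_tilde / (n_tilde - 1.0)) * (1.0 - mean_sum_x2 - h_obs / (2 * n_tilde))
    xbar = sum(xs) / s
    h_t = (
        1.0
        - (xbar * xbar + (1 - xbar) * (1 - xbar))
        + h_s / (n_tilde * s)
        - h_obs / (2 * n_tilde * s)
    )
    return (h_t - h_s) / h_t


def random_tables(rng, n_tables, s_range=(2, 6), n_range=(2, 200)):
    for _ in range(n_tables):
        s = int(rng.integers(*s_range, endpoint=True))
        table = []
        for _ in range(s):
            n = int(rng.integers(*n_range, endpoint=True))
            x = rng.dirichlet([1.0, 1.0, 1.0])
            counts = rng.multinomial(n, x)
            table.append(tuple(int(v) for v in counts))
        # ensure overall polymorphism so fst is defined
        if all(c[1] == 0 and c[2] == 0 for c in table):
            table[0] = (max(table[0][0] - 1, 0), table[0][1] + 1, table[0][2])
        if all(c[0] == 0 and c[1] == 0 for c in table):
            table[0] = (table[0][0], table[0][1] + 1, max(table[0][2] - 1, 0))
        yield table


class TestNeiChesserLocus:
    def test_fixed_difference_limit(self):
        c = nei_chesser_locus([(50, 0, 0), (0, 0, 50)])
        assert c.h_obs == 0.0
        assert c.h_s == 0.0
        assert c.h_t == pytest.approx(0.5, abs=1e-15)
        assert c.fst == 1.0

    def test_identical_pops_near_zero(self):
        c = nei_chesser_locus([(30, 40, 30), (30, 40, 30)])
        assert abs(c.fst) < 0.01  # small negative allowed

    def test_hand_computed_example(self):
        table = [(30, 40, 30), (10, 40, 50)]
        c = nei_chesser_locus(table)
        assert c.fst == pytest.approx(fst_oracle(table), abs=1e-12)

    def test_components_consistent(self):
        table = [(12, 20, 8), (5, 15, 30), (22, 3, 1)]
        c = nei_chesser_locus(table)
        assert c.s == 3
        assert c.n_tilde <= np.mean(c.n_i) + 1e-12  # harmonic <= arithmetic
        assert 0.0 <= c.h_obs <= 1.0
        assert c.h_s <= c.h_t + 1e-12
        assert c.fst == pytest.approx((c.h_t - c.h_s) / c.h_t, abs=1e-14)

    def test_empty_subpop_dropped(self):
        with_empty = nei_chesser_locus([(30, 40, 30), (0, 0, 0), (10, 40, 50)])
        without = nei_chesser_locus([(30, 40, 30), (10, 40, 50)])
        assert with_empty.s == 2
        assert with_empty.fst == pytest.approx(without.fst, abs=1e-14)

    def test_monomorphic_overall_nan(self):
        c = nei_chesser_locus([(20, 0, 0), (35, 0, 0)])
        assert np.isnan(c.fst)

    def test_one_populated_subpop_raises(self):
        with pytest.raises(ValueError, match=">=2"):
            nei_chesser_locus([(10, 5, 5), (0, 0, 0)])

    def test_oracle_equivalence_batch(self):
        rng = np.random.default_rng(123)
        for table in random_tables(rng, 200):
            got = nei_chesser_locus(table).fst
            want = fst_oracle(table)
            assert got == pytest.approx(want, abs=1e-12), table

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_allele_label_invariance(self, seed):
        rng = np.random.default_rng(seed)
        table = next(iter(random_tables(rng, 1)))
        flipped = [(c, b, a) for a, b, c in table]
        f1 = nei_chesser_locus(table).fst
        f2 = nei_chesser_locus(flipped).fst
        if np.isnan(f1):
            assert np.isnan(f2)
        else:
            assert f1 == pytest.approx(f2, abs=1e-12)


class TestProfiles:
    def test_profile_shape_and_nan_policy(self, five_breed_panel):
        gm, _ = five_breed_panel
        f = fst_profile(gm)
        assert f.shape == (gm.n_markers,)
        # NaN only at loci monomorphic overall
        mono = np.array([
            len(np.unique(gm.dosage[:, j][gm.dosage[:, j] != MISSING])) == 1
            for j in range(gm.n_markers)
        ])
        assert np.array_equal(np.isnan(f), mono)

    def test_single_group_raises(self, five_breed_panel):
        gm, _ = five_breed_panel
        with pytest.raises(ValueError, match=">=2 subpopulations"):
            fst_profile(gm, ["BREED1"])

    def test_pooled_grouping(self, five_breed_panel):
        gm, _ = five_breed_panel
        f = fst_profile(gm, {"dairy": ["BREED1", "BREED2"],
                             "beef": ["BREED3", "BREED4"]})
        assert np.isfinite(f).sum() > 0

    def test_unknown_breed_raises(self, five_breed_panel):
        gm, _ = five_breed_panel
        with pytest.raises(KeyError, match="NOPE"):
            fst_profile(gm, ["BREED1", "NOPE"])

    def test_closed_form_recovery_small(self):
        gm, _ = simulate_panel(
            SimulationConfig(n_breeds=5, n_per_breed=(50,) * 5, n_chromosomes=2,
                             n_markers_per_chromosome=1000, f_background=0.1,
                             seed=31)
        )
        assert genomewide_fst(gm) == pytest.approx(expected_gst(0.1, 5), abs=0.01)


class TestOneVsRest:
    def test_two_breeds_symmetric(self):
        gm, _ = simulate_panel(
            SimulationConfig(n_breeds=2, n_per_breed=(20, 30), n_chromosomes=1,
                             n_markers_per_chromosome=100, f_background=0.2, seed=2)
        )
        prof = one_vs_rest_profiles(gm)
        np.testing.assert_allclose(
            prof["BREED1"], prof["BREED2"], atol=1e-12, equal_nan=True
        )

    def test_breed_specific_signal(self):
        gm, truth = simulate_panel(
            SimulationConfig(
                n_breeds=5, n_per_breed=(40,) * 5, n_chromosomes=2,
                n_markers_per_chromosome=400, f_background=0.05,
                selected_blocks=(SelectedBlock(1, 160, 16, 0.8, (0,)),),
                seed=77,
            )
        )
        prof = one_vs_rest_profiles(gm)
        sel = truth.selected
        focal_mean = np.nanmean(prof["BREED1"][sel])
        other_means = [np.nanmean(prof[b][sel]) for b in
                       ("BREED2", "BREED3", "BREED4", "BREED5")]
        assert focal_mean > 3 * max(other_means)
        # the block overlaps the focal breed's outlier regions, and only its
        sel_pos = gm.marker_map["position_bp"].to_numpy()[sel]

        def overlaps_block(breed):
            res = scan(gm, fst_vector=prof[breed], width=8)
            regions = call_outlier_regions(res)
            chr1 = regions[regions["chromosome"] == "1"]
            return any(
                r.start_bp <= sel_pos.max() and sel_pos.min() <= r.end_bp
                for r in chr1.itertuples()
            )

        assert overlaps_block("BREED1")
        hits_others = sum(
            overlaps_block(b) for b in ("BREED2", "BREED3", "BREED4", "BREED5")
        )
        assert hits_others == 0

    def test_singleton_breed_raises(self):
        gm = make_gm(np.zeros((5, 4)), breeds=["A", "A", "A", "A", "B"])
        with pytest.raises(ValueError, match="fewer than 2"):
            one_vs_rest_profiles(gm)


class TestWindows:
    def map_for(self, chroms):
        return make_gm(np.zeros((2, len(chroms))), chromosome=chroms).marker_map

    def test_constant_vector(self):
        mm = self.map_for(["1"] * 10)
        for mode in ("non_overlapping_groups", "sliding_step1"):
            w = window_average(np.full(10, 0.1), mm, width=4, mode=mode)
            assert np.allclose(w["mean_fst"], 0.1)

    def test_groups_and_sliding_arithmetic(self):
        mm = self.map_for(["1"] * 4)
        v = np.array([0.1, 0.2, 0.3, 0.4])
        w = window_average(v, mm, width=2, mode="non_overlapping_groups")
        assert list(w["mean_fst"]) == pytest.approx([0.15, 0.35])
        w = window_average(v, mm, width=2, mode="sliding_step1")
        assert list(w["mean_fst"]) == pytest.approx([0.15, 0.25, 0.35])

    def test_no_cross_chromosome_window(self):
        mm = self.map_for(["1"] * 5 + ["2"] * 5)
        w = window_average(np.arange(10, dtype=float), mm, width=8)
        assert len(w) == 2
        assert list(w["chromosome"]) == ["1", "2"]
        assert list(w["n_snps"]) == [5, 5]

    def test_remainder_rule(self):
        mm = self.map_for(["1"] * 19)
        w = window_average(np.zeros(19), mm, width=8)
        # 19 = 8 + 8 + 3; remainder 3 < ceil(8/2) merges into previous
        assert list(w["n_snps"]) == [8, 11]
        mm = self.map_for(["1"] * 20)
        w = window_average(np.zeros(20), mm, width=8)
        assert list(w["n_snps"]) == [8, 8, 4]

    def test_nan_policy(self):
        mm = self.map_for(["1"] * 4)
        v = np.array([0.1, np.nan, 0.3, np.nan])
        w = window_average(v, mm, width=2)
        assert list(w["mean_fst"]) == pytest.approx([0.1, 0.3])
        assert list(w["n_finite"]) == [1, 1]
        w = window_average(np.full(4, np.nan), mm, width=2)
        assert len(w) == 0  # all-NaN windows dropped

    def test_width1_sliding_identity(self):
        mm = self.map_for(["1"] * 6)
        v = np.array([0.1, 0.5, np.nan, 0.2, 0.9, 0.0])
        w = window_average(v, mm, width=1, mode="sliding_step1")
        assert list(w["mean_fst"]) == pytest.approx([0.1, 0.5, 0.2, 0.9, 0.0])


class TestThresholds:
    def test_order_statistic_example(self):
        lo, hi = quantile_thresholds(np.arange(1.0, 101.0), 0.01, 0.99)
        assert hi == pytest.approx(99.01)
        assert lo == pytest.approx(1.99)

    def test_all_equal(self):
        lo, hi = quantile_thresholds(np.full(10, 0.3))
        assert lo == hi == pytest.approx(0.3)

    def test_bad_order_raises(self):
        with pytest.raises(ValueError):
            quantile_thresholds(np.arange(10.0), 0.9, 0.1)

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError):
            quantile_thresholds(np.array([0.1, np.nan]))


class TestRegions:
    def _result(self, means, chroms=None):
        n = len(means)
        chroms = chroms or ["1"] * n
        windows = pd.DataFrame(
            {
                "chromosome": chroms,
                "start_bp": np.arange(n) * 1000 + 1,
                "end_bp": np.arange(n) * 1000 + 900,
                "center_bp": np.arange(n) * 1000 + 450.0,
                "n_snps": [8] * n,
                "n_finite": [8] * n,
                "mean_fst": means,
                "marker_ids": ["x"] * n,
            }
        )
        return ScanResult(windows, 8, "non_overlapping_groups",
                          0.01, 0.99, t_low=-1.0, t_high=0.5)

    def test_no_outliers_empty(self):
        res = self._result([0.1] * 30)
        assert len(call_outlier_regions(res)) == 0

    def test_merge_logic(self):
        means = [0.1] * 25
        for i in (4, 5, 6, 20):
            means[i] = 0.9
        regions = call_outlier_regions(self._result(means))
        assert list(regions["n_windows"]) == [3, 1]
        assert regions.loc[0, "start_bp"] == 4 * 1000 + 1
        assert regions.loc[0, "end_bp"] == 6 * 1000 + 900

    def test_no_merge_across_chromosomes(self):
        means = [0.9, 0.9, 0.9, 0.9]
        regions = call_outlier_regions(self._result(means, ["1", "1", "2", "2"]))
        assert list(regions["n_windows"]) == [2, 2]

    def test_injected_block_recovered(self, messy_panel):
        gm, truth = messy_panel
        res = scan(gm, width=8)
        regions = call_outlier_regions(res)
        sel_pos = gm.marker_map["position_bp"].to_numpy()[truth.selected]
        cover = regions[
            (regions["chromosome"] == "2")
            & (regions["start_bp"] <= sel_pos.max())
            & (regions["end_bp"] >= sel_pos.min())
        ]
        assert len(cover) >= 1


class TestAnnotate:
    def _regions(self, rows):
        return pd.DataFrame(
            rows, columns=["chromosome", "start_bp", "end_bp",
                           "n_windows", "n_snps", "max_fst", "mean_fst"]
        )

    def test_overlap_reported(self):
        regions = self._regions([("6", 37_000_000, 38_760_000, 2, 16, 0.4, 0.3)])
        bed = pd.DataFrame(
            {"chromosome": ["6"], "start": [37_500_000], "end": [38_100_000],
             "name": ["GENE1"]}
        )
        out = annotate_regions(regions, bed)
        assert out.loc[0, "overlapping_intervals"] == "GENE1"

    def test_adjacent_half_open_no_overlap(self):
        regions = self._regions([("1", 1, 1000, 1, 8, 0.4, 0.3)])
        bed = pd.DataFrame(
            {"chromosome": ["1"], "start": [1000], "end": [1500], "name": ["G"]}
        )
        out = annotate_regions(regions, bed)
        assert out.loc[0, "overlapping_intervals"] == ""

    def test_matches_bruteforce_all_pairs(self):
        rng = np.random.default_rng(44)
        regions = self._regions([
            (str(rng.integers(1, 4)), int(a), int(a + rng.integers(1, 5000)),
             1, 8, 0.4, 0.3)
            for a in rng.integers(1, 100_000, size=30)
        ])
        bed = pd.DataFrame({
            "chromosome": [str(c) for c in rng.integers(1, 4, size=40)],
            "start": rng.integers(0, 100_000, size=40),
            "end": 0,
            "name": [f"g{i}" for i in range(40)],
        })
        bed["end"] = bed["start"] + rng.integers(1, 5000, size=40)
        out = annotate_regions(regions, bed)
        for idx, r in regions.iterrows():
            expect = sorted(
                b["name"] for _, b in bed.iterrows()
                if b["chromosome"] == r["chromosome"]
                and max(r["start_bp"] - 1, b["start"]) < min(r["end_bp"], b["end"])
            )
            got = sorted(x for x in out.loc[idx, "overlapping_intervals"].split(",") if x)
            assert got == expect

    def test_bed_file_roundtrip(self, tmp_path):
        bedfile = tmp_path / "genes.bed"
        bedfile.write_text("6\t37500000\t38100000\tGENE1\n")
        regions = self._regions([("6", 37_000_000, 38_760_000, 2, 16, 0.4, 0.3)])
        out = annotate_regions(regions, bedfile)
        assert out.loc[0, "overlapping_intervals"] == "GENE1"


class TestPermutationNull:
    def test_label_permutation_destroys_signal(self, messy_panel):
        gm, truth = messy_panel
        rng = np.random.default_rng(1)
        shuffled = gm.copy()
        shuffled.breeds = rng.permutation(shuffled.breeds)
        res = scan(shuffled, width=8)
        out = res.outlier_high
        # outlier rate is ~1% by construction of the quantile, and the
        # injected block is no longer preferentially flagged
        assert len(out) <= max(3, int(0.03 * len(res.windows)))
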