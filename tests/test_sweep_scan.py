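import numpy as np
import pandas as pd
import pytest

from ecosweep import (
    bh_qvalues,
    call_sweep_windows,
    empirical_thresholds,
    genes_in_regions,
    make_windows,
    merge_windows,
    permutation_fst,
)
from ecosweep.genotype_io import ValidationError

CONTRAST = ("semi_winter", ("winter", "spring"))
LAB = "semi_winter_vs_winter+spring"


def stats_frame(ratios, fsts):
    n = len(ratios)
    return pd.DataFrame({
        "chrom": "A01",
        "start": np.arange(n) * 10_000,
        "end": np.arange(n) * 10_000 + 100_000,
        f"pi_ratio_{LAB}": ratios,
        f"fst_{LAB}": fsts,
    })


class TestThresholds:
    def test_uniform_1_to_100(self):
        stats = stats_frame(np.arange(1.0, 101.0), np.arange(1.0, 101.0) / 200)
        thr = empirical_thresholds(stats, CONTRAST, tail=0.05)
        assert thr.pi_ratio_low == 5
        assert thr.pi_ratio_high == 96
        assert thr.fst_high == pytest.approx(96 / 200)

    def test_constant_fst_everyone_ties(self):
        stats = stats_frame(np.arange(1.0, 101.0), np.full(100, 0.3))
        thr = empirical_thresholds(stats, CONTRAST)
        assert thr.fst_high == 0.3
        called = call_sweep_windows(stats, thr, CONTRAST)
        # every window passes the FST cut; only the ratio tails restrict
        assert (called["selected_group"] != "").sum() == 10

    def test_half_tail_rejected(self):
        stats = stats_frame(np.arange(1.0, 101.0), np.arange(1.0, 101.0))
        with pytest.raises(ValidationError):
            empirical_thresholds(stats, CONTRAST, tail=0.5)

    def test_missing_windows_excluded(self):
        ratios = np.arange(1.0, 101.0)
        ratios[:50] = np.nan
        stats = stats_frame(ratios, np.arange(1.0, 101.0))
        thr = empirical_thresholds(stats, CONTRAST)
        assert thr.pi_ratio_low >= 51


class TestCallRule:
    def test_intersection_required(self):
        stats = stats_frame(np.arange(1.0, 101.0), np.arange(1.0, 101.0) / 200)
        thr = empirical_thresholds(stats, CONTRAST)
        called = call_sweep_windows(stats, thr, CONTRAST)
        sel = called["selected_group"].to_numpy()
        # high FST but mid-distribution ratio -> unselected
        mid = (called[f"pi_ratio_{LAB}"] > thr.pi_ratio_low) & \
              (called[f"pi_ratio_{LAB}"] < thr.pi_ratio_high)
        assert (sel[mid.to_numpy()] == "").all()

    def test_threshold_ties_inclusive(self):
        ratios = np.arange(1.0, 101.0)
        fsts = np.arange(1.0, 101.0) / 200
        stats = stats_frame(ratios, fsts)
        thr = empirical_thresholds(stats, CONTRAST)
        called = call_sweep_windows(stats, thr, CONTRAST)
        exact = called[(called[f"fst_{LAB}"] == thr.fst_high)
                       & (called[f"pi_ratio_{LAB}"] == thr.pi_ratio_high)]
        assert (exact["selected_group"] == "winter+spring").all() and len(exact) == 1

    def test_direction_convention(self):
        # left ratio tail (low pi in numerator) -> sweep in side A
        stats = stats_frame(np.arange(1.0, 101.0), np.arange(1.0, 101.0) / 200)
        thr = empirical_thresholds(stats, CONTRAST)
        called = call_sweep_windows(stats, thr, CONTRAST)
        low = called[called[f"pi_ratio_{LAB}"] <= thr.pi_ratio_low]
        assert set(low["selected_group"]) <= {"semi_winter", ""}

    def test_calls_invariant_under_monotone_fst_rescale(self):
        stats = stats_frame(np.arange(1.0, 101.0), np.arange(1.0, 101.0) / 200)
        thr = empirical_thresholds(stats, CONTRAST)
        called = call_sweep_windows(stats, thr, CONTRAST)
        stats2 = stats.copy()
        stats2[f"fst_{LAB}"] = np.expm1(stats2[f"fst_{LAB}"])  # strictly increasing map
        thr2 = empirical_thresholds(stats2, CONTRAST)
        called2 = call_sweep_windows(stats2, thr2, CONTRAST)
        assert (called["selected_group"] == called2["selected_group"]).all()


class TestMergeWindows:
    def _called(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "selected_group",
                                         f"fst_{LAB}", f"pi_ratio_{LAB}"])
        df.attrs["contrast"] = LAB
        return df

    def test_overlap_merges(self):
        out = merge_windows(self._called([
            ("A01", 0, 100_000, "semi_winter", 0.5, 0.1),
            ("A01", 10_000, 110_000, "semi_winter", 0.6, 0.05),
        ]))
        assert len(out) == 1
        assert (out.start.iloc[0], out.end.iloc[0]) == (0, 110_000)
        assert out.n_windows.iloc[0] == 2
        assert out.max_fst.iloc[0] == 0.6
        assert out.extreme_pi_ratio.iloc[0] == 0.05  # minimum for side-A sweeps

    def test_different_labels_not_merged(self):
        out = merge_windows(self._called([
            ("A01", 0, 100_000, "semi_winter", 0.5, 0.1),
            ("A01", 100_000, 200_000, "winter+spring", 0.5, 9.0),
        ]))
        assert len(out) == 2

    def test_span_arithmetic(self):
        out = merge_windows(self._called([
            ("A01", 0, 100_000, "semi_winter", 0.5, 0.1),
            ("A01", 10_000, 110_000, "semi_winter", 0.5, 0.1),
            ("A01", 500_000, 600_000, "semi_winter", 0.5, 0.1),
        ]))
        assert len(out) == 2
        # merged intervals [0,110k) and [500k,600k)
        assert out.span_bp.tolist() == [110_000, 100_000]
        assert out.span_bp.sum() == 210_000

    def test_output_sorted_disjoint(self):
        out = merge_windows(self._called([
            ("A01", 500_000, 600_000, "semi_winter", 0.5, 0.1),
            ("A01", 0, 100_000, "semi_winter", 0.5, 0.1),
            ("A02", 0, 100_000, "semi_winter", 0.5, 0.1),
        ]))
        for _, sub in out.groupby("selected_group"):
            sub = sub.sort_values(["chrom", "start"])
            assert (sub.groupby("chrom")["start"].diff().dropna() > 0).all()


class TestGenesInRegions:
    ANN = pd.DataFrame({
        "gene_id": ["g1", "g2", "g3", "g4", "g5"],
        "chrom": ["A01", "A01", "A01", "A01", "A02"],
        "start": [0, 90_000, 100_000, 250_000, 0],
        "end": [1_000, 101_000, 100_500, 260_000, 1_000],
        "strand": "+",
    })

    def test_bookended_gene_not_counted(self):
        regions = pd.DataFrame([{"chrom": "A01", "start": 1_000, "end": 90_000,
                                 "selected_group": "semi_winter"}])
        out, by_group = genes_in_regions(regions, self.ANN)
        assert out["genes"].iloc[0] == []  # g1 ends exactly at region start

    def test_hand_enumerated_overlap(self):
        regions = pd.DataFrame([
            {"chrom": "A01", "start": 0, "end": 100_000, "selected_group": "semi_winter"},
            {"chrom": "A01", "start": 200_000, "end": 300_000, "selected_group": "semi_winter"},
        ])
        out, by_group = genes_in_regions(regions, self.ANN)
        assert out["genes"].tolist() == [["g1", "g2"], ["g4"]]
        assert by_group["semi_winter"] == ["g1", "g2", "g4"]

    def test_gene_spanning_regions_deduplicated(self):
        regions = pd.DataFrame([
            {"chrom": "A01", "start": 0, "end": 95_000, "selected_group": "w"},
            {"chrom": "A01", "start": 95_000, "end": 300_000, "selected_group": "w"},
        ])
        _, by_group = genes_in_regions(regions, self.ANN)
        assert by_group["w"].count("g2") == 1


class TestBhQvalues:
    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q = bh_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert q.min() >= p.min()
        assert q.max() <= 1.0


class TestPermutationFst:
    def test_deterministic_and_add_one_bounds(self, tiny_scenario):
        g, samples = tiny_scenario.genotypes, tiny_scenario.samples
        windows = make_windows(tiny_scenario.config.chrom_lengths).head(30)
        r1 = permutation_fst(g, samples, windows, CONTRAST, n_perm=100, seed=5)
        r2 = permutation_fst(g, samples, windows, CONTRAST, n_perm=100, seed=5)
        pd.testing.assert_frame_equal(r1, r2)
        p = r1["perm_p"].dropna()
        assert (p >= 1 / 101 - 1e-12).all() and (p <= 1.0).all()
        assert r1.attrs["seed"] == 5

    def test_observed_above_all_gets_minimum_p(self, tiny_scenario):
        g, samples = tiny_scenario.genotypes, tiny_scenario.samples
        windows = make_windows(tiny_scenario.config.chrom_lengths)
        sweep = tiny_scenario.truth_sweeps.iloc[0]
        in_sweep = (windows.chrom == sweep.chrom) & (windows.start < sweep.end) \
            & (windows.end > sweep.start)
        res = permutation_fst(g, samples, windows[in_sweep], CONTRAST, n_perm=100, seed=2)
        # the planted sweep's differentiation exceeds any label permutation
        assert (res["perm_p"] <= 2 / 101).any()

    def test_too_few_permutations_rejected(self, tiny_scenario):
        g, samples = tiny_scenario.genotypes, tiny_scenario.samples
        windows = make_windows(tiny_scenario.config.chrom_lengths).head(5)
        with pytest.raises(ValidationError):
            permutation_fst(g, samples, windows, CONTRAST, n_perm=10, seed=1)
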