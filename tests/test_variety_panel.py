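"""Conservation, subgroup consensus, SNP profiles, saturation curves,
distance matrices, and core/distributed proportions."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import stats

from chromdyn.genome_io import BinGrid, BinnedTrack, GenomeIndex, Interval
from chromdyn.segmentation import Segmentation
from chromdyn.synthetic_data import SimConfig, simulate_panel, simulate_states
from chromdyn.variety_panel import (conserved_fraction, core_vs_distributed,
                                    epigenome_distance, saturation_curve,
                                    snp_profile, subgroup_switch,
                                    third_group_similarity)


def panel_from_arrays(arrays, n_states, bp_per_bin=200):
    n = len(next(iter(arrays.values())))
    grid = BinGrid(GenomeIndex({"chr1": n * bp_per_bin}), bp_per_bin)
    return {v: Segmentation(grid, np.asarray(a), n_states)
            for v, a in arrays.items()}


class TestConservedFraction:
    def test_identical_panel_exactly_one(self, rng):
        states = rng.integers(1, 6, size=2000)
        segs = panel_from_arrays({f"v{i}": states for i in range(5)}, 5)
        out = conserved_fraction(segs)
        occupied = np.unique(states)
        for s in occupied:
            assert out[f"state{s}"] == 1.0

    def test_fully_relabeled_variety_zeroes_changed_states(self):
        a = np.ones(100, dtype=int)
        b = np.full(100, 2, dtype=int)
        segs = panel_from_arrays({"v1": a, "v2": b}, 2)
        out = conserved_fraction(segs)
        assert out["state1"] == 0.0 and out["state2"] == 0.0

    def test_independent_panel_closed_form(self):
        # K=3, n=3 independent uniform panels: conserved bins of state s
        # ~ Binomial(N, K^-n); normalized by mean abundance N/K the
        # expectation is K^-(n-1) = 1/9
        rng = np.random.default_rng(0)
        N, K, n = 100_000, 3, 3
        segs = panel_from_arrays(
            {f"v{i}": rng.integers(1, K + 1, size=N) for i in range(n)}, K)
        out = conserved_fraction(segs)
        p = K ** -n
        sigma = np.sqrt(N * p * (1 - p)) / (N / K)
        assert np.allclose(out.to_numpy(), K ** -(n - 1), atol=3 * sigma)

    def test_single_variety_rejected(self):
        segs = panel_from_arrays({"v1": np.ones(10, dtype=int)}, 1)
        with pytest.raises(ValueError):
            conserved_fraction(segs)


class TestSubgroupSwitch:
    def test_planted_fixed_differences_recovered_exactly(self):
        cfg = SimConfig(chrom_lengths={"chr1": 400_000}, within_rate=0.0,
                        between_rate=0.0, n_fixed_differences=50)
        seg = simulate_states(None, cfg, seed=0)[cfg.tissues[0]]
        panel = simulate_panel(seg, cfg, seed=0)
        xian = [v for v, g in panel.subgroups.items() if g == "Xian"]
        geng = [v for v, g in panel.subgroups.items() if g == "Geng"]
        sw = subgroup_switch(panel.segmentations, xian, geng)
        assert np.array_equal(sw.consensus_bins, panel.fixed_bins)

    def test_identical_groups_empty(self, rng):
        states = rng.integers(1, 4, size=500)
        segs = panel_from_arrays({"a1": states, "a2": states,
                                  "b1": states}, 3)
        sw = subgroup_switch(segs, ["a1", "a2"], ["b1"])
        assert len(sw.consensus_bins) == 0

    def test_third_group_identical_to_a(self, rng):
        a = rng.integers(1, 4, size=500)
        b = a.copy()
        b[:50] = (a[:50] % 3) + 1          # differ on 50 bins
        segs = panel_from_arrays({"a1": a, "b1": b, "c1": a.copy()}, 3)
        sw = subgroup_switch(segs, ["a1"], ["b1"])
        sim_a, sim_b = third_group_similarity(segs, sw, ["c1"])
        assert sim_a == 1.0 and sim_b == 0.0

    def test_matrix_normalization(self, rng):
        a = np.ones(100, dtype=int)
        b = np.ones(100, dtype=int)
        b[:10] = 2                          # 10 consensus 1->2 bins
        segs = panel_from_arrays({"a1": a, "b1": b}, 2)
        sw = subgroup_switch(segs, ["a1"], ["b1"])
        # frac(state1 in A) = 1.0 -> matrix = 10 / (1.0 * 100)
        assert sw.matrix[0, 1] == pytest.approx(0.1)

    def test_overlapping_groups_rejected(self, rng):
        segs = panel_from_arrays({"a": np.ones(10, dtype=int)}, 1)
        with pytest.raises(ValueError):
            subgroup_switch(segs, ["a"], ["a"])


class TestSnpProfile:
    def test_uniform_snps_flat_profile(self):
        rng = np.random.default_rng(0)
        rate = 0.01
        L = 1_000_000
        snps = {"chr1": np.sort(rng.choice(
            L, size=rng.poisson(rate * L), replace=False))}
        peaks = [Interval("chr1", s, s + 2000)
                 for s in range(10_000, 900_000, 30_000)]
        prof = snp_profile(snps, peaks)
        n_per_unit = len(peaks) * 10 * rate
        sigma = np.sqrt(n_per_unit) / (len(peaks) * 10)
        assert np.allclose(prof.left_flank, rate, atol=4 * sigma)
        assert np.allclose(prof.body, rate, atol=4 * sigma)

    def test_snps_only_inside_peaks(self):
        peaks = [Interval("chr1", 10_000, 12_000)]
        snps = {"chr1": np.arange(10_100, 11_900, 50)}
        prof = snp_profile(snps, peaks)
        assert prof.left_flank.sum() == 0
        assert prof.right_flank.sum() == 0
        assert prof.body.sum() > 0

    def test_planted_flank_enrichment_rising_trend(self):
        cfg = SimConfig(chrom_lengths={"chr1": 2_000_000},
                        snp_flank_factor=3.0)
        seg = simulate_states(None, cfg, seed=2)[cfg.tissues[0]]
        panel = simulate_panel(seg, cfg, seed=2)
        from chromdyn.synthetic_data import panel_mark_regions
        regions = panel_mark_regions(panel, cfg, "H3K9me2")
        peaks = [r for r in regions[panel.varieties[0]] if len(r) >= 600]
        prof = snp_profile(panel.snps, peaks)
        # density should rise toward the peak across the left flank
        x = np.arange(len(prof.left_flank))
        slope = stats.linregress(x, prof.left_flank).slope
        assert slope > 0

    def test_empty_peaks_rejected(self):
        with pytest.raises(ValueError):
            snp_profile({}, [])


class TestSaturation:
    def grid(self, n_bins=1000):
        return BinGrid(GenomeIndex({"chr1": n_bins * 200}), 200)

    def test_identical_varieties_flat(self):
        grid = self.grid()
        regs = [Interval("chr1", 0, 40_000)]
        by_var = {f"v{i}": list(regs) for i in range(4)}
        diff = pd.DataFrame(0.0, index=by_var, columns=by_var)
        out = saturation_curve(by_var, grid, diff, n_orders=5, seed=0)
        assert np.allclose(out["accumulation_mean"], 0.2)
        assert np.allclose(out["differential_mean"][1:], 0.0)

    def test_disjoint_regions_strictly_increasing(self):
        grid = self.grid()
        by_var = {f"v{i}": [Interval("chr1", i * 40_000,
                                     (i + 1) * 40_000)]
                  for i in range(4)}
        out = saturation_curve(by_var, grid, n_orders=3, seed=0)
        acc = out["accumulation_mean"].to_numpy()
        assert np.all(np.diff(acc) > 0)
        assert np.allclose(acc, [0.2, 0.4, 0.6, 0.8])

    def test_shared_core_private_regions_monotone(self, rng):
        grid = self.grid()
        core = [Interval("chr1", 0, 20_000)]
        by_var = {}
        for i in range(5):
            s = int(rng.integers(30_000, 190_000))
            by_var[f"v{i}"] = core + [Interval("chr1", s, s + 5000)]
        out = saturation_curve(by_var, grid, n_orders=10, seed=1)
        assert np.all(np.diff(out["accumulation_mean"]) >= 0)


class TestEpigenomeDistance:
    def track(self, vals):
        grid = BinGrid(GenomeIndex({"chr1": len(vals) * 200}), 200)
        return BinnedTrack(grid, np.asarray(vals, dtype=float))

    def test_identical_tracks_zero(self):
        t = self.track([1, 2, 3, 4])
        D = epigenome_distance({"a": t, "b": self.track([1, 2, 3, 4])})
        assert D.loc["a", "b"] == 0.0

    def test_bray_curtis_disjoint_is_one(self):
        D = epigenome_distance({"a": self.track([1, 0]),
                                "b": self.track([0, 1])})
        assert D.loc["a", "b"] == pytest.approx(1.0)

    def test_symmetric_zero_diagonal(self, rng):
        tracks = {f"v{i}": self.track(rng.poisson(20, size=50))
                  for i in range(4)}
        D = epigenome_distance(tracks)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_subgroup_structure_recovered(self):
        cfg = SimConfig(chrom_lengths={"chr1": 1_000_000},
                        within_rate=0.02, between_rate=0.25)
        seg = simulate_states(None, cfg, seed=4)[cfg.tissues[0]]
        panel = simulate_panel(seg, cfg, seed=4)
        from chromdyn.synthetic_data import panel_signal_tracks
        tracks = panel_signal_tracks(panel, cfg, "H3K27me3", seed=4)
        D = epigenome_distance(tracks)
        within, between = [], []
        names = panel.varieties
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                (within if panel.subgroups[a] == panel.subgroups[b]
                 else between).append(D.loc[a, b])
        assert np.mean(within) < np.mean(between)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            epigenome_distance({"a": self.track([1.0])}, metric="cosine")


class TestCoreVsDistributed:
    def test_all_core(self):
        presence = pd.DataFrame({"H3K4me3": [True, True, False]},
                                index=["g1", "g2", "g3"])
        labels = pd.Series("core", index=presence.index)
        out = core_vs_distributed(presence, labels)
        assert out.loc["H3K4me3", "core"] == 1.0
        assert out.loc["H3K4me3", "distributed"] == 0.0

    def test_hand_tally_ten_genes(self):
        genes = [f"g{i}" for i in range(10)]
        presence = pd.DataFrame(
            {"m1": [True] * 6 + [False] * 4,
             "m2": [False] * 5 + [True] * 5}, index=genes)
        labels = pd.Series(["core"] * 4 + ["distributed"] * 6, index=genes)
        out = core_vs_distributed(presence, labels)
        assert out.loc["m1", "core"] == pytest.approx(4 / 6)
        assert out.loc["m1", "distributed"] == pytest.approx(2 / 6)
        assert out.loc["m2", "core"] == 0.0
        assert out.loc["m1", "core"] + out.loc["m1", "distributed"] \
            == pytest.approx(1.0)
        assert out.loc["m1", "n_marked"] == 6

    def test_unlabeled_genes_listed(self):
        presence = pd.DataFrame({"m": [True]}, index=["gX"])
        with pytest.raises(ValueError, match="gX"):
            core_vs_distributed(presence, pd.Series(dtype=object))
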