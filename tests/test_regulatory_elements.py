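"""DRE/PRE classification, target linking, DRE clustering, and the six
loop/PRE gene categories."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from chromdyn.genome_io import GenomeIndex, Interval, nearest_tss
from chromdyn.methylation import bin_methylation, cytosine_levels
from chromdyn.regulatory_elements import (_category, classify_faire,
                                          cluster_tissue_dres,
                                          gene_loop_categories,
                                          link_dre_targets)
from chromdyn.synthetic_data import simulate_regulatory_scene
from test_genome_io import make_gene


@pytest.fixture(scope="module")
def scene():
    return simulate_regulatory_scene(seed=0)


def scene_methylbins(scene):
    levels = cytosine_levels(scene.cg_calls)
    return bin_methylation(levels, scene.grid, "CG")


class TestClassifyFaire:
    def simple_setup(self):
        genome = GenomeIndex({"chr1": 100_000})
        from chromdyn.genome_io import BinGrid
        grid = BinGrid(genome, 200)
        gene = make_gene("g1", "chr1", 50_000, "+")
        return grid, [gene]

    def methylbins(self, grid, bin_to_level):
        rows = [{"mean_level": lv, "n_cytosines": 5,
                 "meth_sum": int(lv * 100), "total_sum": 100, "bin": b}
                for b, lv in bin_to_level.items()]
        return pd.DataFrame(
            rows, columns=["mean_level", "n_cytosines", "meth_sum",
                           "total_sum", "bin"]).set_index("bin")

    def test_peak_near_tss_is_pre(self):
        grid, genes = self.simple_setup()
        peak = Interval("chr1", 49_700, 49_900)      # TSS-200
        (el,) = classify_faire([peak], genes, self.methylbins(grid, {}),
                               grid)
        assert el.klass == "PRE"

    def test_intergenic_low_methylation_is_dre(self):
        grid, genes = self.simple_setup()
        peak = Interval("chr1", 10_000, 10_300)
        mb = self.methylbins(grid, {50: 0.05, 51: 0.05})
        (el,) = classify_faire([peak], genes, mb, grid)
        assert el.klass == "DRE"
        assert el.mean_cg == pytest.approx(0.05)

    def test_intergenic_high_methylation_unclassified(self):
        grid, genes = self.simple_setup()
        peak = Interval("chr1", 10_000, 10_300)
        mb = self.methylbins(grid, {50: 0.4, 51: 0.4})
        (el,) = classify_faire([peak], genes, mb, grid)
        assert el.klass == "unclassified"
        assert el.reason == "high_methylation"

    def test_no_methylation_data_excluded(self):
        grid, genes = self.simple_setup()
        peak = Interval("chr1", 10_000, 10_300)
        (el,) = classify_faire([peak], genes, self.methylbins(grid, {}),
                               grid)
        assert el.klass == "unclassified"
        assert el.reason == "no_methylation_data"

    def test_gene_body_overlap_blocks_dre(self):
        from chromdyn.genome_io import GeneModel
        grid, _ = self.simple_setup()
        gene = GeneModel("g1", "chr1", "+", 50_000, 55_000, 50_000, 54_999,
                         50_150, exons=[(50_000, 55_000)])
        peak = Interval("chr1", 50_500, 50_800)      # inside body, near TSS
        mb = self.methylbins(grid, {252: 0.0, 262: 0.0, 263: 0.0})
        (el,) = classify_faire([peak], [gene], mb, grid)
        assert el.klass == "PRE"                     # within pre_distance
        far_in_body = Interval("chr1", 52_500, 52_800)   # 2.5 kb into body
        (el2,) = classify_faire([far_in_body], [gene], mb, grid)
        assert el2.klass == "unclassified"
        assert el2.reason == "overlaps_gene_body"

    def test_planted_scene_precision_recall(self, scene):
        mb = scene_methylbins(scene)
        elements = classify_faire(scene.peaks, scene.genes, mb, scene.grid)
        for klass in ("DRE", "PRE"):
            pred = {e.interval.name for e in elements if e.klass == klass}
            true = {n for n, k in scene.truth.items() if k == klass}
            tp = len(pred & true)
            assert tp / max(len(pred), 1) >= 0.95      # precision
            assert tp / len(true) >= 0.95              # recall
        dre_set = [e for e in elements if e.klass == "DRE"]
        pre_set = {e.interval.name for e in elements if e.klass == "PRE"}
        assert not ({e.interval.name for e in dre_set} & pre_set)
        bodies = [g.body for g in scene.genes]
        for e in dre_set:
            assert all(e.interval.overlap_bp(b) == 0 for b in bodies)


class TestLinkDreTargets:
    def test_nearest_of_two(self):
        genes = [make_gene("gA", "chr1", 10_300, "+"),
                 make_gene("gB", "chr1", 5_000, "-")]
        from chromdyn.regulatory_elements import RegElement
        el = RegElement(interval=Interval("chr1", 9_900, 10_000),
                        klass="DRE")
        link_dre_targets([el], genes)
        assert el.linked_gene == "gA"

    def test_equidistant_tie_breaks_by_id(self):
        genes = [make_gene("gB", "chr1", 10_500, "+"),
                 make_gene("gA", "chr1", 9_500, "-")]
        x = Interval("chr1", 9_990, 10_010)   # 480 bp from both TSSs
        g, _ = nearest_tss(x, genes)
        assert g.gene_id == "gA"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        genes = [make_gene(f"g{i:02d}", "chr1",
                           int(rng.integers(1000, 90_000)),
                           "+" if rng.random() < 0.5 else "-")
                 for i in range(12)]
        from chromdyn.regulatory_elements import RegElement
        from chromdyn.genome_io import tss_distance
        for _ in range(100):
            s = int(rng.integers(0, 99_000))
            el = RegElement(interval=Interval("chr1", s, s + 300),
                            klass="DRE")
            link_dre_targets([el], genes)
            best = min(genes, key=lambda g: (abs(tss_distance(el.interval,
                                                              g)),
                                             g.gene_id))
            assert el.linked_gene == best.gene_id


class TestClusterTissueDres:
    def test_planted_clusters_recovered(self, scene):
        labels, prof, _ = cluster_tissue_dres(scene.dre_signal,
                                              scene.tissues, k=3, seed=0)
        assert adjusted_rand_score(scene.dre_signal_labels, labels) >= 0.9

    def test_k_equal_rows_singletons(self, rng):
        X = rng.normal(size=(5, 3))
        labels, _, _ = cluster_tissue_dres(X, ["a", "b", "c"], k=5)
        assert sorted(labels) == list(range(5))

    def test_cluster_matched_tissue_has_max_expression(self, scene):
        labels, prof, summary = cluster_tissue_dres(
            scene.dre_signal, scene.tissues, k=3, seed=0,
            linked_expression=pd.DataFrame(
                scene.dre_signal, columns=list(scene.tissues)))
        for cluster_id in np.unique(labels):
            peak_tissue = prof.iloc[cluster_id].idxmax()
            assert summary.loc[cluster_id].idxmax() == peak_tissue


def brute_force_categories(genes, loops, pres, window=(1000, 500)):
    proms = {g.gene_id: g.promoter(upstream=window[0], downstream=window[1])
             for g in genes}
    own = {gid: any(p.overlap_bp(q) > 0 for q in pres)
           for gid, p in proms.items()}
    out = {}
    for g in genes:
        prom = proms[g.gene_id]
        looped, partner = False, False
        for a, b, _ in loops:
            for anchor, other in ((a, b), (b, a)):
                if prom.overlap_bp(anchor) > 0:
                    looped = True
                    for h in genes:
                        if proms[h.gene_id].overlap_bp(other) > 0 \
                                and own[h.gene_id]:
                            partner = True
        out[g.gene_id] = _category(own[g.gene_id], looped, partner)
    return out


class TestGeneLoopCategories:
    def test_pre_promoter_without_loop_is_cat5(self):
        g = make_gene("g1", "chr1", 10_000, "+")
        pre = Interval("chr1", 9_800, 10_100)
        cats = gene_loop_categories([g], [], [pre])
        assert cats.loc["g1", "category"] == 5

    def test_bare_gene_is_cat6(self):
        g = make_gene("g1", "chr1", 10_000, "+")
        cats = gene_loop_categories([g], [], [])
        assert cats.loc["g1", "category"] == 6

    def test_two_pre_promoters_joined_both_cat1(self):
        g1 = make_gene("g1", "chr1", 10_000, "+")
        g2 = make_gene("g2", "chr1", 50_000, "+")
        pres = [Interval("chr1", 9_900, 10_050),
                Interval("chr1", 49_900, 50_050)]
        loop = (Interval("chr1", 9_500, 10_400),
                Interval("chr1", 49_500, 50_400), 1.0)
        cats = gene_loop_categories([g1, g2], [loop], pres)
        assert (cats["category"] == 1).all()

    def test_partner_only_pre_is_cat3(self):
        g1 = make_gene("g1", "chr1", 10_000, "+")
        g2 = make_gene("g2", "chr1", 50_000, "+")
        pres = [Interval("chr1", 49_900, 50_050)]
        loop = (Interval("chr1", 9_500, 10_400),
                Interval("chr1", 49_500, 50_400), 1.0)
        cats = gene_loop_categories([g1, g2], [loop], pres)
        assert cats.loc["g1", "category"] == 3
        assert cats.loc["g2", "category"] == 2

    def test_category_function_on_reachable_combinations(self):
        expected = {(True, True, True): 1, (True, True, False): 2,
                    (False, True, True): 3, (False, True, False): 4,
                    (True, False, False): 5, (False, False, False): 6}
        for own, looped, partner in itertools.product([True, False],
                                                      repeat=3):
            if partner and not looped:
                with pytest.raises(AssertionError):
                    _category(own, looped, partner)
            else:
                assert _category(own, looped, partner) \
                    == expected[(own, looped, partner)]

    @settings(max_examples=30, deadline=None)
    @given(st.data())
    def test_matches_brute_force_random_instances(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        genes = [make_gene(f"g{i}", "chr1", 5_000 + 8_000 * i, "+")
                 for i in range(6)]
        pres = [Interval("chr1", int(s), int(s) + 300)
                for s in rng.integers(0, 50_000, size=4)]
        loops = []
        for _ in range(3):
            a, b = sorted(rng.integers(0, 50_000, size=2))
            loops.append((Interval("chr1", int(a), int(a) + 1500),
                          Interval("chr1", int(b), int(b) + 1500), 1.0))
        got = gene_loop_categories(genes, loops, pres)
        expected = brute_force_categories(genes, loops, pres)
        for gid, cat in expected.items():
            assert got.loc[gid, "category"] == cat
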