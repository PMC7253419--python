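"""Binarization, Bernoulli-HMM training/decoding, and state annotation."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from chromdyn.genome_io import (BinGrid, BinnedTrack, GeneModel, GenomeIndex,
                                Interval)
from chromdyn.segmentation import (BernoulliHMM, BinarizedMatrix,
                                   CategoryRules, Segmentation,
                                   annotate_states, binarize,
                                   categorize_states, decode, fit_hmm)
from chromdyn.synthetic_data import DEFAULT_MARKS, DEFAULT_STATES
from test_genome_io import make_gene


def poisson_tail_oracle(c, lam):
    """P(X >= c) by direct pmf summation (independent of scipy.sf)."""
    import math
    if c <= 0:
        return 1.0
    acc = 0.0
    for k in range(0, int(c)):
        acc += math.exp(-lam) * lam ** k / math.factorial(k)
    return 1.0 - acc


class TestBinarize:
    def test_all_zero_counts(self, small_grid):
        t = BinnedTrack.zeros(small_grid)
        out = binarize(t, None)
        assert not out.values.any()

    def test_poisson_tail_example(self, small_grid):
        # lambda = 5, count 20: tail ~ 3.45e-7 <= 1e-4 -> present
        assert poisson_tail_oracle(20, 5.0) == pytest.approx(3.452e-7,
                                                             rel=1e-3)
        counts = np.full(small_grid.n_bins, 5)
        counts[3] = 20
        out = binarize(BinnedTrack(small_grid, counts), None)
        assert out.values[3] == 1
        assert out.values.sum() == 1

    def test_matches_tail_sum_oracle(self, rng):
        grid = BinGrid(GenomeIndex({"chr1": 2_000_000}), 200)
        counts = rng.poisson(np.where(rng.random(grid.n_bins) < 0.2, 30, 2))
        inp = rng.poisson(20, size=grid.n_bins)
        out = binarize(BinnedTrack(grid, counts), BinnedTrack(grid, inp))
        global_rate = counts.mean()
        lam = global_rate * np.maximum(inp / inp.mean(), 1.0)
        expected = np.array(
            [poisson_tail_oracle(c, l) <= 1e-4
             for c, l in zip(counts, lam)]).astype(np.uint8)
        assert np.array_equal(out.values, expected)

    def test_all_zero_input_falls_back(self, small_grid):
        counts = np.full(small_grid.n_bins, 3)
        with pytest.warns(UserWarning, match="all-zero input"):
            binarize(BinnedTrack(small_grid, counts),
                     BinnedTrack.zeros(small_grid))


def sample_hmm_data(rng, E, stickiness, T):
    K = E.shape[0]
    s = np.zeros(T, dtype=int)
    s[0] = rng.integers(K)
    for t in range(1, T):
        if rng.random() < stickiness:
            s[t] = s[t - 1]
        else:
            s[t] = rng.integers(K)
    X = (rng.random((T, E.shape[1])) < E[s]).astype(float)
    return X, s


def match_states(E_hat, E_true):
    """Hungarian matching of estimated to true states by emission distance."""
    cost = np.abs(E_hat[:, None, :] - E_true[None, :, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(rows), dtype=int)
    perm[cols] = rows
    return perm  # perm[k_true] = k_hat


class TestBernoulliHMM:
    def test_k1_closed_form(self, rng):
        X = (rng.random((500, 3)) < [0.2, 0.5, 0.8]).astype(float)
        m = BernoulliHMM(n_states=1, n_init=1).fit(X)
        assert np.allclose(m.emissionprob_[0], X.mean(axis=0), atol=1e-5)
        assert np.allclose(m.transmat_, [[1.0]])

    def test_loglik_trace_nondecreasing(self, rng):
        X = (rng.random((2000, 4)) < 0.3).astype(float)
        m = BernoulliHMM(n_states=3, n_init=2, random_state=0).fit(X)
        assert np.all(np.diff(m.loglik_trace_) >= -1e-6)

    def test_two_state_parameter_recovery(self):
        rng = np.random.default_rng(7)
        E = np.array([[0.9, 0.1], [0.1, 0.9]])
        X, s = sample_hmm_data(rng, E, 0.98, 50_000)
        m = BernoulliHMM(n_states=2, n_init=3, random_state=1).fit(X)
        perm = match_states(m.emissionprob_, E)
        err = np.abs(m.emissionprob_[perm] - E).max()
        assert err <= 0.03
        labels = m.predict(X)
        acc = (perm[s] == labels).mean()
        assert acc >= 0.95

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="binary"):
            BernoulliHMM(n_states=2).fit(np.full((10, 2), 0.5))

    def test_rejects_more_states_than_bins(self):
        with pytest.raises(ValueError, match="fewer bins"):
            BernoulliHMM(n_states=20).fit(np.zeros((10, 2)))

    def test_sklearn_params_roundtrip(self):
        m = BernoulliHMM(n_states=4, tol=1e-3)
        assert m.get_params()["n_states"] == 4
        m.set_params(n_states=6)
        assert m.n_states == 6


def exhaustive_posterior(startprob, transmat, E, X):
    """Exact per-bin marginals by summing over every state path."""
    T, K = X.shape[0], len(startprob)
    marg = np.zeros((T, K))
    for path in itertools.product(range(K), repeat=T):
        p = startprob[path[0]]
        for t in range(1, T):
            p *= transmat[path[t - 1], path[t]]
        for t in range(T):
            for m in range(X.shape[1]):
                p *= E[path[t], m] if X[t, m] else 1 - E[path[t], m]
        for t in range(T):
            marg[t, path[t]] += p
    return marg / marg.sum(axis=1, keepdims=True)


class TestDecode:
    def test_k1_all_state_one(self, small_grid, rng):
        X = (rng.random((small_grid.n_bins, 2)) < 0.4).astype(float)
        B = BinarizedMatrix(small_grid, ("a", "b"), X)
        m = fit_hmm(B, 1, seed=0, n_init=1)
        seg = decode(m, B)
        assert (seg.states == 1).all()

    def test_posterior_equals_exhaustive_marginalization(self):
        rng = np.random.default_rng(3)
        K, T, M = 2, 12, 2
        E = np.array([[0.8, 0.3], [0.2, 0.7]])
        A = np.array([[0.9, 0.1], [0.2, 0.8]])
        pi = np.array([0.6, 0.4])
        for trial in range(5):
            X = (rng.random((T, M)) < 0.5).astype(float)
            m = BernoulliHMM(n_states=K)
            m.emissionprob_, m.transmat_, m.startprob_ = E, A, pi
            m.n_marks_ = M
            post = m.predict_proba(X)
            exact = exhaustive_posterior(pi, A, E, X)
            assert np.allclose(post, exact, atol=1e-9)
            assert np.array_equal(m.predict(X), exact.argmax(axis=1))

    def test_posterior_matches_hmmlearn_encoding(self):
        # independent cross-check: encode 2 binary marks as 4 categorical
        # symbols with product-Bernoulli emission probabilities
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(11)
        E = np.array([[0.85, 0.2], [0.1, 0.9], [0.5, 0.5]])
        A = np.array([[0.8, 0.1, 0.1], [0.15, 0.7, 0.15], [0.3, 0.3, 0.4]])
        pi = np.array([0.5, 0.3, 0.2])
        X = (rng.random((300, 2)) < 0.4).astype(float)
        ours = BernoulliHMM(n_states=3)
        ours.emissionprob_, ours.transmat_, ours.startprob_ = E, A, pi
        ours.n_marks_ = 2
        ref = hmmlearn.CategoricalHMM(n_components=3)
        ref.startprob_, ref.transmat_ = pi, A
        emis = np.zeros((3, 4))
        for k in range(3):
            for x0 in (0, 1):
                for x1 in (0, 1):
                    p = (E[k, 0] if x0 else 1 - E[k, 0]) \
                        * (E[k, 1] if x1 else 1 - E[k, 1])
                    emis[k, 2 * x0 + x1] = p
        ref.emissionprob_ = emis
        symbols = (2 * X[:, 0] + X[:, 1]).astype(int).reshape(-1, 1)
        assert np.allclose(ours.predict_proba(X),
                           ref.predict_proba(symbols), atol=1e-8)

    def test_viterbi_agrees_on_clean_data(self):
        rng = np.random.default_rng(5)
        E = np.array([[0.95, 0.05], [0.05, 0.95]])
        X, s = sample_hmm_data(rng, E, 0.97, 3000)
        m = BernoulliHMM(n_states=2, n_init=2, random_state=0).fit(X)
        post = m.predict(X, rule="posterior")
        vit = m.predict(X, rule="viterbi")
        assert (post == vit).mean() > 0.98

    def test_mark_mismatch_rejected(self, small_grid, rng):
        X = (rng.random((small_grid.n_bins, 2)) < 0.4).astype(float)
        B = BinarizedMatrix(small_grid, ("a", "b"), X)
        m = fit_hmm(B, 2, seed=0, n_init=1)
        B2 = BinarizedMatrix(small_grid, ("a", "c"), X)
        with pytest.raises(ValueError, match="marks"):
            decode(m, B2)


class TestAnnotateStates:
    def test_uniform_segmentation_enrichment_near_one(self):
        rng = np.random.default_rng(0)
        genome = GenomeIndex({"chr1": 2_000_000})
        grid = BinGrid(genome, 200)          # 10^4 bins
        seg = Segmentation(grid, rng.integers(1, 4, size=grid.n_bins), 3)
        # a large feature (half the genome as exonic bp) keeps the
        # law-of-large-numbers tolerance of 0.1 sound at this size
        genes = [GeneModel(f"g{i:03d}", "chr1", "+", s, s + 5000, s,
                           s + 4999, s + 100, exons=[(s, s + 5000)])
                 for i, s in enumerate(range(0, 1_990_000, 10_000))]
        ann = annotate_states(seg, genes, [])
        assert ann.coverage.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(ann.enrichment["exon"], 1.0, atol=0.1)
        assert np.allclose(ann.enrichment["intergenic"], 1.0, atol=0.1)
        assert np.allclose(ann.enrichment["genome"], 1.0, atol=1e-9)

    def test_state_covering_one_feature(self):
        # state 2 covers exactly the single gene's bp
        genome = GenomeIndex({"chr1": 10_000})
        grid = BinGrid(genome, 200)
        states = np.ones(grid.n_bins, dtype=int)
        states[10:15] = 2                      # bp 2000..3000
        seg = Segmentation(grid, states, 2)
        g = GeneModel("g1", "chr1", "+", 2000, 3000, 2000, 2999, 2100,
                      exons=[(2000, 3000)])
        ann = annotate_states(seg, [g], [])
        # enrichment = (1000/1000) / (1000/10000) = 10
        assert ann.enrichment.loc["state2", "exon"] == pytest.approx(10.0)

    def test_te_family_rank(self):
        genome = GenomeIndex({"chr1": 100_000})
        grid = BinGrid(genome, 200)
        states = np.ones(grid.n_bins, dtype=int)
        states[100:300] = 2                    # bp 20k..60k hosts Gypsy
        seg = Segmentation(grid, states, 2)
        tes = [Interval("chr1", 21_000, 55_000, name="Gypsy"),
               Interval("chr1", 70_000, 72_000, name="Copia")]
        ann = annotate_states(seg, [], tes)
        assert ann.enrichment.loc["state2", "Gypsy"] \
            > ann.enrichment.loc["state2", "Copia"]

    def test_empty_segmentation_rejected(self):
        with pytest.raises(ValueError):
            genome = GenomeIndex({"chr1": 200})
            grid = BinGrid(genome, 200)
            seg = Segmentation(grid, np.ones(1, dtype=int), 1)
            grid.n_bins = 0  # simulate degenerate input
            annotate_states(seg, [], [])


class TestCategories:
    def test_default_state_table_categories(self):
        E = np.array([s.emissions for s in DEFAULT_STATES])
        cats = categorize_states(E, DEFAULT_MARKS, CategoryRules())
        assert cats == [s.category for s in DEFAULT_STATES]

    def test_quies_threshold(self):
        E = np.array([[0.05, 0.09], [0.05, 0.11]])
        cats = categorize_states(E, ["H3K4me3", "H3K27ac"])
        assert cats == ["Quies", "active"]
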