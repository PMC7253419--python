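"""Chromatin-state segmentation: Poisson binarization, a multivariate
Bernoulli hidden Markov model, decoding, and state annotation.

The model mirrors the classical genome-segmentation HMM: the genome is tiled
into fixed bins, each mark is reduced to presence/absence per bin by an
upper-tail Poisson test against an input-scaled local expectation, and a
K-state HMM with independent Bernoulli emissions per mark is trained by
Baum-Welch EM.  States are then summarized by genome coverage, feature
enrichment, and a rule-based category (active / repressive / inactive /
Quies) derived from the emission profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from . import _hmm_kernels as _k
from .genome_io import BinGrid, BinnedTrack, GeneModel, Interval, TE_FAMILIES

_EPS = 1e-6


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

def binarize(counts: BinnedTrack, control: BinnedTrack | None = None,
             p_threshold: float = 1e-4) -> BinnedTrack:
    """Presence/absence call per bin by an upper-tail Poisson test.

    The local expectation is the genome-wide mark rate scaled by the input
    coverage of the bin (relative to the mean input), floored at the global
    rate so that input can only *raise* the expectation.  A bin is called
    present iff ``P(X >= c | lambda_b) <= p_threshold``.
    """
    c = np.asarray(counts.values, dtype=float)
    global_rate = c.mean()
    if control is None:
        lam = np.full_like(c, global_rate)
    else:
        if counts.grid != control.grid:
            raise ValueError("counts and control are on different grids")
        inp = np.asarray(control.values, dtype=float)
        if inp.sum() <= 0:
            warnings.warn("all-zero input track; falling back to the global "
                          "rate", stacklevel=2)
            lam = np.full_like(c, global_rate)
        else:
            lam = global_rate * np.maximum(inp / inp.mean(), 1.0)
    with np.errstate(divide="ignore"):
        tail = stats.poisson.sf(c - 1, lam)
    return BinnedTrack(counts.grid, (tail <= p_threshold).astype(np.uint8))


@dataclass
class BinarizedMatrix:
    """Bins x marks 0/1 matrix on a shared grid."""

    grid: BinGrid
    marks: tuple[str, ...]
    X: np.ndarray

    def __post_init__(self):
        self.X = np.ascontiguousarray(self.X, dtype=np.float64)
        if self.X.shape != (self.grid.n_bins, len(self.marks)):
            raise ValueError(f"matrix shape {self.X.shape} inconsistent with "
                             f"{self.grid.n_bins} bins x {len(self.marks)} marks")
        if not np.isin(self.X, (0.0, 1.0)).all():
            raise ValueError("binarized matrix must contain only 0/1 entries")

    @classmethod
    def from_tracks(cls, tracks: dict[str, BinnedTrack],
                    control: BinnedTrack | None = None,
                    p_threshold: float = 1e-4) -> "BinarizedMatrix":
        marks = tuple(tracks)
        grid = tracks[marks[0]].grid
        cols = [binarize(tracks[m], control, p_threshold).values for m in marks]
        return cls(grid, marks, np.column_stack(cols))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.X.astype(int), columns=list(self.marks)
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, grid: BinGrid) -> "BinarizedMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(grid, tuple(df.columns), df.to_numpy())


# ---------------------------------------------------------------------------
# The HMM estimator
# ---------------------------------------------------------------------------

class BernoulliHMM(BaseEstimator):
    """Hidden Markov model with independent Bernoulli emissions per mark.

    Parameters
    ----------
    n_states : number of hidden states K.
    n_init : number of seeded EM restarts; the best final log-likelihood wins.
    max_iter, tol : EM stops when the relative log-likelihood gain drops
        below ``tol`` (or at ``max_iter``).
    sticky_init : initial self-transition probability.
    random_state : seed for the restarts.

    Attributes (after ``fit``)
    --------------------------
    emissionprob_ : (K, M) Bernoulli success probabilities.
    transmat_ : (K, K) transition matrix.
    startprob_ : (K,) initial distribution.
    loglik_trace_ : per-iteration log-likelihood of the winning restart
        (non-decreasing, asserted during training).
    """

    def __init__(self, n_states: int = 15, n_init: int = 5,
                 max_iter: int = 200, tol: float = 1e-4,
                 sticky_init: float = 0.9, random_state=None):
        self.n_states = n_states
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.sticky_init = sticky_init
        self.random_state = random_state

    # -- helpers ------------------------------------------------------------

    @staticmethod
    def _validate(X, lengths):
        X = np.ascontiguousarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (bins x marks)")
        if not np.isin(X, (0.0, 1.0)).all():
            raise ValueError("X must be binary (0/1)")
        if lengths is None:
            lengths = [X.shape[0]]
        if sum(lengths) != X.shape[0]:
            raise ValueError("lengths do not sum to the number of rows")
        return X, list(lengths)

    def _frameprob(self, X, E):
        logE = np.log(np.clip(E, _EPS, 1 - _EPS))
        log1mE = np.log(np.clip(1 - E, _EPS, 1 - _EPS))
        return np.exp(X @ logE.T + (1 - X) @ log1mE.T)

    def _init_params(self, rng, n_marks):
        K = self.n_states
        E = rng.uniform(0.1, 0.9, size=(K, n_marks))
        if K == 1:
            A = np.ones((1, 1))
        else:
            A = np.full((K, K), (1 - self.sticky_init) / (K - 1))
            np.fill_diagonal(A, self.sticky_init)
        pi = np.full(K, 1.0 / K)
        return E, A, pi

    def _em(self, X, lengths, E, A, pi):
        K = self.n_states
        bounds = np.concatenate([[0], np.cumsum(lengths)])
        trace: list[float] = []
        for _ in range(self.max_iter):
            fp = self._frameprob(X, E)
            ll = 0.0
            xi = np.zeros((K, K))
            g0 = np.zeros(K)
            e_num = np.zeros_like(E)
            e_den = np.zeros(K)
            for s, e in zip(bounds[:-1], bounds[1:]):
                alpha, c = _k.forward_scaled(pi, A, fp[s:e])
                beta = _k.backward_scaled(A, fp[s:e], c)
                ll += float(np.log(c).sum())
                gamma = alpha * beta
                gamma /= gamma.sum(axis=1, keepdims=True)
                if K > 1:
                    xi += _k.xi_sum(alpha, beta, A, fp[s:e], c)
                g0 += gamma[0]
                e_num += gamma.T @ X[s:e]
                e_den += gamma.sum(axis=0)
            if trace and ll < trace[-1] - 1e-6 * max(1.0, abs(trace[-1])):
                raise AssertionError(
                    f"EM log-likelihood decreased: {trace[-1]} -> {ll}")
            converged = bool(trace) and \
                (ll - trace[-1]) < self.tol * abs(trace[-1])
            trace.append(ll)
            if converged:
                break
            # M-step
            E = np.clip(e_num / np.maximum(e_den, _EPS)[:, None],
                        _EPS, 1 - _EPS)
            if K > 1:
                rows = xi.sum(axis=1, keepdims=True)
                A = np.where(rows > 0, xi / np.maximum(rows, _EPS),
                             1.0 / K)
            pi = g0 / g0.sum()
        return E, A, pi, trace

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, lengths=None):
        X, lengths = self._validate(X, lengths)
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if X.shape[0] < self.n_states:
            raise ValueError("fewer bins than states")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, self.n_init)):
            E0, A0, pi0 = self._init_params(rng, X.shape[1])
            E, A, pi, trace = self._em(X, lengths, E0, A0, pi0)
            if best is None or trace[-1] > best[3][-1]:
                best = (E, A, pi, trace)
        self.emissionprob_, self.transmat_, self.startprob_, trace = best
        self.loglik_trace_ = np.asarray(trace)
        self.n_iter_ = len(trace)
        self.converged_ = len(trace) < self.max_iter
        self.n_marks_ = X.shape[1]
        return self

    def predict_proba(self, X, lengths=None) -> np.ndarray:
        """Per-bin posterior state probabilities (forward-backward)."""
        X, lengths = self._validate(X, lengths)
        fp = self._frameprob(X, self.emissionprob_)
        bounds = np.concatenate([[0], np.cumsum(lengths)])
        out = np.empty((X.shape[0], self.n_states))
        for s, e in zip(bounds[:-1], bounds[1:]):
            alpha, c = _k.forward_scaled(self.startprob_, self.transmat_,
                                         fp[s:e])
            beta = _k.backward_scaled(self.transmat_, fp[s:e], c)
            gamma = alpha * beta
            out[s:e] = gamma / gamma.sum(axis=1, keepdims=True)
        return out

    def predict(self, X, lengths=None, rule: str = "posterior") -> np.ndarray:
        """0-based state labels; posterior ties break to the lower state id."""
        if rule == "posterior":
            return np.argmax(self.predict_proba(X, lengths), axis=1)
        if rule != "viterbi":
            raise ValueError(f"unknown decode rule {rule!r}")
        X, lengths = self._validate(X, lengths)
        fp = self._frameprob(X, self.emissionprob_)
        with np.errstate(divide="ignore"):
            log_start = np.log(np.maximum(self.startprob_, 1e-300))
            log_trans = np.log(np.maximum(self.transmat_, 1e-300))
            log_frame = np.log(np.maximum(fp, 1e-300))
        bounds = np.concatenate([[0], np.cumsum(lengths)])
        out = np.empty(X.shape[0], dtype=np.int64)
        for s, e in zip(bounds[:-1], bounds[1:]):
            out[s:e] = _k.viterbi_path(log_start, log_trans, log_frame[s:e])
        return out

    def score(self, X, lengths=None) -> float:
        X, lengths = self._validate(X, lengths)
        fp = self._frameprob(X, self.emissionprob_)
        bounds = np.concatenate([[0], np.cumsum(lengths)])
        ll = 0.0
        for s, e in zip(bounds[:-1], bounds[1:]):
            _, c = _k.forward_scaled(self.startprob_, self.transmat_, fp[s:e])
            ll += float(np.log(c).sum())
        return ll

    def to_tsvs(self, prefix) -> None:
        marks = [f"m{i}" for i in range(self.n_marks_)]
        pd.DataFrame(self.emissionprob_, columns=marks,
                     index=[f"state{i + 1}" for i in range(self.n_states)]
                     ).to_csv(f"{prefix}.emissions.tsv", sep="\t")
        pd.DataFrame(self.transmat_).to_csv(f"{prefix}.transitions.tsv",
                                            sep="\t", index=False)


def fit_hmm(B: BinarizedMatrix, K: int, seed=None, n_init: int = 5,
            max_iter: int = 200, tol: float = 1e-4) -> BernoulliHMM:
    """Train a K-state model on a binarized matrix; chromosomes are
    independent sequences."""
    model = BernoulliHMM(n_states=K, n_init=n_init, max_iter=max_iter,
                         tol=tol, random_state=seed)
    model.fit(B.X, lengths=B.grid.sequence_lengths())
    model.marks_ = B.marks
    return model


def select_k(B: BinarizedMatrix, k_values, seed=None, **fit_kwargs
             ) -> pd.DataFrame:
    """Log-likelihood per candidate K (reported, never auto-chosen)."""
    rows = []
    for K in k_values:
        m = fit_hmm(B, K, seed=seed, **fit_kwargs)
        rows.append({"K": K, "loglik": m.loglik_trace_[-1],
                     "n_iter": m.n_iter_})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Segmentation container
# ---------------------------------------------------------------------------

@dataclass
class Segmentation:
    """Per-bin state labels, 1-based (state ids 1..K)."""

    grid: BinGrid
    states: np.ndarray
    n_states: int
    provenance: str = ""

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int32)
        if self.states.shape != (self.grid.n_bins,):
            raise ValueError("segmentation length != grid bins")
        if self.states.min() < 1 or self.states.max() > self.n_states:
            raise ValueError("state ids must lie in 1..K")

    def to_bed(self, path) -> None:
        """Runs of equal state as BED intervals, name = state id."""
        with open(path, "w") as fh:
            for chrom in self.grid.genome.names:
                sl = self.grid.chrom_slice(chrom)
                vals = self.states[sl]
                L = self.grid.genome.lengths[chrom]
                w = self.grid.width
                run_start = 0
                for i in range(1, len(vals) + 1):
                    if i == len(vals) or vals[i] != vals[run_start]:
                        fh.write(f"{chrom}\t{run_start * w}\t"
                                 f"{min(i * w, L)}\t{vals[run_start]}\n")
                        run_start = i

    @classmethod
    def from_bed(cls, path, grid: BinGrid, n_states: int) -> "Segmentation":
        states = np.zeros(grid.n_bins, dtype=np.int32)
        with open(path) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                if len(f) < 4:
                    continue
                chrom, start, end, sid = f[0], int(f[1]), int(f[2]), int(f[3])
                idx = grid.bins_overlapping(Interval(chrom, start, end))
                states[idx.start:idx.stop] = sid
        if (states == 0).any():
            raise ValueError("segmentation BED does not cover every bin")
        return cls(grid, states, n_states, provenance=str(path))


def decode(model: BernoulliHMM, B: BinarizedMatrix,
           rule: str = "posterior") -> Segmentation:
    """Label every bin with its decoded state (1-based)."""
    marks = getattr(model, "marks_", None)
    if marks is not None and tuple(marks) != tuple(B.marks):
        raise ValueError(f"model marks {marks} != matrix marks {B.marks}")
    labels = model.predict(B.X, lengths=B.grid.sequence_lengths(), rule=rule)
    return Segmentation(B.grid, labels + 1, model.n_states,
                        provenance=f"decode:{rule}")


# ---------------------------------------------------------------------------
# State annotation
# ---------------------------------------------------------------------------

@dataclass
class CategoryRules:
    """Emission-profile thresholds mapping states to the four categories.

    A state is Quies when every emission probability is below ``quies_max``;
    repressive when H3K27me3 is its strongest mark at >= ``repressive_min``;
    inactive when H3K9me2 >= ``inactive_min`` (flagged bivalent when H3K4me1
    also exceeds ``bivalent_min``); otherwise active.
    """

    quies_max: float = 0.1
    repressive_min: float = 0.3
    inactive_min: float = 0.3
    bivalent_min: float = 0.3
    repressive_mark: str = "H3K27me3"
    inactive_mark: str = "H3K9me2"
    bivalent_mark: str = "H3K4me1"


def categorize_states(emissionprob: np.ndarray, marks,
                      rules: CategoryRules = CategoryRules()) -> list[str]:
    marks = list(marks)
    cats = []
    for row in np.asarray(emissionprob):
        if row.max() < rules.quies_max:
            cats.append("Quies")
            continue
        rep = row[marks.index(rules.repressive_mark)] \
            if rules.repressive_mark in marks else 0.0
        ina = row[marks.index(rules.inactive_mark)] \
            if rules.inactive_mark in marks else 0.0
        if rep >= rules.repressive_min and rep == row.max():
            cats.append("repressive")
        elif ina >= rules.inactive_min:
            cats.append("inactive")
        else:
            cats.append("active")
    return cats


@dataclass
class StateAnnotation:
    coverage: pd.Series                  # genome bp fraction per state
    enrichment: pd.DataFrame             # states x feature classes
    categories: list[str] | None = None


def _bp_mask(genome, intervals) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(genome.lengths[c], dtype=bool) for c in genome.names}
    for iv in intervals:
        masks[iv.chrom][iv.start:iv.end] = True
    return masks


def annotate_states(seg: Segmentation, genes: list[GeneModel],
                    tes: list[Interval], model: BernoulliHMM | None = None,
                    rules: CategoryRules = CategoryRules(),
                    tss_flank: int = 200) -> StateAnnotation:
    """Genome coverage and fold enrichment of each state over feature classes.

    ``enrichment[s, f] = (bp of s∩f / bp of s) / (bp of f / genome bp)``.
    Computed at bp resolution so partial trailing bins are handled exactly.
    """
    genome = seg.grid.genome
    if seg.grid.n_bins == 0:
        raise ValueError("empty segmentation")
    # per-bp state labels
    state_bp = {}
    for chrom in genome.names:
        sl = seg.grid.chrom_slice(chrom)
        rep = np.repeat(seg.states[sl], seg.grid.width)
        state_bp[chrom] = rep[:genome.lengths[chrom]]

    features: dict[str, dict[str, np.ndarray]] = {}
    ex, gene_body = [], []
    tss_iv, tts_iv = [], []
    for g in genes:
        gene_body.append(g.body)
        ex.extend(Interval(g.chrom, s, e) for s, e in g.exons)
        L = genome.lengths[g.chrom]
        tss_iv.append(Interval(g.chrom, max(0, g.tss - tss_flank),
                               min(L, g.tss + tss_flank + 1)))
        tts_iv.append(Interval(g.chrom, max(0, g.tts - tss_flank),
                               min(L, g.tts + tss_flank + 1)))
    features["TSS"] = _bp_mask(genome, tss_iv)
    features["TTS"] = _bp_mask(genome, tts_iv)
    exon_mask = _bp_mask(genome, ex)
    body_mask = _bp_mask(genome, gene_body)
    features["exon"] = exon_mask
    features["intron"] = {c: body_mask[c] & ~exon_mask[c]
                          for c in genome.names}
    features["intergenic"] = {c: ~body_mask[c] for c in genome.names}
    for fam in TE_FAMILIES:
        fam_ivs = [t for t in tes if t.name == fam]
        if fam_ivs:
            features[fam] = _bp_mask(genome, fam_ivs)
    features["genome"] = {c: np.ones(genome.lengths[c], dtype=bool)
                          for c in genome.names}

    K = seg.n_states
    total_bp = genome.total_bp
    state_sizes = np.zeros(K)
    for chrom in genome.names:
        state_sizes += np.bincount(state_bp[chrom] - 1, minlength=K)
    cov = pd.Series(state_sizes / total_bp,
                    index=[f"state{i + 1}" for i in range(K)], name="coverage")

    enr = pd.DataFrame(index=cov.index, columns=list(features), dtype=float)
    for fname, masks in features.items():
        f_bp = sum(int(m.sum()) for m in masks.values())
        inter = np.zeros(K)
        for chrom in genome.names:
            m = masks[chrom]
            if m.any():
                inter += np.bincount(state_bp[chrom][m] - 1, minlength=K)
        if f_bp == 0:
            enr[fname] = np.nan
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            enr[fname] = (inter / np.maximum(state_sizes, 1)) \
                / (f_bp / total_bp)
        enr.loc[state_sizes == 0, fname] = np.nan

    cats = None
    if model is not None:
        cats = categorize_states(model.emissionprob_,
                                 getattr(model, "marks_",
                                         [f"m{i}" for i in
                                          range(model.n_marks_)]), rules)
    return StateAnnotation(coverage=cov, enrichment=enr, categories=cats)
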