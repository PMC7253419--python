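"""Tissue-pair chromatin-state switching, differential mark regions,
fold-change correlation, and tissue-specific clustering.

The switching matrix between two segmentations counts bins labelled state
``s1`` in one condition and ``s2`` in the other, is symmetrized by adding its
transpose, row-normalized into switching probabilities, and optionally
expressed as a log10 enrichment over the genome fraction of the target state
(so that abundant states do not dominate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .genome_io import BinnedTrack, Interval
from .segmentation import Segmentation


@dataclass
class SwitchMatrix:
    counts: np.ndarray               # raw K x K, A rows -> B columns
    symmetrized: np.ndarray          # counts + counts.T
    probabilities: np.ndarray        # row-normalized symmetrized
    genome_fractions: np.ndarray     # pooled state fractions (both inputs)
    enrichment: np.ndarray           # probabilities / target-state fraction
    log10_enrichment: np.ndarray     # log10, zeros/masked cells NaN
    state_labels: list[str]

    @property
    def n_bins(self) -> int:
        return int(self.counts.sum())


def _derive(counts: np.ndarray, fractions: np.ndarray, labels) -> SwitchMatrix:
    sym = counts + counts.T
    rows = sym.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(rows > 0, sym / np.where(rows > 0, rows, 1), np.nan)
        enr = np.where(fractions[None, :] > 0,
                       prob / np.where(fractions[None, :] > 0,
                                       fractions[None, :], 1), np.nan)
        log10 = np.where(np.nan_to_num(enr) > 0,
                         np.log10(np.where(enr > 0, enr, 1.0)), np.nan)
    return SwitchMatrix(counts=counts, symmetrized=sym, probabilities=prob,
                        genome_fractions=fractions, enrichment=enr,
                        log10_enrichment=log10, state_labels=list(labels))


def switch_matrix(seg_a: Segmentation, seg_b: Segmentation,
                  state_labels: list[str] | None = None) -> SwitchMatrix:
    """K x K switching statistics between two segmentations on one grid."""
    if seg_a.grid != seg_b.grid:
        raise ValueError("segmentations on different grids")
    K = max(seg_a.n_states, seg_b.n_states)
    counts = np.zeros((K, K))
    np.add.at(counts, (seg_a.states - 1, seg_b.states - 1), 1)
    frac = (np.bincount(seg_a.states - 1, minlength=K)
            + np.bincount(seg_b.states - 1, minlength=K)) \
        / (2.0 * seg_a.grid.n_bins)
    labels = state_labels or [f"state{i + 1}" for i in range(K)]
    return _derive(counts, frac, labels)


def combine_pairs(matrices: list[SwitchMatrix]) -> SwitchMatrix:
    """Pool tissue-pair switching matrices by summing raw counts."""
    if not matrices:
        raise ValueError("no matrices to combine")
    labels = matrices[0].state_labels
    for m in matrices[1:]:
        if m.state_labels != labels:
            raise ValueError("state label mismatch between matrices")
    counts = sum(m.counts for m in matrices)
    # pooled genome fractions, weighted by each matrix's bin total
    weights = np.array([m.n_bins for m in matrices], dtype=float)
    frac = sum(w * m.genome_fractions for w, m in zip(weights, matrices)) \
        / weights.sum()
    return _derive(counts, frac, labels)


def switch_to_tsv(matrix: SwitchMatrix, prefix) -> None:
    for attr in ("counts", "symmetrized", "probabilities",
                 "log10_enrichment"):
        pd.DataFrame(getattr(matrix, attr), index=matrix.state_labels,
                     columns=matrix.state_labels
                     ).to_csv(f"{prefix}.{attr}.tsv", sep="\t")


# ---------------------------------------------------------------------------
# Differential regions (median-of-ratios + exact Poisson test substitute)
# ---------------------------------------------------------------------------

def _region_counts(track: BinnedTrack, regions: list[Interval]) -> np.ndarray:
    out = np.empty(len(regions))
    for i, r in enumerate(regions):
        idx = track.grid.bins_overlapping(r)
        out[i] = float(np.asarray(track.values[idx.start:idx.stop],
                                  dtype=float).sum())
    return out


def differential_regions(counts_a: BinnedTrack, counts_b: BinnedTrack,
                         regions: list[Interval], min_fc: float = 1.5,
                         q_max: float = 0.05, fc_scale: str = "natural"
                         ) -> pd.DataFrame:
    """Differential signal per region between two conditions.

    Counts are summed per region, normalized by median-of-ratios size
    factors, and compared with the exact conditional Poisson test (a
    binomial test of condition A's reads among the region total).  A region
    is called when BH q <= ``q_max`` and the fold-change exceeds ``min_fc``
    (on the natural scale by default, or |log2 FC| > ``min_fc`` with
    ``fc_scale='log2'``).
    """
    if fc_scale not in ("natural", "log2"):
        raise ValueError(f"unknown fc_scale {fc_scale!r}")
    a = _region_counts(counts_a, regions)
    b = _region_counts(counts_b, regions)
    with np.errstate(invalid="ignore", divide="ignore"):
        geo = np.sqrt(a * b)
        ok = geo > 0
        ra = np.median(a[ok] / geo[ok]) if ok.any() else 1.0
        rb = np.median(b[ok] / geo[ok]) if ok.any() else 1.0
    sf_a, sf_b = max(ra, 1e-12), max(rb, 1e-12)
    norm_a, norm_b = a / sf_a, b / sf_b

    p0 = sf_a / (sf_a + sf_b)
    rows = []
    for i, r in enumerate(regions):
        total = int(a[i] + b[i])
        skipped = a[i] == 0 or b[i] == 0
        if total == 0:
            p = 1.0
        else:
            p = stats.binomtest(int(a[i]), total, p0).pvalue
        fc = (norm_a[i] + 0.5) / (norm_b[i] + 0.5)
        rows.append({"name": r.name or f"region{i}", "chrom": r.chrom,
                     "start": r.start, "end": r.end,
                     "mean_a": norm_a[i], "mean_b": norm_b[i],
                     "log2fc": np.log2(fc), "p": p, "skipped": skipped})
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    if fc_scale == "natural":
        fc_ok = np.maximum(2.0 ** df["log2fc"], 2.0 ** -df["log2fc"]) > min_fc
    else:
        fc_ok = df["log2fc"].abs() > min_fc
    df["called"] = fc_ok & (df["q"] <= q_max) & ~df["skipped"]
    return df


def fc_correlation(pairs: pd.DataFrame, x: str = "mark_log2fc",
                   y: str = "expr_log2fc") -> tuple[float, float]:
    """Pearson r and fitted slope between two log2 fold-change vectors."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    xv = pairs[x].to_numpy(dtype=float)
    yv = pairs[y].to_numpy(dtype=float)
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise ValueError("non-finite fold-changes (apply pseudocounts first)")
    if np.std(xv) == 0 or np.std(yv) == 0:
        return float("nan"), float("nan")
    res = stats.linregress(xv, yv)
    return float(res.rvalue), float(res.slope)


def make_fc_pairs(mark_a: np.ndarray, mark_b: np.ndarray,
                  expr_a: np.ndarray, expr_b: np.ndarray,
                  count_pseudo: float = 1.0, fpkm_pseudo: float = 0.01
                  ) -> pd.DataFrame:
    """Promoter-mark and expression log2 fold-changes with pseudocounts."""
    return pd.DataFrame({
        "mark_log2fc": np.log2((np.asarray(mark_a, dtype=float) + count_pseudo)
                               / (np.asarray(mark_b, dtype=float)
                                  + count_pseudo)),
        "expr_log2fc": np.log2((np.asarray(expr_a, dtype=float) + fpkm_pseudo)
                               / (np.asarray(expr_b, dtype=float)
                                  + fpkm_pseudo))})


# ---------------------------------------------------------------------------
# Tissue-specific clustering
# ---------------------------------------------------------------------------

def tissue_specific_clusters(signal: np.ndarray, tissues, k: int,
                             seed: int = 0, n_init: int = 10):
    """Row-normalize a regions x tissues matrix and k-means cluster it.

    Constant rows are removed (flagged with label -1).  Cluster ids are
    re-ordered by the tissue of maximal mean signal so the output ordering
    is deterministic and interpretable.  Returns ``(labels, profiles)``
    where profiles is a clusters x tissues frame of mean z-scores.
    """
    X = np.asarray(signal, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError("more clusters than rows")
    sd = X.std(axis=1)
    keep = sd > 0
    Z = (X[keep] - X[keep].mean(axis=1, keepdims=True)) \
        / sd[keep][:, None]
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Z)
    raw = km.labels_
    profiles = np.vstack([Z[raw == c].mean(axis=0) for c in range(k)])
    order = np.lexsort((-profiles.max(axis=1), profiles.argmax(axis=1)))
    remap = {int(old): new for new, old in enumerate(order)}
    labels = np.full(X.shape[0], -1, dtype=int)
    labels[keep] = [remap[int(c)] for c in raw]
    prof = pd.DataFrame(profiles[order], columns=list(tissues),
                        index=[f"cluster{i + 1}" for i in range(k)])
    return labels, prof
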