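"""Multi-variety epigenome statistics on a shared reference grid:
conserved-state fractions, subgroup-consensus switch matrices, SNP density
profiles around peaks, differential-signal saturation curves, epigenome
distance matrices, and core/distributed gene proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis
from scipy.stats import spearmanr

from .genome_io import BinGrid, BinnedTrack, Interval
from .segmentation import Segmentation


def _stack(segmentations: dict[str, Segmentation]) -> np.ndarray:
    segs = list(segmentations.values())
    grid = segs[0].grid
    for s in segs[1:]:
        if s.grid != grid:
            raise ValueError("panel varieties are on different grids")
    return np.vstack([s.states for s in segs])


def conserved_fraction(segmentations: dict[str, Segmentation]) -> pd.Series:
    """Per-state conserved proportion across the panel.

    A bin is conserved for state s when every variety labels it s; the
    reported value normalizes the conserved bin count by the mean
    per-variety abundance of s, removing state-size bias.
    """
    if len(segmentations) < 2:
        raise ValueError("need at least 2 varieties")
    S = _stack(segmentations)
    K = max(s.n_states for s in segmentations.values())
    all_same = (S == S[0]).all(axis=0)
    conserved = np.bincount(S[0, all_same] - 1, minlength=K).astype(float)
    mean_abund = np.vstack([np.bincount(row - 1, minlength=K)
                            for row in S]).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(mean_abund > 0, conserved / np.where(
            mean_abund > 0, mean_abund, 1), np.nan)
    return pd.Series(frac, index=[f"state{i + 1}" for i in range(K)],
                     name="conserved_fraction")


@dataclass
class SubgroupSwitch:
    consensus_bins: np.ndarray          # global bin indices
    state_a: np.ndarray                 # consensus state in group A per bin
    state_b: np.ndarray
    matrix: np.ndarray                  # K x K normalized switch matrix


def subgroup_switch(segmentations: dict[str, Segmentation],
                    group_a: list[str], group_b: list[str]) -> SubgroupSwitch:
    """Consensus bins where all of group A share one state, all of group B
    another, and the two differ; plus the abundance-normalized K x K matrix
    ``matrix[sA, sB] = count / (genome fraction of sA * total bins)``.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if not group_a or not group_b:
        raise ValueError("both groups need at least one variety")
    A = np.vstack([segmentations[v].states for v in group_a])
    B = np.vstack([segmentations[v].states for v in group_b])
    K = max(s.n_states for s in segmentations.values())
    n_bins = A.shape[1]
    a_uni = (A == A[0]).all(axis=0)
    b_uni = (B == B[0]).all(axis=0)
    mask = a_uni & b_uni & (A[0] != B[0])
    bins = np.flatnonzero(mask)
    sA, sB = A[0, bins], B[0, bins]
    counts = np.zeros((K, K))
    np.add.at(counts, (sA - 1, sB - 1), 1)
    frac_a = np.vstack([np.bincount(row - 1, minlength=K) for row in A]
                       ).mean(axis=0) / n_bins
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = np.where(frac_a[:, None] > 0,
                          counts / (np.where(frac_a[:, None] > 0,
                                             frac_a[:, None], 1) * n_bins),
                          np.nan)
    return SubgroupSwitch(consensus_bins=bins, state_a=sA, state_b=sB,
                          matrix=matrix)


def third_group_similarity(segmentations: dict[str, Segmentation],
                           switch: SubgroupSwitch, group_c: list[str]
                           ) -> tuple[float, float]:
    """Majority-vote similarity of a third group to A vs B over the
    consensus bins (fractions matching A's and B's consensus state)."""
    if len(switch.consensus_bins) == 0:
        return float("nan"), float("nan")
    C = np.vstack([segmentations[v].states for v in group_c]
                  )[:, switch.consensus_bins]
    maj = np.array([np.bincount(col).argmax() for col in C.T])
    return (float((maj == switch.state_a).mean()),
            float((maj == switch.state_b).mean()))


# ---------------------------------------------------------------------------
# SNP density profiles
# ---------------------------------------------------------------------------

@dataclass
class SNPDensityProfile:
    """Mean SNPs per bp: flank units + scaled body units, plus the
    boundary-mode upstream profile."""

    left_flank: np.ndarray
    body: np.ndarray
    right_flank: np.ndarray
    upstream_boundary: np.ndarray       # 1-kb before peak start, 20 units

    def combined(self) -> np.ndarray:
        return np.concatenate([self.left_flank, self.body, self.right_flank])


def snp_profile(snps: dict[str, np.ndarray], peaks: list[Interval],
                flank: int = 2000, unit: int = 10, body_units: int = 20,
                boundary_flank: int = 1000, boundary_units: int = 20
                ) -> SNPDensityProfile:
    """SNP density around peaks: ``flank`` bp on each side in ``unit``-bp
    steps, the peak body rescaled to ``body_units`` units, and a separate
    ``boundary_flank`` bp upstream profile in ``boundary_units`` units.
    Densities are (total SNPs in the unit across peaks) / (peaks x unit bp);
    strandless.
    """
    if not peaks:
        raise ValueError("no peaks")
    n_fl = flank // unit
    left = np.zeros(n_fl)
    right = np.zeros(n_fl)
    body = np.zeros(body_units)
    body_bp = np.zeros(body_units)
    upstream = np.zeros(boundary_units)
    b_unit = boundary_flank // boundary_units
    for p in peaks:
        pos = snps.get(p.chrom)
        if pos is None:
            pos = np.array([], dtype=np.int64)
        lo = np.searchsorted(pos, p.start - flank)
        hi = np.searchsorted(pos, p.end + flank)
        local = pos[lo:hi]
        for s in local:
            if s < p.start:
                left[(s - (p.start - flank)) // unit] += 1
            elif s >= p.end:
                right[(s - p.end) // unit] += 1
            else:
                u = int((s - p.start) * body_units // len(p))
                body[min(u, body_units - 1)] += 1
        # bp per scaled body unit differs per peak
        for u in range(body_units):
            body_bp[u] += (len(p) * (u + 1)) // body_units \
                - (len(p) * u) // body_units
        blo = np.searchsorted(pos, p.start - boundary_flank)
        for s in pos[blo:np.searchsorted(pos, p.start)]:
            upstream[(s - (p.start - boundary_flank)) // b_unit] += 1
    n = len(peaks)
    return SNPDensityProfile(
        left_flank=left / (n * unit),
        body=np.where(body_bp > 0, body / np.maximum(body_bp, 1), 0.0),
        right_flank=right / (n * unit),
        upstream_boundary=upstream / (n * b_unit))


# ---------------------------------------------------------------------------
# Saturation curves
# ---------------------------------------------------------------------------

def saturation_curve(regions_by_variety: dict[str, list[Interval]],
                     grid: BinGrid,
                     pairwise_diff: pd.DataFrame | None = None,
                     n_orders: int = 10, seed: int = 0) -> pd.DataFrame:
    """Accumulation and differential-proportion curves over random variety
    orderings.

    For each ordering and prefix size k the accumulation score is the
    fraction of genome bins covered by the union of the mark's regions over
    the first k varieties (non-decreasing in k by construction, asserted);
    the differential proportion is the mean pairwise differential fraction
    among the first k (``pairwise_diff`` is a symmetric variety x variety
    frame).  Reported as mean and sd over orderings.
    """
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")
    varieties = list(regions_by_variety)
    rng = np.random.default_rng(seed)
    masks = {}
    for v, regs in regions_by_variety.items():
        m = np.zeros(grid.n_bins, dtype=bool)
        for r in regs:
            idx = grid.bins_overlapping(r)
            m[idx.start:idx.stop] = True
        masks[v] = m
    acc = np.zeros((n_orders, len(varieties)))
    diff = np.full((n_orders, len(varieties)), np.nan)
    for o in range(n_orders):
        order = rng.permutation(varieties)
        union = np.zeros(grid.n_bins, dtype=bool)
        prev = 0.0
        for k, v in enumerate(order):
            union |= masks[v]
            acc[o, k] = union.mean()
            assert acc[o, k] >= prev - 1e-15, "accumulation must not decrease"
            prev = acc[o, k]
            if pairwise_diff is not None and k >= 1:
                sub = order[:k + 1]
                vals = [pairwise_diff.loc[x, y]
                        for i, x in enumerate(sub) for y in sub[i + 1:]]
                diff[o, k] = float(np.mean(vals))
    if pairwise_diff is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # k=1 has no pairs
            dmean, dsd = np.nanmean(diff, axis=0), np.nanstd(diff, axis=0)
    else:
        dmean = dsd = np.nan
    return pd.DataFrame({
        "k": np.arange(1, len(varieties) + 1),
        "accumulation_mean": acc.mean(axis=0),
        "accumulation_sd": acc.std(axis=0),
        "differential_mean": dmean,
        "differential_sd": dsd,
    })


# ---------------------------------------------------------------------------
# Distance matrices and core/distributed proportions
# ---------------------------------------------------------------------------

def epigenome_distance(tracks: dict[str, BinnedTrack],
                       metric: str = "bray-curtis") -> pd.DataFrame:
    """Symmetric variety x variety distance matrix on binned signal."""
    if metric not in ("bray-curtis", "1-spearman"):
        raise ValueError(f"unknown metric {metric!r}")
    names = list(tracks)
    X = np.vstack([np.asarray(tracks[v].values, dtype=float) for v in names])
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "bray-curtis":
                d = braycurtis(X[i], X[j])
            else:
                rho = spearmanr(X[i], X[j]).statistic
                d = 1.0 - float(rho)
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=names, columns=names)


def mds_ordination(distances: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """2-D metric MDS embedding of a distance matrix (seeded, delegated)."""
    from sklearn.manifold import MDS
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        emb = MDS(n_components=2, dissimilarity="precomputed",
                  random_state=seed, init="random",
                  normalized_stress="auto").fit_transform(
                      distances.to_numpy())
    return pd.DataFrame(emb, index=distances.index, columns=["MDS1", "MDS2"])


def core_vs_distributed(presence: pd.DataFrame, labels: pd.Series
                        ) -> pd.DataFrame:
    """Per-mark proportion of marked genes that are core vs distributed.

    ``presence`` is the genes x marks boolean table; ``labels`` maps every
    gene to 'core' or 'distributed' (pan-genome labels are inputs here).
    """
    unlabeled = [g for g in presence.index if g not in labels.index]
    if unlabeled:
        raise ValueError(f"unlabeled genes: {unlabeled}")
    rows = {}
    for mark in presence.columns:
        marked = presence.index[presence[mark]]
        lab = labels.loc[marked]
        n = len(marked)
        rows[mark] = {
            "n_marked": n,
            "core": float((lab == "core").mean()) if n else np.nan,
            "distributed": float((lab == "distributed").mean()) if n
            else np.nan,
        }
    return pd.DataFrame(rows).T
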