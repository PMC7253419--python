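"""Per-cytosine methylation levels, 200-bp binning, the binomial DMR caller,
and the DMR / state-switch coupling matrix.

A differentially methylated region (DMR) is a fixed-width bin passing two
conditions between two samples: an effect size (the unweighted mean
per-cytosine level differs by at least ``delta_min``, default 0.6) and a
significance condition (two-sided binomial test of sample A's pooled counts
against sample B's pooled level, BH-adjusted q <= ``q_max``, default 0.05).
Only cytosines with coverage >= 3 enter level calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import BinGrid
from .segmentation import Segmentation

CONTEXTS = ("CG", "CHG", "CHH")

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "total"]


def read_calls(path) -> pd.DataFrame:
    """Read a tab-delimited cytosine call table (bisulfite-extractor layout)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"call table lacks columns {missing}")
    return df


def cytosine_levels(calls: pd.DataFrame, min_coverage: int = 3
                    ) -> pd.DataFrame:
    """Keep cytosines with coverage >= ``min_coverage``; add ``level``."""
    if ((calls["meth"] < 0) | (calls["meth"] > calls["total"])).any():
        raise ValueError("methylated count outside [0, total]")
    out = calls[calls["total"] >= min_coverage].copy()
    out["level"] = out["meth"] / out["total"]
    return out


def bin_methylation(levels: pd.DataFrame, grid: BinGrid, context: str,
                    weighting: str = "unweighted") -> pd.DataFrame:
    """Per-bin methylation summary for one context.

    Returns a frame indexed by global bin id with the unweighted (or
    coverage-weighted) mean level, the number of qualifying cytosines, and
    the pooled methylated/total read counts used by the binomial test.  Bins
    without qualifying cytosines are absent (missing).
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    if weighting not in ("unweighted", "coverage"):
        raise ValueError(f"unknown weighting {weighting!r}")
    sub = levels[levels["context"] == context]
    if sub.empty:
        return pd.DataFrame(columns=["mean_level", "n_cytosines",
                                     "meth_sum", "total_sum"])
    offsets = sub["chrom"].map(grid.chrom_offset).to_numpy()
    sub = sub.assign(bin=offsets + sub["pos"].to_numpy() // grid.width)
    g = sub.groupby("bin")
    out = pd.DataFrame({
        "mean_level": g["level"].mean() if weighting == "unweighted"
        else g["meth"].sum() / g["total"].sum(),
        "n_cytosines": g.size(),
        "meth_sum": g["meth"].sum(),
        "total_sum": g["total"].sum(),
    })
    return out


def binom_two_sided(m: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value (minimum-likelihood method).

    Sums P(k) over all outcomes no more likely than the observed one, the
    same convention as ``scipy.stats.binomtest`` (tested against it and an
    exact enumeration oracle).
    """
    k = np.arange(n + 1)
    pmf = stats.binom.pmf(k, n, p0)
    return float(min(1.0, pmf[pmf <= pmf[m] * (1 + 1e-7)].sum()))


@dataclass
class DMRResult:
    """All tested bins plus the subset passing both DMR conditions."""

    tested: pd.DataFrame          # per-bin delta, p, q, counts
    dmrs: pd.DataFrame            # the called subset with direction


def call_dmrs(calls_a: pd.DataFrame, calls_b: pd.DataFrame, grid: BinGrid,
              context: str, delta_min: float = 0.6, q_max: float = 0.05,
              min_cytosines: int = 2, min_coverage: int = 3) -> DMRResult:
    """Call 200-bp DMRs between two samples for one context.

    For each bin with >= ``min_cytosines`` qualifying cytosines in both
    samples, sample A's pooled counts are tested two-sided against sample B's
    pooled level (continuity-clamped away from 0/1), p-values BH-adjusted
    across tested bins of the context.  A DMR needs |delta| >= ``delta_min``
    (delta from unweighted mean levels) and q <= ``q_max``.  A symmetric
    B-vs-A p-value is reported as a QC column.
    """
    la = cytosine_levels(calls_a, min_coverage)
    lb = cytosine_levels(calls_b, min_coverage)
    ba = bin_methylation(la, grid, context)
    bb = bin_methylation(lb, grid, context)
    joined = ba.join(bb, how="inner", lsuffix="_a", rsuffix="_b")
    joined = joined[(joined["n_cytosines_a"] >= min_cytosines)
                    & (joined["n_cytosines_b"] >= min_cytosines)]
    if joined.empty:
        empty = pd.DataFrame(columns=["chrom", "start", "end", "context",
                                      "delta", "p", "q", "p_sym",
                                      "direction"])
        return DMRResult(tested=empty, dmrs=empty)

    n_b = joined["total_sum_b"].to_numpy()
    p_hat_b = joined["meth_sum_b"].to_numpy() / n_b
    p_hat_b = np.clip(p_hat_b, 1.0 / (n_b + 2), 1.0 - 1.0 / (n_b + 2))
    n_a = joined["total_sum_a"].to_numpy()
    p_hat_a = joined["meth_sum_a"].to_numpy() / n_a
    p_hat_a_c = np.clip(p_hat_a, 1.0 / (n_a + 2), 1.0 - 1.0 / (n_a + 2))

    m_a = joined["meth_sum_a"].to_numpy().astype(int)
    m_b = joined["meth_sum_b"].to_numpy().astype(int)
    p = np.array([binom_two_sided(m, int(n), p0)
                  for m, n, p0 in zip(m_a, n_a, p_hat_b)])
    p_sym = np.array([binom_two_sided(m, int(n), p0)
                      for m, n, p0 in zip(m_b, n_b, p_hat_a_c)])
    q = multipletests(p, method="fdr_bh")[1]

    delta = (joined["mean_level_a"] - joined["mean_level_b"]).to_numpy()
    rows = []
    for i, b in enumerate(joined.index):
        biv = grid.bin_interval(int(b))
        rows.append({"bin": int(b), "chrom": biv.chrom, "start": biv.start,
                     "end": biv.end, "context": context,
                     "delta": delta[i], "p": p[i], "q": q[i],
                     "p_sym": p_sym[i],
                     "n_cyt_a": int(joined["n_cytosines_a"].iloc[i]),
                     "n_cyt_b": int(joined["n_cytosines_b"].iloc[i])})
    tested = pd.DataFrame(rows).set_index("bin")
    called = tested[(tested["delta"].abs() >= delta_min)
                    & (tested["q"] <= q_max)].copy()
    called["direction"] = np.sign(called["delta"]).astype(int)
    return DMRResult(tested=tested, dmrs=called)


def write_dmrs(result: DMRResult, path) -> None:
    """DMRs as BED6+ (name=context, score=-log10 q, extra delta/p/q)."""
    with open(path, "w") as fh:
        for b, row in result.dmrs.sort_values(["chrom", "start"]).iterrows():
            score = -np.log10(max(row["q"], 1e-300))
            fh.write(f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}"
                     f"\t{row['context']}\t{score:.3f}\t.\t{row['delta']:.4f}"
                     f"\t{row['p']:.3e}\t{row['q']:.3e}\n")


@dataclass
class DMRSwitchMatrix:
    """DMR counts per chromatin-state transition and derived matrices.

    ``relative = counts / transitions`` (cells with zero genome-wide
    transitions are NaN-masked); ``row_normalized`` scales each relative row
    to sum 1 over unmasked cells; ``log10`` is its log with zeros masked.
    """

    counts: np.ndarray
    transitions: np.ndarray
    relative: np.ndarray
    row_normalized: np.ndarray
    log10: np.ndarray
    state_labels: list[str]


def dmr_state_coupling(dmrs: pd.DataFrame, seg_a: Segmentation,
                       seg_b: Segmentation,
                       state_labels: list[str] | None = None
                       ) -> DMRSwitchMatrix:
    """Couple DMR bins to the chromatin-state transition they sit on."""
    if seg_a.grid != seg_b.grid:
        raise ValueError("segmentations on different grids")
    K = max(seg_a.n_states, seg_b.n_states)
    transitions = np.zeros((K, K))
    np.add.at(transitions, (seg_a.states - 1, seg_b.states - 1), 1)
    counts = np.zeros((K, K))
    if len(dmrs):
        bins = dmrs.index.to_numpy() if "bin" not in dmrs.columns \
            else dmrs["bin"].to_numpy()
        np.add.at(counts, (seg_a.states[bins] - 1, seg_b.states[bins] - 1), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        relative = np.where(transitions > 0, counts / transitions, np.nan)
        rowsum = np.nansum(relative, axis=1, keepdims=True)
        row_normalized = np.where(
            np.isnan(relative) | (rowsum == 0), np.nan, relative / rowsum)
        log10 = np.where(np.nan_to_num(row_normalized) > 0,
                         np.log10(np.where(row_normalized > 0,
                                           row_normalized, 1.0)), np.nan)
    labels = state_labels or [f"state{i + 1}" for i in range(K)]
    return DMRSwitchMatrix(counts=counts, transitions=transitions,
                           relative=relative, row_normalized=row_normalized,
                           log10=log10, state_labels=labels)


def matrix_to_tsv(matrix: np.ndarray, labels, path) -> None:
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path, sep="\t")
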