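"""Open-chromatin element classification (DRE/PRE), target linking,
tissue-specific DRE clustering, and loop-based gene categories.

A FAIRE/ATAC peak is a proximal regulatory element (PRE) when it sits within
``pre_distance`` of a TSS or overlaps a promoter window, and a distal
regulatory element (DRE) when it overlaps neither gene body nor promoter AND
its mean CG methylation is at or below a low-methylation cutoff.  Genes are
then grouped into six categories by whether their own promoter carries a
PRE, whether it participates in a (promoter-anchored) loop, and whether any
loop partner promoter carries a PRE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .genome_io import GeneModel, Interval, nearest_tss, overlap_pairs
from .state_dynamics import tissue_specific_clusters


@dataclass
class RegElement:
    interval: Interval
    klass: str                       # DRE | PRE | unclassified
    reason: str = ""
    mean_cg: float | None = None
    tss_distance: int | None = None
    linked_gene: str | None = None


def _region_mean_methylation(iv: Interval, methylbins: pd.DataFrame,
                             grid) -> float | None:
    """Unweighted mean of per-bin mean levels over the bins a peak touches."""
    idx = [b for b in grid.bins_overlapping(iv) if b in methylbins.index]
    if not idx:
        return None
    return float(methylbins.loc[idx, "mean_level"].mean())


def classify_faire(peaks: list[Interval], genes: list[GeneModel],
                   methylbins: pd.DataFrame, grid,
                   promoter_window: tuple[int, int] = (1000, 500),
                   pre_distance: int = 1000,
                   lowmeth_max: float = 0.1) -> list[RegElement]:
    """Split open-chromatin peaks into PRE / DRE / unclassified.

    ``methylbins`` is the CG output of
    :func:`chromdyn.methylation.bin_methylation`; peaks whose bins carry no
    qualifying cytosines cannot satisfy the low-methylation rule and are
    excluded with reason ``no_methylation_data``.
    """
    up, down = promoter_window
    promoters = [g.promoter(upstream=up, downstream=down) for g in genes]
    bodies = [g.body for g in genes]
    # peaks sit on the b side of both queries
    prom_peak = {pi for _, pi, _ in overlap_pairs(promoters, peaks)}
    body_peak = {pi for _, pi, _ in overlap_pairs(bodies, peaks)}

    out = []
    for i, p in enumerate(peaks):
        g, d = nearest_tss(p, genes)
        el = RegElement(interval=p, klass="unclassified",
                        tss_distance=d)
        if (d is not None and abs(d) <= pre_distance) or i in prom_peak:
            el.klass = "PRE"
            el.linked_gene = g.gene_id if g else None
        elif i in body_peak:
            el.reason = "overlaps_gene_body"
        else:
            mcg = _region_mean_methylation(p, methylbins, grid)
            el.mean_cg = mcg
            if mcg is None:
                el.reason = "no_methylation_data"
            elif mcg <= lowmeth_max:
                el.klass = "DRE"
            else:
                el.reason = "high_methylation"
        out.append(el)
    return out


def link_dre_targets(dres: list[RegElement], genes: list[GeneModel]
                     ) -> list[RegElement]:
    """Link each DRE to its nearest-TSS gene (ties to the smaller gene id)."""
    for el in dres:
        g, d = nearest_tss(el.interval, genes)
        if g is None:
            el.reason = (el.reason + ";unlinked").strip(";")
        else:
            el.linked_gene = g.gene_id
            el.tss_distance = d
    return dres


def cluster_tissue_dres(signal: np.ndarray, tissues, k: int = 9,
                        seed: int = 0,
                        linked_expression: pd.DataFrame | None = None):
    """Cluster tissue-specific DREs by z-scaled signal across tissues.

    Returns ``(labels, profiles, expression_summary)``; the summary is the
    per-cluster mean linked-gene FPKM per tissue when expression is given.
    """
    X = np.asarray(signal, dtype=float)
    if k > X.shape[0]:
        raise ValueError("more clusters than elements")
    if k == X.shape[0]:
        labels = np.arange(k)
        Z = (X - X.mean(axis=1, keepdims=True)) \
            / np.where(X.std(axis=1, keepdims=True) > 0,
                       X.std(axis=1, keepdims=True), 1)
        prof = pd.DataFrame(Z, columns=list(tissues),
                            index=[f"cluster{i + 1}" for i in range(k)])
    else:
        labels, prof = tissue_specific_clusters(X, tissues, k, seed=seed)
    summary = None
    if linked_expression is not None:
        summary = linked_expression.groupby(labels).mean()
    return labels, prof, summary


@dataclass
class GeneLoopCategory:
    gene_id: str
    own_pre: bool
    looped: bool
    partner_pre: bool
    category: int


def _category(own: bool, looped: bool, partner: bool) -> int:
    """Decision table for the six loop/PRE gene groups."""
    if not looped:
        assert not partner, "partner PRE without a loop is unreachable"
        return 5 if own else 6
    if own:
        return 1 if partner else 2
    return 3 if partner else 4


def gene_loop_categories(genes: list[GeneModel],
                         loops: list[tuple[Interval, Interval, float]],
                         pres: list[Interval],
                         promoter_window: tuple[int, int] = (1000, 500)
                         ) -> pd.DataFrame:
    """Assign each gene to one of six loop/PRE categories.

    Predicates per gene: its own promoter overlaps a PRE; any loop anchor
    overlaps its promoter; any promoter at the other anchor of such a loop
    belongs to a gene whose own promoter carries a PRE.  An anchor touching
    several promoters keeps every mapping.
    """
    up, down = promoter_window
    promoters = [g.promoter(upstream=up, downstream=down) for g in genes]
    own = np.zeros(len(genes), dtype=bool)
    for gi, _, _ in overlap_pairs(promoters, pres):
        own[gi] = True

    anchors = []
    for li, (a, b, _) in enumerate(loops):
        anchors.append((li, 0, a))
        anchors.append((li, 1, b))
    anchor_ivs = [iv for _, _, iv in anchors]
    anchor_genes: dict[int, list[int]] = {}
    for ai, gi, _ in overlap_pairs(anchor_ivs, promoters):
        anchor_genes.setdefault(ai, []).append(gi)

    looped = np.zeros(len(genes), dtype=bool)
    partner = np.zeros(len(genes), dtype=bool)
    for ai, (li, side, _) in enumerate(anchors):
        other_ai = 2 * li + (1 - side)
        for gi in anchor_genes.get(ai, []):
            looped[gi] = True
            for pj in anchor_genes.get(other_ai, []):
                if own[pj]:
                    partner[gi] = True
    rows = [GeneLoopCategory(g.gene_id, bool(own[i]), bool(looped[i]),
                             bool(partner[i]),
                             _category(own[i], looped[i], partner[i]))
            for i, g in enumerate(genes)]
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("gene_id")
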