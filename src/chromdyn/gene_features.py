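"""Gene-level integrations: peak-to-gene assignment, promoter mark
combinations, summit position classes, expression breadth, TSS-profile
clustering, and TE insertion-location classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .genome_io import GeneModel, Interval, overlap_pairs


@dataclass
class GeneMarkTable:
    """Per-gene, per-mark peak assignments (presence, peak ids, summits)."""

    genes: list[str]
    marks: list[str]
    presence: pd.DataFrame                       # genes x marks bool
    peaks: dict[tuple[str, str], list[Interval]] = field(default_factory=dict)

    def peaks_for(self, gene_id: str, mark: str) -> list[Interval]:
        return self.peaks.get((gene_id, mark), [])


def assign_peaks_to_genes(peaks_by_mark: dict[str, list[Interval]],
                          genes: list[GeneModel], min_bp: int = 1,
                          scope: str = "body",
                          promoter_window: tuple[int, int] = (1000, 500)
                          ) -> GeneMarkTable:
    """Assign peaks to genes by >= ``min_bp`` overlap.

    ``scope='body'`` uses the annotated gene span; ``scope='promoter'`` uses
    a window of ``promoter_window`` (upstream, downstream) bp around the TSS
    in transcription orientation.  A peak overlapping several genes is
    assigned to all of them.
    """
    if scope == "body":
        targets = [g.body for g in genes]
    elif scope == "promoter":
        up, down = promoter_window
        targets = [g.promoter(upstream=up, downstream=down) for g in genes]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    gene_ids = [g.gene_id for g in genes]
    marks = list(peaks_by_mark)
    presence = pd.DataFrame(False, index=gene_ids, columns=marks)
    assigned: dict[tuple[str, str], list[Interval]] = {}
    for mark, pk in peaks_by_mark.items():
        for gi, pi, _ in overlap_pairs(targets, pk, min_bp=min_bp):
            gid = gene_ids[gi]
            presence.loc[gid, mark] = True
            assigned.setdefault((gid, mark), []).append(pk[pi])
    return GeneMarkTable(genes=gene_ids, marks=marks, presence=presence,
                         peaks=assigned)


def mark_combination_class(table: GeneMarkTable, marks: list[str]
                           ) -> pd.Series:
    """Per-gene label: the exact subset of the requested marks present.

    Labels are '+'-joined mark names in the requested order ('none' for the
    empty subset), giving up to 2^|marks| classes.
    """
    missing = [m for m in marks if m not in table.marks]
    if missing:
        raise ValueError(f"marks not in table: {missing}")
    sub = table.presence[marks]
    labels = sub.apply(
        lambda row: "+".join(m for m in marks if row[m]) or "none", axis=1)
    labels.name = "mark_class"
    return labels


def _summit(peak: Interval) -> int:
    """Summit = score-carrying single bp if encoded, else the midpoint."""
    return (peak.start + peak.end) // 2


def summit_position_class(genes: list[GeneModel],
                          peaks: list[Interval],
                          summits: dict[str, int] | None = None
                          ) -> pd.Series:
    """Class per gene from the H3K4me3 summit position in transcription
    orientation: upstream of the TSS, between TSS and ATG, downstream of the
    ATG, or unmarked.

    With several assigned peaks the one with the highest score wins (tie:
    summit nearest the TSS).  ``summits`` optionally maps peak names to
    summit bp; otherwise the peak midpoint is used.
    """
    bodies = [g.body for g in genes]
    hits: dict[int, list[Interval]] = {}
    for gi, pi, _ in overlap_pairs(bodies, peaks, min_bp=1):
        hits.setdefault(gi, []).append(peaks[pi])
    out = {}
    for gi, g in enumerate(genes):
        cand = hits.get(gi)
        if not cand:
            out[g.gene_id] = "unmarked"
            continue

        def summit_of(p):
            if summits and p.name in summits:
                return summits[p.name]
            return _summit(p)

        best = min(cand, key=lambda p: (-(p.score or 0),
                                        abs(summit_of(p) - g.tss)))
        s = summit_of(best)
        if g.strand == "-":
            if s > g.tss:
                out[g.gene_id] = "upstream"
            elif g.atg is not None and s <= g.atg:
                out[g.gene_id] = "downstream_of_ATG"
            else:
                out[g.gene_id] = "TSS_ATG"
        else:
            if s < g.tss:
                out[g.gene_id] = "upstream"
            elif g.atg is not None and s >= g.atg:
                out[g.gene_id] = "downstream_of_ATG"
            else:
                out[g.gene_id] = "TSS_ATG"
    return pd.Series(out, name="summit_class")


def expression_breadth(fpkm: pd.DataFrame, threshold: float = 1.0
                       ) -> pd.Series:
    """Number of tissues in which a gene is expressed (FPKM strictly >
    threshold)."""
    if fpkm.shape[1] < 1:
        raise ValueError("need at least one tissue column")
    if (fpkm.to_numpy() < 0).any():
        raise ValueError("negative FPKM values")
    breadth = (fpkm > threshold).sum(axis=1)
    breadth.name = "breadth"
    return breadth


def promoter_profile_clusters(profiles: np.ndarray, k: int = 15,
                              min_cluster: int = 2000, seed: int = 0,
                              n_init: int = 10):
    """K-means over concatenated log2(ratio+1) TSS profiles.

    ``profiles`` has shape (genes, marks, positions); the default geometry is
    TSS +/- 2 kb at 10-bp steps, i.e. 401 positions per mark.  Clusters
    smaller than ``min_cluster`` are flagged in the QC frame, never merged.
    Returns ``(labels, qc)``.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 3:
        raise ValueError("profiles must be (genes, marks, positions)")
    n = X.shape[0]
    if k > n:
        raise ValueError("more clusters than genes")
    feat = np.log2(X + 1).reshape(n, -1)
    if np.allclose(feat.std(axis=0), 0):
        labels = np.zeros(n, dtype=int)
        qc = pd.DataFrame({"size": [n], "small": [n < min_cluster],
                           "degenerate": [True]},
                          index=["cluster1"])
        return labels, qc
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(feat)
    labels = km.labels_
    sizes = np.bincount(labels, minlength=k)
    qc = pd.DataFrame({"size": sizes, "small": sizes < min_cluster,
                       "degenerate": False},
                      index=[f"cluster{i + 1}" for i in range(k)])
    return labels, qc


def compute_promoter_profiles(tracks: dict[str, np.ndarray],
                              input_track: np.ndarray,
                              genes: list[GeneModel], chrom_of,
                              flank: int = 2000, step: int = 10,
                              background: float = 1.0) -> np.ndarray:
    """Signal/input ratio profiles around each TSS (orientation-flipped).

    ``tracks``/``input_track`` map chromosome name to a per-``step``-bp value
    array (``tracks[mark][chrom][i]`` covers ``[i*step, (i+1)*step)``).
    Positions outside the chromosome or with missing input are imputed at the
    background rate.  Returns (genes, marks, 2*flank/step+1).
    """
    marks = list(tracks)
    n_pos = 2 * flank // step + 1
    out = np.full((len(genes), len(marks), n_pos), background, dtype=float)
    for gi, g in enumerate(genes):
        chrom = chrom_of(g)
        center = g.tss // step
        for m, mark in enumerate(marks):
            sig = tracks[mark][chrom]
            inp = input_track[chrom]
            for j in range(n_pos):
                off = j - n_pos // 2
                idx = center + (off if g.strand != "-" else -off)
                if 0 <= idx < len(sig):
                    denom = inp[idx] if idx < len(inp) and inp[idx] > 0 \
                        else background
                    out[gi, m, j] = sig[idx] / denom
    return out


def te_insertion_class(genes: list[GeneModel], tes: list[Interval]
                       ) -> pd.DataFrame:
    """Per-gene TE location class per family and overall.

    A TE covering any exonic bp of the gene counts as 'exon' even when it
    also covers intron (exon dominates); a TE touching only intronic bp is
    'intron'; otherwise 'none'.
    """
    bodies = [g.body for g in genes]
    hits: dict[int, list[Interval]] = {}
    for gi, ti, _ in overlap_pairs(bodies, tes, min_bp=1):
        hits.setdefault(gi, []).append(tes[ti])
    families = sorted({t.name for t in tes if t.name})
    rows = []
    for gi, g in enumerate(genes):
        row = {"gene_id": g.gene_id}
        per_family = {f: "none" for f in families}
        overall = "none"
        for te in hits.get(gi, []):
            exon_hit = any(min(te.end, e) - max(te.start, s) > 0
                           for s, e in g.exons)
            intron_hit = any(min(te.end, e) - max(te.start, s) > 0
                             for s, e in g.introns())
            cls = "exon" if exon_hit else ("intron" if intron_hit else "none")
            for scopekey in ([te.name] if te.name in per_family else []):
                per_family[scopekey] = _dominate(per_family[scopekey], cls)
            overall = _dominate(overall, cls)
        row.update(per_family)
        row["overall"] = overall
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def _dominate(current: str, new: str) -> str:
    rank = {"none": 0, "intron": 1, "exon": 2}
    return current if rank[current] >= rank[new] else new
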