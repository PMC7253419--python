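"""One-command synthetic study: simulate an epigenome and run every analysis
stage, writing all declared outputs to a directory.

The pipeline is fully deterministic under one seed and sized so a desk-scale
run (default two 2-Mb chromosomes at 200-bp bins) completes in minutes on a
single CPU.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import (gene_features, genome_io, methylation, regulatory_elements,
               state_dynamics, synthetic_data, variety_panel)
from .segmentation import (BinarizedMatrix, CategoryRules, annotate_states,
                           decode, fit_hmm)


def run_pipeline(config: synthetic_data.SimConfig, seed: int, outdir,
                 hmm_k: int | None = None, hmm_n_init: int = 2,
                 hmm_max_iter: int = 100) -> dict[str, str]:
    """Simulate, segment, call DMRs, and compute every downstream table.

    Returns a manifest mapping output names to file paths (also written as
    ``manifest.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def emit(name: str, fname: str) -> Path:
        path = out / fname
        manifest[name] = str(path)
        return path

    cfg = config
    genome = cfg.genome()
    grid = cfg.grid()
    genome.to_tsv(emit("genome", "genome.tsv"))

    # -- annotation ---------------------------------------------------------
    ann = synthetic_data.simulate_annotation(cfg, seed)
    genome_io.write_gff_genes(ann.genes, emit("genes", "genes.gff3"))
    genome_io.write_bed(ann.tes, emit("tes", "tes.bed"))
    genome_io.write_bed(ann.het_blocks, emit("het_blocks", "het_blocks.bed"))

    # -- hidden states and tracks ------------------------------------------
    truth_states = synthetic_data.simulate_states(ann, cfg, seed)
    tissues = list(truth_states)
    for tissue, seg in truth_states.items():
        seg.to_bed(emit(f"truth_states/{tissue}",
                        f"truth_states.{tissue}.bed"))
    tracks_by_tissue, inputs, presence = {}, {}, {}
    for tissue, seg in truth_states.items():
        tr, inp, pres = synthetic_data.simulate_tracks(seg, cfg, seed,
                                                       name=tissue)
        tracks_by_tissue[tissue], inputs[tissue] = tr, inp
        presence[tissue] = pres
        for mark, track in tr.items():
            track.to_bedgraph(emit(f"tracks/{tissue}/{mark}",
                                   f"track.{tissue}.{mark}.bedgraph"))
        inp.to_bedgraph(emit(f"tracks/{tissue}/input",
                             f"track.{tissue}.input.bedgraph"))

    # -- segmentation: concatenated training, per-tissue decoding ----------
    mats = {t: BinarizedMatrix.from_tracks(tracks_by_tissue[t], inputs[t])
            for t in tissues}
    X = np.vstack([mats[t].X for t in tissues])
    lengths = [n for t in tissues for n in grid.sequence_lengths()]
    concat = _ConcatMatrix(X, lengths, mats[tissues[0]].marks)
    K = hmm_k or cfg.K
    model = fit_hmm(concat, K, seed=seed, n_init=hmm_n_init,
                    max_iter=hmm_max_iter)
    model.to_tsvs(str(out / "hmm"))
    manifest["hmm_emissions"] = str(out / "hmm.emissions.tsv")
    manifest["hmm_transitions"] = str(out / "hmm.transitions.tsv")
    segs = {t: decode(model, mats[t]) for t in tissues}
    for t, seg in segs.items():
        seg.to_bed(emit(f"segmentation/{t}", f"segmentation.{t}.bed"))
    annot = annotate_states(segs[tissues[0]], ann.genes, ann.tes,
                            model=model, rules=CategoryRules())
    table = annot.enrichment.copy()
    table.insert(0, "coverage", annot.coverage)
    if annot.categories:
        table.insert(1, "category", annot.categories)
    table.to_csv(emit("state_annotation", "state_annotation.tsv"), sep="\t")

    # -- methylome and DMRs -------------------------------------------------
    calls_a, calls_b, dmr_truth = synthetic_data.simulate_methylome(
        truth_states[tissues[0]], cfg, seed)
    calls_a.to_csv(emit("methylation/sampleA", "methylation.A.tsv"),
                   sep="\t", index=False)
    calls_b.to_csv(emit("methylation/sampleB", "methylation.B.tsv"),
                   sep="\t", index=False)
    dmr_truth.to_csv(emit("truth_dmrs", "truth_dmrs.tsv"), sep="\t",
                     index=False)
    dmr_res = methylation.call_dmrs(calls_a, calls_b, grid,
                                    cfg.dmr_context)
    methylation.write_dmrs(dmr_res, emit("dmrs", "dmrs.bed"))
    coupling = methylation.dmr_state_coupling(dmr_res.dmrs, segs[tissues[0]],
                                              segs[tissues[1]])
    methylation.matrix_to_tsv(coupling.log10, coupling.state_labels,
                              emit("dmr_coupling", "dmr_coupling.log10.tsv"))

    # -- state switching ----------------------------------------------------
    pair_mats = []
    for i, t1 in enumerate(tissues):
        for t2 in tissues[i + 1:]:
            m = state_dynamics.switch_matrix(segs[t1], segs[t2])
            pair_mats.append(m)
            state_dynamics.switch_to_tsv(
                m, str(out / f"switch.{t1}-{t2}"))
            manifest[f"switch/{t1}-{t2}"] = \
                str(out / f"switch.{t1}-{t2}.probabilities.tsv")
    combined = state_dynamics.combine_pairs(pair_mats)
    state_dynamics.switch_to_tsv(combined, str(out / "switch.combined"))
    manifest["switch_combined"] = \
        str(out / "switch.combined.probabilities.tsv")

    # -- expression and gene features ---------------------------------------
    fpkm = synthetic_data.simulate_expression(truth_states, ann.genes, cfg,
                                              seed)
    fpkm.to_csv(emit("fpkm", "fpkm.tsv"), sep="\t")
    breadth = gene_features.expression_breadth(fpkm)
    breadth.to_csv(emit("breadth", "expression_breadth.tsv"), sep="\t")

    t0 = tissues[0]
    peaks_by_mark = {
        mark: _score_regions(presence[t0][mark], tracks_by_tissue[t0][mark])
        for mark in cfg.marks}
    for mark in ("H3K4me3", "FAIRE"):
        genome_io.write_bed(peaks_by_mark[mark],
                            emit(f"peaks/{mark}", f"peaks.{t0}.{mark}.bed"))
    gm = gene_features.assign_peaks_to_genes(peaks_by_mark, ann.genes)
    gm.presence.to_csv(emit("gene_marks", "gene_marks.tsv"), sep="\t")
    combos = gene_features.mark_combination_class(
        gm, [m for m in ("H3K4me3", "H3K27ac", "RNAPII") if m in gm.marks])
    combos.to_csv(emit("mark_classes", "mark_classes.tsv"), sep="\t")
    summit = gene_features.summit_position_class(ann.genes,
                                                 peaks_by_mark["H3K4me3"])
    summit.to_csv(emit("summit_classes", "summit_classes.tsv"), sep="\t")
    te_cls = gene_features.te_insertion_class(ann.genes, ann.tes)
    te_cls.to_csv(emit("te_classes", "te_classes.tsv"), sep="\t")

    # promoter-mark fold change vs expression fold change (two tissues)
    prom = [g.promoter(genome=genome) for g in ann.genes]
    sig = {t: np.array([_interval_sum(tracks_by_tissue[t]["H3K4me3"], p)
                        for p in prom]) for t in tissues[:2]}
    pairs = state_dynamics.make_fc_pairs(sig[tissues[0]], sig[tissues[1]],
                                         fpkm[tissues[0]].to_numpy(),
                                         fpkm[tissues[1]].to_numpy())
    r, slope = state_dynamics.fc_correlation(pairs)
    pd.DataFrame({"stat": ["pearson_r", "slope"], "value": [r, slope]}
                 ).to_csv(emit("fc_correlation", "fc_correlation.tsv"),
                          sep="\t", index=False)

    # -- regulatory elements ------------------------------------------------
    scene = synthetic_data.simulate_regulatory_scene(seed=seed)
    levels = methylation.cytosine_levels(scene.cg_calls)
    mbins = methylation.bin_methylation(levels, scene.grid, "CG")
    elements = regulatory_elements.classify_faire(scene.peaks, scene.genes,
                                                  mbins, scene.grid)
    dres = [e for e in elements if e.klass == "DRE"]
    regulatory_elements.link_dre_targets(dres, scene.genes)
    _write_elements(elements, emit("elements", "elements.bed"))
    genome_io.write_bedpe(scene.loops, emit("loops", "loops.bedpe"))
    pres = [e.interval for e in elements if e.klass == "PRE"]
    cats = regulatory_elements.gene_loop_categories(scene.genes, scene.loops,
                                                    pres)
    cats.to_csv(emit("loop_categories", "loop_categories.tsv"), sep="\t")
    labels, prof, _ = regulatory_elements.cluster_tissue_dres(
        scene.dre_signal, scene.tissues, k=3, seed=seed)
    pd.DataFrame({"cluster": labels}).to_csv(
        emit("dre_clusters", "dre_clusters.tsv"), sep="\t", index=False)

    # -- variety panel ------------------------------------------------------
    panel = synthetic_data.simulate_panel(truth_states[t0], cfg, seed)
    states_df = pd.DataFrame({v: panel.segmentations[v].states
                              for v in panel.varieties})
    states_df.to_csv(emit("panel_states", "panel_states.tsv"), sep="\t",
                     index=False)
    genome_io.write_bed(
        [genome_io.Interval(c, int(p), int(p) + 1)
         for c, arr in panel.snps.items() for p in arr],
        emit("snps", "snps.bed"))
    cons = variety_panel.conserved_fraction(panel.segmentations)
    cons.to_csv(emit("conserved", "conserved_fraction.tsv"), sep="\t")
    groups: dict[str, list[str]] = {}
    for v, sg in panel.subgroups.items():
        groups.setdefault(sg, []).append(v)
    sw = variety_panel.subgroup_switch(panel.segmentations,
                                       groups[cfg.fixed_group_a],
                                       groups[cfg.fixed_group_b])
    pd.DataFrame(sw.matrix).to_csv(emit("subgroup_switch",
                                        "subgroup_switch.tsv"), sep="\t")
    het_regions = synthetic_data.panel_mark_regions(panel, cfg, "H3K9me2")
    prof_snp = variety_panel.snp_profile(
        panel.snps, het_regions[panel.varieties[0]])
    pd.DataFrame({"density": prof_snp.combined()}).to_csv(
        emit("snp_profile", "snp_profile.tsv"), sep="\t", index=False)
    k4_regions = synthetic_data.panel_mark_regions(panel, cfg, "H3K4me3")
    pw = _pairwise_state_diff(panel)
    sat = variety_panel.saturation_curve(k4_regions, grid, pw, seed=seed)
    sat.to_csv(emit("saturation", "saturation.tsv"), sep="\t", index=False)
    sig_tracks = synthetic_data.panel_signal_tracks(panel, cfg, "H3K27me3",
                                                    seed)
    dist = variety_panel.epigenome_distance(sig_tracks)
    dist.to_csv(emit("epigenome_distance", "epigenome_distance.tsv"),
                sep="\t")
    variety_panel.mds_ordination(dist, seed=seed).to_csv(
        emit("mds", "epigenome_mds.tsv"), sep="\t")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    manifest["manifest"] = str(out / "manifest.json")
    return manifest


class _ConcatMatrix:
    """Binarized matrix stand-in for multi-tissue concatenated training."""

    def __init__(self, X, lengths, marks):
        self.X = X
        self._lengths = lengths
        self.marks = marks
        self.grid = _FakeGrid(lengths)


class _FakeGrid:
    def __init__(self, lengths):
        self._lengths = lengths
        self.n_bins = sum(lengths)

    def sequence_lengths(self):
        return list(self._lengths)


def _score_regions(present, track):
    regions = synthetic_data.presence_regions(present, track.grid)
    out = []
    for r in regions:
        out.append(genome_io.Interval(
            r.chrom, r.start, r.end, name=f"pk_{r.chrom}_{r.start}",
            score=_interval_sum(track, r)))
    return out


def _interval_sum(track, iv) -> float:
    idx = track.grid.bins_overlapping(iv)
    return float(np.asarray(track.values[idx.start:idx.stop],
                            dtype=float).sum())


def _pairwise_state_diff(panel) -> pd.DataFrame:
    names = panel.varieties
    D = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = float((panel.segmentations[a].states
                       != panel.segmentations[b].states).mean())
            D.loc[a, b] = D.loc[b, a] = d
    return D


def _write_elements(elements, path) -> None:
    with open(path, "w") as fh:
        for e in elements:
            iv = e.interval
            mcg = "" if e.mean_cg is None else f"{e.mean_cg:.4f}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                     f"{iv.score if iv.score is not None else '.'}\t.\t"
                     f"{e.klass}\t{mcg}\t{e.tss_distance or ''}\t"
                     f"{e.linked_gene or ''}\t{e.reason}\n")
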