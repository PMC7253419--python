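"""Synthetic multi-tissue / multi-variety epigenomes with planted truth.

A single hidden chromatin-state path per tissue drives everything that is
simulated: mark read counts (Poisson around state-dependent Bernoulli
presence), context-specific methylomes with binomial read sampling, FPKM
tables keyed to the promoter state, SNP densities, and a variety panel with
subgroup structure and planted fixed differences.  Because the truth (state
paths, DMR bins, elements, fixed differences) is recorded, every analysis
stage can be scored against it.

All randomness flows from one master seed through named substreams, so adding
a component never perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .genome_io import (BinGrid, BinnedTrack, GeneModel, GenomeIndex,
                        Interval, TE_FAMILIES)
from .segmentation import Segmentation

DEFAULT_MARKS = ("H3K4me3", "H3K27ac", "H3K4me1", "H3K27me3", "H3K9me2",
                 "RNAPII", "FAIRE")


@dataclass(frozen=True)
class StateDef:
    label: str
    category: str                       # active | repressive | inactive | Quies
    emissions: tuple[float, ...]        # per mark, order of SimConfig.marks


# A 15-state catalogue patterned on the familiar plant chromatin-state
# vocabulary: promoter, enhancer-like, transcribed, bivalent, Polycomb,
# heterochromatin (incl. the Copia-type H3K4me1+H3K9me2 bivalent state),
# open intergenic chromatin, and quiescent background.
DEFAULT_STATES = (
    StateDef("TssA",     "active",     (0.95, 0.80, 0.20, 0.02, 0.01, 0.70, 0.80)),
    StateDef("TssFlank", "active",     (0.70, 0.40, 0.40, 0.05, 0.02, 0.40, 0.50)),
    StateDef("Enh",      "active",     (0.10, 0.70, 0.70, 0.02, 0.02, 0.20, 0.60)),
    StateDef("Tx",       "active",     (0.05, 0.10, 0.30, 0.02, 0.02, 0.80, 0.10)),
    StateDef("TxWeak",   "active",     (0.02, 0.05, 0.20, 0.02, 0.02, 0.40, 0.05)),
    StateDef("Biv",      "repressive", (0.60, 0.10, 0.20, 0.70, 0.05, 0.10, 0.30)),
    StateDef("PcG",      "repressive", (0.05, 0.05, 0.10, 0.80, 0.05, 0.02, 0.05)),
    StateDef("PcGWeak",  "repressive", (0.02, 0.02, 0.05, 0.40, 0.10, 0.02, 0.02)),
    StateDef("Het",      "inactive",   (0.02, 0.02, 0.05, 0.05, 0.85, 0.02, 0.02)),
    StateDef("HetCopia", "inactive",   (0.05, 0.05, 0.50, 0.05, 0.70, 0.02, 0.02)),
    StateDef("HetWeak",  "inactive",   (0.01, 0.01, 0.05, 0.05, 0.35, 0.01, 0.01)),
    StateDef("OpenInt",  "active",     (0.05, 0.05, 0.08, 0.02, 0.02, 0.05, 0.60)),
    StateDef("Quies1",   "Quies",      (0.02, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02)),
    StateDef("Quies2",   "Quies",      (0.04, 0.04, 0.04, 0.04, 0.04, 0.04, 0.04)),
    StateDef("Quies3",   "Quies",      (0.05, 0.02, 0.08, 0.05, 0.08, 0.02, 0.03)),
)

_METH_LEVELS = {          # category -> context -> true methylation level
    "active":     {"CG": 0.08, "CHG": 0.04, "CHH": 0.02},
    "repressive": {"CG": 0.40, "CHG": 0.20, "CHH": 0.05},
    "inactive":   {"CG": 0.90, "CHG": 0.70, "CHH": 0.12},
    "Quies":      {"CG": 0.50, "CHG": 0.30, "CHH": 0.05},
}

_FPKM_LOGMEAN = {"active": np.log(25.0), "repressive": np.log(0.4),
                 "inactive": np.log(0.05), "Quies": np.log(0.2)}

_SNP_DENSITY = {"active": 0.002, "repressive": 0.004,
                "inactive": 0.008, "Quies": 0.005}

_DEF_VARIETIES = {
    "Xian1": "Xian", "Xian2": "Xian", "Xian3": "Xian", "Xian4": "Xian",
    "Geng1": "Geng", "Geng2": "Geng", "Geng3": "Geng",
    "Aus1": "Aus", "Aus2": "Aus", "Arom1": "aromatic",
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic epigenome."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000})
    bin_width: int = 200
    marks: tuple[str, ...] = DEFAULT_MARKS
    states: tuple[StateDef, ...] = DEFAULT_STATES
    stickiness: float = 0.97
    tissues: tuple[str, ...] = ("young_leaf", "mature_leaf", "panicle")
    tissue_switch_rate: float = 0.12
    varieties: dict[str, str] = field(
        default_factory=lambda: dict(_DEF_VARIETIES))
    within_rate: float = 0.02
    between_rate: float = 0.08
    n_fixed_differences: int = 50
    fixed_group_a: str = "Xian"
    fixed_group_b: str = "Geng"
    depth: float = 30.0
    fg_rate: float = 1.0
    bg_rate: float = 0.05
    input_depth: float = 20.0
    overdispersion: float = 0.0          # Gamma-Poisson mixing if > 0
    cyt_density: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.02, "CHG": 0.02, "CHH": 0.05})
    meth_levels: dict = field(default_factory=lambda: dict(_METH_LEVELS))
    coverage_mean: float = 20.0
    n_dmr_bins: int = 100
    dmr_delta: float = 0.7
    dmr_context: str = "CG"
    n_genes: int = 200
    gene_length: tuple[int, int] = (1000, 3000)
    te_gene_frac: float = 0.15
    n_tes: int = 300
    het_block_frac: float = 0.2
    fpkm_logmean: dict[str, float] = field(
        default_factory=lambda: dict(_FPKM_LOGMEAN))
    fpkm_sigma: float = 1.0
    snp_density: dict[str, float] = field(
        default_factory=lambda: dict(_SNP_DENSITY))
    snp_flank_factor: float = 3.0
    snp_flank_bp: float = 2000
    seed: int = 0

    def __post_init__(self):
        for sd in self.states:
            if len(sd.emissions) != len(self.marks):
                raise ValueError(f"state {sd.label}: emission length != marks")
            if min(sd.emissions) < 0 or max(sd.emissions) > 1:
                raise ValueError(f"state {sd.label}: emissions outside [0,1]")
        for r in (self.stickiness, self.tissue_switch_rate, self.within_rate,
                  self.between_rate):
            if not 0 <= r <= 1:
                raise ValueError(f"rate {r} outside [0,1]")

    @property
    def K(self) -> int:
        return len(self.states)

    def genome(self) -> GenomeIndex:
        return GenomeIndex(self.chrom_lengths)

    def grid(self) -> BinGrid:
        return BinGrid(self.genome(), self.bin_width)

    def emission_matrix(self) -> np.ndarray:
        return np.array([sd.emissions for sd in self.states])

    def categories(self) -> list[str]:
        return [sd.category for sd in self.states]

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "states" in raw:
            raw["states"] = tuple(StateDef(s["label"], s["category"],
                                           tuple(s["emissions"]))
                                  for s in raw["states"])
        if "marks" in raw:
            raw["marks"] = tuple(raw["marks"])
        if "tissues" in raw:
            raw["tissues"] = tuple(raw["tissues"])
        if "gene_length" in raw:
            raw["gene_length"] = tuple(raw["gene_length"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = {
            "chrom_lengths": dict(self.chrom_lengths),
            "bin_width": self.bin_width,
            "marks": list(self.marks),
            "states": [{"label": s.label, "category": s.category,
                        "emissions": list(s.emissions)} for s in self.states],
            "stickiness": self.stickiness,
            "tissues": list(self.tissues),
            "tissue_switch_rate": self.tissue_switch_rate,
            "varieties": dict(self.varieties),
            "within_rate": self.within_rate,
            "between_rate": self.between_rate,
            "n_fixed_differences": self.n_fixed_differences,
            "depth": self.depth, "seed": self.seed,
            "n_genes": self.n_genes, "n_tes": self.n_tes,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for a named simulation component."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                zlib.crc32(name.encode()) & 0x7FFFFFFF]))


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

@dataclass
class Annotation:
    genes: list[GeneModel]
    tes: list[Interval]
    het_blocks: list[Interval]


def simulate_annotation(config: SimConfig, seed: int | None = None
                        ) -> Annotation:
    """Non-overlapping genes with exons/ATG, TE intervals, het blocks."""
    seed = config.seed if seed is None else seed
    rng = substream(seed, "annotation")
    genome = config.genome()
    mean_len = sum(config.gene_length) / 2
    if config.n_genes * mean_len >= genome.total_bp:
        raise ValueError("gene density x mean gene length exceeds genome size")

    # heterochromatin blocks: 50-kb units switched on at the configured rate
    het_blocks: list[Interval] = []
    unit = 50_000
    for chrom in genome.names:
        L = genome.lengths[chrom]
        n_units = -(-L // unit)
        on = rng.random(n_units) < config.het_block_frac
        start = None
        for i in range(n_units + 1):
            if i < n_units and on[i]:
                start = i * unit if start is None else start
            elif start is not None:
                het_blocks.append(Interval(chrom, start, min(i * unit, L)))
                start = None

    def in_het(chrom, s, e):
        return any(h.chrom == chrom and s < h.end and e > h.start
                   for h in het_blocks)

    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.names}
    weights = np.array([genome.lengths[c] for c in genome.names], dtype=float)
    weights /= weights.sum()
    per_chrom = rng.multinomial(config.n_genes, weights)
    for chrom, n in zip(genome.names, per_chrom):
        L = genome.lengths[chrom]
        placed = 0
        for _ in range(400 * max(n, 1)):
            if placed >= n:
                break
            length = int(rng.integers(config.gene_length[0],
                                      config.gene_length[1] + 1))
            start = int(rng.integers(0, max(1, L - length)))
            end = start + length
            if any(s < end + 200 and e + 200 > start
                   for s, e in occupied[chrom]):
                continue
            if in_het(chrom, start, end) and rng.random() < 0.9:
                continue
            occupied[chrom].append((start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(1, 5))
            cuts = np.sort(rng.choice(
                np.arange(start + 100, end - 100, 50),
                size=min(2 * (n_ex - 1), max(0, (end - start - 200) // 50)),
                replace=False)) if n_ex > 1 else np.array([], dtype=int)
            bounds = [start] + [int(c) for c in cuts] + [end]
            exons = [(bounds[i], bounds[i + 1])
                     for i in range(0, len(bounds) - 1, 2)]
            atg_off = int(rng.integers(60, 300))
            if strand == "-":
                tss, tts = end - 1, start
                atg = max(start, end - 1 - atg_off)
            else:
                tss, tts = start, end - 1
                atg = min(end - 1, start + atg_off)
            gid = f"g{len(genes) + 1:04d}"
            is_te = rng.random() < config.te_gene_frac
            genes.append(GeneModel(
                gene_id=gid, chrom=chrom, strand=strand, start=start,
                end=end, tss=tss, tts=tts, atg=atg, exons=exons,
                gene_class="TE-gene" if is_te else "gene",
                te_families=(str(rng.choice(TE_FAMILIES)),) if is_te else ()))
            placed += 1
        if placed < n:
            raise ValueError(f"could not place {n} genes on {chrom}: "
                             "density infeasible")

    tes: list[Interval] = []
    het_by_chrom: dict[str, list[Interval]] = {}
    for h in het_blocks:
        het_by_chrom.setdefault(h.chrom, []).append(h)
    gene_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        gene_by_chrom.setdefault(g.chrom, []).append(g)
    het_fams = ("Gypsy", "Copia", "LINE", "CACTA")
    for i in range(config.n_tes):
        length = int(rng.integers(400, 3000))
        u = rng.random()
        if u < 0.6 and het_blocks:                    # heterochromatic TE
            h = het_blocks[int(rng.integers(len(het_blocks)))]
            start = int(rng.integers(h.start, max(h.start + 1,
                                                  h.end - length)))
            chrom = h.chrom
            fam = str(rng.choice(het_fams, p=(0.4, 0.3, 0.2, 0.1)))
        elif u < 0.8 and genes:                       # genic TE insertion
            g = genes[int(rng.integers(len(genes)))]
            chrom = g.chrom
            start = int(rng.integers(g.start, g.end))
            fam = str(rng.choice(TE_FAMILIES))
        else:
            chrom = str(rng.choice(genome.names))
            start = int(rng.integers(0, genome.lengths[chrom] - length))
            fam = str(rng.choice(TE_FAMILIES))
        end = min(start + length, genome.lengths[chrom])
        tes.append(Interval(chrom, start, end, name=fam))
    return Annotation(genes=genes, tes=tes, het_blocks=het_blocks)


# ---------------------------------------------------------------------------
# Hidden state paths
# ---------------------------------------------------------------------------

def _context_weights(annotation: Annotation | None, config: SimConfig,
                     grid: BinGrid) -> np.ndarray:
    """Per-bin state weights biasing promoter/gene-body/het placements."""
    K = config.K
    W = np.ones((grid.n_bins, K))
    if annotation is None:
        return W
    E = config.emission_matrix()
    marks = list(config.marks)
    cats = config.categories()
    prom_states = [k for k in range(K)
                   if cats[k] == "active" and E[k, marks.index("H3K4me3")] >= 0.5]
    tx_states = [k for k in range(K)
                 if E[k, marks.index("RNAPII")] >= 0.3
                 and E[k, marks.index("H3K4me3")] < 0.5]
    het_states = [k for k in range(K) if cats[k] == "inactive"]
    quies_states = [k for k in range(K) if cats[k] == "Quies"]

    def bump(ivs, states, factor):
        for iv in ivs:
            idx = grid.bins_overlapping(iv)
            W[idx.start:idx.stop][:, states] *= factor

    prom_ivs, body_ivs = [], []
    for g in annotation.genes:
        L = grid.genome.lengths[g.chrom]
        prom_ivs.append(Interval(g.chrom, max(0, g.tss - 400),
                                 min(L, g.tss + 401)))
        body_ivs.append(g.body)
    bump(body_ivs, tx_states, 4.0)
    bump(prom_ivs, prom_states, 12.0)
    bump(annotation.het_blocks, het_states, 10.0)
    if quies_states:
        W[:, quies_states] *= 2.0
    return W


def simulate_states(annotation: Annotation | None, config: SimConfig,
                    seed: int | None = None) -> dict[str, Segmentation]:
    """First-order Markov state path per tissue (1-based state ids)."""
    seed = config.seed if seed is None else seed
    if config.K < 2:
        raise ValueError("need K >= 2 states")
    if not 0 < config.stickiness <= 1:
        raise ValueError("stickiness must lie in (0, 1]")
    rng = substream(seed, "states")
    grid = config.grid()
    W = _context_weights(annotation, config, grid)
    cumW = np.cumsum(W, axis=1)
    cumW /= cumW[:, -1:]

    base = np.empty(grid.n_bins, dtype=np.int32)
    for chrom in grid.genome.names:
        sl = grid.chrom_slice(chrom)
        u = rng.random(sl.stop - sl.start)
        stay = rng.random(sl.stop - sl.start) < config.stickiness
        prev = int(np.searchsorted(cumW[sl.start], u[0]))
        base[sl.start] = prev
        for t in range(1, sl.stop - sl.start):
            if not stay[t]:
                prev = int(np.searchsorted(cumW[sl.start + t], u[t]))
            base[sl.start + t] = prev

    out = {config.tissues[0]: Segmentation(grid, base + 1, config.K,
                                           provenance="truth")}
    for tissue in config.tissues[1:]:
        path = _mutate_segments(base, grid, cumW, config.tissue_switch_rate,
                                substream(seed, f"states/{tissue}"))
        out[tissue] = Segmentation(grid, path + 1, config.K,
                                   provenance="truth")
    return out


def _mutate_segments(path: np.ndarray, grid: BinGrid, cumW: np.ndarray,
                     rate: float, rng: np.random.Generator) -> np.ndarray:
    """Re-draw each constant-state segment with the given probability."""
    new = path.copy()
    for chrom in grid.genome.names:
        sl = grid.chrom_slice(chrom)
        vals = path[sl]
        seg_start = 0
        for i in range(1, len(vals) + 1):
            if i == len(vals) or vals[i] != vals[seg_start]:
                if rate > 0 and rng.random() < rate:
                    s = int(np.searchsorted(cumW[sl.start + seg_start],
                                            rng.random()))
                    new[sl.start + seg_start: sl.start + i] = s
                seg_start = i
    return new


# ---------------------------------------------------------------------------
# Mark tracks
# ---------------------------------------------------------------------------

def simulate_tracks(states: Segmentation, config: SimConfig,
                    seed: int | None = None, name: str = ""
                    ) -> tuple[dict[str, BinnedTrack], BinnedTrack,
                               dict[str, np.ndarray]]:
    """Per-mark read-count tracks, an input track, and the presence truth.

    ``count[b, m] ~ Poisson(depth * (bg + fg * present))`` with
    ``present ~ Bernoulli(E[state(b), m])``; optional Gamma-Poisson
    overdispersion.
    """
    seed = config.seed if seed is None else seed
    if config.depth <= 0:
        raise ValueError("depth must be positive")
    rng = substream(seed, f"tracks/{name}")
    E = config.emission_matrix()
    sidx = states.states - 1
    tracks, truth = {}, {}
    for m, mark in enumerate(config.marks):
        present = (rng.random(len(sidx)) < E[sidx, m]).astype(np.uint8)
        lam = config.depth * (config.bg_rate + config.fg_rate * present)
        if config.overdispersion > 0:
            shape = 1.0 / config.overdispersion
            lam = rng.gamma(shape, lam / shape)
        counts = rng.poisson(lam)
        tracks[mark] = BinnedTrack(states.grid, counts.astype(np.int64))
        truth[mark] = present
    input_track = BinnedTrack(
        states.grid, rng.poisson(config.input_depth,
                                 size=len(sidx)).astype(np.int64))
    return tracks, input_track, truth


def presence_regions(present: np.ndarray, grid: BinGrid) -> list[Interval]:
    """Merge consecutive present bins into intervals (truth peak regions)."""
    out = []
    for chrom in grid.genome.names:
        sl = grid.chrom_slice(chrom)
        vals = present[sl]
        L, w = grid.genome.lengths[chrom], grid.width
        run = None
        for i in range(len(vals) + 1):
            if i < len(vals) and vals[i]:
                run = i if run is None else run
            elif run is not None:
                out.append(Interval(chrom, run * w, min(i * w, L)))
                run = None
    return out


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

def simulate_methylome(states: Segmentation, config: SimConfig,
                       seed: int | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two methylomes (A, B) plus the planted-DMR truth table.

    Sample B re-draws coverage and methylated counts from the same
    per-cytosine levels as A except in the planted DMR bins, where the level
    is shifted by the planted delta (direction chosen to stay inside [0,1]).
    """
    seed = config.seed if seed is None else seed
    rng = substream(seed, "methylome")
    grid = states.grid
    dens = config.cyt_density
    if sum(dens.values()) <= 0:
        raise ValueError("all cytosine densities are zero")
    contexts = list(dens)
    probs = np.array([dens[c] for c in contexts], dtype=float)
    probs /= probs.sum()

    frames = []
    for chrom in grid.genome.names:
        L = grid.genome.lengths[chrom]
        n = rng.poisson(sum(dens.values()) * L)
        pos = np.sort(rng.choice(L, size=min(n, L), replace=False))
        ctx = rng.choice(len(contexts), size=len(pos), p=probs)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "strand": np.where(rng.random(len(pos)) < 0.5, "+", "-"),
            "context": [contexts[i] for i in ctx],
            "bin": grid.positions_to_bins(chrom, pos)}))
    cyt = pd.concat(frames, ignore_index=True)

    cats = np.array(config.categories())
    bin_cat = cats[states.states - 1]
    level_lut = {(cat, c): config.meth_levels[cat][c]
                 for cat in config.meth_levels for c in contexts}
    cyt["levelA"] = [level_lut[(bin_cat[b], c)]
                     for b, c in zip(cyt["bin"], cyt["context"])]
    cyt["levelB"] = cyt["levelA"]

    # plant DMRs in bins with enough cytosines of the target context
    truth_rows = []
    if config.n_dmr_bins > 0 and config.dmr_delta > 0:
        target = cyt[cyt["context"] == config.dmr_context]
        # the full |delta| must fit inside [0,1] from the bin's base level
        lvl = target.groupby("bin")["levelA"].first()
        fits = (lvl + config.dmr_delta <= 1.0) | (lvl - config.dmr_delta >= 0.0)
        counts = target.groupby("bin").size()
        eligible = counts[(counts >= 3) & fits].index.to_numpy()
        chosen = rng.choice(eligible,
                            size=min(config.n_dmr_bins, len(eligible)),
                            replace=False)
        chosen_set = set(int(b) for b in chosen)
        mask = cyt["bin"].isin(chosen_set) & \
            (cyt["context"] == config.dmr_context)
        lvlA = cyt.loc[mask, "levelA"].to_numpy()
        shifted = np.where(lvlA + config.dmr_delta <= 1.0,
                           lvlA + config.dmr_delta,
                           lvlA - config.dmr_delta)
        cyt.loc[mask, "levelB"] = np.clip(shifted, 0.0, 1.0)
        for b in sorted(chosen_set):
            biv = grid.bin_interval(int(b))
            sub = cyt[(cyt["bin"] == b) &
                      (cyt["context"] == config.dmr_context)]
            truth_rows.append({
                "bin": int(b), "chrom": biv.chrom, "start": biv.start,
                "end": biv.end, "context": config.dmr_context,
                "delta": float(sub["levelA"].mean() - sub["levelB"].mean())})
    truth = pd.DataFrame(truth_rows,
                         columns=["bin", "chrom", "start", "end", "context",
                                  "delta"])

    def draw(levels, stream):
        r = substream(seed, stream)
        total = r.poisson(config.coverage_mean, size=len(levels))
        meth = r.binomial(total, levels)
        return total, meth

    totA, methA = draw(cyt["levelA"].to_numpy(), "methylome/A")
    totB, methB = draw(cyt["levelB"].to_numpy(), "methylome/B")
    base = cyt[["chrom", "pos", "strand", "context"]]
    callsA = base.assign(meth=methA, total=totA)
    callsB = base.assign(meth=methB, total=totB)
    return callsA, callsB, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(state_paths: dict[str, Segmentation],
                        genes: list[GeneModel], config: SimConfig,
                        seed: int | None = None) -> pd.DataFrame:
    """Gene x tissue FPKM table keyed to the promoter-state category."""
    seed = config.seed if seed is None else seed
    rng = substream(seed, "expression")
    cats = np.array(config.categories())
    grid = next(iter(state_paths.values())).grid
    data = {}
    for tissue, seg in state_paths.items():
        cat_per_gene = []
        for g in genes:
            b = grid.bin_index(g.chrom, g.tss)
            cat_per_gene.append(cats[seg.states[b] - 1])
        mu = np.array([config.fpkm_logmean[c] for c in cat_per_gene])
        data[tissue] = np.exp(rng.normal(mu, config.fpkm_sigma))
    return pd.DataFrame(data, index=[g.gene_id for g in genes])


# ---------------------------------------------------------------------------
# Variety panel
# ---------------------------------------------------------------------------

@dataclass
class Panel:
    grid: BinGrid
    subgroups: dict[str, str]            # variety -> subgroup
    segmentations: dict[str, Segmentation]
    snps: dict[str, np.ndarray]          # chrom -> sorted positions
    fixed_bins: np.ndarray               # planted inter-subgroup bins
    fixed_states: np.ndarray             # (n, 2): state in group A / group B

    @property
    def varieties(self) -> list[str]:
        return list(self.subgroups)


def simulate_panel(base: Segmentation, config: SimConfig,
                   seed: int | None = None) -> Panel:
    """Subgroup-structured variety panel with planted fixed differences."""
    seed = config.seed if seed is None else seed
    if len(config.varieties) < 2:
        raise ValueError("need at least 2 varieties")
    grid = base.grid
    K = config.K
    uniform = np.tile(np.linspace(1 / K, 1.0, K), (grid.n_bins, 1))
    subgroups = sorted(set(config.varieties.values()))
    consensus = {}
    for sg in subgroups:
        consensus[sg] = _mutate_segments(
            base.states - 1, grid, uniform, config.between_rate,
            substream(seed, f"panel/consensus/{sg}"))
    paths = {}
    for var, sg in config.varieties.items():
        paths[var] = _mutate_segments(
            consensus[sg], grid, uniform, config.within_rate,
            substream(seed, f"panel/variety/{var}"))

    rng = substream(seed, "panel/fixed")
    n_fix = min(config.n_fixed_differences, grid.n_bins)
    fixed_bins = np.sort(rng.choice(grid.n_bins, size=n_fix, replace=False))
    sA = rng.integers(1, K + 1, size=n_fix)
    sB = ((sA - 1 + rng.integers(1, K, size=n_fix)) % K) + 1
    for var, sg in config.varieties.items():
        if sg == config.fixed_group_a:
            paths[var][fixed_bins] = sA - 1
        elif sg == config.fixed_group_b:
            paths[var][fixed_bins] = sB - 1

    snps = _simulate_snps(base, config, substream(seed, "panel/snps"))
    segs = {v: Segmentation(grid, p + 1, K, provenance=f"truth:{v}")
            for v, p in paths.items()}
    return Panel(grid=grid, subgroups=dict(config.varieties),
                 segmentations=segs, snps=snps, fixed_bins=fixed_bins,
                 fixed_states=np.column_stack([sA, sB]))


def _simulate_snps(base: Segmentation, config: SimConfig,
                   rng: np.random.Generator) -> dict[str, np.ndarray]:
    """SNP positions with state-category density and flank enrichment.

    Density per bin follows the category of the underlying state; in the
    2-kb flanks of heterochromatic (H3K9me2-emitting) mark regions the
    density ramps linearly up to ``snp_flank_factor`` at the region edge.
    """
    grid = base.grid
    cats = np.array(config.categories())
    dens = np.array([config.snp_density[c] for c in cats[base.states - 1]])
    E = config.emission_matrix()
    het_mark = list(config.marks).index("H3K9me2")
    het_bins = E[base.states - 1, het_mark] >= 0.5
    flank_bins = int(config.snp_flank_bp // grid.width)
    boost = np.ones(grid.n_bins)
    for chrom in grid.genome.names:
        sl = grid.chrom_slice(chrom)
        hb = het_bins[sl]
        edges = np.flatnonzero(np.diff(hb.astype(int)))
        for e in edges:
            rising = hb[e + 1]
            for d in range(1, flank_bins + 1):
                i = e + 1 - d if rising else e + d
                if 0 <= i < len(hb) and not hb[i]:
                    f = 1 + (config.snp_flank_factor - 1) * \
                        (1 - (d - 0.5) / flank_bins)
                    boost[sl.start + i] = max(boost[sl.start + i], f)
    dens = dens * boost
    out = {}
    widths = grid.bin_widths()
    for chrom in grid.genome.names:
        sl = grid.chrom_slice(chrom)
        counts = rng.poisson(dens[sl] * widths[sl])
        pos = []
        w = grid.width
        for i, n in enumerate(counts):
            if n:
                lo = i * w
                hi = lo + widths[sl][i]
                pos.extend(rng.integers(lo, hi, size=n))
        out[chrom] = np.sort(np.unique(np.asarray(pos, dtype=np.int64)))
    return out


def panel_mark_regions(panel: Panel, config: SimConfig, mark: str,
                       threshold: float = 0.5
                       ) -> dict[str, list[Interval]]:
    """Per-variety merged mark regions (bins whose state emits the mark)."""
    E = config.emission_matrix()
    m = list(config.marks).index(mark)
    out = {}
    for var, seg in panel.segmentations.items():
        present = E[seg.states - 1, m] >= threshold
        out[var] = presence_regions(present, panel.grid)
    return out


def panel_signal_tracks(panel: Panel, config: SimConfig, mark: str,
                        seed: int | None = None
                        ) -> dict[str, BinnedTrack]:
    """Per-variety Poisson count track for one mark."""
    seed = config.seed if seed is None else seed
    E = config.emission_matrix()
    m = list(config.marks).index(mark)
    out = {}
    for var, seg in panel.segmentations.items():
        rng = substream(seed, f"panel/signal/{mark}/{var}")
        p = E[seg.states - 1, m]
        present = rng.random(panel.grid.n_bins) < p
        lam = config.depth * (config.bg_rate + config.fg_rate * present)
        out[var] = BinnedTrack(panel.grid, rng.poisson(lam).astype(np.int64))
    return out


# ---------------------------------------------------------------------------
# Focused scenes for individual analyses
# ---------------------------------------------------------------------------

def simulate_differential_tracks(grid: BinGrid, n_diff: int = 30,
                                 n_null: int = 60, fold: float = 2.0,
                                 depth: float = 50.0, region_bins: int = 3,
                                 seed: int = 0):
    """Two count tracks with planted fold-change regions.

    Returns ``(trackA, trackB, regions, truth)`` where ``regions`` is the
    candidate region list (planted + null, shuffled) and ``truth`` is a
    boolean array marking the planted ones.
    """
    rng = substream(seed, "difftracks")
    lam = np.full(grid.n_bins, float(depth))
    lamB = lam.copy()
    n_regions = n_diff + n_null
    starts = rng.choice(grid.n_bins // region_bins, size=n_regions,
                        replace=False) * region_bins
    order = rng.permutation(n_regions)
    starts = starts[order]
    regions, truth = [], []
    for i, s in enumerate(starts):
        s = int(s)
        biv0 = grid.bin_interval(s)
        biv1 = grid.bin_interval(min(s + region_bins - 1, grid.n_bins - 1))
        if biv0.chrom != biv1.chrom:
            biv1 = Interval(biv0.chrom, biv0.start,
                            grid.genome.lengths[biv0.chrom])
        regions.append(Interval(biv0.chrom, biv0.start, biv1.end,
                                name=f"r{i}"))
        is_diff = i < n_diff
        truth.append(is_diff)
        if is_diff:
            lamB[s:s + region_bins] *= fold
    a = BinnedTrack(grid, rng.poisson(lam).astype(np.int64))
    b = BinnedTrack(grid, rng.poisson(lamB).astype(np.int64))
    return a, b, regions, np.array(truth)


def simulate_tissue_matrix(n_per_group: int = 40,
                           tissues=("young_leaf", "mature_leaf", "panicle",
                                    "root"),
                           high: float = 5.0, low: float = 1.0,
                           noise: float = 0.4, seed: int = 0):
    """Region x tissue signal matrix with tissue-exclusive groups."""
    rng = substream(seed, "tissuematrix")
    rows, labels = [], []
    for t, tissue in enumerate(tissues):
        block = np.full((n_per_group, len(tissues)), low)
        block[:, t] = high
        rows.append(block + rng.normal(0, noise,
                                       size=(n_per_group, len(tissues))))
        labels.extend([t] * n_per_group)
    X = np.vstack(rows)
    order = rng.permutation(len(X))
    return X[order], np.array(labels)[order], list(tissues)


def simulate_promoter_archetypes(n_per: int = 60,
                                 marks=("H3K4me3", "H3K27ac", "H3K4me1",
                                        "H3K9me2", "FAIRE"),
                                 n_pos: int = 401, seed: int = 0):
    """TSS-centred signal-ratio profiles for three promoter archetypes.

    Archetypes: an active promoter (H3K4me3/H3K27ac/FAIRE peak over the TSS),
    a heterochromatic flank (elevated H3K9me2 away from the TSS), and a blank
    background.  Returns ``(profiles, labels, marks)`` with profiles of shape
    (genes, marks, positions).
    """
    rng = substream(seed, "promarch")
    x = np.linspace(-2000, 2000, n_pos)
    bumps = {
        0: {"H3K4me3": 8 * np.exp(-(x / 400) ** 2),
            "H3K27ac": 5 * np.exp(-(x / 600) ** 2),
            "FAIRE": 4 * np.exp(-(x / 300) ** 2)},
        1: {"H3K9me2": 3 * (1 - np.exp(-(x / 800) ** 2)),
            "H3K4me1": 1.5 * np.ones_like(x)},
        2: {},
    }
    profiles, labels = [], []
    for arch in (0, 1, 2):
        for _ in range(n_per):
            P = np.full((len(marks), n_pos), 0.2)
            for m, mark in enumerate(marks):
                if mark in bumps[arch]:
                    P[m] += bumps[arch][mark]
                P[m] *= np.exp(rng.normal(0, 0.15, size=n_pos))
            profiles.append(P)
            labels.append(arch)
    profiles = np.array(profiles)
    order = rng.permutation(len(profiles))
    return profiles[order], np.array(labels)[order], tuple(marks)


@dataclass
class RegulatoryScene:
    """A planted DRE/PRE classification scene with clean margins."""

    genome: GenomeIndex
    grid: BinGrid
    genes: list[GeneModel]
    peaks: list[Interval]
    truth: dict[str, str]                # peak name -> {DRE, PRE, decoy}
    cg_calls: pd.DataFrame               # cytosine calls covering the peaks
    loops: list[tuple[Interval, Interval, float]]
    dre_signal: np.ndarray               # tissue-specific DREs x tissues
    dre_signal_labels: np.ndarray
    tissues: tuple[str, ...]


def simulate_regulatory_scene(n_genes: int = 60, n_dre: int = 20,
                              n_pre: int = 20, n_decoy: int = 10,
                              chrom_length: int = 2_000_000,
                              dre_min_dist: int = 3000,
                              pre_max_dist: int = 500,
                              dre_meth: float = 0.02, decoy_meth: float = 0.4,
                              coverage: int = 30, seed: int = 0
                              ) -> RegulatoryScene:
    """Genes on a regular lattice plus planted DRE/PRE/decoy peaks.

    Margins are clean by construction: true DREs sit >= ``dre_min_dist`` from
    every TSS with CG methylation ``dre_meth``; decoys are placed the same way
    but with high methylation; PREs sit within ``pre_max_dist`` of a TSS.
    """
    rng = substream(seed, "regscene")
    genome = GenomeIndex({"chr1": chrom_length})
    grid = BinGrid(genome, 200)
    spacing = chrom_length // (n_genes + 1)
    genes = []
    for i in range(n_genes):
        start = spacing * (i + 1)
        strand = "+" if i % 2 == 0 else "-"
        end = start + 2000
        genes.append(GeneModel(
            gene_id=f"g{i + 1:03d}", chrom="chr1", strand=strand,
            start=start, end=end,
            tss=start if strand == "+" else end - 1,
            tts=end - 1 if strand == "+" else start,
            atg=start + 150 if strand == "+" else end - 151,
            exons=[(start, end)]))

    peaks, truth, meth_of = [], {}, {}
    pre_genes = rng.choice(n_genes, size=n_pre, replace=False)
    for j, gi in enumerate(pre_genes):
        g = genes[int(gi)]
        off = int(rng.integers(-pre_max_dist + 150, pre_max_dist - 150))
        center = g.tss + off
        name = f"pre{j}"
        peaks.append(Interval("chr1", max(0, center - 150), center + 150,
                              name=name, score=float(rng.integers(5, 50))))
        truth[name] = "PRE"
        meth_of[name] = dre_meth
    # midpoints between adjacent genes are >= dre_min_dist from both TSSs
    mid_slots = [spacing * (i + 1) + spacing // 2 for i in range(n_genes - 1)]
    slots = rng.choice(len(mid_slots), size=n_dre + n_decoy, replace=False)
    for j, si in enumerate(slots):
        center = mid_slots[int(si)]
        kind = "DRE" if j < n_dre else "decoy"
        name = f"{kind.lower()}{j}"
        peaks.append(Interval("chr1", center - 150, center + 150, name=name,
                              score=float(rng.integers(5, 50))))
        truth[name] = kind
        meth_of[name] = dre_meth if kind == "DRE" else decoy_meth
    assert all(min(abs(p.start + 150 - g.tss) for g in genes) >= dre_min_dist
               for p in peaks if truth[p.name] != "PRE")

    rows = []
    for p in peaks:
        level = meth_of[p.name]
        for pos in range(p.start + 5, p.end, 20):
            total = max(1, int(rng.poisson(coverage)))
            rows.append({"chrom": "chr1", "pos": pos, "strand": "+",
                         "context": "CG",
                         "meth": int(rng.binomial(total, level)),
                         "total": total})
    cg_calls = pd.DataFrame(rows)

    pre_set = [p for p in peaks if truth[p.name] == "PRE"]
    loops = []
    for j in range(min(10, len(pre_set) - 1)):
        a = genes[int(pre_genes[j])]
        partner = genes[(int(pre_genes[j]) + 7) % n_genes]
        ivs = sorted([a.promoter(genome=genome),
                      partner.promoter(genome=genome)],
                     key=lambda iv: iv.start)
        loops.append((ivs[0], ivs[1], float(rng.integers(2, 20))))

    sig, labels, tissues = simulate_tissue_matrix(
        n_per_group=20, tissues=("young_leaf", "mature_leaf", "panicle"),
        seed=seed + 1)
    return RegulatoryScene(genome=genome, grid=grid, genes=genes,
                           peaks=peaks, truth=truth, cg_calls=cg_calls,
                           loops=loops, dre_signal=sig,
                           dre_signal_labels=labels, tissues=tuple(tissues))
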