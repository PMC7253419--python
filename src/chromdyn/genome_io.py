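"""Genome model, interval arithmetic, fixed-width binning and text-format I/O.

Every downstream analysis works on a shared coordinate system: an ordered set
of chromosomes (:class:`GenomeIndex`), 0-based half-open intervals
(:class:`Interval`), and a fixed-width tiling of the genome
(:class:`BinGrid`, default 200 bp) carrying per-bin values
(:class:`BinnedTrack`).  GFF3 input (1-based, inclusive) is converted to the
internal convention at read time; BED/bedGraph/BEDPE are consumed natively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TE_FAMILIES = (
    "Copia", "Gypsy", "LINE", "SINE", "hAT",
    "CACTA", "Mariner", "Mutator", "Harbinger", "Helitron",
)


class GenomeIndex:
    """Ordered chromosome names and lengths (bp)."""

    def __init__(self, lengths: dict[str, int]):
        if len(lengths) == 0:
            raise ValueError("GenomeIndex needs at least one chromosome")
        names = list(lengths)
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in lengths.items():
            if int(length) < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self.names: tuple[str, ...] = tuple(names)
        self.lengths: dict[str, int] = {n: int(lengths[n]) for n in names}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __len__(self) -> int:
        return len(self.names)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeIndex) and self.lengths == other.lengths \
            and self.names == other.names

    def __repr__(self) -> str:
        return f"GenomeIndex({self.lengths!r})"

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())

    def to_tsv(self, path) -> None:
        pd.DataFrame({"chrom": self.names,
                      "length": [self.lengths[n] for n in self.names]}
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenomeIndex":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))


@dataclass
class Interval:
    """0-based half-open genomic interval with optional BED6 metadata."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GeneModel:
    """A gene with orientation-aware landmarks (TSS, TTS, ATG) and exons.

    ``tss``/``tts``/``atg`` are single-bp positions (0-based).  For a minus
    strand gene the TSS is the last covered base of the annotated span.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    tss: int
    tts: int
    atg: int | None
    exons: list[tuple[int, int]] = field(default_factory=list)
    gene_class: str = "gene"          # {"gene", "TE-gene"}
    te_families: tuple[str, ...] = ()

    @property
    def body(self) -> Interval:
        return Interval(self.chrom, self.start, self.end,
                        name=self.gene_id, strand=self.strand)

    def introns(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return [(a_end, b_start) for (_, a_end), (b_start, _) in zip(ex, ex[1:])
                if b_start > a_end]

    def promoter(self, upstream: int = 1000, downstream: int = 500,
                 genome: GenomeIndex | None = None) -> Interval:
        """Promoter window around the TSS in transcription orientation."""
        if self.strand == "-":
            lo, hi = self.tss - downstream + 1, self.tss + upstream + 1
        else:
            lo, hi = self.tss - upstream, self.tss + downstream
        if genome is not None:
            hi = min(hi, genome.lengths[self.chrom])
        lo = max(lo, 0)
        return Interval(self.chrom, lo, max(hi, lo + 1),
                        name=self.gene_id, strand=self.strand)


class BinGrid:
    """Fixed-width chromosome-major tiling; the last bin may be short."""

    def __init__(self, genome: GenomeIndex, width: int = 200):
        if int(width) < 1:
            raise ValueError(f"bin width must be >= 1, got {width}")
        self.genome = genome
        self.width = int(width)
        self.n_bins_per_chrom: dict[str, int] = {
            c: -(-genome.lengths[c] // self.width) for c in genome.names}
        offsets = np.cumsum([0] + [self.n_bins_per_chrom[c] for c in genome.names])
        self._offsets = {c: int(offsets[i]) for i, c in enumerate(genome.names)}
        self.n_bins = int(offsets[-1])

    def __eq__(self, other) -> bool:
        return (isinstance(other, BinGrid) and other.width == self.width
                and other.genome == self.genome)

    def chrom_offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin covering base ``pos``."""
        if not 0 <= pos < self.genome.lengths[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self._offsets[chrom] + pos // self.width

    def bin_interval(self, index: int) -> Interval:
        for chrom in self.genome.names:
            off, n = self._offsets[chrom], self.n_bins_per_chrom[chrom]
            if off <= index < off + n:
                i = index - off
                start = i * self.width
                end = min(start + self.width, self.genome.lengths[chrom])
                return Interval(chrom, start, end)
        raise IndexError(index)

    def bin_widths(self) -> np.ndarray:
        """Actual bp width of every bin (trailing bins may be short)."""
        w = np.full(self.n_bins, self.width, dtype=np.int64)
        for chrom in self.genome.names:
            off, n = self._offsets[chrom], self.n_bins_per_chrom[chrom]
            w[off + n - 1] = self.genome.lengths[chrom] - (n - 1) * self.width
        return w

    def bins_overlapping(self, iv: Interval) -> range:
        """Global indices of all bins intersecting ``iv``."""
        off = self._offsets[iv.chrom]
        first = iv.start // self.width
        last = (iv.end - 1) // self.width
        return range(off + first, off + last + 1)

    def positions_to_bins(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        return self._offsets[chrom] + np.asarray(pos, dtype=np.int64) // self.width

    def chrom_slice(self, chrom: str) -> slice:
        off = self._offsets[chrom]
        return slice(off, off + self.n_bins_per_chrom[chrom])

    def sequence_lengths(self) -> list[int]:
        """Per-chromosome bin counts in genome order (HMM sequence lengths)."""
        return [self.n_bins_per_chrom[c] for c in self.genome.names]


class BinnedTrack:
    """One value per grid bin (float, int, bool; NaN marks missing)."""

    def __init__(self, grid: BinGrid, values: np.ndarray):
        values = np.asarray(values)
        if values.shape != (grid.n_bins,):
            raise ValueError(
                f"track length {values.shape} != grid bins ({grid.n_bins},)")
        self.grid = grid
        self.values = values

    @classmethod
    def zeros(cls, grid: BinGrid, dtype=float) -> "BinnedTrack":
        return cls(grid, np.zeros(grid.n_bins, dtype=dtype))

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.grid.genome.names:
                sl = self.grid.chrom_slice(chrom)
                vals = self.values[sl]
                L = self.grid.genome.lengths[chrom]
                w = self.grid.width
                for i, v in enumerate(vals):
                    if np.isnan(float(v)):
                        continue
                    fh.write(f"{chrom}\t{i * w}\t{min((i + 1) * w, L)}\t{v:g}\n")


def make_bins(genome: GenomeIndex, width: int = 200) -> BinGrid:
    """Tile the genome into fixed-width bins (chromosome-major indexing)."""
    return BinGrid(genome, width)


# ---------------------------------------------------------------------------
# BED / bedGraph / BEDPE / GFF3
# ---------------------------------------------------------------------------

def read_bed(path, genome: GenomeIndex | None = None) -> list[Interval]:
    """Read BED3-BED6.  Malformed lines and unknown chromosomes raise."""
    out: list[Interval] = []
    bad_chroms: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED fields")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
            if genome is not None and chrom not in genome:
                bad_chroms.append(f"{chrom} (line {lineno})")
                continue
            name = f[3] if len(f) > 3 and f[3] != "." else None
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            strand = f[5] if len(f) > 5 else "."
            out.append(Interval(chrom, start, end, name=name, score=score,
                                strand=strand))
    if bad_chroms:
        raise ValueError(f"{path}: chromosomes absent from genome: "
                         + ", ".join(bad_chroms))
    return out


def write_bed(intervals, path) -> None:
    """Write BED6, sorted by (chrom, start, end)."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in ivs:
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                     f"{score}\t{iv.strand}\n")


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph fields")
            rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
    return rows


def read_bedpe(path) -> list[tuple[Interval, Interval, float]]:
    """Read BEDPE loops; anchors are ordered (anchor1 before anchor2)."""
    loops = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 BEDPE fields")
            a = Interval(f[0], int(f[1]), int(f[2]))
            b = Interval(f[3], int(f[4]), int(f[5]))
            score = float(f[7]) if len(f) > 7 and f[7] != "." else 0.0
            if (b.chrom, b.start) < (a.chrom, a.start):
                a, b = b, a
            loops.append((a, b, score))
    return loops


def write_bedpe(loops, path) -> None:
    with open(path, "w") as fh:
        for a, b, score in loops:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t"
                     f"{b.end}\tloop\t{score:g}\n")


def _gff_attributes(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff_genes(path) -> list[GeneModel]:
    """Read gene models from GFF3.

    GFF3 1-based inclusive coordinates become 0-based half-open.  The TSS is
    the first transcribed base (``start-1`` on +, ``end-1`` on -) and the ATG
    is the first CDS base in transcription orientation.  Genes lacking
    exon/CDS children are kept with an empty exon list (with a warning).
    """
    genes: dict[str, dict] = {}
    children: dict[str, dict[str, list]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 fields")
            chrom, _, ftype, start1, end1, _, strand, _, attrs = f
            start, end = int(start1) - 1, int(end1)
            at = _gff_attributes(attrs)
            if ftype == "gene":
                gid = at.get("ID", f"gene{lineno}")
                genes[gid] = dict(chrom=chrom, strand=strand, start=start,
                                  end=end,
                                  gene_class=at.get("gene_class", "gene"),
                                  te=tuple(x for x in
                                           at.get("te_families", "").split(",")
                                           if x))
            elif ftype in ("exon", "CDS"):
                parent = at.get("Parent", "").split(".")[0]
                children.setdefault(parent, {}).setdefault(ftype, []).append(
                    (start, end))
    out = []
    for gid, g in genes.items():
        ch = children.get(gid, {})
        exons = sorted(ch.get("exon", []))
        cds = sorted(ch.get("CDS", []))
        if not exons and not cds:
            warnings.warn(f"gene {gid} has no exon/CDS features", stacklevel=2)
        if g["strand"] == "-":
            tss, tts = g["end"] - 1, g["start"]
            atg = cds[-1][1] - 1 if cds else None
        else:
            tss, tts = g["start"], g["end"] - 1
            atg = cds[0][0] if cds else None
        out.append(GeneModel(gene_id=gid, chrom=g["chrom"], strand=g["strand"],
                             start=g["start"], end=g["end"], tss=tss, tts=tts,
                             atg=atg, exons=exons, gene_class=g["gene_class"],
                             te_families=g["te"]))
    out.sort(key=lambda gm: (gm.chrom, gm.start, gm.gene_id))
    return out


def write_gff_genes(genes, path) -> None:
    """Write gene models as GFF3 (inverse of :func:`read_gff_genes`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda gm: (gm.chrom, gm.start, gm.gene_id)):
            attrs = f"ID={g.gene_id};gene_class={g.gene_class}"
            if g.te_families:
                attrs += f";te_families={','.join(g.te_families)}"
            fh.write(f"{g.chrom}\tchromdyn\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            for s, e in sorted(g.exons):
                fh.write(f"{g.chrom}\tchromdyn\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tParent={g.gene_id}\n")
            if g.atg is not None:
                if g.strand == "-":
                    cs, ce = g.start, g.atg + 1
                else:
                    cs, ce = g.atg, g.end
                fh.write(f"{g.chrom}\tchromdyn\tCDS\t{cs + 1}\t{ce}\t.\t"
                         f"{g.strand}\t.\tParent={g.gene_id}\n")


# ---------------------------------------------------------------------------
# Binning signal and interval queries
# ---------------------------------------------------------------------------

def track_to_bins(rows, grid: BinGrid, reducer: str = "mean") -> BinnedTrack:
    """Aggregate bedGraph-style rows ``(chrom, start, end, value)`` onto bins.

    Values are treated as per-bp densities: ``sum`` accumulates value x
    covered bp, ``mean`` is the bp-weighted mean over covered bases, ``max``
    the maximum value touching the bin.  Empty bins are 0 for ``sum`` and NaN
    for ``mean``/``max``.  Overlapping input intervals are ambiguous and
    rejected.
    """
    if reducer not in ("sum", "mean", "max"):
        raise ValueError(f"unknown reducer {reducer!r}")
    by_chrom: dict[str, list] = {}
    for chrom, start, end, value in rows:
        if chrom not in grid.genome:
            raise ValueError(f"chromosome {chrom!r} absent from genome")
        by_chrom.setdefault(chrom, []).append((start, end, value))
    mass = np.zeros(grid.n_bins)
    covered = np.zeros(grid.n_bins)
    mx = np.full(grid.n_bins, -np.inf)
    for chrom, items in by_chrom.items():
        items.sort()
        prev_end = -1
        L = grid.genome.lengths[chrom]
        for start, end, value in items:
            if start < prev_end:
                raise ValueError(f"overlapping bedGraph intervals on {chrom}")
            prev_end = end
            end = min(end, L)
            for b in grid.bins_overlapping(Interval(chrom, start, end)):
                biv = grid.bin_interval(b)
                bp = min(end, biv.end) - max(start, biv.start)
                mass[b] += value * bp
                covered[b] += bp
                mx[b] = max(mx[b], value)
    if reducer == "sum":
        return BinnedTrack(grid, mass)
    if reducer == "mean":
        with np.errstate(invalid="ignore"):
            vals = np.where(covered > 0, mass / np.maximum(covered, 1), np.nan)
        return BinnedTrack(grid, vals)
    return BinnedTrack(grid, np.where(covered > 0, mx, np.nan))


def overlap_pairs(a, b, min_bp: int = 1) -> list[tuple[int, int, int]]:
    """All index pairs ``(i, j, overlap_bp)`` with overlap >= ``min_bp``.

    Deterministic a-major ordering.  Linear-ish sweep per chromosome; the
    brute-force quadratic equivalent is used as the test oracle.
    """
    b_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, iv in enumerate(b):
        b_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    for items in b_by_chrom.values():
        items.sort()
    out: list[tuple[int, int, int]] = []
    for i, iv in enumerate(a):
        items = b_by_chrom.get(iv.chrom, ())
        if not items:
            continue
        starts = [s for s, _, _ in items]
        hi = np.searchsorted(starts, iv.end - min_bp, side="right")
        hits = []
        for s, e, j in items[:hi]:
            ov = min(iv.end, e) - max(iv.start, s)
            if ov >= min_bp:
                hits.append((j, ov))
        hits.sort()
        out.extend((i, j, ov) for j, ov in hits)
    return out


def tss_distance(iv: Interval, gene: GeneModel) -> int | None:
    """Signed bp distance from ``iv`` to the gene's TSS.

    0 when the interval covers the TSS; negative when the interval lies
    upstream of the TSS in the gene's orientation.
    """
    if iv.chrom != gene.chrom:
        return None
    t = gene.tss
    if iv.start <= t < iv.end:
        return 0
    if iv.end <= t:                       # interval left of TSS
        d = t - iv.end
        return -d if gene.strand != "-" else d
    d = iv.start - t                      # interval right of TSS
    return d if gene.strand != "-" else -d


def nearest_tss(iv: Interval, genes) -> tuple[GeneModel | None, int | None]:
    """Nearest gene by |TSS distance|; ties go to the smaller gene id."""
    best: tuple[int, str] | None = None
    best_gene, best_d = None, None
    for g in genes:
        d = tss_distance(iv, g)
        if d is None:
            continue
        key = (abs(d), g.gene_id)
        if best is None or key < best:
            best, best_gene, best_d = key, g, d
    return best_gene, best_d
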