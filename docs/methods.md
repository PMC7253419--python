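# Methods

This note documents the models implemented in `chromdyn`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that make results deterministic.

## Coordinate conventions

All internal coordinates are 0-based half-open (BED convention); GFF3 input
(1-based inclusive) is converted at read time. The TSS of a minus-strand
gene is the last covered base of its annotated span, and the ATG is the
first CDS base in transcription orientation. The genome is tiled into
fixed-width bins (default 200 bp, the resolution of all state and DMR
analyses); trailing partial bins are kept, and any statistic that needs a
bin width uses the actual width, so bin-level summaries conserve genome
coverage identities exactly. Nearest-gene ties break lexicographically by
gene id — an arbitrary but documented rule that makes every classifier
deterministic and brute-force-checkable.

## Binarization

A mark count track is reduced to presence/absence with an upper-tail
Poisson test: bin b is present iff P(X ≥ c_b | λ_b) ≤ p, default p = 10⁻⁴.
The local expectation λ_b is the genome-wide mark rate scaled by the bin's
input coverage relative to the mean input, floored at the global rate so
that input can only raise the expectation (local depletion of input never
makes a call easier). An all-zero input track falls back to the global rate
with a warning. The test is implemented with the exact Poisson survival
function and is checked bin-for-bin against a direct pmf-summation oracle.

## The segmentation HMM

`BernoulliHMM` is a K-state hidden Markov model whose emission for state k
is a product of independent Bernoullis, one per mark — the standard
genome-segmentation emission model. Training is Baum-Welch EM with the
scaled (normalized) forward/backward recursions; per-step scale factors
give the log-likelihood and a posterior `gamma = alpha * beta` directly.
The recursions are compiled with numba; chromosomes are independent
sequences.

Numerical choices:

- emission probabilities are clipped to [10⁻⁶, 1−10⁻⁶] to keep logs finite;
- the log-likelihood trace is asserted non-decreasing every iteration
  (tolerance 10⁻⁶ relative) — a violated assertion is a bug, not noise;
- convergence is a relative log-likelihood gain below `tol` (default 10⁻⁴);
- `n_init` seeded restarts (default 5) guard against local optima; the
  best final likelihood wins;
- posterior decoding takes the per-bin argmax with ties to the lower state
  id; Viterbi decoding is available via `rule="viterbi"`.

The decoder is verified two independent ways: against exact marginalization
over all K^T paths on 12-bin instances, and against `hmmlearn`'s
categorical HMM after encoding M binary marks as 2^M symbols with
product-Bernoulli emission probabilities. Neither reference participates in
the implementation.

Model selection across K is exposed (`select_k`, CLI `--k-range`) as a
log-likelihood report only; no automatic choice is made, because the
appropriate K for a genome segmentation is a judgment about
interpretability, not a likelihood maximum.

State categories (active / repressive / inactive / Quies) are assigned from
the emission profile by explicit thresholds (`CategoryRules`): Quies when
every emission < 0.1; repressive when H3K27me3 is the strongest mark at
≥ 0.3; inactive when H3K9me2 ≥ 0.3 (flagged bivalent when H3K4me1 is also
≥ 0.3, the Copia-type combination); otherwise active. Published analyses
assign these categories by inspection of the emission heat map; an explicit
rule was required for automation, and every threshold is configurable.

## DMR calling

Cytosines with coverage < 3 are discarded; levels are methylated/total.
For each bin with ≥ 2 qualifying cytosines in both samples (per context),
sample A's pooled counts (m_A out of n_A) are tested two-sided against
sample B's pooled level, continuity-clamped to [1/(n_B+2), 1−1/(n_B+2)] so
degenerate levels of exactly 0 or 1 remain testable. p-values are
BH-adjusted within the context across tested bins only. A DMR requires
both |Δ| ≥ 0.6 — Δ computed from *unweighted* mean cytosine levels, the
region-averaging convention — and q ≤ 0.05. The direction of the test is
asymmetric by construction (A against B's level); the symmetric B-vs-A
p-value is reported as a QC column so the asymmetry is auditable. The
two-sided p-value uses the minimum-likelihood convention and matches both
`scipy.stats.binomtest` and an exact enumeration oracle to 10⁻¹⁰.

Design choices made where the procedure was genuinely open: the q-value
family is per-context (CG, CHG, CHH scales differ too much to share one
family); the effect-size condition uses mean-of-cytosines while the test
uses pooled counts (effect size and significance are deliberately separate
conditions); `min_cytosines = 2` keeps single-cytosine bins from dominating
the tested family.

DMR-state coupling divides the K×K DMR count matrix element-wise by the
genome-wide bin count of each state transition (cells with zero transitions
are masked as NaN), row-normalizes over unmasked cells, and applies log₁₀
with zero cells masked.

## State switching and differential regions

The switching matrix counts bins per ordered state pair, is symmetrized by
adding its transpose, and row-normalized into probabilities. The
"enrichment" output divides each probability by the genome fraction of the
target state pooled across the two inputs — the natural reference for a
log-ratio display, since it removes state-abundance bias; the raw
probability matrix is always emitted alongside, as the two readings of a
log-ratio figure differ exactly by this reference. Pooling tissue pairs
sums raw counts and re-normalizes, which is identical to pooling all bin
pairs directly (tested as an identity).

Differential mark regions use a documented substitute for a negative-
binomial GLM test: counts are summed per region, normalized by
median-of-ratios size factors, and compared with the exact conditional
Poisson test (a binomial test of condition A's reads among the region
total), BH-adjusted. A call requires both q ≤ q_max and fold-change above
the threshold. The fold-change scale is explicit (`fc_scale`: natural 1.5
by default, or a log₂ threshold) because published thresholds alternate
between the two scales; a 0.5 pseudocount on normalized totals keeps the
fold-change finite for empty regions, which are additionally skipped and
flagged when a condition has zero counts. This is a substitute test — it
shares the size-factor normalization and the exact-test logic but not the
dispersion model of the original tooling; its FDR behaviour is verified on
null re-draws.

Tissue-specific clustering z-scores each region's signal across tissues,
removes constant rows (flagged with label −1), runs seeded k-means, and
re-orders clusters by the tissue of maximal mean signal so output is
deterministic and interpretable.

## Gene features and regulatory elements

Peak-to-gene assignment uses the 1-bp-overlap rule against the gene body,
with a promoter-scoped variant (window TSS−1000..+500, configurable —
published analyses alternate between "gene" and "promoter" scope without
fixing a window). Mark-combination classes are the exact subset of present
marks. Summit classes (upstream of TSS / TSS–ATG / downstream of ATG /
unmarked) use the summit of the highest-scoring assigned peak (tie: summit
nearest the TSS), with the peak midpoint as summit when none is provided.
Expression breadth counts tissues with FPKM strictly above 1; the separate
FPKM > 0.15 inclusion threshold used for TE-location expression analyses
is exposed as its own constant. TE location classes let exon dominate
intron when a TE covers both.

DRE/PRE classification is rule-ordered: proximity first (PRE within 1 kb
of a TSS or overlapping a promoter window), then the distal rule (no gene
body or promoter overlap AND mean CG methylation ≤ 0.1). Peaks whose bins
carry no qualifying cytosines cannot satisfy the low-methylation rule and
are excluded with an explicit reason rather than guessed. The 0.1 cutoff
is the conventional "low methylation" boundary; it, the 1-kb proximal
distance, and the promoter window are all configuration keys. The six
loop/PRE gene categories are a pure function of three predicates (own-PRE,
looped, partner-PRE); partner-PRE implies looped by construction, and the
two impossible predicate combinations are asserted unreachable.

## Variety panel

All varieties live on one shared reference grid (the single-reference
projection used in multi-variety epigenome studies). Conserved fractions
normalize the fully-conserved bin count of each state by the state's mean
per-variety abundance; the subgroup switch matrix normalizes consensus
fixed-difference counts by the source-state genome fraction. Both
normalizations implement "relative to genome proportion" with the
source-state denominator; since the reading is ambiguous in prose
descriptions of such figures, the un-normalized counts are always
available. Saturation curves report union bin coverage over prefixes of
random variety orderings (10 orderings by default) — union coverage is
monotone by construction and asserted so. Distances are Bray-Curtis or
1−Spearman on binned signal; 2-D ordination is delegated to scikit-learn's
seeded MDS and labelled as such.

## The synthetic-data generator

A single hidden chromatin-state path per tissue drives every observable:

- **states**: first-order Markov chains over bins with self-transition
  `stickiness` (default 0.97, giving ~6.5-bin ≈ 1.3-kb mean segments);
  with an annotation present, promoter-adjacent bins are biased toward
  H3K4me3-emitting active states, gene bodies toward RNAPII states, and
  heterochromatin blocks toward H3K9me2 states. Additional tissues re-draw
  whole segments with probability `tissue_switch_rate` (default 0.12).
- **tracks**: counts ~ Poisson(depth·(bg + fg·present)) with
  present ~ Bernoulli(E[state, mark]); defaults depth 30 reads/bin,
  bg 0.05, fg 1.0 (a 20:1 foreground ratio), input ~ Poisson(20). Poisson
  was chosen over negative binomial because it matches the Poisson
  binarization model; a Gamma-Poisson `overdispersion` knob exists.
- **methylome**: cytosines are placed at per-context densities (CG 0.02,
  CHG 0.02, CHH 0.05 per bp — reduced relative to a real plant genome to
  keep desk-scale arrays small while leaving ≥ 10 cytosines per 200-bp
  bin), levels set by the state category (heterochromatin high-CG, active
  promoters low), coverage ~ Poisson(20 or 30), methylated ~
  Binomial(coverage, level). Planted DMR bins shift the level by exactly
  ±delta, restricted to bins whose base level admits the full shift.
- **panel**: subgroup consensus paths diverge from the base at
  `between_rate`, varieties from their consensus at `within_rate`
  (defaults 0.08 / 0.02, between > within so subgroup structure is real);
  a configured number of bins is planted as fixed inter-subgroup
  differences. The default panel is 10 varieties in 4 subgroups. SNP
  density follows the state category (heterochromatin highest) with a
  linear ramp up to 3× in the 2-kb flanks of H3K9me2 regions.
- **expression**: FPKM ~ log-normal with the mean set by the promoter-state
  category (active ≈ 25, repressive ≈ 0.4, heterochromatic ≈ 0.05,
  quiescent ≈ 0.2; σ = 1), so repressed and heterochromatic genes fall
  mostly below the FPKM > 1 expressed threshold.

The default 15-state catalogue (promoter, enhancer-like, transcribed,
bivalent, Polycomb, heterochromatin including a Copia-type
H3K4me1+H3K9me2 state, open intergenic, and quiescent states over marks
H3K4me3, H3K27ac, H3K4me1, H3K27me3, H3K9me2, RNAPII, FAIRE) is chosen so
the category rules partition it into 6 active, 3 repressive, 3 inactive
and 3 Quies states.

All randomness derives from one master seed through named substreams
(CRC-32 of the component name spawns a child `SeedSequence`), so adding a
component never perturbs another's draws and every artifact is bitwise
reproducible under a seed.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: mappability and copy-number artifacts,
fragment-level read structure and GC bias, overdispersion beyond the
optional Gamma-Poisson knob, bisulfite non-conversion error, linkage
between SNPs, realistic sequence content, and peak-shape detail (truth
peaks are unions of 200-bp bins). Recovery rates measured here are
upper bounds for field data.

## Problem sizes

The bundled study conditions are desk-scale: two 2-Mb chromosomes
(20,000 bins) for the default pipeline, 10⁵ bins for HMM
parameter-recovery and switching-independence checks, 2×10⁴ bins for DMR
calibration, and 10 varieties for the panel. These sizes make every
property measurable with comfortable statistical margins while the full
suite and the acceptance script each run in well under a minute of compute
plus numba compilation.

## Known limitations

- The Baum-Welch implementation treats chromosomes as independent
  sequences and offers no multi-threading; 10⁶+ bin genomes at K ≥ 30
  would need minibatch or spectral initialization strategies.
- The DMR caller tests pooled counts and is calibrated for the
  high-coverage regime (≥ ~10 reads/bin pooled); sparse CHH analyses at
  low coverage would need a dispersion-aware model.
- The differential-region test is an exact Poisson substitute, not a
  negative-binomial GLM; with strong biological replication variance it
  will be anticonservative (it is used here with simulated Poisson data
  and flagged as a substitute in the API documentation).
- `classify_faire` trusts the provided methylation bins; no imputation is
  attempted for uncovered peaks (they are excluded with a reason).
- MDS ordination is seeded but, like all stress-minimization embeddings,
  only defined up to rotation; downstream comparisons should use the
  distance matrices, not the embedding coordinates.
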