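# chromdyn

Comparative epigenomics of a multi-tissue, multi-variety plant genome at
fixed 200-bp resolution: chromatin-state segmentation with a multivariate
Bernoulli hidden Markov model, binomial differentially-methylated-region
(DMR) calling, state-switching statistics between tissues, open-chromatin
regulatory-element (DRE/PRE) classification with chromatin-loop gene
categories, and conservation/divergence statistics across a variety panel.

The package is written for analyses of the kind performed on rice reference
epigenomes — several histone marks, RNAPII and FAIRE open-chromatin signal
over a few tissues, whole-genome bisulfite methylomes, and panels of
varieties from distinct subspecies groups — but every stage runs end-to-end
on built-in synthetic epigenomes with planted truth, so the whole pipeline
is testable without any external data.

## The models at the core

**Chromatin states.** The genome is tiled into 200-bp bins. Each mark track
is reduced to presence/absence per bin by an upper-tail Poisson test
against an input-scaled local expectation (bin is "present" iff
P(X ≥ c | λ_b) ≤ 10⁻⁴). A K-state HMM with independent Bernoulli emissions
per mark — emission matrix E ∈ [0,1]^{K×M}, transition matrix A, initial
distribution π — is trained by Baum-Welch EM (log-likelihood monotonicity
asserted every iteration, best of several seeded restarts) and decoded by
the forward-backward posterior (argmax per bin, ties to the lower state
id). States are annotated with genome coverage, fold enrichment over
feature classes (TSS, TTS, exon, intron, intergenic, TE families), and a
rule-based category (active / repressive / inactive / Quies) read off the
emission profile.

**DMRs.** Per-cytosine methylation levels are methylated/total reads,
keeping cytosines with coverage ≥ 3. A 200-bp bin is a DMR between two
samples when both conditions hold: |Δ| ≥ 0.6, where Δ is the difference of
unweighted mean cytosine levels, and BH-adjusted q ≤ 0.05 from a two-sided
binomial test of sample A's pooled counts against sample B's pooled level.
DMR bins are then coupled to chromatin-state transitions: a K×K DMR count
matrix is divided element-wise by the genome-wide count of each state
transition, row-normalized, and log₁₀-transformed.

**State switching.** For a tissue pair, counts[s₁,s₂] = bins labelled s₁
in one tissue and s₂ in the other; the matrix is symmetrized by adding its
transpose, row-normalized into switching probabilities, and optionally
expressed as log₁₀ enrichment over the genome fraction of the target state.
Tissue pairs are pooled by summing counts.

**Regulatory elements.** An open-chromatin peak is a PRE when it lies
within 1 kb of a TSS or overlaps a promoter window (TSS−1000..+500), and a
DRE when it overlaps neither gene body nor promoter *and* its mean CG
methylation is ≤ 0.1. Genes fall into six categories by three predicates:
own promoter carries a PRE, promoter participates in a loop, and any loop
partner promoter carries a PRE.

**Variety panel.** On a shared reference grid: per-state conserved
fractions (conserved bin count over mean state abundance), consensus fixed
differences between subgroups (all of group A share s_A, all of group B
share s_B ≠ s_A), SNP-density profiles around peaks (2-kb flanks in 10-bp
units plus a scaled body, and a 1-kb/20-unit boundary profile), saturation
curves over random variety orderings, and Bray-Curtis / rank-correlation
epigenome distance matrices with seeded MDS ordination.

## Worked example

Plant 50 DMRs (|Δ| = 0.7, coverage ≈ 30×) in a simulated methylome driven
by a hidden 15-state path, call them back, and summarize tissue switching:

```python
import numpy as np
from chromdyn import SimConfig
from chromdyn.synthetic_data import simulate_states, simulate_methylome
from chromdyn.methylation import call_dmrs
from chromdyn.state_dynamics import switch_matrix

cfg = SimConfig(coverage_mean=30.0, n_dmr_bins=50, dmr_delta=0.7)
truth_states = simulate_states(None, cfg, seed=1)
seg = truth_states["young_leaf"]

calls_a, calls_b, truth = simulate_methylome(seg, cfg, seed=1)
result = call_dmrs(calls_a, calls_b, seg.grid, "CG")
planted, called = set(truth["bin"]), set(result.dmrs.index)
print(f"{len(result.tested)} bins tested, {len(result.dmrs)} DMRs called")
print(f"recall {len(called & planted)/len(planted):.2f}, "
      f"precision {len(called & planted)/len(called):.2f}")

m = switch_matrix(seg, truth_states["mature_leaf"])
print(f"switch probability diagonal mean: "
      f"{np.nanmean(np.diag(m.probabilities)):.3f}")
```

prints

```
18284 bins tested, 49 DMRs called
recall 0.98, precision 1.00
switch probability diagonal mean: 0.845
```

— of the 20,000 bins on the default two 2-Mb chromosomes, 18,284 carry
enough CG cytosines in both samples to be testable; 49 of the 50 planted
DMRs are recovered with no false calls, and about 85 % of the genome keeps
its chromatin state between the two simulated tissues.

The same study runs as one command, writing every intermediate (tracks,
segmentations, DMRs, switch matrices, elements, panel statistics) plus a
`manifest.json`:

```bash
chromdyn simulate --seed 1 --out results/run1
```

Individual stages are exposed as subcommands (`chromdyn binarize`,
`chromdyn learn --k 15`, `chromdyn segment`, `chromdyn dmr`,
`chromdyn switch`, `chromdyn elements`, `chromdyn conserve`, ...); run
`chromdyn --help` for the full list.

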