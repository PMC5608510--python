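# Methods

This note documents the statistical procedures, the synthetic-data model,
and the numerical and design choices behind `coregdep`.

## Study design being modeled

The package targets a three-way design: a panel of putative direct AR
target genes (defined by ARBS–TSS proximity plus membership in published
androgen-regulated gene lists), measured on an intensity array under every
combination of siRNA condition (non-targeting control plus one siRNA per
coregulator), treatment (synthetic androgen vs vehicle), and biological
replicate (3 per cell by default). The quantity of interest per gene is the
androgen response — the log2 fold change androgen vs vehicle — and how it
changes when a coregulator is silenced.

## Target nomination

A peak is assigned to a gene when |midpoint − TSS| ≤ w with w = 300 000 bp,
boundary inclusive. Distances use the peak midpoint, floor((start+end)/2) on
0-based half-open intervals; the alternative nearest-edge convention is not
implemented because the midpoint is symmetric and the window dwarfs peak
widths. A peak within the window of *any* TSS of a multi-TSS gene counts for
that gene; one assignment row is emitted per (peak, TSS) pair. Nomination
additionally requires membership in ≥ `min_lists` regulated gene lists
(default 1); the cross-match is mandatory — an empty list collection is an
error rather than a pass-through.

Peak genomic context uses precedence promoter > exon > intron > intergenic,
with the promoter window [TSS − 3000, TSS + 500] oriented by strand. These
category definitions are conventional rather than canonical, and are
configurable; an "enhancer" category cannot be derived from a gene table
alone and is deliberately absorbed into intron/intergenic.

## Normalization and moderated statistics

Quantile normalization maps every column onto the per-rank cross-column
mean reference; ties within a column receive the mean of the reference
values at the ranks they jointly occupy, preserving within-column order.
The operation is idempotent.

Contrasts are fit as cell-means models: effect = Σ wᵢ·meanᵢ with variance
factor Σ wᵢ²/nᵢ and residual variance pooled within cells (df = N − #cells).
Empirical-Bayes moderation shrinks s²_g toward a scaled-F prior (d₀, s₀²)
estimated by method of moments on e_g = log s²_g − ψ(d_g/2) + log(d_g/2):
the excess of var(e) over ψ′(d_g/2) identifies d₀ via trigamma inversion
(Newton, 50 iterations, relative tolerance 1e-10) and mean(e) identifies
s₀². d₀ is capped at 10⁶ to represent "infinite".

Degenerate branch: when var(e) − ψ′(d_g/2) ≤ 0 there is no detectable
between-gene variance heterogeneity; the estimator then sets d₀ to the cap
and s₀² to the **geometric mean of the observed s²** (no digamma bias
correction). This makes identical gene variances an exact fixed point of
the shrinkage — the natural zero-dispersion limit — at the cost of a small
downward bias in s₀² that is irrelevant in that regime because every
gene receives the same shrunken variance.

Zero residual variance (noise-free data) is handled explicitly: t = ±∞ and
p = 0 for a nonzero effect, t = 0 and p = 1 for a zero effect, so noise-free
simulations propagate exactly.

BH adjustment is delegated to `statsmodels` (`fdr_bh`); the test suite
verifies it against an independently coded step-up formula. All tests are
two-sided.

## Dependence classification

The interaction c3 = (si_X, androgen − si_X, vehicle) − (control, androgen −
control, vehicle) is fit as a single four-cell contrast with its own
moderated test, rather than by comparing two DE lists; the
difference-of-differences estimate is algebraically identical to c2 − c1
from independent two-group fits, but the pooled four-cell variance gives the
interaction its own test. p-values are BH-adjusted across genes within each
of the three comparisons separately.

Affectedness gate: c3_fdr < 0.05 ∧ |c3| ≥ 1 (the same dual rule used for
each comparison) ∧ max(|c1|, |c2|) ≥ 1. The last condition restricts calls
to genes that are androgen-regulated somewhere, mirroring an analysis
performed on an already-regulated panel; without it, never-regulated genes
with a knockdown-induced response would be labeled.

Tie-breaks (measure-zero at nonzero noise, but reachable in noise-free
data): |c2| = |c1| takes suffix "+"; a zero sign in c1 or c2 is not a
strict flip, so the prefix defaults to "co". Labels are invariant under a
global sign flip of (c1, c2, c3).

The whole-percent affected fraction uses half-up rounding
(floor(100·a/n + 0.5)), so 258/452 reports as 57.

## Set statistics

Overlap significance is the upper-tail hypergeometric P(X ≥ k) computed via
`scipy.stats.hypergeom.sf` (log-space internally; verified exact against
rational enumeration for all universes ≤ 15). The **universe defaults to
the analysis panel**, not the genome: this choice materially changes
p-values and is exposed in every entry point. The one-sided (enrichment)
convention means a large observed overlap that is still below expectation
yields p near 1.

Directionality consistency between signed sets A and B reports, e.g., among
A-increased genes that are members of B, the percentage that are also
B-increased — four conditional percentages plus consistent/opposite counts
over the overlap. Empty denominators yield NaN rather than 0, since "no
gene to assess" differs from "0% consistent".

Correlation-based combination: Pearson correlation of per-gene interaction
effects between coregulator columns; zero-variance columns are reported as
r = 0 with a warning (keeping the r ≥ 0.25 rule total). Merged sets keep a
gene's direction tag only when both parents agree; conflicts become
untagged members. Pair ordering is by descending r with label tie-breaks,
so results are invariant to column order.

Clustering is average-linkage agglomeration on 1 − Pearson row distances
(scipy). Constant-profile rows have undefined correlation; they are
assigned distance 1 to everything and flagged. The merge tree is exported
as newick with heights as branch lengths.

## Motif scanning and enrichment

PWM probabilities get a pseudocount of 10⁻³ (renormalized) before log2
odds against the background base composition. The default hit threshold is
80% of the maximum achievable score of the motif — a conventional choice;
the external web tools this stage replaces do not publish theirs. Both
strands are scanned; a reverse-strand hit is reported at its forward-strand
window start. Windows containing non-ACGT characters are skipped.

Sequence-level enrichment uses the binomial upper tail
P(X ≥ k_fg | n_fg, k_bg/n_bg) — appropriate because backgrounds are large
and resampled — with an exact pooled hypergeometric variant behind a flag.
A zero background count is floored at 1/(n_bg + 1), so a single chance
foreground hit cannot produce p = 0. p-values are BH-adjusted across motifs
within each signature; "selective" motifs are enriched in ≥ 1 and ≤ 2
signatures.

The dinucleotide-preserving background is implemented as a seeded
first-order Markov resample of the pooled foreground (add-one smoothed
transition matrix), which preserves dinucleotide composition in expectation;
an exact Euler-path shuffle was judged unnecessary for this null.

## Synthetic-data model

Intensities are generated multiplicatively: intensity = 2^(b_g + effect +
ε), ε ~ N(0, σ), so the additive effect model is exact after the pipeline's
log2 transform. Per-gene baselines b_g ~ N(8, 1) (log2 scale, arbitrary
units typical of array intensities). Defaults:

| parameter | default | meaning |
|---|---|---|
| n_genes | 2000 | panel-scale gene count with headroom for null genes |
| reps_per_condition | 3 | biological replicates per (siRNA, treatment) cell |
| effect_log2fc | 2.0 | planted androgen response under control siRNA |
| delta_log2fc | 1.5 | planted knockdown-induced change in that response |
| noise_sd | 0.25 | residual SD on the log2 scale |
| regulated_fraction | 0.9 | genes with a nonzero androgen response |
| up_fraction | 0.55 | of regulated genes, fraction androgen-induced |
| class_fractions | .08/.12/.03/.02/.75 | co+/co−/op+/op−/unaffected |

The class mix was chosen once as a mid-range realistic setting: reported
per-coregulator affected fractions span 0–57% with direction-consistent
changes dominating flips. The real arrays publish no noise model or
effect-size distribution, so `noise_sd` and the effect sizes are explicit
stand-ins; they are study conditions, not tuning knobs. Planted classes fix
the knockdown response deterministically: co± keeps sign(c1) and moves
|c1| by ±Δ, op± additionally flips the sign; configurations in which a
magnitude-decreased class would cross zero (Δ ≥ |c1|) are rejected at
construction.

Geometry: genes occupy a per-chromosome "gene territory" (first 40% of each
chromosome); true peaks are placed with midpoint uniform within ±window of
their gene's TSS, while decoys are drawn beyond territory + window — outside
the assignment window of every TSS by construction, emulating gene deserts.
Truth travels in peak names (`arbs_<gene>` vs `decoy_<i>`).

Randomness: one master seed; per-stage generators are spawned as
`SeedSequence(seed, spawn_key=(k,))` with k = 0 annotation/peaks,
1 expression, 2 regulated lists, 3 motif sequences, so stages regenerate
independently and byte-identically.

What the simulator does **not** emulate: probe-level structure (one row per
gene; the probe-collapse step of real arrays is out of scope), spatial or
batch artifacts, intensity-dependent variance, siRNA off-target effects,
correlated knockdown effects between coregulators, and real genome sequence
composition. Passing recovery tests therefore demonstrate correctness of
the statistical machinery under the stated generative model, not
performance on scanner output.

## Quantile normalization and the simulated path

The simulator plants no array-level technical bias, and forcing every
column to a common value multiset would distort the planted treatment
effects (and break noise-free exactness). Quantile normalization is
therefore exposed as its own operation — applied to real intensity matrices
before analysis — but is not inserted into the simulated-data analysis
path.

## Problem sizes

Default analyses run at 2000 genes × 6 coregulators × 3 replicates
(~78 samples), 17-set overlap matrices, and motif studies of ~30 foreground
sequences per signature against 200 background sequences of 200 bp; these
sizes make every end-to-end check reproducible on a laptop in seconds while
keeping per-category planted counts in the hundreds.

## Known limitations

- Long-range (beyond-window) regulation and chromatin looping are not
  modeled; the 300 kb window is a hard cutoff.
- The fixed-effects cell-means model has no array random effect; designs
  needing one should pre-average or use a dedicated mixed-model tool.
- The binomial enrichment test treats sequences as exchangeable; length or
  composition imbalance between foreground and background must be handled
  by the caller (the Markov background helper exists for this).
- Pie-chart-style genomic categories depend on the promoter-window
  convention; comparisons across annotation sources should fix it
  explicitly.
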