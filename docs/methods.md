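# Methods

`gutdynamics` implements the chromatin-accessibility statistics of early
gut organogenesis as a reusable, tested pipeline.  This note records the
models, the tunable parameters, the numerical choices, what the
synthetic-data generator does and does not emulate, and the design
decisions taken where the procedure was genuinely open.

## The analyses

**Per-cell QC.**  Cells are kept iff they carry at least 1000 fragments
*and* a TSS enrichment score of at least 4 (both removals are strict
"less than").  The TSS enrichment score is the mean per-bp insertion
count (both Tn5 insertion sites per fragment) within ±50 bp of annotated
TSSs divided by the mean per-bp insertion count in a distal background
band 1901–2000 bp from the TSSs on both sides.  This is the
community-standard construction, which makes the threshold of 4
meaningful; a cell with zero background coverage scores 0 and is
flagged.

**Gene activity scores.**  For gene *g* and cell *c*,

```
score(g, c) = L(g) · Σ_b w(d_b) · count(b, c) / depth(c) · target
```

summed over 500 bp bins *b* within ±100 kb of the gene body, where
`w(d) = exp(−d / 5000) + e⁻¹` and `d_b` is the bp distance from the bin
center to the nearest gene-body edge (0 inside the body).  `L(g)` is a
gene-length factor: genes are binned into 5 quantiles of total region
size (body + both 100 kb flanks) and assigned factors linearly spaced
from 5 (smallest quintile) to 1 (largest).  `depth(c)` is the cell's
total fragment count and `target` = 10⁴, making scores invariant to
uniform per-cell depth scaling.  The kernel shape, the floor weight
e⁻¹, the decay length 5 kb and the 5-level length scaling are package
choices — the qualitative requirements (distance weighting, length and
depth normalization) admit several concrete kernels; all constants are
exposed in `GeneScoreParams`.

**Organ labeling.**  Clustering itself is an input (the synthetic data
carries true cluster labels); labeling computes, per cluster, the mean
gene score of each organ's markers, z-scores each marker gene across
clusters, and assigns the argmax organ.  If the winning organ declares a
secondary marker table (e.g. a broad foregut signature resolved into
stomach vs lung by finer markers), assignment re-runs once within the
cluster on the secondary table.  Ties break by declared organ order and
are flagged.

**Organ-specific peaks and genes.**  Depth-normalized bulk signal
(feature × organ) is quantile-normalized (ties receive the mean of their
rank values), log2(x+1)-transformed, and partitioned by K-means
(default k = 8, deterministic under seed; rows are z-scored before
clustering so clusters reflect cross-organ *pattern* rather than overall
magnitude).  Clusters whose linear-scale centroid is high in exactly one
organ — operationalized as max ≥ 2× the second-highest organ — are
candidates; candidate features pass if target / mean(other organs) ≥ 2.5
on the quantile-normalized linear signal.  Neither k, the initialization,
nor the candidate rule is canonical; all are recorded, configurable
choices.  Single-cell marker features instead use a two-sided rank-sum
test on depth-normalized counts with BH correction (FDR ≤ 0.05 and
log2FC ≥ 1.5 for genes, ≥ 1 for peaks); the test is a plain rank-sum
without bias-matched backgrounds.

**Overlap enrichment.**  Overlap of two peak sets inside a universe
(membership by ≥ 1 bp overlap, half-open coordinates) is scored by a
one-sided hypergeometric tail `P(X ≥ obs)`, BH-adjusted across the
tested grid and reported as −log10(P-adj).

**Gene–peak association score.**  With G genes total, O of them having
≥ 1 target peak within ±50 kb of the TSS, and G_T / O_T the same counts
within a target gene set:

```
association = (O_T / G_T) / (O / G)
```

Random target sets give a score of 1 in expectation; the permutation
null mean is checked to 1.00 ± 0.02 over 1000 draws.

**Relative motif enrichment.**  Per peak, the accessibility fold change
between stages is `(late + 0.5)/(early + 0.5)` on normalized signal.
Peaks split into motif-overlapping and motif-free groups (≥ 1 bp overlap
with genome-wide motif sites); a two-sided rank-sum test compares the
groups' fold changes and the score is −log10 p signed so that positive
means motif peaks gain accessibility over development.  The rank-sum p
is computed by full enumeration (midranks for ties) when the smaller
group has ≤ 8 members and the total is ≤ 20, and by the normal
approximation with continuity and tie correction otherwise; scores are
capped at ±320 and flagged when p underflows.

**PWM scanning.**  Motif sites are called by log2-odds scanning against
the background model on both strands.  Scores are discretized to a 0.01
grid and the exact null score distribution is built by dynamic
programming over per-column score histograms, giving an exact p-value
for every attainable score; positions with p ≤ 10⁻⁴ (default) are
sites.  Hits at identical coordinates on both strands (palindromes)
collapse to a single strand-"." record.

**KO peak fates.**  On the merged KO∪WT peak set, with depth-normalized
counts averaged over replicates, `FC = (KO + 0.5)/(WT + 0.5)`; FC > 2 is
gained, FC < 1/2 is lost, everything else maintained — the three sets
partition the merged set by construction.  The 0.5 pseudocount guards
division by zero and is configurable.  Replicates are normalized first
and averaged second, since depth differences otherwise dominate.

**Deviation z-scores.**  For a peak set, each cell's expected in-set
count is depth × (set total / grand total); the raw deviation is
(observed − expected)/expected.  Fifty background peak sets, sampled to
match the annotation's mean-accessibility deciles (GC matching is
uninformative on i.i.d. synthetic sequence), provide the mean and SD
that standardize the raw deviation into a z-score.  Sampling is
deterministic under the seed.

**Lineage restriction.**  Early per-organ peak sets are merged by
iterative overlap (retain the highest-scoring remaining peak, discard
everything overlapping it by ≥ 1 bp, repeat; ties break by coordinate);
merged peaks overlapping ≥ 1 peak of *every* foregut organ are the
common early peaks.  A common peak is "closed" in an organ if it has no
1 bp overlap in that organ's late peak set but does in the other's
(closed in both if absent from both).  A gene is repressed in an organ
if `(late + 0.5)/(early + 0.5) < 0.5` on normalized expression — the
fold change is taken on linear-scale normalized expression, since a
ratio of logarithms would depend on the measurement scale.  Repressed
genes split into both / organ-A-specific / organ-B-specific (disjoint by
construction), and each category is refined to the genes with a
correspondingly closed peak within ±50 kb of the TSS.  Refined fractions
are compared across organs by a one-sided exact binomial test of k₁/n₁
against the null proportion p₀ = k₂/n₂; both roles (which proportion is
the reference, and the direction) are explicit arguments because the
construction admits either convention.

## The synthetic study

The generator (`sim_gut` module, `SimConfig`) emulates the study's data
shapes with planted ground truth (`PlantedTruth`):

* a random i.i.d. ACGT genome (default 4 × 5 Mb) with ~200 genes and
  5000 non-overlapping 500 bp peaks on a slot grid;
* five organs × 200 cells; each cell draws ~Poisson(2500) fragments, of
  which 25% pile at TSSs, 35% fall in peaks (with weight `signal_fold`
  = 8 on the cell's own organ-specific peaks), and the rest uniformly
  outside peaks, so the planted in-peak fold is multiplicative; 5% of
  cells are planted at ~300 fragments, below the QC bar;
* per organ, 3 marker genes carry two specific peaks 2–10 kb from the
  TSS, and other organs' specific peaks avoid all marker windows and all
  TSSs — otherwise shared TSS pileup and rival peaks would corrupt the
  planted marker contrast;
* stage-paired bulk ATAC counts: organ-specific peaks are elevated in
  their organ at both stages, temporally gained peaks only in the late
  stage; KO/WT pairs plant 150 gained and 150 lost peaks; counts are
  negative binomial with dispersion 0.2 (Poisson at dispersion 0) and
  log-normal library sizes, so depth normalization is exercised;
* expression tables with planted late-stage up-genes (80% of them
  co-located with gained peaks within 50 kb of the TSS);
* the first PWM's consensus is planted into every gained peak (a
  late-enriched motif by construction), other motifs into random peaks.

Everything is byte-identical under the same seed: each stage draws from
its own seed stream, so stages are order-insensitive.

What the generator does **not** emulate: read-level sequence errors,
doublets, batch effects beyond library size, GC or mappability bias,
realistic genome structure (repeats, chromatin domains), or inter-cell
depth structure beyond Poisson.  Passing recovery tests therefore shows
the statistics behave as designed under their own assumptions — not that
they are robust to artifacts real data would add.

## Problem sizes

The default synthetic study (1000 cells, ~2.5 M fragments, 5000 peaks,
200 genes) keeps a full end-to-end run, including the acceptance script,
under a minute on one CPU while leaving every planted contrast
comfortably detectable; test fixtures use a few hundred peaks and cells.

## Degenerate inputs and numerical edges

* Empty fragment streams, zero-rate cells, and zero-depth cells yield
  all-zero scores with warnings rather than NaNs.
* An all-tied fold-change ranking is flagged degenerate; selection falls
  back to identifier order.
* Quantile normalization of a constant column triggers the tie rule
  with a warning; tied entries receive the mean of their rank values, so
  the "identical sorted columns" property is exact only at tie-free
  positions.
* K-means uses scikit-learn with a fixed `random_state`; equal-score
  ties in iterative merging break by (contig, start).
* The association score raises on O = 0 (undefined background rate)
  instead of returning infinity.

## Known limitations

* The marker-feature rank-sum test does not match backgrounds for bias,
  so its calls on real data would be anticonservative near accessibility
  extremes.
* The per-organ "open/closed" peak sets the pipeline derives from bulk
  signal (≥ 0.5 × the peak's cross-organ maximum) stand in for per-organ
  peak calling, which is outside this package's scope.
* The PWM scanner assumes an i.i.d. background; higher-order sequence
  composition is not modeled.
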