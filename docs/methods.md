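# Methods

`epimem` re-implements, as a tested pipeline, the bespoke computational
analysis used to characterise the enhancer landscape of innate-memory
(T_IM) CD8 single-positive thymocytes and its concordance with
conventional antigen-experienced memory (T_M) cells. This note documents
the models, the conventions chosen where several were defensible, the
synthetic study generator, and known limitations.

## Interval algebra and the peak atlas

All coordinates are 0-based half-open (BED convention). The *atlas* of a
collection of peak sets is the merge of the pooled peaks under the
relation "overlap by at least 1 bp", taken to its transitive closure;
each atlas region carries one boolean membership flag per source,
true iff some source peak overlaps the region by ≥ 1 bp.

Conventions fixed for determinism:

- **Book-ended intervals do not merge.** A minimum overlap of 1 bp is a
  strict requirement; intervals sharing only a boundary stay separate.
  This differs from the default of several genome-arithmetic tools.
- **Point-to-interval distance** is measured to the nearest included
  base: 0 inside `[start, end)`, `start − p` to the left,
  `p − (end − 1)` to the right. Ties between equidistant points break
  toward the smaller coordinate.
- Strand is carried through I/O but ignored by merge/overlap; peak calls
  are unstranded. Only TSS-anchored windows are strand-aware.
- BED name/score survive reading but are dropped on merge (a merged
  region has no single parent).

For a general minimum overlap the merge is computed as connected
components of the pairwise relation (a component's spanning interval may
overlap an outside interval without any member doing so); for the
default 1 bp threshold a sorted sweep is exact and is used instead.

## Promoter and enhancer annotation

Two promoter conventions coexist and are both implemented, selected per
pipeline stage:

- **Histone analyses** — the promoter window runs from −5 kb to +2 kb
  around the TSS in gene orientation. H3K4me3⁺ regions overlapping such
  a window by ≥ 1 bp are promoters. H3K4me1⁺ regions whose closest edge
  lies ≥ 2 kb from every TSS *and* which overlap no promoter are
  enhancers. "Located between" was read as ≥ 1 bp overlap (the
  permissive, conventional interpretation) rather than full containment.
- **Accessibility (ATAC) analyses** — a strand-independent ±2 kb window
  around the TSS; peaks touching it are promoter-class, all others
  enhancer-class.

Activity (H3K27ac) regions are labelled by overlap with the annotated
promoter/enhancer sets, promoter taking precedence when a region touches
both; every region receives exactly one of promoter/enhancer/unclassified.
Regions on chromosomes absent from the TSS table are enhancer-eligible
(distance +∞) with a logged warning. The genomic-distribution summary
assigns each peak one category by precedence promoter > 5′UTR > exon >
intron > distal intergenic; promoter windows come from the TSS table
(±2 kb), the other features from a plain feature TSV.

## Differential chromatin activity

Counting, normalization and testing operate on a fixed atlas:

1. a fragment adds 1 to every region it overlaps by ≥ 1 bp (atlas
   disjointness bounds this at two regions for a gap-spanning fragment);
2. replicate counts are pooled by summation per condition;
3. every pooled sample is scaled to the smallest total library size,
   `round(k · Nmin/N)`, rounding half away from zero. Rescaling all
   library sizes by a common factor leaves everything downstream
   unchanged;
4. each region receives `log2((n_a + c)/(n_b + c))` with pseudocount
   `c = 1` (keeps (0, 0) at 0) and an exact two-sided Poisson p-value
   under the equal-split null: `λ = (n_a + n_b)/2`,
   `p = min(1, 2·min(P[X ≤ min], P[X ≥ max]))`. The test is symmetric
   in its arguments and returns 1 at (0, 0). Sidedness is configurable;
   two-sided is the default since both gain and loss calls are made;
5. optionally, the "proportion of library" filter on *raw* pooled counts:
   conditional on the total, `k_a ~ Binomial(k_a + k_b, N_a/(N_a + N_b))`
   under the null, two-sided by doubled smaller tail. This is the exact
   statistical content of the named filter in interactive seq-analysis
   tools. Defaults: α = 0.05, with 0.001 used for the ectopic-EOMES
   accessibility comparison;
6. Benjamini–Hochberg adjustment over all regions (the R `p.adjust`
   "fdr" step-up); a region is called up/down when its adjusted p (and
   the filter's, when enabled) clears α and |log2FC| exceeds the
   threshold (0 for chromatin, 1 for expression tables).

**Calibration.** The equal-split Poisson test is *structurally
conservative*, not merely discrete: under the null, conditional on the
total `n`, the count allocation is Binomial(n, ½) with variance n/4,
while the test evaluates Poisson(n/2) tails with variance n/2. The
z-score is therefore deflated by √2 and the fraction of null regions
with p < 0.05 is ≈ 2·Φ(−1.96·√2) ≈ 0.006 (measured 0.004–0.008 across
seeds). The test never exceeds its nominal level; power against planted
two-fold effects at counts ≥ 50 remains essentially 1. Users wanting a
calibrated test at small effect sizes should rely on the conditional
binomial filter, which is exact.

"Total library size" is ambiguous between mapped reads and in-atlas
counts; the in-atlas total is the default, with externally supplied
sizes supported.

## Memory-concordance clusters

Each enhancer-activity region carries (log2FC, q) from three
memory-vs-naive comparisons: two conventional-memory infection models
(LCMV; Listeria) and the innate-memory thymocyte comparison. The two
conventional datasets collapse to a consensus status: a sign wins when
at least one dataset is significant with that sign and the other is not
significantly of the opposite sign (a strict both-significant variant is
available). The (T_M, T_IM) status pair maps onto six clusters — C1/C4
gains/losses specific to conventional memory, C2/C5 shared, C3/C6
specific to innate memory; contradictory sign pairs are dropped with a
warning; (none, none) is unlabelled. Composition percentages are
computed per side (C1–C3 gains, C4–C6 losses) over labelled regions and
sum to 100.

A robust per-region fold-change variant normalizes each replicate to the
lowest library, takes per-condition medians, then the log2 ratio — used
for heatmap-style summaries where a single outlying replicate should not
dominate.

Cluster-associated expression shifts are tested with the two-sided
Wilcoxon matched-pairs signed-rank test on paired (T_M/naive, T_IM/naive)
gene log2FCs. Zero differences are dropped (Wilcoxon's original
treatment; all-zero pairs give p = 1 by convention). For n ≤ 25 the
exact permutation null is used, computed by subset-sum dynamic
programming over doubled midranks so ties are handled exactly; above
that, the normal approximation with continuity correction.

## Transcription-factor co-binding and motif positions

Co-binding is summarised by two fractions over factor-bound (EOMES)
regions: the fraction overlapping partner (RUNX3) peaks from either cell
state, and the fraction overlapping partner peaks from the *naive* state
specifically — the pioneer-factor pre-positioning signal.

The motif scanner is deliberately minimal. A JASPAR plain-text PFM is
converted to probabilities; a pseudo-probability (0.01) is added and
rows renormalised before taking log2-odds against the background
(uniform by default), so JASPAR zeros stay finite. `N` scores 0
(background). The best hit per sequence is the maximum log-odds over all
offsets and both strands (reverse-complement matrix scan; offsets always
refer to the forward sequence); ties prefer the smaller offset, then the
+ strand. No score threshold is applied by default (one best site per
region); a threshold is available. Positional density histograms the
best-hit *match centers* relative to the sequence midpoint, default
±250 bp in 10 bp bins (bin width configurable; the underlying figure
style does not fix one).

## Regulatory-potential target inference

Gene scores follow the exponential-decay regulatory-potential model:
`S_g = Σ exp(−(0.5 + 4Δ))` over peaks whose *centers* lie within 100 kb
of the gene's TSS, `Δ` the distance as a fraction of the window. A peak
on the TSS contributes e^−0.5 ≈ 0.607, one at the window edge
e^−4.5 ≈ 0.011. This re-implements the documented core of the
established target-inference approach; internals of the external
package beyond the published decay form (e.g. its multi-TSS gene models)
are not reproduced.

Expression tables are split into up/down/static groups at FDR < 0.05 and
|log2FC| > 1. Activating/repressive function is inferred by two-sided
two-sample Kolmogorov–Smirnov tests of the up- and down-group score
distributions against the static background (asymptotic p with effective
sample size n_x·n_y/(n_x+n_y)), plus cumulative group curves over the
descending-score rank axis. The published "predicted targets" gene count
has no stated selection rule; an explicit quantile rule is exposed
instead: differentially expressed genes scoring above a chosen quantile
(default median) of the static-score distribution.

## Single-cell correlation comparison

Fluorescence intensities are digitized and tie-heavy, so the
tie-corrected Kendall tau-b is used. Two groups' correlations are
compared via the Fisher Z transformation, `z_i = atanh(τ_i)`, with
Fieller's variance `0.437/(n_i − 4)` for the Fisher-z of a Kendall
coefficient — the source analysis names the transformation but not the
variance; Fieller's is the standard choice for tau, and the
Pearson-style `1/(n − 3)` is available for sensitivity analyses. The
difference is referred to a standard normal, two-sided. Intensities are
used raw by default; arcsinh is optional. The LOESS trend is a local
linear fit with tricube weights over the span-nearest fraction of
points, with the usual linear-smoother pointwise standard-error band.

## Synthetic study generator

The generator emits a complete study as a pure function of
(config, seed): TSS annotation, replicate peak landscapes, count
matrices, sequences, expression tables, cell intensities and a
ground-truth manifest sufficient to score every stage.

What it emulates, and the defaults:

- TSSs uniform with ≥ 20 kb spacing, strands Bernoulli(½). H3K4me3
  peaks (0.6–1.5 kb) placed inside promoter windows with enough margin
  that ±50 bp replicate jitter cannot push a merged peak out; H3K4me1
  peaks (0.4–1.2 kb) in intergenic stretches ≥ 7 kb from every TSS,
  placed in non-adjacent slots so replicate jitter cannot merge distinct
  elements. These margins make the planted promoter/enhancer truth
  recoverable exactly, by construction — passing annotation tests show
  the geometry rules are implemented correctly, not that real peaks are
  this clean.
- H3K27ac laid inside 90% of each element class; concordance clusters
  assigned to 40% of activity enhancers, split evenly into gains and
  losses, with within-side compositions 55/34/11 and 57/36/7 planted
  *exactly* (largest-remainder apportionment) to emulate the printed
  percentage splits.
- Counts Poisson: `count ~ Poisson(N_s/N_ref · μ_r · 2^{β_r x_s})`,
  μ_r log-uniform on [20, 500], library sizes 10⁶ ± 20%, 2 replicates
  per condition, planted β = ±2 in 10% of regions (cluster-driven for
  the three-comparison design: gains up in the comparisons where their
  cluster applies, losses down). Poisson by default so the analysis
  model is well-specified; a gamma-Poisson overdispersed mode exists to
  probe robustness.
- EOMES peaks (200 bp) at the centers of shared/innate-gain (C2/C3)
  enhancers plus a 10% background elsewhere; RUNX3 co-placed at a
  20–60 bp offset for 65% of EOMES regions in the memory state, and
  pre-placed in the naive state for 43% (a subset of the co-bound set,
  so naive-prebound ≤ any-state by construction).
- Sequences: iid background at configurable GC, motif consensus planted
  at Normal(center, 20 bp) offsets, reverse strand with probability ½.
- Expression: target genes |log2FC| ~ Normal(2, 0.5) truncated at ≥ 1.25
  with q ~ U(0, 0.01); static genes Normal(0, 0.3) truncated at ≤ 0.95
  with q ~ U(0.2, 1). The truncation keeps the planted groups exactly
  recoverable at the q < 0.05, |log2FC| > 1 thresholds; without it the
  normal tails would blur the group boundary by a few percent.
- Cells: Gaussian copula with ρ = sin(π·τ/2) and lognormal marginals,
  hitting a target Kendall tau per group (defaults 0.6 vs 0.2, n = 1000).

The default scale is roughly a tenth of the printed study (300
promoters / 800 enhancers by default; a `paper_scale` preset restores
9,814 / 20,103 with the ~29 k activity-region atlas implied). Small
scales keep the full pipeline under a few seconds; scale presets change
problem size only, never the planted effect structure.

What the generator does **not** emulate: read-level noise and mapping
artefacts, peak-caller boundary uncertainty beyond uniform jitter,
correlated replicates, GC/accessibility biases, overdispersion (unless
enabled), overlapping or nested genes, and enhancer–promoter contact
structure. Recovery results on synthetic data therefore certify the
*analysis logic*, not performance on real sequencing data.

## Numerical choices

- Normalized counts round half away from zero (symmetric).
- p-value floors at the smallest positive double keep the (0, 1]
  contract when normal/Kolmogorov tails underflow.
- BH adjustment delegates to the standard step-up implementation and is
  oracle-checked against the closed form.
- LOESS bandwidth h is the k-th nearest distance (k = ⌈span·n⌉); an
  all-zero-distance neighbourhood falls back to the global range.
- The exact signed-rank null uses doubled midranks so tied absolute
  differences stay integral in the DP.
- Degenerate inputs error early and loudly: empty query sets for overlap
  fractions, all-tied vectors for tau, |τ| = 1 for Fisher-z, fewer than
  two or more than two conditions for the differential caller.

## Known limitations

- The Poisson test's structural conservatism (above) means raw p-value
  exceedance rates sit well below nominal under the null; calls are
  correspondingly cautious.
- The concordance consensus rule across the two conventional-memory
  datasets is a reconstruction (the source states none); both the
  default and the strict variants are exposed.
- The regulatory-potential module reproduces the decay model and KS
  comparison, not the external package byte-for-byte.
- LOESS confidence bands are pointwise, not simultaneous.
- The CLI's `run-all` exercises the synthetic route end-to-end; real
  datasets enter through the per-stage subcommands on BED/TSV inputs.
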