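# epimem

Analysis pipeline for the enhancer landscape of **innate-memory CD8 T
cells** — thymocytes that acquire memory-like chromatin without ever
meeting antigen — and its concordance with conventional,
infection-induced memory cells.

The package is aimed at computational biologists who have peak calls
(BED), region count tables (TSV) and expression tables, and want the
complete downstream analysis: peak-atlas construction, histone-mark
promoter/enhancer annotation, differential chromatin activity,
cross-dataset memory-concordance clustering, transcription-factor
co-binding statistics, regulatory-potential target inference, and
single-cell correlation comparison. A synthetic-study generator with a
machine-readable ground truth makes every stage testable without any
download.

## The model in brief

- **Atlas.** Peaks from all samples are merged wherever they overlap by
  ≥ 1 bp (book-ended regions stay separate); each atlas region carries
  per-source membership flags.
- **Annotation.** Promoters are H3K4me3⁺ regions overlapping a window
  from −5 kb to +2 kb of a TSS (gene orientation); enhancers are
  H3K4me1⁺ regions ≥ 2 kb from every TSS that overlap no promoter.
  Accessibility peaks use a strand-independent ±2 kb TSS window instead.
- **Differential activity.** Replicates are pooled per condition,
  scaled to the lowest total library size, and each region is tested
  with an exact two-sided Poisson p-value under the equal-split null
  λ = (n_a + n_b)/2, plus an optional exact conditional-binomial
  "proportion of library" filter on raw counts,
  k_a ~ Bin(k_a + k_b, N_a/(N_a+N_b)). Benjamini–Hochberg FDR over all
  regions; calls require |log2FC| above a threshold.
- **Concordance clusters.** Each enhancer's status in two
  conventional-memory comparisons is collapsed to a consensus and
  crossed with the innate-memory status, yielding six clusters:
  gains/losses specific to conventional memory (C1/C4), shared (C2/C5),
  or specific to innate memory (C3/C6).
- **Co-binding.** Fractions of EOMES-bound regions carrying RUNX3 peaks
  in either state or pre-bound in the naive state; PWM best-hit
  positional density (log2-odds, both strands, ±250 bp) around region
  centers.
- **Target inference.** Regulatory potential
  S_g = Σ exp(−(0.5 + 4Δ)) over peaks within 100 kb of a TSS
  (Δ = distance/window), with two-sample Kolmogorov–Smirnov comparison
  of up/down gene groups against a static background.
- **Single-cell correlation.** Kendall tau-b per group and a Fisher-Z
  comparison of two independent correlations using Fieller's variance
  0.437/(n − 4).

See `docs/methods.md` for conventions, calibration properties and
limitations.

## Worked example

Run the whole pipeline on a freshly simulated study:

```bash
epimem run-all --seed 1 --out results/demo
```

This simulates a landscape (300 promoters, 800 enhancers, three
memory-vs-naive count comparisons, motif sequences, expression and
single-cell tables), then annotates, tests, clusters and scores it.
Selected output (`results/demo/...`):

`concordance/composition.tsv` — recovered cluster composition versus
the planted 55/34/11 and 57/36/7 splits:

```
side         cluster  count  percent
more_active  C1       81     55.10
more_active  C2       49     33.33
more_active  C3       17     11.56
less_active  C4       84     57.93
less_active  C5       51     35.17
less_active  C6       10      6.90
```

`cobinding/cobinding.json` — fraction of EOMES-bound regions with RUNX3
in any state, and pre-bound in the naive state (planted: 0.65 / 0.43):

```json
{"frac_any": 0.647, "frac_naive_prebound": 0.432}
```

`sccorr/sccorr.json` — per-group Kendall tau (planted 0.6 vs 0.2) and
the Fisher-Z comparison:

```json
{"taus": {"control": {"tau": 0.616, "n": 1000},
          "deficient": {"tau": 0.214, "n": 1000}},
 "comparison": {"z": 16.95, "p": 2.1e-64}}
```

The run writes a `manifest.json` with per-stage timings and a checksum
for every output file; re-running with the same seed reproduces every
byte.

Library use mirrors the CLI:

```python
from epimem import intervals, diff

atlas = intervals.build_atlas([intervals.read_bed(p) for p in bed_paths])
m = diff.read_counts_tsv("counts.tsv", "samples.tsv")
results = diff.call_differential(m)          # region_id, log2fc, p, q, direction
```

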