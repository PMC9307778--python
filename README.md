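# semap

Super-enhancer multi-omic analysis for regulatory genomics. `semap`
implements, as one tested pipeline, the bespoke computational procedures
used to dissect super-enhancer-driven gene expression programs in
high-grade serous ovarian cancer:

- **Super-enhancer calling** from BRD4/H3K27ac ChIP-seq peaks: active
  enhancers are BRD4 peaks with ≥ 1 bp H3K27ac co-occupancy, minus
  anything overlapping annotated genes or promoters; surviving peaks are
  stitched at ≤ 12.5 kb (the ROSE default) and super-enhancers are the
  stitched regions above the geometric inflection of the signal-vs-rank
  curve (scaled derivative > 1).
- **Copy-number windowing and amplification tests**: the autosomal genome
  is tiled into 15-kb windows (the embedded hg19 autosomes give ~192,000);
  each window gets, per patient, the overlap-length-weighted mean of its
  SEG-style copy-number segments. SE-overlapping windows are tested
  against 10,000 equally sized random window draws (one-sided Welch *t*
  plus Mann–Whitney *U* per draw) and against the whole genome directly.
- **CNVeQTL scan**: every (window, gene) pair is tested by OLS of
  expression on copy number, *t* = β̂₁/SE(β̂₁) with *n* − 2 df, threshold
  *p* < 10⁻³. The null is built by permuting the patient columns of the
  expression matrix and rescanning; the empirical FDR is
  median(null counts) / observed count.
- **Rank-change screen statistic** for a replicate-free CRISPRi screen:
  genes are ranked within each well (rank 1 = highest) and against a
  global rank; RC = within-well rank − global rank. Per well, targets are
  genes beyond the smallest rank-change threshold whose empirical FDR
  (median control exceedances / well exceedances) is ≤ 0.1.
- **Hi-C direct-target classification**: contact matrices are
  Knight–Ruiz balanced, expected contact is estimated per bin distance,
  and each SE–gene pair is summarized by observed/expected contact.
  Downregulated genes are *direct* targets when their O/E exceeds the
  75th percentile of a pooled control distribution from 100 permutations
  of distance-matched non-significant genes on the same chromosome.
- **Modified Activity-by-Contact score**: per SE–gene pair,
  z(log₂(BRD4 activity + 1)) × z(log₂(balanced 50-kb contact + 1)),
  restricted to expressed genes (baseMean > 100).

A first-class synthetic-data module generates every input with planted
ground truth (clustered peak tracks, piecewise-constant copy-number
cohorts with linked expression, negative-binomial screen counts,
power-law-decay contact matrices with planted loops), so the whole
pipeline is testable end to end without any download.

## Worked example

```python
from semap import cnv_windows, cnveqtl, enhancer_se, synthetic_data
from semap.core_io import GenomeTable, LabelledMatrix

genome = GenomeTable({"chr1": 10_000_000, "chr2": 8_000_000})
brd4, k27ac, genes, promoters, truth = synthetic_data.simulate_peaks(genome, seed=7)
ses, stitched, cutoff = enhancer_se.call_super_enhancers(brd4, k27ac, genes, promoters)
print(f"{len(stitched)} stitched regions, cutoff {cutoff:.1f}, {len(ses)} super-enhancers")

grid = cnv_windows.tile_genome(genome, width=15_000)
amp = [f"chr1:{i}" for i in range(10, 30)]
segments, expression, _ = synthetic_data.simulate_cohort(
    grid, n_patients=300, amp_windows=amp, linked_pairs=20, seed=7)
cn = cnv_windows.assign_copy_number(grid, segments)
welch_p, _ = cnv_windows.direct_comparison(cn, set(amp))

cn_se = LabelledMatrix(cn.df.loc[amp])
expr = cnveqtl.filter_expression(expression)
assoc = cnveqtl.scan(cn_se, expr)
null = cnveqtl.permutation_null(cn_se, expr, n_perm=100, seed=7)
print(f"{len(assoc)} CNVeQTL linkages; null median {null.median_count:.0f}; "
      f"eFDR {cnveqtl.empirical_fdr(len(assoc), null.median_count):.3f}")
```

prints

```
457 stitched regions, cutoff 5.8, 5 super-enhancers
25 CNVeQTL linkages; null median 4; eFDR 0.160
```

The five called super-enhancers are exactly the five planted peak
clusters; the direct amplification comparison on the planted cohort
reports its p-value at the 2.2e-16 floor. Of the 25 linkages, 20 are the
planted (window, gene) pairs; the eFDR of 0.16 reflects the handful of
chance discoveries expected at this small scale (2,000 tests at
*p* < 10⁻³).

A CLI mirrors the stages:

```sh
semap --out-dir fixtures --seed 3 simulate
semap --out-dir out call-se --brd4 fixtures/brd4.bed --k27ac fixtures/k27ac.bed \
      --genes fixtures/genes.bed --promoters fixtures/promoters.bed
```

with further subcommands `cnv-windows`, `cnv-test`, `cnveqtl`, `screen`,
`hic-targets` and `abc` (see `semap --help`).

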