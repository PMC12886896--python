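# germ-epimem

A tested, reusable pipeline linking **H3K4me3 chromatin changes to 22G-RNA
deregulation** in *C. elegans* chromatin-regulator mutants, exercised end to
end on synthetic data with recorded ground truth.

In worms, the TSS-proximal mark H3K4me3 and the 22G-RNA class of secondary
siRNAs (21–23 nt, 5′ guanosine, antisense to their target mRNAs) intersect in
germline epigenetic inheritance: mutants of certain SET-domain regulators gain
H3K4me3 at a subset of gene TSSs while the 22G-RNA populations targeting
overlapping gene sets are deregulated. This package implements the
computational chain needed to quantify that relationship from aligned reads:

* **Tracks** — binned (10 bp) fragment coverage per ChIP library, CPM
  normalization, replicate averaging, per-bin `log2((IP+c)/(input+c))`
  enrichment and the mutant−wild-type fold-change track (bedGraph in/out).
* **TSS scoring and classification** — strand-aware metagene matrices around
  TSSs; per-gene mean enrichment in TSS ±500 bp; genes ranked by the
  mutant−wild-type score delta Δg, and the shortest prefix with
  ∑Δ(g) ≥ 0.8 · ∑(Δ>0) classified as *H3K4me3-enriched genes*; a Welch
  two-sided t-test compares mutant vs wild-type scores.
* **Sliding-window differential binding** — 200 bp windows at 10 bp shift
  genome-wide, fragment-overlap counts, NB testing per window.
* **22G-RNA quantification** — read-class filter (21–23 nt, first base G),
  exact end-to-end mapping with seeded random placement of multimappers
  (≤100 loci), unstranded per-gene counting over exons with ambiguous
  alignments dropped.
* **Differential statistics** — median-of-ratios size factors, moderated
  method-of-moments NB dispersion, a delta-method Wald test on normalized
  group means with a Welch–Satterthwaite t reference, Benjamini–Hochberg
  FDR, and threshold calling (22G: fold change > 2 at 5% FDR; mRNA:
  padj < 0.01).
* **Integration** — crosstabs of the enriched gene set against 22G/mRNA call
  sets and user-supplied reference lists (e.g. WAGO or Mutator pathway
  targets), with exact set arithmetic and an optional hypergeometric
  overlap p-value.
* **Synthetic data** — generators for toy genomes, annotations, TSS-peaked
  IP/input ChIP libraries, 22G-dominated FASTQ and NB count matrices, every
  planted effect recorded for parameter-recovery testing.

## Worked example

The one-command demo generates a 2×0.5 Mb genome with 300 genes, plants a 3×
H3K4me3 gain at 30 genes (2 IP + 2 input ChIP replicates per genotype) and
±2 log2 fold-change 22G effects at 15+15 genes (4 small-RNA replicates per
genotype, 50 k reads each), then runs every stage:

```sh
germ-epimem make-demo --out demo --seed 1
germ-epimem run --config demo/config.yaml
```

The same study can be stepped through as a narrative via the numbered
scripts in `analysis/` (each writes its tables under `results/`):

```sh
python analysis/01_simulate.py
python analysis/02_chip_tracks.py
python analysis/03_enriched_genes.py   # prints:
# 300 genes scored; 26 classified H3K4me3-enriched
# mean delta, planted genes : +1.018
# mean delta, other genes   : -0.130
# Jaccard vs planted truth  : 0.867
python analysis/04_window_diff.py
python analysis/05_smallrna.py         # prints:
# calls: 15 up, 15 down (FC > 2, 5% FDR)
# sensitivity up  : 1.00
# sensitivity down: 1.00
# false calls     : 0
python analysis/06_integrate.py        # prints:
# n_enriched                     26
# n_enriched_with_22g_change     17
# n_22g_up                       8
# n_22g_down                     9
# enriched vs 22G-down overlap: 9 genes, hypergeometric p = 2.35e-07
```

Reading the numbers: 26 of the 30 planted genes carry enough of the total
increased TSS enrichment to be classified (the cumulative-80% rule stops
before the weakest planted genes, Jaccard 0.87 against truth); all planted
22G effects are recovered with no false calls; and the crosstab shows the
planted coupling — 17 of the 26 enriched genes have deregulated 22G-RNAs,
far more than chance (hypergeometric p ≈ 2×10⁻⁷).

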