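# Methods

This note documents the models, parameter choices and numerical decisions
behind the pipeline, and what the synthetic test bed does and does not
establish about real data.

## Coordinate and track conventions

All internal coordinates are 0-based half-open intervals on the forward
strand; GFF3 (1-based closed) is converted at the I/O boundary and nowhere
else. Chromosome names are taken verbatim — a mismatch between FASTA and
annotation names is a hard error listing the difference, never silently
aliased. The gene-level TSS is the 5′ end of the gene feature (`start` on
+, `end − 1` on −); transcript-level TSS selection is out of scope, so
genes, not transcripts, are the scoring unit throughout.

Tracks are fixed-bin vectors (default 10 bp) tiling each chromosome; the
last bin may be shorter and is treated as a plain count over its truncated
span. A ChIP read is reduced to its 5′ position and extended in its strand
direction to the fragment length (default 200 bp, clipped at chromosome
edges); a fragment increments **every bin it overlaps** (occupancy
counting, not per-base averaging — the downstream window score averages
over bins anyway, and the two conventions differ only by a bounded local
factor). bedGraph output merges runs of equal-valued bins and serializes
values with `repr`, so a write→read round trip is bit-exact.

## Enrichment and the cumulative-80% classifier

Each library is CPM-normalized individually, replicates are averaged, and
enrichment is `log2((IP + c) / (input + c))` with pseudocount c = 1 CPM.
The pseudocount bounds the ratio and pins zero-coverage bins at 0; its
scale (1 CPM ≈ one read at typical depth) makes it negligible wherever
there is signal. The mutant−wild-type track is a plain difference of log2
enrichments. Per-gene scores are the arithmetic mean of enrichment over
the bins intersecting TSS ±500 bp, computed on the log2 scale; windows
truncated by a chromosome end are scored on the surviving bins rather than
dropped.

*H3K4me3-enriched genes* are classified by increased enrichment: genes
with positive score delta Δ = score_mut − score_wt are ranked by Δ
descending (ties broken by gene id so the rule is deterministic), and the
shortest prefix whose cumulative Δ reaches 80% of the **sum of positive
deltas** is selected. Using only positive deltas in the denominator
("total increased enrichment") keeps the rule monotone in the fraction and
makes the empty set the correct output when nothing increases. An optional
wild-type-signal floor can restrict candidates to genes already marked in
wild-type; it is off by default. The mutant-vs-wild-type score comparison
uses Welch's unequal-variance two-sided t-test throughout (one t-test
variant everywhere rather than mixing pooled and unpooled forms).

## Count-based differential testing

One NB toolkit serves windows, 22G genes and mRNA genes. It is
deliberately small — no GLM, no shrinkage of fold-changes — and its
validity is established by calibration simulations rather than numerical
agreement with any larger framework:

* **Size factors** — median-of-ratios: per feature the geometric mean
  across samples, per sample the median of count/geomean over features
  with positive geometric means. Note the factors are equivariant only up
  to a global rescaling (scaling one sample by c scales every geometric
  mean by c^(1/n)); factor *ratios* gain exactly c.
* **Dispersion** — method-of-moments α = (s² − m)/m² on normalized counts,
  computed **within** condition groups (weights n_g − 1) so a real group
  difference is not read as overdispersion, then moderated toward the
  across-feature median with 6 prior degrees of freedom and floored at
  10⁻⁸. With 3–4 replicates the raw estimator is far too noisy to plug
  into a Wald statistic; the mild moderation (which preserves the
  across-feature median, so Poisson data still estimates ≈0) is what makes
  the test calibrated at realistic replicate numbers.
* **Wald test** — log2fc compares normalized group means with pseudocount
  0.5 (finite fold-changes when a group is all zero); the standard error
  comes from the delta method on Var = μ + αμ² summed per group. The
  statistic is referred to a Student t with a per-feature
  Welch–Satterthwaite effective df: the Poisson part of the variance is
  treated as known given the mean, and only the αμ² part carries
  estimation df ((N − 2) + prior). The effective df is therefore large for
  Poisson-like counts (the statistic is nearly normal) and approaches the
  dispersion df when overdispersion dominates. Simulations at 4 vs 4 show
  a plain normal reference is anti-conservative (null p<0.05 fraction
  ≈ 0.10, realized FDR ≈ 0.24) while the effective-df t reference sits at
  ≈ 0.05 null and ≈ 0.04 realized FDR with sensitivity ≈ 0.99 at planted
  |log2fc| = 2 — these numbers are recomputed by the test suite and
  `scripts/acceptance.py`, not quoted from anywhere.
* **Multiple testing** — Benjamini–Hochberg step-up (statsmodels) with a
  brute-force step-up implementation kept as an independent oracle in the
  tests. Calls: 22G genes at fold change > 2 and 5% FDR on the raw (not
  shrunken) log2fc; mRNA at padj < 0.01 with no fold-change floor.
  Independent filtering is not implemented; all features are tested.

Sliding windows (200 bp, 10 bp shift, only fully contained windows) count
a fragment in every window it overlaps with no cross-window
deduplication. Neighbouring windows share fragments, so window tests are
correlated: FDR over windows is reported, but only raw-p calibration is
asserted as a property.

## 22G-RNA operationalization

The 22G class is purely a read filter: length 21–23 nt and first base G
(N fails; length is checked before the 5′ base, so a 24 nt G-read rejects
as too-long). Mapping requires a perfect end-to-end match against either
strand, found with a seed-and-verify hash index of genomic 21-mers; reads
with 1–100 hits report exactly one locus chosen uniformly by a generator
seeded from (seed, read id) — reproducible per read, mirroring
random-multimapper single-reporting aligner behaviour — and reads with
more hits are discarded. Counting is **unstranded** over exons (matching
the cited counting convention's default even though 22Gs are biologically
antisense), and alignments touching exons of more than one gene are
dropped as ambiguous.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of their parameters including the seed
(independent streams are derived by folding stage/genotype/role/replicate
into a SeedSequence), and every planted effect is recorded — no silent
randomization.

ChIP IP libraries mix a uniform Poisson background (0.1 expected reads/bp)
with per-gene peak reads placed Normal(TSS, 150 bp) — TSS-peaked metagenes
with no further shape structure, the simplest unimodal stand-in — at 300
expected reads per gene, ×3 for planted genes in the mutant; input
libraries are uniform at 200 k reads. Reads falling off-chromosome are
clipped rather than redrawn so library sizes stay exact. Small-RNA
libraries draw genes proportional to lognormal(0, 0.5) abundances
(multiplied by 2^±2 for planted genes in the mutant), emit antisense
21–23-mers whose 5′ G is natural where the template allows (otherwise
overwritten and flagged in the read id), and make the remaining 20% of
reads violate the class rule by construction, so filter bookkeeping is
exact by design. The demo scenario (2×0.5 Mb, 300 genes, 30 planted
enriched, 2 ChIP + 4 small-RNA replicates per genotype, 50 k small-RNA
reads per library) was sized to run the full pipeline in well under a
minute on one CPU while leaving clear signal-to-noise margins.

Not emulated: sequencing errors, adapters, quality scores, PCR
duplicates, mappability structure, nucleosome positioning, biological
replicate variability beyond counting noise, isoform structure, and
chromatin marks other than the one modelled. Passing the recovery tests
therefore shows the *pipeline logic* is correct and calibrated under its
stated model, not that the thresholds are optimal for any real library.

## Degenerate inputs and tie-breaks

Empty read sets give all-zero tracks; a score table with no positive
deltas selects the empty set (not an error); equal-and-constant score
columns return t = 0, p = 1, and unequal constant columns return the
smallest representable p with a degenerate-variance flag; selection ties
break by gene id; BH monotonicity is enforced by the step-up cummin. The
pipeline writes result tables at 6 significant digits — a presentation
choice for hash-stable manifests; bedGraph tracks keep exact floats so
track round trips are lossless.

## Known limitations

* The NB test assumes exactly two groups with ≥2 replicates each and no
  covariates.
* The exact-match mapper is built for toy genomes (hash of every 21-mer);
  real-genome mapping and mismatch tolerance are out of scope.
* Window-level FDR is reported but not calibrated under the window
  correlation structure.
* The hypergeometric overlap p-value assumes a well-defined gene universe
  (all annotated genes in the run) and exchangeability within it; it is an
  explicit extension beyond plain Venn counting and is reported, not used
  for calling.
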