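# Methods

## The analysis

`trchip` identifies candidate thyroid-hormone-receptor (TR) target genes
from ChIP-Seq peak calls of premetamorphic *Xenopus* intestine, across two
genotypes (wild type; TRα⁻/⁻, where only TRβ remains) and two treatments
(−T3 / +T3), with three technical replicates per sample. The pipeline
chains five operations:

1. **Replicate-consensus peaks.** Technical replicates vary, and peaks
   present in every replicate are far more likely to be real binding
   events. "Present at the same location in all replicates" is formalized
   per base: a consensus peak is a maximal genomic run in which every
   replicate has at least one called peak covering each base. The
   consensus interval is therefore the mutually covered region — symmetric
   in the replicates, not anchored to any one replicate's coordinates —
   and its height is the minimum over replicates of the best contributing
   peak height (a deliberately conservative support measure). The
   definition makes the operation directly checkable against a brute-force
   per-base counting oracle, which the test suite does on random
   instances. A consequence worth knowing: independent false-positive
   peaks must co-occur in all R replicates to survive, so the intersection
   suppresses noise at roughly the R-th power of the per-replicate
   false-call density, while a site lost from even one replicate is lost
   from the consensus (detection probability (1 − dropout)^R).

2. **Peak-to-gene assignment.** A consensus peak is assigned to a gene
   when it overlaps, by at least one base, the gene body (introns
   included) extended by 5 kb on both sides. The extension is symmetric
   and strand-independent, and a peak overlapping several gene windows is
   assigned to all of them — the definition is gene-centric ("is this gene
   bound?"), so no nearest-gene tie-break is wanted. A gene is *TR-bound*
   in a sample iff at least one consensus peak hits its window. Peaks
   hitting no window are reported as not-annotated; most true binding in
   this system is intergenic, and assigning it would require chromatin-
   interaction data that is out of scope here.

3. **DR4 scanning.** The canonical TR-RXR element is a direct repeat of
   two (A/G)GGTCA half-sites separated by 4 unconstrained bases (DR4). The
   scanner matches the IUPAC half-site `RGGTCA` twice at the configured
   spacing, on both strands, with an optional per-half-site mismatch
   budget spent only at non-degenerate pattern positions (a degenerate
   position must match outright; genomic `N` never satisfies a fixed
   base). Only direct repeats are scanned — everted/inverted repeats and
   PWM scoring are out of scope. Overlapping hits are all reported, since
   no collapsing rule is defined for this element class.

4. **Set analytics.** T3-regulated gene sets are selected from a
   per-gene expression table at 1.5-fold regulation and FDR < 0.05. The
   fold cutoff is applied on the log2 scale and is *inclusive*
   (|log2FC| ≥ log2 1.5); the FDR cutoff is *strict* (< 0.05). Overlap
   percentages are reported as integers rounded half away from zero.
   Venn decompositions (2 or 3 sets) are exact set algebra; the
   genotype comparison partitions bound genes into
   {WT-only, common, KO-only}, and the fold-change matrix orders each
   block by descending WT log2 fold change with unmeasured genes last
   (the ordering is this package's convention).

5. **Enrichment.** Term enrichment uses the one-sided hypergeometric
   test (Fisher exact upper tail) with Benjamini–Hochberg adjustment,
   over user-supplied GMT gene–term files. The background is the set of
   annotation genes that appear in the GMT universe; terms empty after
   background restriction are dropped (their p-value would be
   undefined). The genotype-differential ("subtraction") analysis keeps
   terms enriched in the WT-bound set and not in the KO-bound set,
   matching terms by identifier and retaining the WT statistics and
   ranking.

A simplified **pileup caller** is included for end-to-end realism on
simulated fragments: per-base coverage is tested against a Poisson
background with mean = background rate × mean fragment length, p-values
are BH-adjusted over all genome bases, and significant bases are merged
(gaps ≤ 50 bp closed) into peaks of at least 50 bp, with the summit at the
leftmost maximal-coverage base. It makes no attempt at local-background
(lambda) modelling, fragment-size estimation or paired-end handling, and
is not a substitute for a production peak caller on real reads.

## Coordinate conventions

All intervals are 0-based half-open internally (BED convention); GFF3
(1-based inclusive) is converted at the I/O boundary via
`start − 1, end`. Book-ended intervals `[a,b)` and `[b,c)` merge at gap 0,
consistent with per-base semantics. Chromosome names are matched exactly
(no `chr` aliasing).

## The synthetic study generator

`simulate()` emulates the study design so the pipeline can be scored
against known truth:

- **Genome and genes.** An i.i.d. uniform ACGT genome (default 2 × 1.2 Mb)
  with non-overlapping genes spaced at least `2·flank + 500` bp apart, so
  neighbouring assignment windows never overlap and each genic site maps
  to exactly one gene. Defaults: 120 genes of 2–6 kb.
- **Binding sites.** 150 sites of 150–400 bp (peak widths in this system
  are mostly under 500 bp); 60 % are placed inside gene bodies (at most
  one per gene, which keeps gene-level retention estimates unbiased) and
  40 % are intergenic, > 5 kb from every gene. Each site carries one DR4
  element (`RGGTCA`-N4-`RGGTCA`, random half-site choices, spacer and
  strand) planted at its centre.
- **Condition structure.** A fraction `t3_gain = 0.25` of sites is
  T3-dependent (detectable only under +T3); the rest are constitutive —
  mirroring a study design in which most binding is constitutive and the
  +T3 set is larger. Each site is retained in the knockout with
  probability `ko_retention = 0.7`, independent of treatment.
- **Peak-call noise.** Per replicate: boundary jitter (Gaussian, default
  sd 25 bp, width floored at 50 bp), Bernoulli dropouts (default 5 % per
  site per replicate), and Poisson false peaks (default 10 % of the
  detectable-site count) at uniform positions; per-replicate log-normal
  height noise around a per-site base height.
- **Expression linkage.** A gene bound in the WT truth is T3-upregulated
  with probability `p_up_given_bound = 0.19` (downregulated with 0.09);
  effect sizes are N(1.5, 0.5) on the log2 scale, truncated just above
  the 1.5-fold cutoff so a regulated gene always passes selection, with
  FDR ~ U(0, 0.04). Knockout fold changes are attenuated by 0.5 for
  KO-bound genes; everything else is null (log2FC ~ N(0, 0.1),
  FDR ~ U(0, 1)), which cannot pass the 1.5-fold cutoff.
- **Determinism.** All randomness flows from the single config seed
  through one generator in a fixed consumption order; identical configs
  give byte-identical output trees.

What the generator deliberately does **not** model: read-level noise
(sequencing errors, duplicates, mappability), input/control tracks,
correlated replicate failures, overlapping genes and windows, binding
without a DR4 element, and indirect (TR-free) T3 regulation. Passing
recovery tests therefore demonstrates that the pipeline's interval
algebra, set logic and statistics are correct under the stated noise
model — not that the end-to-end error rates transfer to real ChIP-Seq
data, where peak calling itself and window-overlap ambiguity dominate.

## Calibration checks and estimator choices

- **Noisy recovery** (jitter 25 bp, 5 % dropout, 10 % false peaks) is
  scored pooled over 10 seeded runs of 300 sites. The expected site
  recall is (1 − 0.05)³ ≈ 0.857 — dropout is the only recall loss at
  these settings — and measured precision is ≈ 1 because false peaks
  essentially never co-occur in three replicates.
- **Knockout retention** is estimated as the fraction of truth WT-bound
  genes also called bound in the knockout. Per-replicate dropout deflates
  this estimator by (1 − dropout)^R for reasons unrelated to the knockout
  effect, so the calibration check runs with dropout 0 (jitter and false
  peaks kept), 400 sites, averaged over 3 seeds.
- **Expression linkage** — the percentage of called WT-bound genes that
  are T3-upregulated — is unbiased under detection noise (regulation is
  assigned independently of which sites drop out), so it runs at the full
  noisy defaults, scaled up to 2000 genes/2000 sites over 2 seeds to
  shrink the binomial error below the ±3-point check width.
- **Null calibration** of enrichment uses 100 replicates of a 300-gene
  query drawn uniformly from a 2000-gene background against 200 random
  terms; under the global null BH behaves as a family-wise control, so
  the mean flagged fraction sits far below the nominal 0.05.

Problem sizes throughout (genome in the low-megabase range, hundreds of
sites, thousands of genes for the linkage check) were chosen so every
check has enough statistical resolution for its stated tolerance while a
full run of the suite and the acceptance script completes in well under a
minute each on one core.

## Numerical and degenerate-input choices

- Consensus height ties and support lists are ordered by replicate id;
  consensus peaks are named `"{sample}_cons_{i}"` in coordinate order.
- `peak_width_summary` uses strict `< 500 bp` for the reported fraction.
- Pileup BH adjustment is computed on unique coverage values (bases with
  equal coverage share a p-value), which is exact and keeps the
  genome-wide adjustment cheap; `q_cutoff` is strict, so a cutoff of 0
  returns nothing.
- `hypergeom_p(k=0, ...) = 1` exactly; enrichment of an empty-overlap
  term is never flagged.
- Empty peak lists: `merge_intervals([]) = []`; `peak_width_summary`
  raises (a histogram of nothing is a user error);
  `intersect_replicates({})` raises, but an empty *replicate* absorbs to
  an empty consensus.
- Rounding of percentages is half away from zero (19.457 → 19,
  94.05 → 94, 0.5 → 1).

## Known limitations

- The per-base consensus definition requires full mutual coverage; a
  replicate whose peak narrowly misses a region vetoes it. No
  summit-proximity or IDR-style reproducibility alternative is provided.
- The enrichment background must be supplied (annotation ∩ GMT universe
  by default); results are sensitive to that choice, as with any
  hypergeometric enrichment.
- The DR4 scanner is a consensus-pattern matcher, not a PWM; mismatch
  tolerance is uniform across fixed positions.
- `pileup_call` assumes a single global background rate.
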