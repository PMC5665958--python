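# Methods

This note documents the models, conventions and numerical choices behind
`linctools`, and what the synthetic data can and cannot show.

## Coordinates and data model

All coordinates are 0-based half-open internally. GTF (1-based closed)
and Bismark-style cytosine reports (1-based positions) convert at the
I/O boundary; bedGraph and BED are already half-open. The TSS of a
transcript is the 0-based position of its first transcribed base:
`span.start` on the plus strand, `span.end − 1` on the minus strand.
`gap_distance` counts the bases strictly between two intervals, so the
"at least 500 bp away" intergenic rule reads `gap ≥ 500`; overlap is a
distinct outcome, not distance 0. Outputs are ordered by
(chromosome, start, identifier) and floats are written at six
significant digits, so reruns diff cleanly.

## Filter cascade

Thresholds follow the published wording literally: "at least" is
inclusive (exon coverage ≥ 0.80, per-junction reads ≥ 3, intergenic gap
≥ 500 bp), "more than 200 nucleotides" and "CPC score of less than −1"
are strict. Junction support is enforced per intron — every junction
needs ≥ 3 reads — which is the stricter reading of read support for "the
predicted splice structure". The intergenic test is strand-agnostic and
is applied against coding and housekeeping loci only; other lincRNAs do
not disqualify a candidate. Annotation-derived candidates (the curated
RefSeq/UniGene-style path) carry no exon-coverage or junction evidence;
those two filters return "not-evaluated" for them and do not block.
Filters are independent predicates, so the surviving set is identical
whether or not evaluation short-circuits at the first failure; the
default run short-circuits and records later verdicts as not-evaluated.

Survivor clustering is a deliberate simplification of assembler merging
(Cuffmerge-style): single-linkage over ≥ 1 bp of *exonic* overlap on the
same strand, so transcripts that overlap only across introns stay in
separate loci. Locus identifiers are assigned by leftmost coordinate.

Interval statistics measure span-to-span gaps (lincRNA to nearest coding
locus; coding locus to nearest other coding locus) and compare samples
with the two-sided Mann-Whitney test — exact when the combined sample is
≤ 20 and tie-free, otherwise the tie-corrected normal approximation.

## Tissue specificity

Expression densities use no pseudocount; `0·log 0 = 0`. Entropy is base
2, which makes the Jensen-Shannon divergence — and therefore the score
`1 − sqrt(JSD)` — live exactly in [0, 1], with 1 attained only by a
single-tissue density and 0 by expression concentrated entirely in a
different tissue. Replicate columns labelled `tissue:repN` are averaged
(mean FPKM) before scoring. Genes with zero total FPKM have no density
and are reported as not-evaluable rather than scored 0. Argmax ties
break to the lowest tissue index.

## Metaprofiles

Window geometry: flank 5000 bp each side, 100 bins of 100 bp, bin 1
covering transcription-direction offsets −5000…−4901. The TSS base is
the first base of bin 51. Minus-strand windows are reversed so bin 1 is
always upstream — the standard metagene convention; the unflipped mode
is available by treating transcripts as plus-strand. Profiles are
averaged per transcript (each transcript's TSS counts once); a per-gene
mode keeps one canonical (longest) transcript per locus.

Methylation bins apply the `m = 0 ⇒ M = 0` convention, which also covers
bins containing no cytosine call; an alternative mode
(`per_covered=True`) averages each bin over covered transcripts only.
Binding intensity is mean per-base depth; positions absent from the
coverage track, including positions beyond chromosome ends, contribute
depth 0. GC and CpG observed/expected windows use step = width = 100 bp
(non-overlapping; the step is configurable). N bases are excluded from
both numerator and denominator; an all-N window contributes nothing to
its bin's mean, and CpG o/e is defined 0 when a window has no C or no G.

## Naive DMR caller

The caller is a labelled stand-in for dispersion-shrinkage methods such
as DSS, suitable for synthetic data and smoke tests: replicate counts
are pooled per CpG within group, each CpG shared by both groups gets a
two-sided two-proportion z-test (pooled variance; p = 1 where the pooled
proportion is 0 or 1), and significant CpGs (p < 0.01 by default) with a
consistent direction merge into regions when consecutive ones are
≤ 100 bp apart. Regions are kept at length ≥ 50 bp with ≥ 3 CpGs —
the documented defaults of DSS's `callDMR`. The region score is the sum
of −log10 p over member CpGs. Externally called DMRs can be supplied as
a BED-like table to the overlap step, which reports every (gene, DMR)
pair with ≥ 1 bp overlap, ignoring strand.

## Synthetic data

The generator emulates the statistical structure of the real studies the
pipeline targets: bulk multi-tissue expression, whole-genome bisulfite
data from two strain groups, and TF-binding coverage. Defaults are two
5 Mb chromosomes carrying 300 coding, 20 housekeeping and 150 lincRNA
genes plus 100 decoy candidates (20 each: single-exon, ≤ 200 nt,
within 500 bp of a gene, coding-potential-positive, housekeeping-like),
11 tissues × 2 replicates of FPKM, CpG sites every ~50 bp observed at
~30× Poisson depth with 2 replicates per group, and a 50 bp-step binding
track. Everything derives from one seeded generator, so a configuration
reproduces byte-identical bundles.

Planted structure and the reasoning behind the key defaults:

* **Lengths and intervals.** LincRNAs get 2–4 exons and shorter exonic
  lengths than coding genes (4–10 exons); intergenic gaps are lognormal
  (median ≈ 4.5 kb) with a hard 600 bp floor, and gaps on *both* flanks
  of a lincRNA are scaled ×2.5, making mRNA–lincRNA intervals
  stochastically larger than mRNA–mRNA intervals by about the ratio seen
  in real catalogues. The gap median is sized so the default gene load
  fits the 2 × 5 Mb genome with margin; overcrowding raises an error
  before any file is written.
* **Expression.** Baseline FPKM is lognormal with lincRNA median ~2 vs
  coding ~15. A fraction of genes (40 % of lincRNAs, 15 % of coding) is
  tissue-specific: one tissue's baseline is multiplied by the dominance
  fold (50). The across-tissue baseline spread (σ = 0.5 on the log
  scale) was calibrated by Monte-Carlo so that fold-50 planted genes are
  recovered at JS > 0.5 in ≥ 95 % of cases while fold-1 data yields
  essentially none — the generator's stated operating point. Specific
  lincRNAs land in testes with probability 0.489, echoing the testes
  bias of mammalian lincRNA surveys.
* **Methylation.** Per-CpG background level is Beta(15, 5) (mean 0.75).
  Every TSS subtracts a triangular dip — depth 0.55 for
  coding/housekeeping, 0.35 for lincRNA, half-width 1.5 kb — so both
  biotypes show a V at the TSS with lincRNAs higher, and coding gene
  bodies additionally subtract a flat 0.15 so gene-body methylation is
  higher in lincRNAs, matching the ordering in real bisulfite data.
  Triangular (not Gaussian) shapes were chosen because bin expectations
  are then exactly piecewise-linear and testable analytically. Observed
  counts are binomial at Poisson(30)+1 depth.
* **Binding.** Background depth 2 plus a triangular TSS peak (height 8,
  half-width 1 kb) and Gaussian step noise, written as a 50 bp
  step-constant bedGraph.
* **DMRs.** Three regions of 400 bp are planted inside lincRNA spans;
  group 2 shifts their level by 0.4, in the direction away from the
  nearer clipping boundary so the effect size is never truncated.

What the generator does **not** emulate: read-level artefacts (mapping
bias, bisulfite conversion failure, duplicate reads), correlated
methylation between neighbouring CpGs, isoform diversity within loci
(one transcript per simulated gene), expression correlation between
neighbouring genes, and realistic chromosome-scale composition (CpG
islands exist only as periodic CG insertions around TSSs). Passing the
end-to-end tests therefore demonstrates that the *operations* are
correct on data with known truth, not that the thresholds are optimal
for any particular real dataset.

## Problem sizes

Tests run the default configuration (450 genes, ~200k CpG sites) for
end-to-end recovery, and a scaled-up configuration (500 coding + 500
lincRNA genes over six chromosomes) for the distribution comparisons, so
that rank-sum and KS tests operate at ≥ 500 values per group. Oracle
equivalence checks use ≤ 100-element instances against naive per-base or
all-pairs reimplementations at 1e−12 absolute tolerance.

## Known limitations

The naive DMR caller has no dispersion model, so its type-I behaviour on
overdispersed real replicates would be anticonservative; use a dedicated
caller for real data and feed its output to the overlap step. Locus
clustering does not reconstruct assembler transfrag graphs. The
housekeeping filter trusts the supplied BLAST table; it does not run
alignments. FPKM replicate collapsing assumes replicates are labelled
`tissue:repN` in column names.
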