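# linctools

Long intergenic noncoding RNAs (lincRNAs) are spliced transcripts longer
than 200 nt that do not encode protein and lie away from protein-coding
genes. `linctools` is a desk-scale pipeline for discovering lincRNAs from
assembled-transcript evidence and characterising their expression and
epigenome, written for genomicists who want each analysis step available
as a tested, scriptable Python function (with a thin CLI on top). It was
built around the analysis design used in rat lincRNA surveys, but nothing
in it is species-specific.

The package covers four analyses plus a ground-truth simulator:

1. **LincRNA filter cascade.** A candidate transcript is kept iff it has
   ≥ 2 exons, exonic length > 200 nt, RNA-seq exon coverage ≥ 80 %, every
   splice junction supported by ≥ 3 reads, lies ≥ 500 bp from any
   protein-coding or housekeeping gene, has a coding-potential (CPC)
   score < −1, and no BLASTN hit to housekeeping RNAs at
   e-value ≤ 1e−10 and identity ≥ 80 %. Survivors are clustered into
   loci by single-linkage exonic overlap, and every transcript gets an
   audit record.

2. **Jensen–Shannon tissue specificity.** For a gene's FPKM vector across
   *T* tissues normalised to a density *p*, the specificity for tissue
   *t* is `1 − sqrt(JSD(p, e_t))` with base-2 entropy, where `e_t` is the
   single-tissue density. The gene's JS score is the maximum over
   tissues; JS > 0.5 calls the gene tissue-specific, and a gene expressed
   in exactly one tissue scores exactly 1.

3. **TSS-centred metaprofiles.** The 10 kb window around each TSS is cut
   into 100 bins of 100 bp, oriented 5′→3′. Per transcript *t* and bin
   *i*, methylation is `M_ti = m_ti/(m_ti + u_ti)` (0 when `m_ti` = 0)
   and binding intensity `I_ti` is the mean per-base read depth; profiles
   average over the *n* transcripts (`V_i = Σ_t M_ti / n`,
   `B_i = Σ_t I_ti / n`). GC content and CpG observed/expected ratio
   (`#CpG · L / (#C · #G)`) are computed in the same windows. Gene-level
   methylation uses `M = m/(m+u)` over the gene span, with M = 0 when
   m = 0.

4. **DMR overlap.** Differentially methylated regions (from any caller,
   or the built-in naive two-proportion caller) are intersected with gene
   loci; every pair with ≥ 1 bp of overlap is reported.

The seeded simulator generates a complete miniature dataset — genome
FASTA, annotation and candidate GTFs, evidence tables, an FPKM matrix,
cytosine reports for two strain groups, a binding bedGraph and planted
DMRs — with truth tables, so every stage can be validated against known
ground truth.

## Worked example

```python
from linctools.simulate import SimulationConfig, simulate_dataset
from linctools.filtering import run_filter_cascade, stage_counts, interval_statistics
from linctools.specificity import score_genes
from linctools.profiles import tss_methylation_profile, transcripts_of

ds = simulate_dataset(SimulationConfig(seed=7))
loci, audits = run_filter_cascade(ds.candidates, ds.evidence, ds.annotation)
print(stage_counts(audits).to_string(index=False))
```

```
           stage  surviving
           input        250
    multi_exonic        230
          length        210
   exon_coverage        210
junction_support        210
      intergenic        190
coding_potential        170
    housekeeping        150
```

The funnel starts from 250 candidates (150 true lincRNAs plus five
20-strong decoy classes, each violating exactly one filter) and ends with
exactly the 150 planted lincRNAs. Continuing with interval statistics,
specificity and the TSS methylation profile:

```python
coding = [g for g in ds.annotation if g.biotype == "coding"]
st = interval_statistics(loci, coding)
print(f"median mRNA-lincRNA gap: {st['median_lincrna_gap']:.0f} nt")
print(f"median mRNA-mRNA gap:    {st['median_coding_gap']:.0f} nt")
res = score_genes(ds.expression.collapse_replicates())
print(f"tissue-specific genes (JS > 0.5): {sum(r.is_specific for r in res)} of {len(res)}")
prof_l = tss_methylation_profile(transcripts_of(loci), ds.methylation["group1"][0])
prof_c = tss_methylation_profile(transcripts_of(coding), ds.methylation["group1"][0])
print(f"TSS-bin methylation, lincRNA: {prof_l.values[50]:.3f}  coding: {prof_c.values[50]:.3f}")
```

```
median mRNA-lincRNA gap: 11814 nt
median mRNA-mRNA gap:    4608 nt
tissue-specific genes (JS > 0.5): 108 of 450
TSS-bin methylation, lincRNA: 0.403  coding: 0.088
```

LincRNA loci sit in larger intergenic intervals than coding genes
(rank-sum p = 4.4e−28 here), a larger share of them is tissue-specific,
and both biotypes show a V-shaped methylation dip at the TSS with the
lincRNA dip shallower — the orderings the simulator plants and the real
data show.

The same stages are available from the shell:

```bash
linctools simulate --seed 7 --out-dir demo/
linctools classify --candidates demo/candidates.gtf --annotation demo/annotation.gtf \
    --evidence demo/evidence.tsv --hk-hits demo/housekeeping_hits.tsv \
    --out-gtf demo/lincrnas.gtf --out-audit demo/audit.tsv
linctools specificity --expression demo/expression.tsv --out demo/js_scores.tsv
```

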