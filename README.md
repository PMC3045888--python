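# estmine

EST transcriptome mining: assembly-level analysis of expressed sequence tag
(EST) collections the way classic Sanger-era cDNA projects analysed them —
read trimming, overlap clustering into contigs, CDS/GC3 profiling,
haplotype-filtered SNP discovery with KA/KS classification, digital
differential expression from per-library EST counts, and annotation-term
enrichment — plus a synthetic EST-library generator with planted ground
truth that makes every stage testable.

It is written for researchers who work with EST or other low-depth count
transcriptome data (or who need a transparent, seedable testbed for such
pipelines): every stage is a plain library function with a thin `estmine`
command-line wrapper, standard formats in and out.

## The statistics at the core

**Digital differential expression.** Expression is inferred from EST counts
per cDNA library. Two tests identify differentially expressed contigs:

- the *Audic–Claverie* exact test — the probability of observing count *y*
  in a library of *n₂* ESTs given count *x* in a library of *n₁*:

      p(y|x) = (n₂/n₁)^y (x+y)! / ( x! y! (1 + n₂/n₁)^(x+y+1) )

  with two-sided p = min(1, 2·min(lower tail, upper tail)), evaluated in
  log space and exact to the summation;

- the *R statistic* — a log-likelihood-ratio heterogeneity measure over all
  m libraries at once, R = Σⱼ xⱼ ln( xⱼ / (Nⱼ·Σx/ΣN) ), tested via the
  asymptotic null 2R ~ χ²(m−1) with Bonferroni correction.

A contig is reported when either test fires (union rule); selected profiles
are row-normalised and hierarchically clustered with average linkage on
1 − Pearson correlation for heat-map/dendrogram rendering.

**SNP discovery** applies three haplotype-based quality filters to each
contig alignment (≥ 4 reads): candidate polymorphic columns; partition of
reads into haplotypes with removal of single-read haplotypes and unlinked
singleton alleles; and a redundancy/balance confidence score
(1 − 1/d)(2·minor/d). Contigs whose two major haplotypes differ at
> 3 fixed differences per 100 bp are flagged as collapsed paralogs. Calls
are labelled synonymous/nonsynonymous on the predicted CDS and summarised
as KA/KS with per-codon fractional site counting (S + N = 3 × codons).

**Composition profiling** computes GC and GC3 (G+C at third codon
positions) per CDS and renders 100-class histograms smoothed with a
three-class moving average — the standard view for detecting uni- vs
bimodal GC3 populations.

**Enrichment** uses exact hypergeometric tails for term
over/under-representation, normalised domain percentages for two-dataset
comparison, and a rule-based screen of a family × species count matrix for
species-specific and prominent gene families.

## Worked example

Simulate a six-library experiment (three development, three stress
libraries of 700 reads each from 120 genes, 12 of them condition-shifted,
with planted SNPs and paralogs) and run every stage:

```yaml
# sim.yaml
seed: 42
outdir: out
simulate:
  n_genes: 120
  n_allelic_variants: 12
  n_paralog_pairs: 3
  designs: {n_dev: 3, n_stress: 3, n_de: 12, n_reads: 700}
```

```bash
estmine run --config sim.yaml
# 8 stages -> out/manifest.json
```

The run writes reads, contigs, count matrix, CDS annotations, SNP calls,
DE table, dendrogram/heat map and enrichment table. With this seed:

- assembly: **120 clusters** (120 contigs, 0 singlets) — one per simulated
  gene, mean consensus length 904 bp;
- SNPs: **36 calls**, all bi-allelic, transition:transversion 1.57, density
  0.034 SNP/100 bp over screened contigs; all **3 planted paralog pairs
  flagged** and excluded;
- differential expression: **12 significant contigs** — exactly the 12
  planted genes, e.g. `contig00003  R=20.26  p_R=1.2e-07`;
- enrichment: the planted `stress_response` term is carried by 12/12
  selected contigs vs 12/120 overall, hypergeometric p_over = 9.5e-17.

Individual stages run standalone (`estmine trim`, `estmine cluster
--min-identity 0.90 --min-overlap 40`, `estmine dde --alpha 0.05`,
`estmine families …`), and each is a one-call library function
(`estmine.cluster_ests`, `estmine.ac_pvalue`, `estmine.detect_snps`, …).

## Layout

```
src/estmine/
  simulate.py     synthetic transcriptomes and EST libraries with truth
  preprocess.py   trimming and contaminant screening
  assemble.py     overlap clustering, count matrix, assembly summary
  orfgc.py        CDS prediction, GC/GC3 metrics, smoothed histograms
  snp.py          three-filter SNP detection, synonymy, KA/KS
  dde.py          AC + R statistics, DE selection, profile clustering
  enrich.py       hypergeometric tests, domain prevalence, family screen
  pipeline.py     stage orchestration, manifest, seeding
  cli.py          `estmine` command-line interface
docs/methods.md   models, defaults, numerical choices, limitations
```
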