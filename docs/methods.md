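# Methods

`estmine` implements the classic Sanger-era EST mining workflow — trimming,
overlap clustering, ORF/GC profiling, haplotype-filtered SNP discovery, and
digital differential expression from cDNA library counts — together with a
synthetic EST-library generator that plants known truth so every stage can
be validated against ground truth rather than against itself. This note
records the models, the defaults and why they hold, the numerical choices,
and what the synthetic data do and do not establish about real data.

## Synthetic EST libraries

The generator emulates 5'-sequenced cDNA clone reads from a transcript set.

**Transcript model.** Each gene is a 5'UTR + CDS + 3'UTR. CDS lengths are
truncated normal (mean 240 codons, sd 80, floor 60), giving a ~720 bp median
CDS; UTR lengths are truncated normal with means 160 bp (5') and 240 bp
(3') — the scale typical of plant ESTs. Coding sequence is built by sampling
amino acids uniformly from the 18 residues whose codon families offer both
an A/T and a G/C third position, then choosing the third base G/C with
per-gene probability `gc3_target`. This makes GC3 a directly controllable
binomial quantity: a gene targeted at 0.40 realises GC3 ≈ Binomial(n, 0.40)/n.
Multiple `(center, weight)` modes produce uni- or bimodal GC3 populations.
Met and Trp are excluded from the sampled alphabet because their fixed third
base would bias GC3 away from its target; the start ATG and the stop codon
are always present (the stop is excluded from GC3 by default, since its
third position is constrained by the code rather than by mutation pressure).

UTRs are generated start-codon-free (every arising ATG is broken to ATC).
This is a deliberate simplification: it makes CDS-prediction errors
attributable to the frame-selection heuristic itself rather than to
spurious upstream starts the simulator happened to plant. Real UTRs contain
uATGs, so the CDS-recovery rates measured here are an upper bound for real
data.

**Variation.** Allelic variants are planted as one alternate haplotype per
chosen gene: several linked substitutions (default 3) within the 5' 500 bp,
so that 5'-anchored reads observe them; reads draw the alternate haplotype
with probability 0.5. Substitutions are transitions with odds
`ts_tv_ratio : 1` (default 2:1, the ratio regime reported for plant EST
SNPs). Paralog pairs are planted by duplicating a gene and mutating
`divergence × transcript length` positions spread over UTRs and CDS
(avoiding start/stop codons, new in-frame stops and new UTR ATGs), so the
fixed-difference density of a collapsed pair per aligned base equals the
nominal divergence.

**Reads.** Each read is `adapter + 5' transcript prefix (+ substitution
errors) + polyA` where the polyA run is appended only when the prefix
reaches the transcript's 3' end. Read lengths are truncated normal, mean
650, sd 150, floor 100 — matching the ~660 bp average cluster length of the
assemblies this pipeline targets. Errors are substitutions only by default
so that the assembly and SNP oracles stay exact; contaminant reads are
drawn from a uniform-composition pool and recorded in the truth object.
Optional quality strings decay from Q40 to ~Q8 over the last 120 bases to
exercise quality trimming. All sampling is driven by `numpy` generators
seeded per library design, so identical seeds give byte-identical output.

What the generator does **not** model: chimeric clones, alternative
splicing, indel sequencing errors (available but off by default),
chromatogram-level artefacts, and non-uniform codon usage within a gene.
Passing tests on this data therefore demonstrate algorithmic correctness
under the stated assumptions, not robustness to every artefact of real
Sanger traces.

## Trimming and contaminant screening

Trimming applies, iterated to a fixed point: leading-adapter removal
(substitution-only match, ≤ 2 mismatches, anchored at the read start by
default — a mismatch-tolerant scan of a wider window hits random sequence
too often for short adapters; `adapter_scan` widens it when vector remnants
may sit deeper), terminal polyT (5') and polyA (3') runs of ≥ 8, a 3'
sliding-window quality clip (window 20, mean floor Q16), and a 100 bp
minimum-length filter with a rejection reason code. Iterating the phases
makes trimming idempotent: one phase can expose material for another (a
quality clip uncovering a polyA run). The output is always a contiguous
substring of the input.

Bacterial screening consumes a 12-column tabular similarity-hit table; a
cluster is a contaminant iff some hit has E-value ≤ 1e-40 **and** identity
> 80%. The published account of this rule states the E-value inequality in
the opposite direction, which would flag only *weak* hits as contamination;
we treat that as a typographical inversion (configurable via
`require_significant=False`).

## Overlap clustering

Full overlap-graph assembly is out of scope; what matters for reproducing
the analysis are its two published parameters — minimum overlap 40 bases and
minimum overlap identity 90%. The clusterer is a greedy seed-and-extend
agglomerator: reads sorted longest-first; shared 12-mers vote for a
candidate diagonal against each existing cluster's reference; the best
diagonal's ungapped identity decides membership, with a banded affine
alignment (band 10, gap open 5, extend 1) as fallback for borderline
diagonals so indel-containing overlaps are not lost. A read joins the first
(creation-order) acceptable cluster, else founds a new one — ties are
therefore deterministic. Consensus is column-wise majority with alphabetical
tie-break (A<C<G<T); coordinates are 0-based half-open. Reverse-complement
joining is on by default (vector orientation can flip inserts) and
exercised in tests.

## CDS prediction and GC profiling

Frames in the original workflow come from protein similarity; without a
database dependency we substitute the longest ATG-initiated ORF across six
frames ('+' strand, then lower frame, on ties), with a guide channel
`(frame, strand)` through which similarity-derived frames can be injected —
a guided call expands 5' to the nearest upstream in-frame ATG and 3' to the
next in-frame stop, which is exactly what the longest ORF in that frame is.
When no frame has an ATG the longest stop-free stretch is annotated with
`full_length=False` and a reason code. The CDS span includes its terminal
stop.

GC is the G+C fraction of the CDS; GC3 the G+C fraction of third codon
positions, stop excluded by default. Whether "total GC" should include UTRs
is ambiguous in EST practice, so both per-CDS and per-consensus values are
available and labelled. Distributions are summarised as 100 equal classes
over [0,1], smoothed with a three-class moving average whose edge classes
average their two available neighbours (this rule does not conserve the
histogram sum; the raw histogram is returned alongside).

## SNP discovery

Three filters, in sequence, on each contig with ≥ 4 reads (four reads are
the minimum that can show two copies of each allele):

1. **Candidate screen** — columns with ≥ 2 observed alleles; `N` never
   supports an allele; with qualities present, bases below Q20 are ignored.
2. **Haplotype filter** — reads are partitioned into haplotypes by
   allele-vector *compatibility* over shared covered columns (greedy,
   largest-coverage first). Exact-vector grouping is the special case when
   all reads span all candidate columns; compatibility grouping is needed
   because 5'-anchored reads have ragged 3' coverage. Haplotypes with a
   single read are removed; a singleton allele survives only if its carrier
   belongs to a surviving haplotype defined by ≥ 1 other polymorphism.
   Contigs whose two largest haplotypes show fixed differences above
   3 per 100 bp of shared span are flagged as collapsed paralogs and
   excluded from summaries.
3. **Confidence screen** — `(1 − 1/d)·(2·minor/d)` with column depth `d`,
   floor 0.2. The original tool's exact score is unpublished; this surrogate
   is monotone in redundancy and allele balance, which is what the score is
   described as measuring. At the canonical balanced 2+2 column it equals
   0.75; an unbalanced 3+1 column at depth 4 scores 0.375.

Synonymy labels substitute each alternate allele into its codon on the
annotated CDS and compare translations (noncoding outside the CDS;
mixed-effect multi-allelic sites are ambiguous). KA/KS uses per-codon
fractional site counting (each position contributes the fraction of its
three possible changes that are synonymous; S + N = 3 × codons, terminal
stop excluded) and uncorrected substitution proportions — within-contig SNP
divergence is far too small for multiple-hit correction to matter, so no
Jukes–Cantor correction is applied. `ks = 0` yields an explicitly undefined
ratio, never infinity.

## Digital differential expression

The Audic–Claverie conditional law of count `y` given `x` and library sizes
`n1, n2` is

    p(y|x) = (n2/n1)^y (x+y)! / ( x! y! (1 + n2/n1)^(x+y+1) ),

a negative binomial in `y`. Terms are evaluated via log-gamma (no overflow
for counts ≤ 1e6); the lower tail is a finite sum, the upper tail is summed
directly with geometric truncation (terms past the mode decay at rate
`r/(1+r)`), and the two-sided value is `min(1, 2·min(lower, upper))`. The
argument pair is first put into canonical orientation (the smaller
`(count, total)` pair conditions), making the p-value symmetric under
swapping the two libraries — without this, discrete tail-point inclusion
breaks symmetry. Values within 5e-13 of 1 are snapped to exactly 1.0: at
`x = y` with equal totals the lower tail is exactly 1/2 by a binomial
identity, and the snap removes float-summation residue from that exact
case.

The R statistic is the log-likelihood-ratio heterogeneity measure
`R = Σ_j x_j ln(x_j / (N_j Σx/ΣN))` with `0·ln 0 = 0`. The published
workflow reports no R→p mapping; we adopt the standard asymptotic
chi-square(m−1) law for 2R and report R itself alongside.

Selection: libraries are merged per a user map, libraries with < 300 total
ESTs are dropped (small libraries destabilise the tests), contigs with < 3
ESTs are dropped, the R test runs at a Bonferroni-adjusted level
`alpha / n_tested` (the correction attaches to the R test only, and the
divisor is the contig count, not contigs × pairs), a contig is
AC-significant when for at least one library all its pairwise AC p-values
against the other libraries fall below 0.05 (per-comparison, configurable),
and the result is the union of the two selections, each tagged with which
test fired.

Profiles (row-normalised frequencies) are clustered with average linkage on
1 − Pearson correlation. Zero-variance profiles get distance 1 to
everything (uncorrelated by convention). The linkage method is not stated
in the published workflow; average linkage is the default for correlation
distances in expression work. Output: linkage tree (Newick), leaf order,
and the reordered matrix for grayscale heat-map rendering (black = high
relative frequency).

## Enrichment and family screening

Term over/under-representation uses exact hypergeometric tails
(`P[X ≥ k]`, `P[X ≤ k]`) computed via `scipy.stats.hypergeom`, with
Benjamini–Hochberg FDR columns reported alongside raw p-values (the
original analysis reported raw p only; FDR is additive, not a
replacement). Domain prevalence normalises per-term counts by the number of
annotated clusters per dataset and reports percentage differences and
ratios.

The family × species screen labels a family **specific** when its focal
total is ≥ 3 and every non-focal species has zero members, **prominent**
when the focal total is ≥ 3, no non-focal count exceeds 1 and the focal
total is ≥ 3× the largest non-focal count, else **background**. The
published criterion is narrative, not formulaic; these thresholds are
declared surrogates chosen to reproduce the qualitative membership of the
published reference rows (e.g. a 21+6 focal family with one outside member
is prominent; a 3-member single-species family is specific; a family large
in all species is background), and all three are configurable.

## Pipeline, reproducibility and problem sizes

`run_pipeline` executes simulate → trim → screen → cluster → orfgc → snp →
dde → enrich, writing standard formats (FASTA/FASTQ, TSV, JSON, Newick,
PNG) and a manifest with per-stage parameters and SHA-256 output checksums.
A single global seed is expanded into per-stage substreams (SHA-256 of
`seed:stage`), so stages rerun identically in isolation; `from_counts`
restarts the run at the DE stage from an on-disk count matrix. In the
simulated pipeline the contaminant hit table and the per-gene term
annotation are derived from the planted truth (a "stress_response" term is
attached to the condition-shifted genes), closing the loop so the
enrichment stage also has a planted signal to recover.

Default validation problem sizes are chosen to keep the full suite and the
acceptance script comfortably fast while leaving no statistical check
underpowered: 10,000 null contigs for calibration, 200 genes × 8 libraries
× 1,500 ESTs for DE recovery, 100 genes × 1,200 reads for the assembly
oracle, 1,000 genes for GC3 profiling, and a 120-gene end-to-end pipeline
demonstration.

## Known limitations

- The clusterer is greedy and reference-based; it honours the published
  overlap/identity parameters but is not an overlap-graph assembler, and
  very short true overlaps with clustered indels can be missed.
- Haplotype compatibility grouping can attach an uninformative read (one
  covering no distinguishing column) to the largest compatible haplotype.
- The chi-square law for 2R is asymptotic; at very small contig totals the
  R test is approximate (the AC test, which is exact, covers that regime).
- The confidence score and the prominence thresholds are declared
  surrogates for unpublished criteria; both are configurable.
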