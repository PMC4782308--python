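# Methods

This note documents the models, parameter choices and numerical conventions
behind `capseq`, and what the synthetic-data tests do and do not establish
about real data.

## 5′-end counting and normalization

The 5′ end of a plus-strand alignment is its leftmost *aligned* reference
base, of a minus-strand alignment its rightmost; soft-clipped bases are
excluded, since under local alignment the first mappable base is the best
available estimate of the transcript 5′ end. Counts accumulate per
(reference, position, strand). The relative read score RRS = (Rns/Rt)·10⁶
uses, as Rt, the number of *retained* reads (mapped, primary, unique), so
numerator and denominator describe the same read population and RRS sums to
10⁶ per library. Uniqueness follows the aligner's secondary-alignment score
tag (`XS`) when present; otherwise a MAPQ floor (default 10) is the
fallback, so files from any aligner behave sensibly. Multi-mapped reads are
excluded by default in both single-genome and microbiome modes
(configurable): the microbiome definition of a putative TSS explicitly
requires unique reads, and keeping the single-genome mode consistent avoids
a silent semantic switch.

## TSS calling and the control comparison

A position is a TSS when RRS\_cap ≥ `rrs_min` (default 1.5) and
log₂(RRS\_cap/RRS\_control) ≥ `enrichment_min` (default 0). Conventions for
the zero cases: a candidate absent from the control receives +∞ enrichment
and is retained — absence from the control is maximal enrichment, and a
pseudocount would silently shift the published threshold semantics; a
position absent from both libraries has an undefined score (NaN), which
fails every threshold and can never be called. Depleted (processed-site)
candidates are positions with RRS\_control ≥ 1.5 and enrichment < 0; the
control-side floor reuses the TSS-side value because no separate published
floor exists, and it is a parameter (`rrs_control_min`).

## Clustering

Promoters initiate at several neighboring bases, so called positions are
clustered greedily, strongest first: the highest-RRS unassigned position
becomes a peak and absorbs all unassigned positions within ±cutoff bases on
the same reference and strand (cutoff 5 single-genome, 50 microbiome —
"strongest TSS within 100 bp"). Membership is distance-to-peak, not
transitive chaining. Ties in RRS break to the leftmost coordinate and all
iteration orders are fixed (reference, strand, position), so results are
bit-reproducible. The test suite checks this implementation against an
independent, literal "take the global maximum, remove its neighborhood,
repeat" reference on thousands of random instances, plus idempotence and
peak-separation properties.

## Annotation

Context is assigned by interval overlap (1-based inclusive): intergenic, or
intragenic sense/antisense by strand match with the host gene. When genes
overlap, the sense-matching gene is preferred and, among several, the one in
which the TSS lies closest to the gene's 5′ end — a TSS near a start is most
plausibly that gene's promoter-proximal start. Codon phase is
((pos − cds\_start) mod 3) + 1 on plus-strand CDS and the mirrored formula
on minus; antisense TSS are indexed on the host gene's coding strand, so
phase statistics for both orientations share a frame. Leaderless calls
require an exact coordinate match between the TSS and the annotated gene
start, same strand (a window parameter allows relaxation). Read-per-feature
fractions assign each read by its 5′-end position with precedence
rRNA > tRNA > CDS > intergenic.

## Promoter sequence analysis

Windows span −45..+5 around the TSS (offset 0 = the TSS base), written
5′→3′ on the TSS strand. Information content per position is the relative
entropy Σ p·log₂(p/q) of the column base distribution against the genome
composition q (uniform fallback); N bases are excluded from column counts,
and the statistic is non-negative, zero exactly when a column matches
background. PWMs use pseudocount-smoothed probabilities
(count + 0.5)/(n + 2) per column and base-2 log-odds. Motif scanning is
restricted by default to offsets −15..−4 — the −10 element is positionally
constrained — and a window "has the motif" when its best placement exceeds
the 95th percentile of best-hit scores over windows drawn at random genome
positions. This null calibration makes the reported fraction
background-relative with a nominal 5% false-positive rate, verified by
self-calibration tests; both the quantile and the scan interval are
parameters. Initiation precision is operationalized per cluster as
peak RRS / total cluster RRS ≥ 0.75 → "precise"; the threshold is this
package's own rule for an otherwise qualitative notion, and is a parameter.

## Microbiome mode

Without a control library, every position with ≥ 1 unique-read 5′ end is a
putative TSS; a genome is "present" with ≥ 300 clustered putative TSS
(cutoff 50). High-confidence TSS require ≥ 10 raw reads ("absolute"
meaning the floor applies to counts, not RRS) before clustering. Replicate
agreement is Pearson correlation of untransformed RRS over the union of
high-confidence clustered TSS from either replicate, zero-filled where a
position is absent — log transformation is available as an option but the
default matches the plain-RRS definition. Genomes are processed
independently with per-genome Rt, so processing order cannot affect any
report; cross-genome read deduplication is not attempted.

## Synthetic data generator

The generator emulates the data-generating assumptions of a 5′-end
enrichment experiment on a toy genome (default 120 kb, GC 0.5, 40 coding
genes, 2 rRNA and 4 tRNA loci):

* **TSS**: 200 planted positions, strengths log-uniform on [1, 100]
  (expected-read weights), strand Bernoulli(0.5), pairwise separation ≥ 80
  bases so planted promoter elements never collide.
* **Initiation precision**: 40% of promoters are precise; the rest jitter
  their 5′ ends by a rounded Normal(0, 1.5 bases) clipped at ±4 — the
  dispersion is bounded by the 5-base clustering radius, consistent with
  treating a promoter's output as one cluster. The real dispersion law is
  unknown; this choice is symmetric, discrete and bounded.
* **Processed sites**: 100 positions that dominate the control library and
  leak into the enriched library at 2%.
* **Library composition**: control = 85% rRNA-locus background + 10%
  processed + 5% TSS; enriched = 3% rRNA + 2% processed + 95% TSS. These
  mirror the observed read composition of real enriched/control libraries
  (~85% rRNA without enrichment, ~3% with). Planted TSS and processed sites
  avoid rRNA loci, where dense control background would dominate.
* **Sequence signals**: TATAAT planted at offsets −12..−7 and TTGACA at
  −36..−31 on the TSS strand; with probability 0.8 the −1/+1 bases are set
  to pyrimidine/purine (the YR configuration).
* **Reads**: fixed-length (50 bp) perfect-match alignments written as valid
  coordinate-sorted SAM; sequencing errors and indels are omitted because
  they do not affect 5′-end logic, which keeps the truth exact.

Simulations are fully deterministic given (config, seed). Default depths
are 10⁵ reads per library — small enough that the whole pipeline runs in
seconds, large enough that every planted TSS is sampled.

**What passing tests show, and what they do not.** The generator plants
point signals in i.i.d. background sequence: it has no transcription-unit
structure, no operons or 5′UTR-length distribution, no sequence-dependent
capture or ligation bias, no PCR duplicates, and jitter is symmetric.
Recovery of planted TSS therefore validates the pipeline's arithmetic,
thresholds and clustering logic — not the biological error rate on real
libraries, where enrichment efficiency and mapping artifacts dominate.

## Reproducing published-scale results

The desk-scale checks above run on synthetic data. Running the pipeline on
real Cappable-seq data (ENA accession PRJEB9717, *E. coli* U00096.2, with a
known-TSS catalog such as RegulonDB) requires downloading ~20M reads,
aligning them (the original analysis used Bowtie2), and feeding the
coordinate-sorted alignments to `capseq run-all` with default parameters.
Stage counts (candidates, depleted-removed, TSS, clustered TSS,
common/specific vs the catalog) are then directly comparable to published
values; note that aligner choice and version affect the mapped-read set and
hence Rt, RRS and all downstream counts, so exact reproduction requires the
original mapping parameters.

## Known limitations

* Hard thresholds only; no significance testing or FDR control on
  enrichment scores.
* Single-end logic: mate handling reduces to read 1's 5′ end.
* No operon inference, UTR-length estimation, or assignment of intergenic
  TSS to downstream genes.
* The initiation-precision rule and the depleted-site control floor are
  this package's operationalizations of qualitative published notions, and
  are exposed as parameters rather than fixed facts.
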