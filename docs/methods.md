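# Methods

## Coordinates and containers

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
converted on read and the conversion is an exact bijection. A segmentation
is stored as sorted run-length intervals tiling each chromosome on a fixed
bin grid (200 bp by default, matching the binarisation convention of
multi-mark hidden-Markov segmentations). Genome not covered by any record
is kept explicitly under the reserved `unassigned` label and excluded from
every statistical denominator: coverage percentages, composition rows,
neighbourhood backgrounds and occupancy totals are all over assigned bp
only. Peak "centre" is `floor((start+end)/2)` throughout.

Both the ChromHMM "dense" and "segments" BED dialects carry the state label
in column 4, so one reader accepts either; extra dense columns are ignored.

## Per-state statistics

- **Coverage**: `bp(state) / assigned bp × 100`.
- **Feature composition** assigns every base pair exactly one class with
  priority protein_coding > TE > other > intergenic, so rows sum to 1. The
  implementation paints per-bp class arrays per chromosome; this is exact
  and fine at the megabase scales the package targets (memory is one byte
  per bp).
- **Neighbourhood enrichment** works on the segmentation's own bin grid,
  never re-binned. The anchor bin (offset 0) is the bin containing the
  first (TSS) or last (TTS) transcribed base — coordinates derived from an
  interval's exclusive end are shifted by one so the anchor base itself is
  used. Offsets are mirrored for minus-strand anchors. Anchors whose offset
  bin leaves the chromosome or lands on `unassigned` are excluded from that
  offset's denominator, which preserves the total-probability identity
  `Σ_s fraction(s)·enr(s,k) = 1` at complete offsets. The background is the
  uniform genome-bin fraction of each state (a signal-weighted background is
  a possible extension; the flag is reserved). Default half-width L = 10
  bins (±2 kb), enough to span promoter, +1 nucleosome and early gene body
  at 200 bp resolution.

## Domain classification and nomenclature

Published state maps classify domains by inspection of emissions and
feature overlap; here the cascade is explicit and every assignment records
the rule that fired:

1. **H** if max emission over a heterochromatin mark set (defaults:
   H3K9me1/2, H3K27me1, H2A.W, H2A.M variants) ≥ τ_H = 0.5 **and** TE bp
   proportion ≥ τ_TE = 0.3;
2. **I** if max emission over all marks < τ_I = 0.2 (nucleosome-free
   regulatory space);
3. **F** if max emission over facultative marks (H3K27me3, H2A.Z, H2Aub)
   ≥ τ_F = 0.5;
4. **E** otherwise.

All thresholds are parameters. E/F/I states are numbered by ascending
argmax TSS offset (ties: enrichment-weighted profile centroid, then label),
i.e. the order in which states appear walking from the TSS into the gene
body. H states are numbered by ascending median distance to the centromere
when centromere coordinates are given, else by descending coverage.

## Model comparison

Transition matrices and Jaccard similarities are computed at base-pair
granularity (bin-exact whenever both models share the grid), excluding bp
unassigned in either model. Mark-removal analysis matches every full-model
state to its best-Jaccard reduced-model state, aggregable per domain.
Emission clustering merges two state models over shared marks (a mark map
lets near-equivalent variants of two species, e.g. one species' H2A.W and
the other's H2A.M.2, be used interchangeably) and emits the dendrogram as a
plain merge table (scipy linkage convention; default Euclidean/average) so
it is testable and portable. TSS/TTS updating assigns each experimental
anchor to the nearest same-strand gene anchor within 500 bp (configurable),
ties to the smaller gene id; shifts are signed in the gene's reading
direction.

## Expression association

CV uses the sample (n−1) standard deviation over the mean. Gene bins are
rank-based and equal-sized (±1), ties broken by stable gene-id order; the
ordering statistic for TPM bins is the designated reference tissue (the
tissue whose chromatin the state map describes), not the row mean.
Promoters are the 1,000 bp upstream of the TSS, strand-aware and clipped at
chromosome edges. State-proportion profiles are bp-weighted per region and
averaged per bin; gene-body profiles reuse the same operation with the gene
interval as region. Tissue-specific calls require tissue TPM ≥ 2× the
cross-tissue mean; genes qualifying in several tissues are all reported
with a multiplicity column so either convention (keep or drop) can be
applied downstream, and genes with zero mean everywhere are never called
(the rule would otherwise call every silent gene specific to every tissue).

## TF occupancy and activity

Occupancy is bp-level: `(a_s/b)/(c_s/d)` with `a_s` the peak bp in state s,
`b` total peak bp (over assigned genome), `c_s` the state's bp and `d` the
assigned genome. Peaks are assigned one state by the bin containing their
centre. Targets follow a cascade on the peak centre: promoter window
(default −1000/+100 bp around the TSS, strand-oriented) with nearest TSS on
ties, then gene body, then nearest TSS within 10 kb, else unassigned; the
promoter window and distance cap are parameters since annotation tools'
defaults vary.

Co-expression filtering keeps positively (rank score < 2000, strict) and
negatively (score > per-TF max − 1000, strict) co-expressed genes; the two
sets are pooled into one co-expressed set for testing (per-sign testing is
available to callers by passing either set alone). For each state the 2×2
table is derived from the margins (k, m−k; q−k, N−m−q+k) with k = targets ∩
co-expressed, m = targets in the state, q = co-expressed, N = the gene
universe; a `literal_table` option reproduces the alternative four-count
layout for comparison. The one-sided (greater) p comes from the exact
hypergeometric tail; the odds ratio is the sample OR with Haldane 0.5 on
zero cells (the score needs a finite OR; a conditional-MLE OR could be
added behind the same interface). The activity score is
`−log10(p) + log2(OR+1)`, with p floored at 1e−300 to stay finite; states
without targets score 0 (p = 1, OR = 0). TFs whose maximum raw score is
below 8 are dropped; remaining rows are normalised by their own maximum.
Clustering is hierarchical (complete linkage, Euclidean, both
configurable) cut at a user-chosen k — no selection rule is imposed.
Family enrichment uses the same exact-test convention per (family, cluster)
with Benjamini–Hochberg q-values.

The null is the deterministic full-universe hypergeometric (equivalent to
the expectation over random gene samples of the same size); an actual
resampled null would only add Monte-Carlo noise around the same p.

## Synthetic epigenome

The generator's defaults are the package's standard study conditions: one
1 Mb chromosome of 200 bp bins, 500 protein-coding genes, 40 TE blocks of
5 kb (20 % of the genome, the order of constitutive-heterochromatin loads
in compact plant genomes), 30 TFs in 5 planted groups at preference weight
0.8 with 60 peaks and ~50 functional targets each, 5 tissues × 2
replicates of log-normal TPM (μ=1, σ=1) with 10 % silent and 20 %
tissue-specific genes boosted 8-fold in their owning tissue, and per-TF
integer co-expression ranks 1..G with functional targets strictly below a
ceiling of 100. One master seed expands into independent child streams
(genome / peaks / expression classes / replicate noise / co-expression), so
identical config + seed gives byte-identical files while layers stay
decoupled.

Gene cassettes carry 2 promoter bins (intergenic state), a TSS bin
(offset 0, nucleosome-free), then body bins sampled from the palette's
per-offset profiles: the +1 bin is the +1-nucleosome state E1, +2 the early
body state E2, +3 and deeper the elongation state E3 — mirrored for minus
genes. Gene bodies are swapped wholesale to the facultative state F1 with a
probability that falls linearly (0.9 → 0.05) with the gene's expression
rank, planting the repression/expression gradient the profile analyses
recover. TE blocks sample an H1/H2 mixture. Items and multinomial spacers
tile the chromosome exactly, so segmentations have no gaps.

Because co-expression ranks span only the synthetic gene count, the
absolute thresholds of a ~27k-gene compendium (2000 / max−1000) are
meaningless at G = 500; synthetic runs pass the generator's own ceiling and
tail through the same configurable thresholds the scoring functions expose.
This is a property of rank semantics, not of the method.

What the generator does **not** emulate: read-level noise, peak-width/shape
variation beyond uniform 200–400 bp, overlapping transcripts, unmappable
(unassigned) bins, correlated mark emissions within a bin, or biological
co-expression structure beyond the planted target links. Passing recovery
tests therefore demonstrates the correctness of the analytics and the
internal consistency of the framework, not performance on real ChIP-seq
noise.

## Numerical and testing choices

All overlap statistics are validated against naive per-bp oracles on
randomised genomes ≤ 100 kb; exact-test p-values against exhaustive
enumeration of contingency tables with fixed margins (N ≤ 200, 1e−12).
Pipelines are deterministic: per-stage outputs are hashed into a manifest,
identical config + seed reproduces identical hashes, and changing only the
clustering linkage changes only clustering-derived artifacts. The
acceptance script runs the default study conditions end to end; its problem
sizes (1 Mb, 500 genes, 30 TFs) keep the whole run under a minute while the
planted effects remain comfortably detectable.

## Known limitations

- Composition painting allocates one byte per bp per chromosome; fine to
  ~100 Mb chromosomes, not for mammalian-scale assemblies in one pass.
- GFF3 reading keeps gene-level records only (genes, TE genes/elements,
  pseudogenes); transcript hierarchies are out of scope.
- The promoter-priority target cascade can assign a deep-gene-body peak of
  a compact genome to the downstream neighbour's promoter; this mirrors the
  behaviour of standard annotation tools and is the main source of the few
  TFs falling below the confidence filter in dense synthetic layouts.
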