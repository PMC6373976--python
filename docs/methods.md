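# Methods

## Coordinates and formats

All internal coordinates are 0-based half-open. GFF3 input (1-based
inclusive) is converted on read; bedGraph and BED are native. The bedGraph
dialect is 4 columns with no required track line (track/browser lines are
skipped); an absent base reads as 0. Written bedGraph is canonical: maximal
runs of equal adjacent values as single records, sorted by chromosome then
start, zeros omitted — so write∘read and read∘write are identities on
canonical files.

## Feature derivation

For a gene with 5′-end base *g* (span start on `+`, span end − 1 on `-`):

* promoter = the symmetric 201-base closed window `[g−100, g+100]`,
  i.e. `[g−100, g+101)` half-open. The window width is stated in the
  literature as "(gene start)−100 bp to (gene start)+100 bp", which is
  ambiguous between 200 and 201 bases; the symmetric 201-base reading was
  chosen because it is strand-independent and introduces no off-by-one
  bias between strands.
* proximal = the 400-base window strictly upstream of the promoter window
  in transcription orientation (`[g−500, g−100)` on `+`, mirrored on `-`).
* introns = gaps between consecutive exons.
* Windows extending past a chromosome edge are clipped, never rejected.
* One representative gene model per gene; overlapping exons across
  isoforms are out of scope (the data model holds gene-level features).

## Cluster calling

The support rule operates per genotype: a base is a candidate when
≥ `min_tags` (default 2) tags appear in ≥ `min_libraries` (default 2)
libraries of that genotype. Clustering merges the **union** of all
genotypes' candidates, so every genotype is scored against one shared
cluster coordinate system — categories then compare like-for-like
intervals, which the per-mutant Venn analysis requires. Cluster
score = total raw tags in the interval over **all** libraries (not only
candidate bases), divided by the total number of libraries in the
experiment; summit ties break to the leftmost base for deterministic
output. "Detected in genotype *g*" at cluster level is defined as: the
cluster contains ≥ 1 candidate position of *g* — the direct extension of
the per-position rule.

## Annotation and gene assignment

Overlap uses the full cluster interval (≥ 1 shared base), not only the
summit. Genic categories (promoter, proximal, fiveUTR, exon, intron,
threeUTR) require same-strand overlap; antisense means opposite-strand
gene-span overlap; intergenic is the floor. Conflicts resolve by the fixed
hierarchy (highest wins):
`intergenic < antisense < intron < exon < threeUTR < fiveUTR < proximal < promoter`.
Gene assignment: the nearest same-strand gene overlapping the cluster or
within 500 bp edge-to-edge (bases strictly between the interval edges);
ties break to the smaller gene start; intergenic and antisense clusters
are never gene-assigned. Overlap queries run on interval trees; the test
suite cross-checks them against brute-force pairwise scans.

## Classification and summary arithmetic

Categories partition every cluster: basal (wild-type flag and ≥ 1 mutant
flag), wt_specific (wild-type only), fact_specific (≥ 1 mutant, no
wild-type). Percentages are rounded half-away-from-zero — 1 decimal at
≥ 10%, 2 decimals below — which reproduces published figures such as
80.8% (77738/96232) and 1.06% (1023/96232). Two known printed-value
idiosyncrasies are *not* matched: 17471/96232 = 18.16% prints here as
18.2% (the source reports 18.1%), and 43414/2460 = 17.65-fold rounds to
18 (the source reports 17.4-fold); standard rounding is reported and the
discrepancy documented rather than imitated. The two-mutant Venn
restricts to exonic + intronic + antisense fact-specific clusters. CAGE
overlap counts a cluster when its interval contains ≥ 1 summit
(strand-matched for stranded summits, strand-blind otherwise).

## Expression quantification

CPM uses each library's genome-wide tag total as denominator, matching
read-count normalization semantics, not only in-cluster tags. A
pseudocount of 1 is added after CPM scaling (`log2(CPM + 1)`), so zero
counts map to 0; the pseudocount is configurable. Promoter expression per
genotype is the mean of its replicates' CPM at the gene's
promoter-annotated cluster (highest-scoring one if several); the
with/without contrast uses the two-sided Wilcoxon rank-sum test.

## Signal aggregation

* 20 bp boxplot window = `[p−10, p+10)`; 400 bp metagene offsets
  −200…+199. Widths alone are stated in the source; centred half-open
  conventions were chosen for determinism.
* Metagene values are strand-flipped (offset *o* reads *p−o* on minus
  anchors); confidence bands are mean ± 1.96·sd/√n (normal-based, not
  t-based).
* Boxplot hinges are 25th/75th percentiles with linear interpolation;
  whiskers are the most extreme data values within 1.5·IQR of the hinges.
* Control positions are sampled uniformly over each gene's exonic bases
  with a seeded generator; the gene-end exclusion (default 200 bp when
  enabled) is a post-filter against the 3′ end, motivated by exaggerated
  run-on signal at polyadenylation sites.
* The Wilcoxon rank-sum implementation is scipy's Mann–Whitney U:
  exact when both groups have n ≤ 25 and no cross-group ties, otherwise
  the normal approximation with tie correction; all-tied input returns
  p = 1 by convention. The test suite verifies the exact path against
  exhaustive enumeration of rank assignments and the asymptotic path
  against null uniformity.
* Single-end resizing: each read becomes an interval of length
  ⌊insert/2⌋ ending at its 3′ end, extending toward the 5′ side, clipped
  at chromosome bounds. Insert-size estimation itself is out of scope;
  the insert size is a required parameter.

## Synthetic study generator

The generator emulates the reference study design: 2 chromosomes ×
250 kb, 200 non-overlapping alternating-strand genes (1–4 exons of
150–500 bp, introns 60–200 bp, intergenic gaps 300–1500 bp), genotypes
wild_type/spt16/ssrp1 with 2 replicates each. Planted structure:

* a promoter TSS at every gene's 5′ end, active in all genotypes, tag
  counts per library ~ NegBin(mean 50, dispersion 10);
* a mutant-specific intragenic TSS in 30% of genes (10% of those in
  introns, the rest exonic), active only in mutants (both mutants with
  probability 0.8, else one at random), NegBin(mean 10, dispersion 10) —
  deliberately weaker than promoters, as derepressed intragenic
  initiation is in real data;
* singleton background noise at Poisson(0.5/kb) positions: exactly one
  tag in one random library, strictly sub-threshold so the support rule's
  rejection is testable (a supra-threshold "confusable noise" mode exists
  behind a flag);
* signal tracks on baseline 1.0 with Gaussian bumps (amplitude 1.0,
  σ = 75 bp) at intragenic mutant-specific sites (H3K4me1-style) and at
  promoters (H3K4me3-style), a gene-body elevation (MNase-style), and
  Gaussian observation noise (sd 0.1).

Negative-binomial counts (variance μ + μ²/k) are the standard
overdispersion model for tag-count replicates. Tag positions jitter by a
geometric magnitude (p = 0.7, capped at ±5 bp), and planted sites are kept
≥ 31 bp apart (merge gap 20 + 2 × jitter cap 5 + 1) so each planted site
forms exactly one ≤ 20 bp cluster by construction. All randomness flows
from one mandatory seed through spawned child generators; same seed gives
byte-identical output bundles. The default chromosome length (250 kb)
leaves packing headroom for unlucky gene-length draws at 100
genes/chromosome.

What the generator does **not** emulate: promoter shape diversity
(broad/sharp cluster architecture), mapping artifacts, sequence content
and motif structure, genome-scale feature density, UTR annotation, or
correlated biological replicate noise. Passing recovery tests therefore
demonstrates the correctness of the calling/annotation/classification
logic under the stated statistical model, not performance on real
libraries.

## Problem sizes and numerical choices

The test suite and acceptance script run the reference condition (200
genes, ~260 clusters) for end-to-end recovery, a 250-gene/100%-planted
condition for the enrichment contrast (200 anchors per set), 500–1000
random fixtures for the rule oracles, and 2000 null simulations at
n = 50/50 for rank-sum calibration. Aggregation oracles compare at
tolerance 1e−9. Degenerate inputs raise (`ValueError`) rather than
silently recovering: zero-tag score intervals, genotypes with fewer
libraries than the support rule needs, empty contrast gene sets,
zero-total CPM libraries, empty boxplot input.

## Known limitations

* One gene model per gene; isoform-aware UTR arbitration is out of scope.
* The caller reimplements the stated support/merge/score rules directly;
  it does not reproduce pooled-TPM thresholding or decomposition features
  of tag-clustering frameworks built on the same ideas, so cluster counts
  on real data may differ from pipelines using those extras.
* CPM pseudocount and the promoter-window reading (201 bp) are documented
  choices where the source is silent or ambiguous; both are configurable
  or centralized.
* bedGraph ingestion materializes per-base maps; genome-scale
  (100 Mb+) tracks would want a block-compressed backend, which the
  pipeline deliberately does not require.
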