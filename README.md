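# tsscall

Genome-wide transcription start site (TSS) analysis for stranded 5′-tag
sequencing data (TSS-seq / 5′-CAP-seq), built for genotype-contrast studies
of intragenic transcription initiation — e.g. wild-type plants versus
mutants of the FACT histone chaperone complex (*spt16*, *ssrp1*), where loss
of FACT derepresses thousands of TSSs inside gene bodies.

## What it does

Given per-library stranded per-base 5′-tag count tracks (bedGraph), gene
models (GFF3), and optional CAGE peak summits and chromatin signal tracks,
the pipeline:

1. **Calls TSS clusters.** A base is a TSS candidate for genotype *g* when
   it carries ≥ 2 tags in ≥ 2 libraries of *g*. Candidate positions (union
   over genotypes) separated by ≤ 20 bp merge into clusters. Each cluster
   gets a *score* (total tags / number of libraries), a *summit* (base with
   maximal pooled count, leftmost on ties), and per-genotype detection
   flags.
2. **Annotates clusters** against derived features — promoter
   `[g−100, g+100]` and proximal `[g−500, g−100)` windows around each
   gene's 5′ end *g*, exons, introns, UTRs, antisense gene spans — with
   conflicts resolved by the fixed priority
   `intergenic < antisense < intron < exon < threeUTR < fiveUTR < proximal < promoter`,
   and assigns the nearest same-strand gene within 500 bp.
3. **Classifies clusters** by genotype contrast: *basal* (wild type and
   ≥ 1 mutant), *wt_specific* (wild type only), *fact_specific* (≥ 1 mutant
   but not wild type); and computes category/annotation summaries, the
   per-mutant Venn overlap of intragenic fact-specific clusters, and CAGE
   summit overlap fractions.
4. **Quantifies expression** per cluster (CPM against genome-wide library
   totals, `log2(CPM + 1)`), replicate Pearson concordance, and the
   promoter-expression-ratio contrast (mutant/wild-type log2 ratios at
   canonical promoters, genes with vs. without fact-specific TSSs, Wilcoxon
   rank-sum).
5. **Profiles chromatin signal** around TSS anchor sets: 20 bp
   window-median boxplot statistics (quartile hinges, 1.5·IQR whiskers),
   400 bp metagene profiles with normal-based 95% confidence bands, seeded
   exonic control-position sampling (with a 200 bp gene-end exclusion for
   run-on-style assays), and single-end read resizing to half the insert
   size.

A fully seeded synthetic-study generator (`tsscall.simulate`) plants known
promoter and mutant-specific intragenic TSSs with negative-binomial tag
counts, sub-threshold singleton noise, and H3K4me1/H3K4me3/MNase-style
signal tracks, and scores recovery of the planted truth — so every stage is
testable end to end without external data.

## Worked example

```python
import tsscall as t

bundle = t.simulate(t.SimulationConfig(seed=42))      # 200 genes, 2 reps x 3 genotypes
clusters = t.call_tss(bundle.libraries)
features = t.build_feature_set(bundle.genes)
t.annotate_clusters(clusters, features)
t.classify_clusters(clusters)

print(len(clusters))                        # 261
print(t.summarize(clusters).to_dict())
# {'counts': {'basal': 200, 'wt_specific': 0, 'fact_specific': 61},
#  'percentages': {'basal': 76.6, 'wt_specific': 0.0, 'fact_specific': 23.4},
#  'total': 261, 'fold_ratios': {}}

report = t.score_recovery(clusters, bundle.truth, libraries=bundle.libraries)
print(report.to_dict())
# {'recall_by_kind': {'promoter': 1.0, 'fact_specific_exonic': 1.0,
#                     'fact_specific_intronic': 1.0},
#  'overall_precision': 1.0, 'category_agreement': 1.0,
#  'n_noise_clusters': 0, ...}
```

All 200 planted promoters are recovered as basal clusters, all 61 planted
mutant-specific intragenic TSSs as fact-specific clusters (55 exonic, 6
intronic), and none of the ~470 singleton noise tags produces a cluster —
the support rule rejects them by construction.

The same analysis runs from the shell:

```bash
tsscall simulate --outdir data --seed 42
tsscall call-tss --manifest data/manifest.tsv --out clusters.tsv
tsscall run-all --config config.yaml     # full pipeline from a YAML config
```

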