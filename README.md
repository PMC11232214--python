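# norfnet

Coexpression-network inference and genomic-context analysis for lowly
expressed **noncanonical ORFs** (nORFs) — the unannotated, often
species-specific open reading frames that standard coexpression pipelines
drop because they are detected in only a fraction of RNA-seq samples.

The package is aimed at computational biologists studying de novo gene
birth and nORF function in yeast-like compendia. It implements a pipeline
that keeps sparse ORFs in the analysis instead of discarding them:

1. **Detection masking.** Raw counts below 5 are treated as missing, not
   zero; every downstream statistic is pairwise-complete over the samples
   where both ORFs are detected.
2. **clr + proportionality.** Counts are centered-log-ratio transformed per
   sample over detected entries, and association is measured with the
   proportionality statistic

   ρ(x, y) = 2·cov(aₓ, a_y) / (var(aₓ) + var(a_y)) = 1 − var(aₓ − a_y) / (var(aₓ) + var(a_y)),

   which is composition-aware and rewards equal-magnitude covariation.
3. **Spatial quantile normalization (SpQN).** Raw ρ distributions drift
   with expression level; ORFs are binned into expression strata by mean
   clr and each stratum-pair's ρ distribution is quantile-mapped onto the
   highest-expression bin, removing the mean-expression bias while
   preserving within-bin ranks.
4. **Network + null model.** The top 0.2% of ρ values (or a threshold
   covering 90% of canonical ORFs) defines a network; topology is compared
   against degree-preserving randomizations that rewire only
   noncanonical-incident edges.
5. **Modules and function.** Soft-threshold power β=12, topological
   overlap, Ward clustering with a branch cut, per-cluster Fisher GO
   enrichment, per-ORF preranked GSEA on ρ profiles, neighbor-voting AUROC,
   and Schlicker-Relevance GO similarity.
6. **Piggybacking.** De novo ORFs are classified by orientation relative to
   their nearest conserved neighbor (≤500 bp): down same / up same /
   up opposite can inherit transcription (shared promoter or readthrough);
   down opposite / antisense overlap cannot. Promoter sharing is called
   from transcript-isoform (TIF) coverage, terminator interruption from
   Pcf11/Nrd1-type binding in the intergenic gap, and the groups are
   contrasted with Cliff's delta and Mann-Whitney tests.

A first-class synthetic-data generator (`norfnet.synthetic`) emulates the
statistical structure this analysis assumes — two expression strata with
conditional detection, planted modules including noncanonical-majority
ones, neighbor pairs in all five orientations with readthrough-coupled
expression, TIFs with and without terminator interruption, binding tracks,
a module-aligned GO DAG and a DE table — with every planted fact recorded
in a ground-truth object, so each stage can be validated exactly.

## Worked example

```sh
python examples/02_coexpression_network.py
```

```
rho threshold (top 0.2% of pairs): 0.958
network: 70 ORFs, 88 edges
observed transitivity: 0.281
null transitivity:     0.108 (mean of 100 degree-preserving randomizations)
noncanonical ORFs with a canonical partner: 0.78
```

The threshold is the empirical 99.8th percentile of all pairwise ρ values;
the 88 edges are the pairs above it. Observed transitivity (0.281) well
above the degree-preserving null (0.108) shows the network's clustering is
real structure, not a degree-sequence artifact; 78% of noncanonical nodes
have at least one canonical partner, the property that lets function be
transferred to unannotated ORFs.

`examples/03_modules_and_function.py` continues the chain (module
recovery ARI 1.00 against the planted truth, neighbor-voting AUROC 0.995)
and `examples/04_piggybacking.py` runs the genomic-context analysis
(promoter-sharing down-same pairs: median neighbor-ρ 0.963 vs 0.577 for
terminator-interrupted pairs; Cliff's delta 1.00, Mann-Whitney
p = 1.1e-5).

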