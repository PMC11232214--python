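"""End-to-end orchestration: simulate (or load) inputs, run every analysis
stage, and write the artifact directory with a provenance manifest.

Stage order mirrors the analysis workflow: counts -> detection filter ->
clr -> proportionality -> spatial quantile normalization -> threshold ->
network (+ degree-preserving null) -> TOM clustering + cluster enrichment ->
per-ORF GSEA -> prevalence -> genomic context -> piggybacking. Each stage
reads only the previous stage's in-memory results, and every file the run
writes is checksummed into ``manifest.json`` together with the seed and
configuration, so identical configurations produce identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .context import classify_orientation, piggyback_analysis
from .enrichment import (GeneSetAnnotation, enriched_terms, gsea_preranked,
                         neighbor_voting, prevalence_comparison)
from .expression import CountMatrix, clr_transform, detection_filter, median_tpm
from .modules import (adjacency_power, cluster_go_enrichment, cluster_tom,
                      tom_similarity)
from .network import build_network, null_summaries
from .proportionality import (SpqnConfig, coverage_threshold,
                              percentile_threshold, rho_matrix, spqn_normalize)
from .synthetic import SimConfig, simulate


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the published analysis settings.

    Runs on synthetic data typically scale down ``min_samples`` and
    ``min_shared`` together with the simulated sample count.
    """

    seed: int = 0
    min_count: int = 5
    min_samples: int = 400
    min_shared: int = 400
    spqn_groups: int = 10
    spqn_quantile_points: int = 1000
    threshold_rule: str = "percentile"       # percentile | coverage
    top_fraction: float = 0.002
    coverage: float = 0.90
    beta: int = 12
    min_cluster_size: int = 20
    cut_height_fraction: float = 0.5
    gsea_n_perm: int = 2000
    gsea_fdr: float = 0.01
    prevalence_fdr: float = 0.001
    prevalence_ratio: float = 2.0
    orientation_max_dist: int = 500
    tf_window: int = 200
    de_lfc_cut: float = 0.5
    de_padj_cut: float = 0.05
    n_random_networks: int = 1000
    sim: SimConfig = field(default_factory=SimConfig)


@dataclass
class PipelineResult:
    config: PipelineConfig
    sim: object
    count_matrix: CountMatrix
    clr: object
    coex_raw: object
    coex: object
    threshold: object
    graph: object
    null: object
    clusters: object
    cluster_enrichment: pd.DataFrame
    gsea: dict
    enriched: dict
    prevalence: pd.DataFrame
    voting: pd.DataFrame
    orientations: list
    piggyback: pd.DataFrame
    contrasts: dict
    tpm: pd.Series


def run_all(config: PipelineConfig, outdir=None,
            run_null: bool = True) -> PipelineResult:
    """Execute every stage on a synthetic study defined by ``config.sim``."""
    config.sim.seed = config.sim.seed or config.seed
    sim = simulate(config.sim)
    classes = sim.annotation.set_index("orf_id")["orf_class"]

    cm = CountMatrix.from_annotation(sim.counts, sim.annotation)
    cm = detection_filter(cm, config.min_count, config.min_samples)
    clr = clr_transform(cm, config.min_count)
    coex_raw = rho_matrix(clr, min_shared=config.min_shared)
    # stratum count is capped so each expression bin holds >= ~60 ORFs:
    # quantile mapping against a reference bin with only a few hundred
    # pairs is dominated by sampling noise in the bin's tail
    n_groups = max(2, min(config.spqn_groups,
                          coex_raw.rho.shape[0] // 60))
    coex = spqn_normalize(
        coex_raw, clr.mean_clr,
        SpqnConfig(n_groups=n_groups,
                   n_quantile_points=config.spqn_quantile_points))

    if config.threshold_rule == "coverage":
        thr = coverage_threshold(coex, classes, config.coverage)
    else:
        thr = percentile_threshold(coex, config.top_fraction)
    graph = build_network(coex, thr, classes)
    null = null_summaries(graph, n=config.n_random_networks,
                          seed=config.seed) if run_null else None

    tom = tom_similarity(adjacency_power(coex, beta=config.beta))
    clusters = cluster_tom(tom, config.min_cluster_size,
                           config.cut_height_fraction)
    anno = GeneSetAnnotation(
        {t: info["is_a"] for t, info in sim.ontology_terms.items()},
        sim.term_annotations)
    cluster_enr = cluster_go_enrichment(clusters, classes,
                                        anno.genesets(min_size=2))

    genesets = anno.genesets(min_size=2)
    gsea = {}
    rho = coex.rho
    for orf in rho.index:
        scores = rho.loc[orf].drop(orf)
        gsea[orf] = gsea_preranked(scores, genesets,
                                   n_perm=config.gsea_n_perm,
                                   seed=config.seed, fdr=config.gsea_fdr)
    enriched = enriched_terms(gsea, fdr=config.gsea_fdr)
    prevalence = prevalence_comparison(enriched, classes,
                                       fdr_out=config.prevalence_fdr,
                                       ratio_cut=config.prevalence_ratio)
    voting = neighbor_voting(rho.clip(lower=0).fillna(0.0),
                             sim.truth.module_sets(),
                             size_range=(3, 1000), folds=3, seed=config.seed)

    tpm_med = median_tpm(CountMatrix.from_annotation(sim.counts,
                                                     sim.annotation))
    ann = sim.annotation
    orientations = classify_orientation(ann, config.orientation_max_dist)
    piggy, contrasts = piggyback_analysis(
        orientations, ann, coex, tpm_med, sim.tifs, sim.terminators,
        enriched=enriched, anno=anno)

    result = PipelineResult(config, sim, cm, clr, coex_raw, coex, thr, graph,
                            null, clusters, cluster_enr, gsea, enriched,
                            prevalence, voting, orientations, piggy,
                            contrasts, tpm_med)
    if outdir is not None:
        write_artifacts(result, outdir)
    return result


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_artifacts(result: PipelineResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.sim.write(out / "inputs")
    result.clr.values.to_csv(out / "clr.tsv", sep="\t")
    result.coex.to_long().to_csv(out / "coexpression.tsv", sep="\t",
                                 index=False)
    edges = pd.DataFrame(
        [(u, v, d.get("rho")) for u, v, d in result.graph.edges(data=True)],
        columns=["orf1", "orf2", "rho"])
    edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    result.clusters.labels.to_csv(out / "clusters.tsv", sep="\t")
    result.cluster_enrichment.to_csv(out / "cluster_enrichment.tsv",
                                     sep="\t", index=False)
    result.prevalence.to_csv(out / "prevalence.tsv", sep="\t", index=False)
    result.voting.to_csv(out / "neighbor_voting.tsv", sep="\t", index=False)
    result.piggyback.to_csv(out / "piggyback.tsv", sep="\t", index=False)
    nio.write_json(result.contrasts, out / "contrasts.json")

    cfg = asdict(result.config)
    files = sorted(p for p in out.rglob("*") if p.is_file()
                   and p.name != "manifest.json")
    manifest = {
        "seed": result.config.seed,
        "config": json.loads(json.dumps(cfg, default=str)),
        "threshold": {"value": result.threshold.threshold,
                      "rule": result.threshold.rule},
        "n_nodes": result.graph.number_of_nodes(),
        "n_edges": result.graph.number_of_edges(),
        "checksums": {str(p.relative_to(out)): _checksum(p) for p in files},
    }
    nio.write_json(manifest, out / "manifest.json")
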