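"""Function-level analyses on the coexpression matrix: per-ORF preranked
gene-set enrichment, canonical-vs-noncanonical term prevalence,
neighbor-voting function prediction, GO semantic similarity (Relevance with
best-match averaging), and the transmembrane / TF-target contingency
analyses.

The GSEA here is the classic weighted Kolmogorov-Smirnov running sum with
weight exponent 1: annotated ORFs are ranked by their proportionality to the
query ORF, hits advance the sum proportionally to |rho| and misses retreat
it by 1/(N - n). Significance comes from gene-label permutations (random
sets of the same size drawn from the ranked list), with the p-value floored
at 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .stats import bh_adjust, fisher_exact
from . import io as nio

__all__ = [
    "GeneSetAnnotation", "gsea_preranked", "enriched_terms",
    "prevalence_comparison", "neighbor_voting",
    "relevance_similarity", "go_relevance_similarity",
    "tm_transport_enrichment", "tf_target_analysis",
]


# ---------------------------------------------------------------------------
# ontology container

@dataclass
class GeneSetAnnotation:
    """A term DAG with gene annotations propagated to ancestors.

    ``parents`` maps term -> list of parent terms; ``direct`` maps term ->
    directly annotated genes. Propagated sets, term probabilities
    p(t) = |genes at t or below| / |all annotated genes| and information
    content IC(t) = -ln p(t) are computed once at construction.
    """

    parents: dict
    direct: dict
    annotated: dict = field(init=False)
    p: dict = field(init=False)
    ic: dict = field(init=False)

    def __post_init__(self):
        terms = set(self.parents) | {p for ps in self.parents.values()
                                     for p in ps} | set(self.direct)
        self.parents = {t: list(self.parents.get(t, [])) for t in terms}
        anc_cache: dict[str, frozenset] = {}

        def ancestors(t):
            if t not in anc_cache:
                acc = {t}
                for p in self.parents[t]:
                    acc |= ancestors(p)
                anc_cache[t] = frozenset(acc)
            return anc_cache[t]

        self._ancestors = ancestors
        annotated = {t: set() for t in terms}
        universe: set = set()
        for t, genes in self.direct.items():
            universe |= set(genes)
            for a in ancestors(t):
                annotated[a] |= set(genes)
        self.annotated = annotated
        n_tot = max(len(universe), 1)
        self.p = {t: len(g) / n_tot for t, g in annotated.items()}
        self.ic = {t: -np.log(p) if p > 0 else float("inf")
                   for t, p in self.p.items()}

    @classmethod
    def from_obo(cls, obo_path, gaf_path) -> "GeneSetAnnotation":
        import obonet
        g = obonet.read_obo(obo_path)
        parents = {}
        for node in g.nodes:
            parents[node] = [v for _, v, k in g.out_edges(node, keys=True)
                             if k == "is_a"]
        return cls(parents, nio.read_gaf(gaf_path))

    def ancestors(self, term):
        return self._ancestors(term)

    def genesets(self, min_size: int = 1, max_size: int | None = None) -> dict:
        out = {}
        for t, g in self.annotated.items():
            if len(g) >= min_size and (max_size is None or len(g) <= max_size):
                out[t] = set(g)
        return out


# ---------------------------------------------------------------------------
# preranked GSEA

def _es_from_positions(pos: np.ndarray, w: np.ndarray, n_total: int):
    """Signed enrichment score for sorted hit positions.

    ``pos`` has shape (..., n) with positions sorted ascending along the
    last axis; ``w`` are the |score| weights of the full ranked list.
    """
    n = pos.shape[-1]
    wh = w[pos]
    tot = wh.sum(axis=-1, keepdims=True)
    # degenerate all-zero weights: fall back to unweighted hits
    wh = np.where(tot > 0, wh, 1.0)
    tot = np.where(tot > 0, tot, float(n))
    p_hit = np.cumsum(wh, axis=-1) / tot
    idx = np.arange(n)
    p_miss = (pos - idx) / (n_total - n)          # misses strictly before hit
    dev_hi = p_hit - p_miss
    prev = np.concatenate(
        [np.zeros(p_hit.shape[:-1] + (1,)), p_hit[..., :-1]], axis=-1)
    dev_lo = prev - p_miss
    hi = dev_hi.max(axis=-1)
    lo = dev_lo.min(axis=-1)
    return np.where(hi >= -lo, hi, lo)


def gsea_preranked(scores: pd.Series, genesets: dict, n_perm: int = 10000,
                   seed: int = 0, fdr: float = 0.01) -> pd.DataFrame:
    """Preranked GSEA of one ranked profile against a geneset collection.

    ``scores`` maps gene -> ranking score (e.g. rho to the query ORF; the
    query itself must not be in the index). NaN scores are dropped; ties
    are broken by gene id so results are deterministic. Terms with zero
    overlap or covering the whole list are skipped.
    """
    s = scores.dropna()
    order = sorted(s.index, key=lambda g: (-s[g], g))
    ranked = np.array([s[g] for g in order])
    w = np.abs(ranked)
    pos_of = {g: i for i, g in enumerate(order)}
    n_total = len(order)
    if n_total < 2:
        return pd.DataFrame(columns=["term", "es", "nes", "p", "fdr",
                                     "n_hits", "significant"])
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}

    rows = []
    for term in sorted(genesets):
        hits = sorted(set(genesets[term]) & set(order))
        n = len(hits)
        if n == 0 or n >= n_total:
            continue
        pos = np.sort(np.array([pos_of[g] for g in hits]))
        es = float(_es_from_positions(pos, w, n_total))
        if n not in null_cache:
            u = rng.random((n_perm, n_total))
            perm = np.argpartition(u, n - 1, axis=1)[:, :n] if n < n_total \
                else np.tile(np.arange(n_total), (n_perm, 1))
            null_cache[n] = _es_from_positions(np.sort(perm, axis=1),
                                               w, n_total)
        null = null_cache[n]
        if es >= 0:
            side = null[null >= 0]
            p = (1 + np.sum(side >= es)) / (1 + side.size)
        else:
            side = null[null < 0]
            p = (1 + np.sum(side <= es)) / (1 + side.size)
        denom = np.abs(side).mean() if side.size else float("nan")
        nes = es / denom if denom and denom > 0 else float("nan")
        leading = int(np.argmax(np.abs(
            np.atleast_1d(_running_extreme(pos, w, n_total)))) + 1)
        rows.append({"term": term, "es": es, "nes": nes, "p": float(p),
                     "n_hits": n, "leading_edge": leading})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["fdr"] = bh_adjust(df["p"])
        df["significant"] = df["fdr"] < fdr
    return df


def _running_extreme(pos, w, n_total):
    """Per-hit deviation profile (for leading-edge size)."""
    n = pos.size
    wh = w[pos]
    tot = wh.sum() or float(n)
    p_hit = np.cumsum(wh if wh.sum() > 0 else np.ones(n)) / tot
    p_miss = (pos - np.arange(n)) / (n_total - n)
    return p_hit - p_miss


def enriched_terms(gsea_tables: dict, fdr: float = 0.01) -> dict:
    """orf -> set of terms significant at BH FDR < ``fdr``.

    ``gsea_tables`` maps orf -> the DataFrame from :func:`gsea_preranked`.
    """
    out = {}
    for orf, df in gsea_tables.items():
        if df.empty:
            out[orf] = set()
        else:
            out[orf] = set(df.loc[df["fdr"] < fdr, "term"])
    return out


# ---------------------------------------------------------------------------
# prevalence of enrichments across ORF classes

def prevalence_comparison(enriched: dict, classes: pd.Series,
                          fdr_out: float = 0.001,
                          ratio_cut: float = 2.0) -> pd.DataFrame:
    """Which terms are over-represented among noncanonical enrichments?

    ``enriched`` maps orf -> set of significantly enriched terms. Per term
    a Fisher test compares enriched/not across the two classes; the
    proportion ratio divides the noncanonical proportion by the canonical
    one. Terms pass when BH FDR < ``fdr_out`` and the ratio exceeds
    ``ratio_cut`` (noncanonical-enriched) or falls below 1/ratio_cut.
    """
    orfs = list(enriched)
    cls = classes.reindex(orfs)
    non = [o for o in orfs if cls[o] == "noncanonical"]
    can = [o for o in orfs if cls[o] == "canonical"]
    all_terms = sorted({t for s in enriched.values() for t in s})
    rows = []
    for term in all_terms:
        k_n = sum(term in enriched[o] for o in non)
        k_c = sum(term in enriched[o] for o in can)
        res = fisher_exact([[k_n, len(non) - k_n],
                            [k_c, len(can) - k_c]])
        prop_n = k_n / len(non) if non else float("nan")
        prop_c = k_c / len(can) if can else float("nan")
        if prop_c > 0:
            ratio = prop_n / prop_c
        else:
            ratio = float("inf") if prop_n > 0 else float("nan")
        rows.append({"term": term, "n_noncanonical": k_n,
                     "total_noncanonical": len(non),
                     "n_canonical": k_c, "total_canonical": len(can),
                     "proportion_ratio": ratio, "odds_ratio": res.value,
                     "p": res.p})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["fdr"] = bh_adjust(df["p"])
        df["noncanonical_enriched"] = (df["fdr"] < fdr_out) & \
            (df["proportion_ratio"] > ratio_cut)
        df["noncanonical_depleted"] = (df["fdr"] < fdr_out) & \
            (df["proportion_ratio"] < 1.0 / ratio_cut)
    return df


# ---------------------------------------------------------------------------
# neighbor voting

def neighbor_voting(weights: pd.DataFrame, genesets: dict,
                    size_range: tuple = (20, 1000), folds: int = 3,
                    seed: int = 0) -> pd.DataFrame:
    """Guilt-by-association prediction scored by cross-validated AUROC.

    For each term of in-range size, gene labels are hidden fold by fold;
    a hidden gene's score is the weight-normalized sum of its training
    neighbors' labels, and the fold AUROC separates hidden positives from
    hidden negatives.
    """
    W = weights.to_numpy(dtype=float)
    if not np.allclose(W, W.T):
        raise ValueError("weights must be symmetric")
    if np.nanmin(W) < 0:
        raise ValueError("weights must be nonnegative")
    W = np.nan_to_num(W)
    np.fill_diagonal(W, 0.0)
    genes = weights.index
    rng = np.random.default_rng(seed)
    rows = []
    for term in sorted(genesets):
        members = set(genesets[term]) & set(genes)
        if not (size_range[0] <= len(members) <= size_range[1]):
            continue
        y = np.asarray(genes.isin(members), dtype=float)
        fold_of = rng.permutation(len(genes)) % folds
        aurocs = []
        for f in range(folds):
            test = fold_of == f
            train = ~test
            denom = W[np.ix_(test, train)].sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                score = W[np.ix_(test, train)] @ y[train] / denom
            score = np.nan_to_num(score)
            y_test = y[test]
            if y_test.min() == y_test.max():
                continue
            aurocs.append(roc_auc_score(y_test, score))
        rows.append({"term": term, "n_genes": len(members),
                     "fold_aurocs": aurocs,
                     "mean_auroc": float(np.mean(aurocs)) if aurocs
                     else float("nan")})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GO semantic similarity (Relevance + best-match average)

def relevance_similarity(t1: str, t2: str, anno: GeneSetAnnotation) -> float:
    """Schlicker Relevance similarity of two terms.

    sim(t1,t2) = max over common ancestors a of
    [2 IC(a) / (IC(t1) + IC(t2))] * (1 - p(a)); 0 when only the root is
    shared (IC(root) = 0).
    """
    common = anno.ancestors(t1) & anno.ancestors(t2)
    if not common:
        return float("nan")
    denom = anno.ic[t1] + anno.ic[t2]
    if denom == 0 or not np.isfinite(denom):
        return 0.0
    best = 0.0
    for a in common:
        ic = anno.ic[a]
        if np.isfinite(ic):
            best = max(best, (2.0 * ic / denom) * (1.0 - anno.p[a]))
    return float(best)


def go_relevance_similarity(terms_a, terms_b,
                            anno: GeneSetAnnotation) -> float:
    """Best-match-average Relevance similarity of two term sets.

    Mean of the row maxima and column maxima of the pairwise similarity
    matrix; NaN when either set is empty.
    """
    ta = [t for t in terms_a if t in anno.ic]
    tb = [t for t in terms_b if t in anno.ic]
    if not ta or not tb:
        return float("nan")
    M = np.array([[relevance_similarity(a, b, anno) for b in tb] for a in ta])
    return float((np.nanmax(M, axis=1).mean()
                  + np.nanmax(M, axis=0).mean()) / 2.0)


# ---------------------------------------------------------------------------
# downstream contingency analyses

def tm_transport_enrichment(enriched: dict, tm_flags: pd.Series,
                            transport_terms) -> dict:
    """Are transport-coexpressed noncanonical ORFs enriched for TM domains?

    An ORF counts as transport-coexpressed if any listed transport term is
    among its enriched terms; the association with having at least one
    predicted transmembrane domain is a Fisher exact test.
    """
    transport = set(transport_terms)
    orfs = [o for o in enriched if o in tm_flags.index]
    coex = {o: bool(enriched[o] & transport) for o in orfs}
    tm = {o: bool(tm_flags[o]) for o in orfs}
    a = sum(coex[o] and tm[o] for o in orfs)
    b = sum(coex[o] and not tm[o] for o in orfs)
    c = sum((not coex[o]) and tm[o] for o in orfs)
    d = sum((not coex[o]) and not tm[o] for o in orfs)
    if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
        return {"table": [[a, b], [c, d]], "odds_ratio": float("nan"),
                "p": float("nan")}
    res = fisher_exact([[a, b], [c, d]])
    return {"table": [[a, b], [c, d]], "odds_ratio": res.value, "p": res.p,
            "ci": (res.ci_low, res.ci_high)}


def tf_target_analysis(bound: pd.Series, de_table: pd.DataFrame,
                       enriched: dict, classes: pd.Series,
                       lfc_cut: float = 0.5, padj_cut: float = 0.05,
                       fdr: float = 0.05) -> dict:
    """TF-target classification plus the two association tests.

    A gene is differentially expressed when |lfc| > ``lfc_cut`` and
    padj < ``padj_cut``; a TF target when additionally bound and
    downregulated (lfc < -lfc_cut). Reports the bound x downregulated
    Fisher association per ORF class and, for noncanonical ORFs, a per-term
    Fisher test of targets vs non-targets being enriched in the term.
    """
    de = de_table.set_index("orf_id")
    if not {"lfc", "padj"} <= set(de.columns):
        raise ValueError("de_table needs columns orf_id, lfc, padj")
    orfs = de.index
    down = (de["lfc"] < -lfc_cut) & (de["padj"] < padj_cut)
    is_bound = bound.reindex(orfs).fillna(False).astype(bool)
    targets = sorted(orfs[down & is_bound])

    association = {}
    cls = classes.reindex(orfs)
    for c in ("canonical", "noncanonical"):
        sel = cls == c
        a = int((is_bound & down & sel).sum())
        b = int((is_bound & ~down & sel).sum())
        cc = int((~is_bound & down & sel).sum())
        d = int((~is_bound & ~down & sel).sum())
        res = fisher_exact([[a, b], [cc, d]])
        association[c] = {"table": [[a, b], [cc, d]],
                          "odds_ratio": res.value, "p": res.p}

    target_set = set(targets)
    non_orfs = [o for o in enriched
                if classes.get(o) == "noncanonical" and o in set(orfs)]
    terms = sorted({t for o in non_orfs for t in enriched[o]})
    rows = []
    for term in terms:
        a = sum(o in target_set and term in enriched[o] for o in non_orfs)
        b = sum(o in target_set and term not in enriched[o] for o in non_orfs)
        c2 = sum(o not in target_set and term in enriched[o] for o in non_orfs)
        d = sum(o not in target_set and term not in enriched[o]
                for o in non_orfs)
        res = fisher_exact([[a, b], [c2, d]])
        rows.append({"term": term, "table": [[a, b], [c2, d]],
                     "odds_ratio": res.value, "p": res.p})
    per_term = pd.DataFrame(rows)
    if not per_term.empty:
        per_term["fdr"] = bh_adjust(per_term["p"])
        per_term["significant"] = per_term["fdr"] < fdr
    return {"targets": targets, "association": association,
            "per_term": per_term}
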