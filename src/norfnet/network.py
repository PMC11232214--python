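"""Coexpression-network construction, topology metrics, and the
class-constrained degree-preserving null model.

The null model rewires only edges that touch a noncanonical ORF: two such
edges (a,b), (c,d) are repeatedly chosen and their endpoints exchanged to
(a,d), (c,b). A proposal is rejected if it would create a self-loop, a
duplicate edge, or a canonical-canonical edge (the canonical subnetwork is
held fixed). Double edge swaps preserve every node's degree exactly, so no
node can be disconnected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .proportionality import CoexpressionMatrix, ThresholdResult

__all__ = [
    "NullEnsemble", "build_network", "topology_metrics",
    "randomize_network", "null_summaries", "fraction_attached",
]


def build_network(coex: CoexpressionMatrix, thr: ThresholdResult,
                  classes: pd.Series | None = None) -> nx.Graph:
    """Threshold the coexpression matrix into a simple undirected graph.

    Nodes are ORFs with at least one passing pair (isolated ORFs are not
    included); each node carries its ORF class when ``classes`` is given.
    """
    R = coex.rho.to_numpy()
    ids = coex.orf_ids.to_numpy()
    iu, ju = np.triu_indices(len(ids), k=1)
    vals = R[iu, ju]
    ok = ~np.isnan(vals)
    ok[ok] = thr.passes(vals[ok])
    g = nx.Graph(threshold=thr.threshold, rule=thr.rule)
    for i, j, r in zip(iu[ok], ju[ok], vals[ok]):
        g.add_edge(ids[i], ids[j], rho=float(r))
    if classes is not None:
        nx.set_node_attributes(
            g, {n: classes.get(n, "canonical") for n in g}, "orf_class")
    return g


def topology_metrics(g: nx.Graph):
    """Degree map, diameter and global transitivity.

    The diameter of a disconnected graph is the maximum diameter over its
    connected components; both metrics are None on an empty graph.
    """
    degree = dict(g.degree())
    if g.number_of_edges() == 0:
        return degree, None, None
    diameter = max(nx.diameter(g.subgraph(c))
                   for c in nx.connected_components(g))
    return degree, int(diameter), float(nx.transitivity(g))


def _is_canonical(g: nx.Graph, n) -> bool:
    return g.nodes[n].get("orf_class", "canonical") == "canonical"


def randomize_network(g: nx.Graph, n_swap_factor: int = 10,
                      seed: int | np.random.Generator = 0) -> nx.Graph:
    """Degree-preserving randomization of the noncanonical edges.

    Attempts ``n_swap_factor * |E|`` double-edge swaps over the swappable
    edge set (edges with at least one noncanonical endpoint). Returns a new
    graph; the input is untouched.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    out = g.copy()
    swappable = [tuple(e) for e in out.edges
                 if not (_is_canonical(out, e[0]) and _is_canonical(out, e[1]))]
    if len(swappable) < 2:
        warnings.warn("fewer than 2 swappable edges; returning a copy")
        return out
    n_attempts = n_swap_factor * out.number_of_edges()
    edges = swappable  # mutated in place as swaps are accepted
    for _ in range(n_attempts):
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        # randomly orient the second edge so both pairings are reachable
        if rng.random() < 0.5:
            c, d = d, c
        # proposed new edges (a,d) and (c,b)
        if a == d or c == b:
            continue
        if out.has_edge(a, d) or out.has_edge(c, b):
            continue
        if (_is_canonical(out, a) and _is_canonical(out, d)) or \
                (_is_canonical(out, c) and _is_canonical(out, b)):
            continue
        out.remove_edge(a, b)
        out.remove_edge(c, d)
        out.add_edge(a, d)
        out.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
    return out


def fraction_attached(g: nx.Graph) -> float:
    """Fraction of noncanonical nodes with >= 1 canonical partner."""
    non = [n for n in g if not _is_canonical(g, n)]
    if not non:
        return float("nan")
    hit = sum(any(_is_canonical(g, m) for m in g[n]) for n in non)
    return hit / len(non)


@dataclass
class NullEnsemble:
    observed: dict
    replicates: pd.DataFrame             # diameter, transitivity, attached
    p_values: dict
    n_replicates: int
    seed: int


def null_summaries(g: nx.Graph, n: int = 1000, seed: int = 0,
                   n_swap_factor: int = 10) -> NullEnsemble:
    """Observed vs degree-preserving-null topology summaries.

    For each replicate the network is re-randomized from the observed graph
    and its diameter, transitivity and fraction of noncanonical nodes with
    a canonical partner are recorded. Empirical two-sided rank p-values use
    the add-one rule (1 + #as-extreme) / (1 + n).
    """
    rng = np.random.default_rng(seed)
    _, diam, trans = topology_metrics(g)
    observed = {"diameter": diam, "transitivity": trans,
                "fraction_attached": fraction_attached(g)}
    rows = []
    for _ in range(n):
        r = randomize_network(g, n_swap_factor=n_swap_factor, seed=rng)
        _, d, t = topology_metrics(r)
        rows.append((d, t, fraction_attached(r)))
    reps = pd.DataFrame(rows, columns=["diameter", "transitivity",
                                       "fraction_attached"])
    pvals = {}
    for col in reps.columns:
        obs = observed[col]
        if obs is None or np.isnan(obs):
            pvals[col] = float("nan")
            continue
        null = reps[col].to_numpy(dtype=float)
        lo = (1 + np.sum(null <= obs)) / (1 + n)
        hi = (1 + np.sum(null >= obs)) / (1 + n)
        pvals[col] = float(min(1.0, 2 * min(lo, hi)))
    return NullEnsemble(observed, reps, pvals, n, seed)
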