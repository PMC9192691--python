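"""Protein-protein interaction graphs: Markov clustering and dense complexes.

Graphs are undirected, weighted (weights in (0, 1]), optionally restricted
to physical interactions. Two detection routines are provided:

* :func:`mcl_cluster` — Markov clustering by alternating expansion (matrix
  squaring) and inflation (elementwise power + column normalization) on the
  column-stochastic transition matrix with self-loops added.
* :func:`mcode` — molecular-complex detection: vertex weighting by the
  density of the densest k-core of the closed neighborhood times its core
  number, greedy outward complex growth from high-weight seeds, and a
  2-core/size-3 filter with haircut. Scores are density times node count.

Both are deterministic; ties are broken by node identifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from fxiselect.enrichment import GeneSetDB, enrich

logger = logging.getLogger(__name__)


@dataclass
class Complex:
    """A densely connected complex: node set, seed, density and score."""

    nodes: tuple[str, ...]
    seed: str
    density: float
    score: float  # density x node count

    def __len__(self) -> int:
        return len(self.nodes)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a TSV edge list: node_a, node_b[, weight[, physical]]."""
    return pd.read_csv(path, sep="\t")


def build_graph(
    edges: pd.DataFrame | str | Path, restrict_physical: bool = False
) -> nx.Graph:
    """Deduplicated undirected graph from an edge table.

    Self-loops and malformed rows are dropped with a logged count; repeated
    edges keep the maximum weight. With ``restrict_physical``, rows whose
    ``physical`` column is falsy are dropped.
    """
    if not isinstance(edges, pd.DataFrame):
        edges = read_edge_list(edges)
    if edges.shape[1] < 2:
        raise ValueError("edge table needs at least two endpoint columns")
    cols = list(edges.columns)
    w_idx = cols.index("weight") if "weight" in cols else None
    p_idx = cols.index("physical") if "physical" in cols else None
    g = nx.Graph()
    n_bad = n_self = 0
    for row in edges.itertuples(index=False, name=None):
        a, b = row[0], row[1]
        if pd.isna(a) or pd.isna(b):
            n_bad += 1
            continue
        a, b = str(a), str(b)
        if a == b:
            n_self += 1
            continue
        physical = bool(row[p_idx]) if p_idx is not None else True
        if restrict_physical and not physical:
            continue
        weight = float(row[w_idx]) if w_idx is not None else 1.0
        if not np.isfinite(weight) or weight <= 0:
            n_bad += 1
            continue
        if g.has_edge(a, b):
            g[a][b]["weight"] = max(g[a][b]["weight"], weight)
            g[a][b]["physical"] = g[a][b]["physical"] or physical
        else:
            g.add_edge(a, b, weight=weight, physical=physical)
    if n_bad or n_self:
        logger.info("dropped %d malformed rows, %d self-loops", n_bad, n_self)
    return g


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------


def _column_normalize(m: np.ndarray) -> np.ndarray:
    s = m.sum(axis=0)
    s[s == 0] = 1.0
    return m / s


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-8,
    self_loop_weight: float = 1.0,
    return_info: bool = False,
):
    """Markov clustering; returns node -> integer cluster label.

    Clusters are read off attractor rows of the converged matrix; labels
    are assigned in order of each cluster's smallest node id. With
    ``return_info`` a diagnostics dict (iterations, per-iteration column-sum
    deviation, convergence flag) is returned as a second value.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes())
    m = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    np.fill_diagonal(m, self_loop_weight)
    m = _column_normalize(m)
    deviations = []
    converged = False
    for it in range(max_iter):
        expanded = m @ m
        inflated = _column_normalize(expanded**inflation)
        deviations.append(float(np.max(np.abs(inflated.sum(axis=0) - 1.0))))
        diff = float(np.max(np.abs(inflated - m)))
        m = inflated
        if diff < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations", max_iter)

    thresh = 1e-6
    attractors = [i for i in range(len(nodes)) if m[i, i] > thresh]
    # union-find over attractor rows: overlapping supports merge
    parent = list(range(len(nodes)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    membership: dict[int, set[int]] = {}
    for i in attractors:
        membership[i] = {j for j in range(len(nodes)) if m[i, j] > thresh}
        union(i, i)
    for i in attractors:
        for j in attractors:
            if i < j and membership[i] & membership[j]:
                union(i, j)
    assigned: dict[int, int] = {}
    for i in attractors:
        root = find(i)
        for j in membership[i]:
            if j not in assigned or root < assigned[j]:
                assigned[j] = root
    # orphan nodes (numerically wiped out): attach to their strongest row
    for j in range(len(nodes)):
        if j not in assigned:
            i = int(np.argmax(m[:, j]))
            assigned[j] = find(i) if i in attractors else j
    roots = sorted(set(assigned.values()))
    relabel = {r: k for k, r in enumerate(roots)}
    labels = {nodes[j]: relabel[assigned[j]] for j in range(len(nodes))}
    if return_info:
        info = {
            "iterations": len(deviations),
            "converged": converged,
            "column_sum_deviation": deviations,
        }
        return labels, info
    return labels


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _node_weights(graph: nx.Graph, degree_cutoff: int) -> dict[str, float]:
    """Weight = core number of the densest k-core of the closed neighborhood,
    times that k-core's density (the core-clustering coefficient)."""
    weights = {}
    for v in graph.nodes():
        if graph.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = graph.subgraph(set(graph[v]) | {v})
        core = nx.core_number(nbhd)
        kmax = max(core.values())
        core_nodes = [u for u, c in core.items() if c >= kmax]
        weights[v] = kmax * _density(nbhd.subgraph(core_nodes))
    return weights


def mcode(
    graph: nx.Graph,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    max_depth: int = 100,
    haircut: bool = True,
) -> list[Complex]:
    """Molecular complex detection. Edge weights are ignored (topological).

    Returns complexes with >= 3 nodes, each containing a ``k_core``-core,
    sorted by descending score (density x size; ties by smallest node id).
    Node sets are pairwise disjoint (each node is used once).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    weights = _node_weights(graph, degree_cutoff)
    order = sorted(graph.nodes(), key=lambda v: (-weights[v], v))
    used: set[str] = set()
    complexes: list[Complex] = []
    for seed in order:
        if seed in used or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [(seed, 0)]
        while frontier:
            v, depth = frontier.pop(0)
            if depth >= max_depth:
                continue
            for u in sorted(graph[v]):
                if u in used or u in members:
                    continue
                if weights[u] >= threshold:
                    members.add(u)
                    frontier.append((u, depth + 1))
        used |= members
        sub = graph.subgraph(members)
        if haircut:
            sub = nx.k_core(sub, 2)
        if sub.number_of_nodes() < 3:
            continue
        if nx.k_core(sub, k_core).number_of_nodes() == 0:
            continue
        dens = _density(sub)
        complexes.append(
            Complex(
                nodes=tuple(sorted(sub.nodes())),
                seed=seed,
                density=dens,
                score=dens * sub.number_of_nodes(),
            )
        )
    complexes.sort(key=lambda c: (-c.score, c.nodes))
    return complexes


def label_complexes(
    complexes: list[Complex],
    db: GeneSetDB,
    background,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Label each complex with its lowest-p enriched gene set (p < alpha).

    Returns a frame with one row per complex: nodes, seed, score, label
    (None when no set reaches significance) and the label's p-value.
    """
    background = {str(g).upper() for g in background}
    rows = []
    for i, cx in enumerate(complexes):
        query = [n for n in cx.nodes if n.upper() in background]
        label, p = None, None
        if query:
            res = enrich(query, db, background, alpha=alpha)
            if len(res) and res.iloc[0]["significant"]:
                label = res.iloc[0]["set"]
                p = float(res.iloc[0]["p"])
        rows.append(
            {
                "complex": i,
                "nodes": ",".join(cx.nodes),
                "n_nodes": len(cx),
                "seed": cx.seed,
                "density": cx.density,
                "score": cx.score,
                "label": label,
                "label_p": p,
            }
        )
    return pd.DataFrame(rows)
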