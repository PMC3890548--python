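"""Markov Cluster (MCL) algorithm on weighted similarity graphs.

MCL simulates random walks on a graph: the column-stochastic transition
matrix is alternately squared (expansion — walks spread along paths) and
raised entrywise to the inflation power r with column renormalization
(inflation — strong transitions are strengthened, weak ones starved).
Iterating to a fixed point leaves a matrix whose attractor structure defines
the clusters. Higher inflation gives more, smaller clusters.

The implementation is sparse (scipy CSR) with threshold pruning after each
inflation step; results are deterministic for fixed parameters.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .similarity import SimilarityGraph
from .store import ClusterRun, PangenomeStore, canonical_families

__all__ = ["mcl", "mcl_partition", "cluster_stats", "singleton_completion"]


def _normalize_columns(m: sp.csc_matrix) -> sp.csc_matrix:
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    return m @ sp.diags(1.0 / sums)


def mcl_partition(
    nodes: list[str],
    weights: sp.spmatrix,
    inflation: float = 2.0,
    max_iter: int = 100,
    prune_threshold: float = 1e-5,
    tol: float = 1e-6,
) -> list[frozenset[str]]:
    """Run MCL on a symmetric weight matrix; return the node partition.

    Self-loops are set to each node's maximum incident edge weight (1 for
    isolated nodes) before normalization — standard preconditioning that
    damps oscillation between odd and even path lengths.
    """
    if inflation <= 1.0:
        raise ValueError(f"inflation must exceed 1, got {inflation}")
    n = len(nodes)
    if n == 0:
        raise ValueError("empty graph")
    w = sp.csr_matrix(weights, dtype=np.float64)
    if (abs(w - w.T) > 1e-12).nnz:
        raise ValueError("input matrix must be symmetric")
    w = w.tolil()
    maxw = np.asarray(w.tocsr().max(axis=0).todense()).ravel()
    for i in range(n):
        w[i, i] = maxw[i] if maxw[i] > 0 else 1.0
    m = _normalize_columns(w.tocsc())

    for _ in range(max_iter):
        prev = m.copy()
        m = (m @ m).tocsc()                       # expansion
        m = m.power(inflation)                    # inflation
        m = _normalize_columns(m)
        if prune_threshold > 0:
            m.data[m.data < prune_threshold] = 0.0
            m.eliminate_zeros()
            m = _normalize_columns(m)
        diff = abs(m - prev)
        if diff.nnz == 0 or diff.max() < tol:
            break

    return _read_clusters(nodes, m.tocsr())


def _read_clusters(nodes: list[str], m: sp.csr_matrix) -> list[frozenset[str]]:
    """Interpret the converged matrix: attractors are rows with a nonzero
    diagonal; each node joins the attractor system(s) that flow into it.
    Overlaps are resolved toward the family with the smallest member."""
    n = len(nodes)
    diag = m.diagonal()
    attractors = np.flatnonzero(diag > 0)
    if attractors.size == 0:       # degenerate; fall back to singletons
        return [frozenset([x]) for x in nodes]

    # Attractor systems: attractors sharing support belong to one cluster.
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(int(a) for a in attractors)
    aset = set(int(a) for a in attractors)
    for a in attractors:
        row = m.getrow(int(a))
        for j in row.indices:
            if int(j) in aset and int(j) != int(a):
                g.add_edge(int(a), int(j))
    systems = [sorted(c) for c in nx.connected_components(g)]
    sys_of_attractor = {}
    for si, members in enumerate(systems):
        for a in members:
            sys_of_attractor[a] = si

    clusters: list[set[int]] = [set(s) for s in systems]
    assigned: dict[int, int] = {}
    for si, members in enumerate(clusters):
        for a in members:
            assigned[a] = si
    # Non-attractor node j flows to attractor a iff m[a, j] > 0.
    mc = m.tocsc()
    for j in range(n):
        if j in assigned:
            continue
        col = mc.getcol(j)
        cands = sorted({sys_of_attractor[int(i)] for i in col.indices
                        if int(i) in sys_of_attractor})
        if not cands:
            clusters.append({j})
            assigned[j] = len(clusters) - 1
            continue
        if len(cands) > 1:
            # deterministic tie-break: smallest member name wins
            cands.sort(key=lambda si: min(nodes[i] for i in clusters[si]))
        clusters[cands[0]].add(j)
        assigned[j] = cands[0]

    return [frozenset(nodes[i] for i in c) for c in clusters if c]


def mcl(
    graph: SimilarityGraph,
    inflation: float = 2.0,
    max_iter: int = 100,
    prune_threshold: float = 1e-5,
    tol: float = 1e-6,
) -> ClusterRun:
    """Cluster a similarity graph into protein families."""
    nodes = list(graph.nodes)
    if not nodes:
        raise ValueError("empty graph")
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    for (a, b), w in graph.edges.items():
        i, j = index[a], index[b]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    w = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    fams = mcl_partition(nodes, w, inflation=inflation, max_iter=max_iter,
                         prune_threshold=prune_threshold, tol=tol)
    return ClusterRun(
        group=graph.group, method="MCL", metric=graph.metric,
        cutoff=graph.cutoff, inflation=inflation,
        families=canonical_families(fams),
    )


def cluster_stats(run: ClusterRun, store: PangenomeStore) -> pd.DataFrame:
    """Per-family size, genome span and representative annotation.

    The representative annotation is the most frequent annotation string in
    the family; ties break to the lexicographically first.
    """
    rows = []
    for fid in sorted(run.families):
        members = run.families[fid]
        genomes = set()
        annots: dict[str, int] = {}
        for g in sorted(members):
            rec = store.gene(g)
            genomes.add(rec.genome_id)
            annots[rec.annotation] = annots.get(rec.annotation, 0) + 1
        rep = min(annots, key=lambda a: (-annots[a], a)) if annots else ""
        rows.append((fid, len(members), len(genomes), rep))
    return pd.DataFrame(rows, columns=["family_id", "size", "n_genomes",
                                       "representative_annotation"])


def singleton_completion(run: ClusterRun, group_genes: Iterable[str]) -> ClusterRun:
    """Add every group gene missing from the run as its own singleton family.

    Family ids are reassigned canonically over the completed partition so the
    ordering rule (size desc, then smallest member) holds for the whole run.
    """
    clustered = run.all_genes()
    missing = sorted(set(group_genes) - clustered)
    if not missing:
        return run
    fams = list(run.families.values()) + [frozenset([g]) for g in missing]
    return ClusterRun(
        group=run.group, method=run.method, metric=run.metric,
        cutoff=run.cutoff, inflation=run.inflation,
        families=canonical_families(fams),
    )
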