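"""Weighted protein-similarity graphs from all-vs-all BLAST bit scores.

A pairwise bit score B(q,t) is normalized by the proteins' self-alignment
scores to give a symmetric similarity in [0, 1]:

    maxbit(q,t) = B(q,t) / max(B(q,q), B(t,t))
    minbit(q,t) = B(q,t) / min(B(q,q), B(t,t))
    avgbit(q,t) = 2 * B(q,t) / (B(q,q) + B(t,t))

maxbit is the most conservative of the three (it divides by the larger
self-score) and is the default metric throughout; scores are clamped to
[0, 1] because compositional effects can push a raw ratio slightly above 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .store import PangenomeStore, StoreError

__all__ = ["METRICS", "SimilarityGraph", "self_scores", "score_edge", "build_graph"]

logger = logging.getLogger(__name__)

METRICS = ("maxbit", "minbit", "avgbit")


def _metric_value(bit: float, self_q: float, self_t: float, metric: str) -> float:
    if metric == "maxbit":
        return bit / max(self_q, self_t)
    if metric == "minbit":
        return bit / min(self_q, self_t)
    if metric == "avgbit":
        return 2.0 * bit / (self_q + self_t)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def score_edge(bit_score: float, self_q: float, self_t: float, metric: str = "maxbit") -> float:
    """Normalized similarity for one directed hit, clamped to [0, 1]."""
    if self_q <= 0 or self_t <= 0:
        raise ValueError("self-scores must be positive")
    return min(1.0, max(0.0, _metric_value(bit_score, self_q, self_t, metric)))


@dataclass
class SimilarityGraph:
    """Undirected weighted graph over all genes of an organism group.

    Edges are stored once under the sorted id pair; isolated genes remain as
    nodes so that downstream clustering assigns them singleton families.
    """

    nodes: list[str]
    edges: dict[tuple[str, str], float]
    metric: str
    cutoff: float
    group: str = ""

    def weight(self, a: str, b: str) -> float | None:
        return self.edges.get((a, b) if a <= b else (b, a))

    def neighbors(self, a: str) -> list[str]:
        out = []
        for (x, y) in self.edges:
            if x == a:
                out.append(y)
            elif y == a:
                out.append(x)
        return sorted(out)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(metric=self.metric, cutoff=self.cutoff, group=self.group)
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from((a, b, w) for (a, b), w in self.edges.items())
        return g

    @classmethod
    def from_edges(
        cls,
        edges: Mapping[tuple[str, str], float] | Iterable[tuple[str, str, float]],
        nodes: Iterable[str] | None = None,
        metric: str = "maxbit",
        cutoff: float = 0.0,
        group: str = "",
    ) -> "SimilarityGraph":
        if isinstance(edges, Mapping):
            items = [(a, b, w) for (a, b), w in edges.items()]
        else:
            items = list(edges)
        edict: dict[tuple[str, str], float] = {}
        nodeset = set(nodes) if nodes is not None else set()
        for a, b, w in items:
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            edict[key] = max(w, edict.get(key, 0.0))
            nodeset.update((a, b))
        return cls(nodes=sorted(nodeset), edges=edict, metric=metric,
                   cutoff=cutoff, group=group)

    def write_tsv(self, fh) -> None:
        for (a, b), w in sorted(self.edges.items()):
            fh.write(f"{a}\t{b}\t{w:.6g}\n")


def self_scores(store: PangenomeStore, group: str) -> tuple[dict[str, float], dict[str, str]]:
    """Per-gene self-alignment bit scores B(g, g) for a group.

    Genes lacking a stored self-hit fall back to their best observed bit score
    over any hit (flagged "fallback" in the report); genes with no hits at all
    are excluded from the map and flagged "no_hits".
    """
    genes = store.group_genes(group)
    geneset = set(genes)
    best: dict[str, float] = {}
    selfs: dict[str, float] = {}
    for e in store.blast_edges(genes):
        if e.query_id == e.subject_id:
            selfs[e.query_id] = max(selfs.get(e.query_id, 0.0), e.bit_score)
        for gid in (e.query_id, e.subject_id):
            if gid in geneset:
                best[gid] = max(best.get(gid, 0.0), e.bit_score)
    scores: dict[str, float] = {}
    report: dict[str, str] = {}
    for g in genes:
        if g in selfs:
            scores[g] = selfs[g]
        elif g in best:
            scores[g] = best[g]
            report[g] = "fallback"
            logger.info("gene %s: no self-hit; using best observed bit %.1f", g, best[g])
        else:
            report[g] = "no_hits"
    return scores, report


def build_graph(
    store: PangenomeStore,
    group: str,
    metric: str = "maxbit",
    cutoff: float = 0.3,
) -> SimilarityGraph:
    """Build the filtered similarity graph for a group.

    Directed scores are symmetrized by the maximum of the two directions;
    edges below the cutoff are dropped; every group gene stays as a node.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in (0, 1], got {cutoff}")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    genes = store.group_genes(group)
    if not genes:
        raise StoreError(f"group {group} has no genes")
    scores, _report = self_scores(store, group)
    edges: dict[tuple[str, str], float] = {}
    for e in store.blast_edges(genes):
        if e.query_id == e.subject_id:
            continue
        if e.query_id not in scores or e.subject_id not in scores:
            continue
        w = score_edge(e.bit_score, scores[e.query_id], scores[e.subject_id], metric)
        key = (e.query_id, e.subject_id) if e.query_id <= e.subject_id \
            else (e.subject_id, e.query_id)
        edges[key] = max(w, edges.get(key, 0.0))
    edges = {k: w for k, w in edges.items() if w >= cutoff}
    return SimilarityGraph(nodes=sorted(genes), edges=edges, metric=metric,
                           cutoff=cutoff, group=group)
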